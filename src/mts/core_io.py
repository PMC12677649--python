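"""Domain containers and tab-separated I/O shared across the pipeline.

The analysis revolves around paired soil surveys: each sampling site
contributes one nutrient-poor open-field (OF) sample and one or more
nutrient-rich greenhouse (GH) samples.  Everything downstream (trait
inference, assembly null models, paired contrasts) consumes the containers
defined here.

All tables are tab-separated UTF-8 with a single header row.  Abundance
inputs may be counts or proportions; rows are always renormalized to
relative abundances on read.  Missing taxonomy ranks are encoded as empty
strings and may only occur as a contiguous tail of the lineage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("mts")

#: Canonical rank order, highest to lowest.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Allowed cultivation-system labels: open field (nutrient poor) and
#: greenhouse (nutrient rich).
SYSTEMS = ("OF", "GH")

#: Soil physicochemical variables carried per sample.  EC in µS cm⁻¹,
#: nutrient concentrations (NH4, NO3, AP, AK) in mg kg⁻¹, SOM in g kg⁻¹.
SOIL_VARS = ("pH", "EC", "SOM", "NH4", "NO3", "AP", "AK")

#: The four plant-available nutrient pools averaged into the NPK delta.
NUTRIENT_VARS = ("NH4", "NO3", "AP", "AK")


class MtsError(ValueError):
    """Raised on contract violations in inputs or configuration."""


def normalize_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Renormalize each row of a nonnegative table to sum to one."""
    arr = matrix.to_numpy(dtype=float)
    if (arr < 0).any():
        bad = matrix.index[(arr < 0).any(axis=1)][0]
        raise MtsError(f"negative abundance in sample {bad!r}")
    sums = arr.sum(axis=1)
    if (sums <= 0).any():
        bad = matrix.index[sums <= 0][0]
        raise MtsError(f"all-zero abundance row for sample {bad!r}")
    return matrix.div(pd.Series(sums, index=matrix.index), axis=0)


@dataclass
class CommunitySurvey:
    """Sample × taxon relative abundances with per-sample site metadata.

    ``abundance`` is indexed by sample id (rows) and taxon id (columns);
    every row sums to one.  ``meta`` is indexed by sample id and carries
    ``site_id``, ``system`` (OF/GH), ``latitude``, ``longitude`` and the
    soil variables in :data:`SOIL_VARS`.
    """

    abundance: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if self.abundance.index.has_duplicates:
            dups = self.abundance.index[self.abundance.index.duplicated()]
            raise MtsError(f"duplicate sample ids: {sorted(set(dups))}")
        missing = set(self.abundance.index) ^ set(self.meta.index)
        if missing:
            raise MtsError(f"samples present in only one table: {sorted(missing)}")
        self.meta = self.meta.loc[self.abundance.index]
        bad = ~self.meta["system"].isin(SYSTEMS)
        if bad.any():
            sample = self.meta.index[bad][0]
            label = self.meta.loc[sample, "system"]
            raise MtsError(
                f"sample {sample!r} has unknown system {label!r}; "
                f"allowed labels are {set(SYSTEMS)}"
            )
        arr = self.abundance.to_numpy(dtype=float)
        if (arr < 0).any():
            raise MtsError("negative abundances")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
            raise MtsError("abundance rows must sum to 1 (renormalize first)")

    # -- convenience ------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.abundance.columns)

    def subset(self, samples: Sequence[str]) -> "CommunitySurvey":
        return CommunitySurvey(
            self.abundance.loc[list(samples)].copy(), self.meta.loc[list(samples)].copy()
        )

    def pairs(self) -> list[tuple[str, str]]:
        """Resolve (GH sample, OF sample) pairs via shared ``site_id``.

        Each GH sample pairs with its site's single OF sample; a site may
        contribute several GH samples and hence several pairs.
        """
        of = self.meta[self.meta["system"] == "OF"]
        gh = self.meta[self.meta["system"] == "GH"]
        of_by_site: dict[str, str] = {}
        for sample, row in of.iterrows():
            site = row["site_id"]
            if site in of_by_site:
                raise MtsError(f"site {site!r} has more than one OF sample")
            of_by_site[site] = sample
        out = []
        for sample, row in gh.iterrows():
            site = row["site_id"]
            if site not in of_by_site:
                raise MtsError(f"GH sample {sample!r}: site {site!r} has no OF sample")
            out.append((sample, of_by_site[site]))
        return out


@dataclass
class TaxonomyTable:
    """Per-taxon ranked lineage; missing names only as a contiguous tail."""

    lineage: pd.DataFrame  # index taxon id, columns = RANKS

    def __post_init__(self) -> None:
        missing_cols = [r for r in RANKS if r not in self.lineage.columns]
        if missing_cols:
            raise MtsError(f"taxonomy missing rank columns: {missing_cols}")
        self.lineage = self.lineage[list(RANKS)].fillna("").astype(str)
        filled = (self.lineage != "").to_numpy()
        # a named rank below an unnamed one means a mid-lineage gap
        for i, taxon in enumerate(self.lineage.index):
            row = filled[i]
            if row.any() and not row[: row.sum()].all():
                raise MtsError(f"taxon {taxon!r}: mid-lineage gap in ranks")

    def names_at(self, rank: str) -> pd.Series:
        return self.lineage[rank]


@dataclass
class TraitReference:
    """Rank-indexed taxon → trait lookup (rrnDB-like).

    Rows of (name, rank, trait, value); duplicates of the same key are
    collapsed by arithmetic mean on construction.
    """

    table: pd.DataFrame  # columns: name, rank, trait, value

    def __post_init__(self) -> None:
        required = {"name", "rank", "trait", "value"}
        if not required.issubset(self.table.columns):
            raise MtsError(f"trait reference needs columns {sorted(required)}")
        bad_rank = ~self.table["rank"].isin(RANKS)
        if bad_rank.any():
            raise MtsError(
                f"unknown ranks in trait reference: {sorted(set(self.table.loc[bad_rank, 'rank']))}"
            )
        counts = self.table["trait"].str.endswith("copy_number")
        if (self.table.loc[counts, "value"].astype(float) <= 0).any():
            raise MtsError("count-like trait values must be > 0")
        dup = self.table.duplicated(subset=["name", "rank", "trait"], keep=False)
        if dup.any():
            logger.warning(
                "trait reference: %d duplicate (name, rank, trait) rows collapsed by mean",
                int(dup.sum()),
            )
        self.table = (
            self.table.groupby(["name", "rank", "trait"], as_index=False, sort=False)["value"]
            .mean()
        )

    def lookup(self, name: str, rank: str, trait: str) -> float | None:
        hit = self.table[
            (self.table["name"] == name)
            & (self.table["rank"] == rank)
            & (self.table["trait"] == trait)
        ]
        if hit.empty:
            return None
        return float(hit["value"].iloc[0])

    def entries(self, trait: str) -> pd.DataFrame:
        return self.table[self.table["trait"] == trait]


@dataclass
class MetagenomeSummary:
    """Per-sample assembled-metagenome coverage summary.

    ``genes`` has columns (gene_id, category, coverage, annotated_bp,
    gene_length): single-copy-marker rows carry per-gene coverage (×),
    16S rows carry annotated base pairs, other rows may carry either.
    ``total_bp`` is the total assembled base pairs of the sample.
    """

    sample_id: str
    total_bp: float
    genes: pd.DataFrame
    marker_set_size: int = 35

    def __post_init__(self) -> None:
        if self.total_bp <= 0:
            raise MtsError(f"sample {self.sample_id!r}: total_bp must be > 0")
        required = {"gene_id", "category", "coverage", "annotated_bp", "gene_length"}
        if not required.issubset(self.genes.columns):
            raise MtsError(f"metagenome summary needs columns {sorted(required)}")
        markers = self.marker_rows()
        if markers["gene_id"].nunique() != self.marker_set_size:
            raise MtsError(
                f"sample {self.sample_id!r}: expected {self.marker_set_size} distinct "
                f"single-copy marker genes, found {markers['gene_id'].nunique()}"
            )
        if (markers["coverage"].astype(float) < 0).any():
            raise MtsError("negative marker coverage")

    def marker_rows(self) -> pd.DataFrame:
        return self.genes[self.genes["category"] == "single_copy_marker"]

    def rrna_rows(self) -> pd.DataFrame:
        return self.genes[self.genes["category"] == "rrna_16S"]


@dataclass
class CodingSequenceSet:
    """Predicted coding sequences with highly-expressed flags and coverages.

    ``genes`` columns: gene_id, sequence (A/C/G/T, length divisible by 3),
    is_highly_expressed (ribosomal-protein flag), coverage (≥ 0).
    """

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "sequence", "is_highly_expressed", "coverage"}
        if not required.issubset(self.genes.columns):
            raise MtsError(f"coding sequence set needs columns {sorted(required)}")
        seqs = self.genes["sequence"].astype(str)
        if not (seqs.str.len() % 3 == 0).all():
            raise MtsError("sequence lengths must be divisible by 3")
        if not seqs.str.fullmatch("[ACGT]*").all():
            raise MtsError("sequences must use alphabet {A,C,G,T}")
        heg = self.genes["is_highly_expressed"].astype(bool)
        if not heg.any() or heg.all():
            raise MtsError("need at least one highly expressed and one background gene")
        if (self.genes["coverage"].astype(float) < 0).any():
            raise MtsError("coverage weights must be >= 0")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_survey(
    abundance_path: str | Path,
    metadata_path: str | Path,
    taxonomy_path: str | Path | None = None,
) -> tuple[CommunitySurvey, TaxonomyTable | None]:
    """Read a community survey (and optional taxonomy) from TSV files.

    The abundance table has samples as rows and taxa as columns; values may
    be counts or proportions and are renormalized per row.  All-zero taxa
    are dropped with a log line.
    """
    abundance = pd.read_csv(abundance_path, sep="\t", index_col=0)
    abundance.index = abundance.index.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    for col in ("system", "site_id"):
        if col not in meta.columns:
            raise MtsError(f"metadata missing required column {col!r}")
    zero_taxa = abundance.columns[(abundance == 0).all(axis=0)]
    if len(zero_taxa):
        logger.info("dropping %d all-zero taxa", len(zero_taxa))
        abundance = abundance.drop(columns=zero_taxa)
    survey = CommunitySurvey(normalize_rows(abundance), meta)
    taxonomy = None
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0, keep_default_na=False)
        tax.index = tax.index.astype(str)
        taxonomy = TaxonomyTable(tax)
    return survey, taxonomy


def write_survey(
    survey: CommunitySurvey,
    abundance_path: str | Path,
    metadata_path: str | Path,
    taxonomy: TaxonomyTable | None = None,
    taxonomy_path: str | Path | None = None,
) -> None:
    survey.abundance.rename_axis("sample_id").to_csv(abundance_path, sep="\t")
    survey.meta.rename_axis("sample_id").to_csv(metadata_path, sep="\t")
    if taxonomy is not None and taxonomy_path is not None:
        taxonomy.lineage.rename_axis("taxon_id").to_csv(taxonomy_path, sep="\t")


def read_trait_reference(path: str | Path) -> TraitReference:
    table = pd.read_csv(path, sep="\t", keep_default_na=False)
    table["value"] = pd.to_numeric(table["value"])
    return TraitReference(table)


def write_trait_reference(reference: TraitReference, path: str | Path) -> None:
    reference.table.to_csv(path, sep="\t", index=False)


def read_metagenome_summary(path: str | Path) -> MetagenomeSummary:
    """Read one sample's coverage summary from TSV.

    The header comment lines ``# sample_id=...``, ``# total_bp=...`` and
    optionally ``# marker_set_size=...`` precede the gene table.
    """
    header: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            header[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    genes = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    return MetagenomeSummary(
        sample_id=header.get("sample_id", Path(path).stem),
        total_bp=float(header["total_bp"]),
        genes=genes,
        marker_set_size=int(header.get("marker_set_size", 35)),
    )


def write_metagenome_summary(summary: MetagenomeSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_id={summary.sample_id}\n")
        fh.write(f"# total_bp={summary.total_bp!r}\n")
        fh.write(f"# marker_set_size={summary.marker_set_size}\n")
        summary.genes.to_csv(fh, sep="\t", index=False)


def read_coding_sequences(path: str | Path) -> CodingSequenceSet:
    """Read coding sequences from FASTA.

    Per-gene attributes ride in the description as ``key=value`` tokens:
    ``heg=1`` flags a highly expressed (ribosomal protein) gene and
    ``coverage=...`` carries the read-coverage weight.
    """
    from Bio import SeqIO

    rows = []
    for record in SeqIO.parse(str(path), "fasta"):
        attrs = dict(
            token.split("=", 1) for token in record.description.split()[1:] if "=" in token
        )
        rows.append(
            {
                "gene_id": record.id,
                "sequence": str(record.seq).upper(),
                "is_highly_expressed": attrs.get("heg", "0") == "1",
                "coverage": float(attrs.get("coverage", 1.0)),
            }
        )
    if not rows:
        raise MtsError(f"no sequences in {path}")
    return CodingSequenceSet(pd.DataFrame(rows))


def write_coding_sequences(cds: CodingSequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in cds.genes.itertuples(index=False):
            heg = 1 if row.is_highly_expressed else 0
            fh.write(f">{row.gene_id} heg={heg} coverage={row.coverage!r}\n")
            seq = row.sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_tree(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise MtsError("negative branch length in tree")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tree_distance_matrix(tree: dendropy.Tree, taxa: Sequence[str]) -> np.ndarray:
    """Patristic tip-to-tip distance matrix aligned to ``taxa`` order."""
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [t for t in taxa if t not in labels]
    if missing:
        raise MtsError(f"taxa missing from tree tips: {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    pdm = tree.phylogenetic_distance_matrix()
    index = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    out = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(index[a], index[taxa[j]])
            out[i, j] = out[j, i] = d
    return out


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        stream=__import__("sys").stderr,
    )
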