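"""Community life-history-trait inference.

Two routes are implemented:

* **Amplicon route** — per-taxon rrn operon copy numbers are imputed from a
  rank-indexed reference (rrnDB-like) by hierarchical matching from the
  lowest rank upward, then averaged per sample weighted by relative
  abundance.

* **Metagenome route** — the genome count of a sample is the mean coverage
  of 35 universal single-copy marker genes; average genome size (AGS) is
  total assembled bp / genome count, average 16S copy number (ACN) is 16S
  gene coverage / genome count.  Maximum growth rate comes from the codon
  usage bias (MILC) of highly expressed ribosomal-protein genes mapped
  through a log-linear minimum-generation-time calibration and inverted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    RANKS,
    CodingSequenceSet,
    CommunitySurvey,
    MetagenomeSummary,
    MtsError,
    TaxonomyTable,
    TraitReference,
)
from .synthetic import BACKGROUND_CODON_WEIGHTS, CODON_FAMILIES

logger = logging.getLogger("mts")

#: Imputation search order: lowest rank first.
IMPUTE_ORDER = tuple(reversed(RANKS))  # species ... domain

#: Default copiotroph/oligotroph phylum lists (r- vs K-strategists).
DEFAULT_COPIOTROPH_PHYLA = frozenset({"Proteobacteria", "Firmicutes", "Bacteroidota"})
DEFAULT_OLIGOTROPH_PHYLA = frozenset({"Chloroflexi", "Acidobacteriota", "Nitrospirota"})


@dataclass
class TraitAssignment:
    """Per-taxon imputed trait values with match rank and provenance."""

    table: pd.DataFrame  # index taxon id; columns value, rank, provenance
    trait: str

    def values_for(self, taxa: list[str]) -> np.ndarray:
        return self.table.loc[taxa, "value"].to_numpy(dtype=float)


def impute_trait(
    taxonomy: TaxonomyTable,
    reference: TraitReference,
    trait: str = "rrn_copy_number",
    start_rank: str = "species",
) -> TraitAssignment:
    """Hierarchically impute a trait for every taxon in the taxonomy.

    For each taxon, ranks are tried from ``start_rank`` upward.  At each
    rank, a direct reference entry for the taxon's name at that rank wins;
    failing that, if reference entries exist for taxa that the community
    taxonomy places below that name, their arithmetic mean is assigned
    (provenance ``parent_mean``).  Taxa unmatched at every rank receive the
    global mean of all reference values for the trait (``global_mean``).
    """
    entries = reference.entries(trait)
    if entries.empty:
        raise MtsError(f"trait reference has no entries for trait {trait!r}")
    global_mean = float(entries["value"].mean())
    direct = {
        (row.name_, row.rank_): float(row.value)
        for row in entries.rename(columns={"name": "name_", "rank": "rank_"}).itertuples()
    }

    order = IMPUTE_ORDER[IMPUTE_ORDER.index(start_rank):]
    lineage = taxonomy.lineage

    # descendant names per (ancestor rank, ancestor name): the set of
    # (name, rank) pairs occurring below it anywhere in the community taxonomy
    descendants: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for _, row in lineage.iterrows():
        named = [(rank, row[rank]) for rank in RANKS if row[rank] != ""]
        for i, (arank, aname) in enumerate(named):
            bucket = descendants.setdefault((arank, aname), set())
            for drank, dname in named[i + 1:]:
                bucket.add((dname, drank))

    records = {}
    n_global = 0
    for taxon, row in lineage.iterrows():
        assigned = None
        for rank in order:
            name = row[rank]
            if name == "":
                continue
            if (name, rank) in direct:
                assigned = (direct[(name, rank)], rank, "direct")
                break
            child_vals = [
                direct[key] for key in descendants.get((rank, name), ()) if key in direct
            ]
            if child_vals:
                assigned = (float(np.mean(child_vals)), rank, "parent_mean")
                break
        if assigned is None:
            assigned = (global_mean, "global", "global_mean")
            n_global += 1
        records[taxon] = {"value": assigned[0], "rank": assigned[1], "provenance": assigned[2]}
    if n_global:
        logger.info("impute_trait(%s): %d/%d taxa fell back to the global mean",
                    trait, n_global, len(records))
    table = pd.DataFrame.from_dict(records, orient="index")
    return TraitAssignment(table, trait)


def community_weighted_trait(
    survey: CommunitySurvey, assignment: TraitAssignment
) -> pd.Series:
    """Per-sample abundance-weighted mean trait, Σᵢ pᵢ·tᵢ.

    Abundances are renormalized over the assigned taxa so the result is a
    proper weighted mean even if the assignment covers a subset.
    """
    taxa = [t for t in survey.taxa if t in assignment.table.index]
    missing = [
        t for t in survey.taxa
        if t not in assignment.table.index and (survey.abundance[t] > 0).any()
    ]
    if missing:
        raise MtsError(f"taxa with nonzero abundance lack trait assignments: {missing[:5]}")
    sub = survey.abundance[taxa].to_numpy(dtype=float)
    sums = sub.sum(axis=1)
    if (sums <= 0).any():
        bad = survey.abundance.index[sums <= 0][0]
        raise MtsError(f"sample {bad!r} has zero total abundance over assigned taxa")
    weights = sub / sums[:, None]
    values = assignment.values_for(taxa)
    out = pd.Series(weights @ values, index=survey.abundance.index, name=assignment.trait)
    return out


# ---------------------------------------------------------------------------
# Metagenome-derived traits
# ---------------------------------------------------------------------------

def genome_count(summary: MetagenomeSummary) -> float:
    """Estimated genome count: arithmetic mean single-copy-marker coverage."""
    markers = summary.marker_rows()
    cov = markers["coverage"].astype(float)
    if cov.isna().any():
        bad = markers.loc[cov.isna(), "gene_id"].tolist()
        raise MtsError(f"markers missing coverage: {bad}")
    if (cov == 0).any():
        logger.warning("sample %s: %d marker(s) with zero coverage retained in the mean",
                       summary.sample_id, int((cov == 0).sum()))
    return float(cov.mean())


def coverage_16S(summary: MetagenomeSummary, gene_length: float = 1550.0) -> float:
    """16S gene coverage: summed annotated base pairs / reference gene length."""
    if gene_length <= 0:
        raise MtsError("16S gene length must be > 0")
    rows = summary.rrna_rows()
    if rows.empty:
        logger.warning("sample %s: no 16S rows; coverage reported as 0", summary.sample_id)
        return 0.0
    return float(rows["annotated_bp"].astype(float).sum() / gene_length)


def average_16S_copy_number(summary: MetagenomeSummary, gene_length: float = 1550.0) -> float:
    """ACN = 16S coverage / genome count."""
    n_genomes = genome_count(summary)
    if n_genomes <= 0:
        raise MtsError(f"sample {summary.sample_id!r}: genome count is zero")
    return coverage_16S(summary, gene_length) / n_genomes


def average_genome_size(summary: MetagenomeSummary) -> float:
    """AGS (bp) = total assembled base pairs / genome count."""
    if summary.total_bp <= 0:
        raise MtsError("total_bp must be > 0")
    n_genomes = genome_count(summary)
    if n_genomes <= 0:
        raise MtsError(f"sample {summary.sample_id!r}: genome count is zero")
    return summary.total_bp / n_genomes


# ---------------------------------------------------------------------------
# Codon usage bias (MILC) and growth rate
# ---------------------------------------------------------------------------

_CODON_TO_AA = {c: aa for aa, codons in CODON_FAMILIES.items() for c in codons}


def _codon_counts(sequence: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(0, len(sequence) - 2, 3):
        codon = sequence[i : i + 3]
        if codon in _CODON_TO_AA:  # stop codons and ambiguous triplets ignored
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def _background_frequencies(cds: CodingSequenceSet) -> dict[str, float]:
    """Within-amino-acid codon frequencies pooled over all genes."""
    totals: dict[str, float] = {}
    for seq in cds.genes["sequence"]:
        for codon, n in _codon_counts(seq).items():
            totals[codon] = totals.get(codon, 0.0) + n
    freqs: dict[str, float] = {}
    for aa, codons in CODON_FAMILIES.items():
        fam_total = sum(totals.get(c, 0.0) for c in codons)
        for c in codons:
            if fam_total > 0:
                freqs[c] = totals.get(c, 0.0) / fam_total
            else:
                freqs[c] = 1.0 / len(codons)
    return freqs


def milc(sequence: str, background: dict[str, float]) -> float | None:
    """MILC statistic of one gene against background codon frequencies.

    Mₐ = 2 Σ_c o_c ln(f_c / e_c) summed over the synonymous codons of amino
    acid a (o observed counts, f within-family observed frequencies, e
    background frequencies); MILC = (Σₐ Mₐ)/L − C with length correction
    C = Σₐ (rₐ − 1) / L over amino acids present.  Genes with no usable
    codons return None.
    """
    counts = _codon_counts(sequence)
    L = sum(counts.values())
    if L == 0:
        return None
    total_m = 0.0
    correction_df = 0.0
    for aa, codons in CODON_FAMILIES.items():
        fam_counts = np.array([counts.get(c, 0) for c in codons], dtype=float)
        n_aa = fam_counts.sum()
        if n_aa == 0:
            continue
        f = fam_counts / n_aa
        e = np.array([max(background[c], 1e-12) for c in codons])
        nz = fam_counts > 0
        total_m += 2.0 * float((fam_counts[nz] * np.log(f[nz] / e[nz])).sum())
        correction_df += len(codons) - 1
    return total_m / L - correction_df / L


def codon_usage_bias(
    cds: CodingSequenceSet, min_codons: int = 80
) -> tuple[pd.DataFrame, float]:
    """Per-gene MILC values and the coverage-weighted community CUB.

    The community statistic is the coverage-weighted mean MILC over highly
    expressed (ribosomal protein) genes, with background expectations
    computed from all genes.  Genes shorter than ``min_codons`` usable
    codons are flagged; genes with zero usable codons are excluded.
    """
    background = _background_frequencies(cds)
    rows = []
    for row in cds.genes.itertuples(index=False):
        value = milc(row.sequence, background)
        if value is None:
            logger.warning("gene %s: no usable codons, excluded from CUB", row.gene_id)
            continue
        n_codons = sum(_codon_counts(row.sequence).values())
        if n_codons < min_codons:
            logger.warning("gene %s: only %d usable codons (< %d), CUB unstable",
                           row.gene_id, n_codons, min_codons)
        rows.append({"gene_id": row.gene_id, "milc": value,
                     "is_highly_expressed": bool(row.is_highly_expressed),
                     "coverage": float(row.coverage)})
    table = pd.DataFrame(rows)
    heg = table[table["is_highly_expressed"]]
    if heg.empty:
        raise MtsError("no usable highly expressed genes for community CUB")
    w = heg["coverage"].to_numpy()
    if w.sum() <= 0:
        w = np.ones(len(heg))
    community = float(np.average(heg["milc"], weights=w))
    return table, community


@dataclass
class GrowthEstimate:
    """Community CUB with the implied minimum generation time and μmax."""

    sample_id: str
    cub: float
    min_generation_h: float
    max_growth_rate_per_h: float


def max_growth_rate(
    community_cub: float,
    calibration: tuple[float, float] = (1.5, -3.0),
    sample_id: str = "S0",
) -> GrowthEstimate:
    """Map community CUB to maximum growth rate.

    Minimum generation time d = exp(b0 + b1·CUB) with b1 < 0 (stronger
    ribosomal-protein codon bias ⇒ shorter generation time), and
    μmax = 1/d.  The default (b0, b1) is illustrative and should be
    replaced by published calibration constants when absolute rates
    matter; all in-package uses rely only on monotonicity.
    """
    b0, b1 = calibration
    if b1 >= 0:
        raise MtsError("growth calibration slope b1 must be < 0")
    d = float(np.exp(b0 + b1 * community_cub))
    return GrowthEstimate(sample_id, community_cub, d, 1.0 / d)


def classify_strategy(
    taxonomy: TaxonomyTable,
    copiotroph_phyla: frozenset[str] = DEFAULT_COPIOTROPH_PHYLA,
    oligotroph_phyla: frozenset[str] = DEFAULT_OLIGOTROPH_PHYLA,
) -> pd.Series:
    """Phylum-level copiotroph/oligotroph (r/K) classification."""
    overlap = set(copiotroph_phyla) & set(oligotroph_phyla)
    if overlap:
        raise MtsError(f"phyla listed as both copiotroph and oligotroph: {sorted(overlap)}")
    phyla = taxonomy.names_at("phylum")
    out = pd.Series("unclassified", index=phyla.index, name="strategy")
    out[phyla.isin(copiotroph_phyla)] = "copiotroph"
    out[phyla.isin(oligotroph_phyla)] = "oligotroph"
    return out
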