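"""Synthetic survey, metagenome, coding-sequence and assembly generators.

These generators provide ground-truth-bearing inputs for every downstream
stage: paired open-field (OF) / greenhouse (GH) surveys in which elevated
NPK shifts community mass toward fast-growing copiotrophs, metagenome
coverage summaries that the average-genome-size and 16S-copy-number
estimators must invert, codon-usage-biased gene sets, and neutral- or
selection-driven community assembly scenarios on a phylogeny.

Every generator is a pure function of its parameters and seed; ground
truth is always emitted alongside the data so tests never reach into
generator internals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .core_io import (
    NUTRIENT_VARS,
    RANKS,
    CodingSequenceSet,
    CommunitySurvey,
    MetagenomeSummary,
    MtsError,
    TaxonomyTable,
    TraitReference,
)

logger = logging.getLogger("mts")

# Copiotroph / oligotroph phylum pools; community-mean rrn copy numbers of
# the copiotroph phyla sit around 2.5 (Proteobacteria), 9.7 (Firmicutes)
# and 3.8 (Bacteroidota), oligotrophs around 1.2-2.6.
COPIOTROPH_PHYLA = ("Proteobacteria", "Firmicutes", "Bacteroidota")
OLIGOTROPH_PHYLA = ("Chloroflexi", "Acidobacteriota", "Nitrospirota")

# GH / OF multiplicative nutrient shifts (fold = 1 + printed % increase):
# NH4 +88.4%, NO3 +681.6%, AP +211.6%, AK +125.7%, EC +139.3%; pH and SOM
# show no systematic difference between systems.
GH_NUTRIENT_FOLD = {"NH4": 1.884, "NO3": 7.816, "AP": 3.116, "AK": 2.257}
GH_EC_FOLD = 2.393

# OF baseline soil levels (lognormal medians): NH4/NO3/AP/AK in mg kg⁻¹,
# EC in µS cm⁻¹, SOM in g kg⁻¹.
OF_BASELINE = {"NH4": 10.0, "NO3": 20.0, "AP": 30.0, "AK": 120.0, "EC": 150.0, "SOM": 20.0}


@dataclass
class SyntheticSpec:
    """Parameters of the paired-survey generator.

    ``theta`` is the log-odds shift of copiotroph community mass per unit
    of delta-NPK (the mean log10 GH/OF nutrient ratio); positive values
    reproduce the copiotroph enrichment of nutrient-rich soils.
    ``trait_coupling`` in [0, 1] scales how strongly rrn copy number,
    genome size and doubling time track the copiotroph/oligotroph split.
    """

    n_sites: int = 20
    n_taxa: int = 120
    copiotroph_fraction: float = 0.3
    theta: float = 2.0
    dispersion: float = 300.0
    trait_coupling: float = 1.0
    reference_coverage: float = 0.7  # fraction of genera with a direct rrn entry
    read_depth: int = 5000  # reads per sample; finite depth keeps tables sparse
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta):
            raise MtsError("theta must be finite")
        if not (0 <= self.copiotroph_fraction <= 1):
            raise MtsError("copiotroph_fraction must be in [0, 1]")
        if self.n_taxa < 2:
            raise MtsError("need at least 2 taxa")
        if self.seed is None:
            raise MtsError("seed is mandatory")


def _taxon_traits(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-taxon ground-truth traits coupled to life-history strategy."""
    n = spec.n_taxa
    n_cop = int(round(n * spec.copiotroph_fraction))
    strategy = np.array(["copiotroph"] * n_cop + ["oligotroph"] * (n - n_cop))
    rng.shuffle(strategy)
    is_cop = strategy == "copiotroph"
    c = spec.trait_coupling

    # strategy-conditional means, linearly mixed toward the pooled mean as
    # coupling weakens
    rrn_mu = np.where(is_cop, 6.0, 1.8)
    size_mu = np.where(is_cop, 4.0e6, 6.0e6)
    dt_mu = np.where(is_cop, 1.0, 8.0)
    rrn_mu = c * rrn_mu + (1 - c) * rrn_mu.mean()
    size_mu = c * size_mu + (1 - c) * size_mu.mean()
    dt_mu = c * dt_mu + (1 - c) * dt_mu.mean()

    rrn = np.clip(rrn_mu * rng.lognormal(0.0, 0.25, n), 1.0, 15.0)
    genome_size = np.clip(size_mu * rng.lognormal(0.0, 0.10, n), 1.5e6, 1.2e7)
    doubling_time = np.clip(dt_mu * rng.lognormal(0.0, 0.30, n), 0.3, 48.0)
    return pd.DataFrame(
        {
            "taxon_id": [f"t{i:04d}" for i in range(n)],
            "strategy": strategy,
            "rrn_copy_number": rrn,
            "genome_size_bp": genome_size,
            "doubling_time_h": doubling_time,
        }
    ).set_index("taxon_id")


def _taxonomy(traits: pd.DataFrame, rng: np.random.Generator) -> TaxonomyTable:
    """Balanced artificial lineage: strategy phyla → families → genera."""
    rows = {}
    counters: dict[str, int] = {}
    for taxon, row in traits.iterrows():
        pool = COPIOTROPH_PHYLA if row["strategy"] == "copiotroph" else OLIGOTROPH_PHYLA
        k = counters.setdefault(row["strategy"], 0)
        counters[row["strategy"]] += 1
        phylum = pool[k % len(pool)]
        family_idx = k // 8  # 2 genera x 4 taxa per family
        genus_idx = k // 4
        lineage = {
            "domain": "Bacteria",
            "phylum": phylum,
            "class": f"{phylum}_c1",
            "order": f"{phylum}_o{family_idx % 2 + 1}",
            "family": f"{phylum}_f{family_idx}",
            "genus": f"{phylum}_g{genus_idx}",
            # 30% of taxa resolve to species level
            "species": f"{phylum}_g{genus_idx}_s{k % 4}" if rng.random() < 0.3 else "",
        }
        rows[taxon] = lineage
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))


def _trait_reference(
    traits: pd.DataFrame, taxonomy: TaxonomyTable, spec: SyntheticSpec, rng: np.random.Generator
) -> TraitReference:
    """rrnDB-like reference: direct entries for most genera, all phyla."""
    rows = []
    lineage = taxonomy.lineage
    for genus, members in lineage.groupby("genus").groups.items():
        if genus == "":
            continue
        if rng.random() < spec.reference_coverage:
            value = float(traits.loc[list(members), "rrn_copy_number"].mean())
            rows.append({"name": genus, "rank": "genus", "trait": "rrn_copy_number",
                         "value": max(value * rng.lognormal(0.0, 0.05), 1.0)})
    for phylum, members in lineage.groupby("phylum").groups.items():
        value = float(traits.loc[list(members), "rrn_copy_number"].mean())
        rows.append({"name": phylum, "rank": "phylum", "trait": "rrn_copy_number",
                     "value": max(value, 1.0)})
    # genus-level plant-beneficial annotations on a third of copiotroph genera
    cop_genera = sorted(
        set(lineage.loc[traits["strategy"] == "copiotroph", "genus"]) - {""}
    )
    for genus in cop_genera[:: 3]:
        rows.append({"name": genus, "rank": "genus", "trait": "plant_beneficial", "value": 1.0})
    return TraitReference(pd.DataFrame(rows))


def simulate_survey(
    spec: SyntheticSpec,
) -> tuple[CommunitySurvey, TaxonomyTable, TraitReference, pd.DataFrame]:
    """Generate a paired OF/GH survey with known per-taxon traits.

    For each site one OF and one GH sample are drawn.  GH nutrient
    concentrations are stochastically higher; the community composition is
    Dirichlet around expected proportions whose copiotroph mass is shifted
    by ``theta`` x the sample's delta-NPK relative to the OF baseline.

    Returns (survey, taxonomy, trait_reference, truth) where ``truth`` has
    one row per sample with the expected community-weighted traits.
    """
    rng = np.random.default_rng(spec.seed)
    logger.info("simulate_survey: seed=%d n_sites=%d n_taxa=%d", spec.seed, spec.n_sites, spec.n_taxa)
    traits = _taxon_traits(spec, rng)
    taxonomy = _taxonomy(traits, rng)
    reference = _trait_reference(traits, taxonomy, spec, rng)

    is_cop = (traits["strategy"] == "copiotroph").to_numpy()
    # lognormal base composition; copiotroph abundances are more uneven
    # (nutrient-driven blooms are dominated by a few taxa), so shifting
    # mass toward them lowers community evenness
    base_logw = rng.normal(0.0, np.where(is_cop, 1.8, 1.0), spec.n_taxa)

    abund_rows, meta_rows, truth_rows = {}, {}, {}
    for s in range(spec.n_sites):
        site = f"site{s:03d}"
        lat = rng.uniform(20.0, 45.0)
        lon = rng.uniform(100.0, 125.0)
        ph = rng.normal(6.8, 0.5)
        som = OF_BASELINE["SOM"] * rng.lognormal(0.0, 0.3)
        for system in ("OF", "GH"):
            sample = f"{site}_{system}"
            soil = {}
            for var in NUTRIENT_VARS:
                fold = GH_NUTRIENT_FOLD[var] if system == "GH" else 1.0
                soil[var] = OF_BASELINE[var] * fold * rng.lognormal(0.0, 0.25)
            soil["EC"] = OF_BASELINE["EC"] * (GH_EC_FOLD if system == "GH" else 1.0) * rng.lognormal(0.0, 0.2)
            soil["pH"] = ph + rng.normal(0.0, 0.1)
            soil["SOM"] = som * rng.lognormal(0.0, 0.1)
            # delta-NPK of this sample relative to the OF baseline levels
            dnpk = float(np.mean([np.log10(soil[v] / OF_BASELINE[v]) for v in NUTRIENT_VARS]))
            logw = base_logw + spec.theta * dnpk * is_cop
            expected = np.exp(logw - logw.max())
            expected /= expected.sum()
            alpha = spec.dispersion * expected
            p = rng.dirichlet(np.maximum(alpha, 1e-6))
            counts = rng.multinomial(spec.read_depth, p)
            if counts.sum() == 0:
                counts[int(np.argmax(p))] = 1
            abund_rows[sample] = counts / counts.sum()
            meta_rows[sample] = {
                "site_id": site, "system": system,
                "latitude": lat + rng.normal(0.0, 0.005),
                "longitude": lon + rng.normal(0.0, 0.005),
                **soil,
            }
            nz = expected > 0
            truth_rows[sample] = {
                "site_id": site,
                "system": system,
                "delta_npk": dnpk,
                "copiotroph_mass": float(expected[is_cop].sum()),
                "true_community_rrn": float(expected @ traits["rrn_copy_number"].to_numpy()),
                "true_community_ags": float(expected @ traits["genome_size_bp"].to_numpy()),
                "true_community_doubling_h": float(expected @ traits["doubling_time_h"].to_numpy()),
                "expected_shannon": float(-(expected[nz] * np.log(expected[nz])).sum()),
            }

    abundance = pd.DataFrame.from_dict(abund_rows, orient="index", columns=traits.index)
    abundance = abundance.div(abundance.sum(axis=1), axis=0)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    survey = CommunitySurvey(abundance, meta)
    truth = pd.DataFrame.from_dict(truth_rows, orient="index").rename_axis("sample_id")
    return survey, taxonomy, reference, truth


def simulate_survey_with_taxon_truth(
    spec: SyntheticSpec,
) -> tuple[CommunitySurvey, TaxonomyTable, TraitReference, pd.DataFrame, pd.DataFrame]:
    """As :func:`simulate_survey` but also returning the per-taxon truth table.

    The per-taxon draw is the first thing the generator does from its seed,
    so replaying it with a fresh generator reproduces the same table.
    """
    survey, taxonomy, reference, truth = simulate_survey(spec)
    traits = _taxon_traits(spec, np.random.default_rng(spec.seed))
    return survey, taxonomy, reference, truth, traits


def simulate_metagenome_summary(
    genome_sizes_bp: np.ndarray,
    copies_16S: np.ndarray,
    coverages: np.ndarray,
    noise_sd: float = 0.05,
    seed: int = 0,
    sample_id: str = "S0",
    gene_length_16S: float = 1550.0,
    marker_set_size: int = 35,
) -> tuple[MetagenomeSummary, dict[str, float]]:
    """Simulate one sample's coverage summary from a mock genome mixture.

    The 35 single-copy-marker coverages scatter multiplicatively around the
    summed genome coverage; 16S annotated base pairs and total assembled bp
    follow the same mixture.  Ground truth is the coverage-weighted mean
    genome size (AGS) and 16S copy number (ACN).
    """
    sizes = np.asarray(genome_sizes_bp, dtype=float)
    copies = np.asarray(copies_16S, dtype=float)
    cov = np.asarray(coverages, dtype=float)
    if not (len(sizes) == len(copies) == len(cov)):
        raise MtsError("genome size, copy and coverage lists must have equal length")
    if (cov <= 0).any():
        raise MtsError("coverages must be > 0")
    if noise_sd < 0:
        raise MtsError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)

    total_cov = cov.sum()
    # multiplicative noise per marker gene and per genome contribution
    marker_cov = total_cov * rng.lognormal(0.0, noise_sd, marker_set_size)
    bp_16S = (copies * cov * rng.lognormal(0.0, noise_sd, len(cov))).sum() * gene_length_16S
    total_bp = (sizes * cov * rng.lognormal(0.0, noise_sd, len(cov))).sum()

    rows = [
        {"gene_id": f"marker{i:02d}", "category": "single_copy_marker",
         "coverage": marker_cov[i], "annotated_bp": np.nan, "gene_length": 1000.0}
        for i in range(marker_set_size)
    ]
    rows.append({"gene_id": "rrna16S", "category": "rrna_16S", "coverage": np.nan,
                 "annotated_bp": bp_16S, "gene_length": gene_length_16S})
    summary = MetagenomeSummary(
        sample_id=sample_id, total_bp=float(total_bp),
        genes=pd.DataFrame(rows), marker_set_size=marker_set_size,
    )
    truth = {
        "true_ags_bp": float((sizes * cov).sum() / total_cov),
        "true_acn": float((copies * cov).sum() / total_cov),
    }
    return summary, truth


# ---------------------------------------------------------------------------
# Coding sequences with controlled codon-usage bias
# ---------------------------------------------------------------------------

def _codon_families() -> dict[str, list[str]]:
    """Amino acid → synonymous sense codons under the standard code."""
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    fams: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        fams.setdefault(aa, []).append(codon)
    for aa in fams:
        fams[aa] = sorted(fams[aa])
    return fams


CODON_FAMILIES = _codon_families()

#: Fixed mildly uneven background codon frequencies within each family:
#: weight 1, 2, ..., r for the sorted codons of an r-codon family.
BACKGROUND_CODON_WEIGHTS = {
    aa: np.arange(1, len(codons) + 1, dtype=float) / np.arange(1, len(codons) + 1).sum()
    for aa, codons in CODON_FAMILIES.items()
}


def simulate_coding_sequences(
    n_background: int = 50,
    n_heg: int = 50,
    bias: float = 0.5,
    length_codons: int = 300,
    seed: int = 0,
) -> CodingSequenceSet:
    """Generate coding sequences whose highly-expressed genes carry a
    controlled codon-usage bias.

    Background genes draw codons from a fixed frequency table; highly
    expressed (ribosomal-protein-like) genes draw from the mixture
    ``(1 - bias) * background + bias * preferred-codon`` where each amino
    acid's preferred codon is its most frequent background codon.  At
    ``bias = 0`` the two distributions coincide.
    """
    if not (0.0 <= bias <= 1.0):
        raise MtsError("bias must be in [0, 1]")
    if length_codons < 100:
        logger.warning("length %d codons < 100: codon-usage bias is unstable", length_codons)
    rng = np.random.default_rng(seed)
    aas = sorted(CODON_FAMILIES)

    def draw_gene(biased: bool) -> str:
        aa_seq = rng.integers(0, len(aas), size=length_codons)
        codons = np.empty(length_codons, dtype=object)
        for ai in range(len(aas)):
            positions = np.flatnonzero(aa_seq == ai)
            if len(positions) == 0:
                continue
            aa = aas[ai]
            fam = CODON_FAMILIES[aa]
            w = BACKGROUND_CODON_WEIGHTS[aa].copy()
            if biased:
                preferred = int(np.argmax(w))
                w = (1.0 - bias) * w
                w[preferred] += bias
            picks = rng.choice(len(fam), size=len(positions), p=w / w.sum())
            for pos, pick in zip(positions, picks):
                codons[pos] = fam[pick]
        return "".join(codons)

    rows = []
    for i in range(n_background):
        rows.append({"gene_id": f"bg{i:03d}", "sequence": draw_gene(False),
                     "is_highly_expressed": False, "coverage": float(rng.lognormal(0.0, 0.3))})
    for i in range(n_heg):
        rows.append({"gene_id": f"heg{i:03d}", "sequence": draw_gene(True),
                     "is_highly_expressed": True, "coverage": float(rng.lognormal(0.5, 0.3))})
    return CodingSequenceSet(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Phylogeny and assembly scenarios
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed: int = 0, mean_branch: float = 0.1,
                  labels: list[str] | None = None) -> dendropy.Tree:
    """Pure-birth random tree with exponential branch lengths."""
    if n_taxa < 2:
        raise MtsError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"t{i:04d}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    leaves = [tree.seed_node]
    while len(leaves) < n_taxa:
        node = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            child = node.new_child(edge_length=float(rng.exponential(mean_branch)))
            leaves.append(child)
    shuffled = list(labels)
    rng.shuffle(shuffled)
    for leaf, label in zip(leaves, shuffled):
        leaf.taxon = ns.new_taxon(label)
    # root edge length irrelevant; make internal zero-length edges explicit
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return tree


def brownian_trait(tree: dendropy.Tree, seed: int = 0, sigma: float = 1.0) -> pd.Series:
    """Brownian-motion trait on the tree (phylogenetically conserved)."""
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = values[id(node.parent_node)]
        bl = node.edge.length or 0.0
        values[id(node)] = parent + rng.normal(0.0, sigma * np.sqrt(max(bl, 0.0)))
    return pd.Series(
        {leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()}
    )


def simulate_assembly(
    scenario: str,
    tree: dendropy.Tree,
    meta_abundance: np.ndarray | None = None,
    N: int = 1000,
    m: float = 0.1,
    n_samples: int = 20,
    seed: int = 0,
    selection_sd: float = 0.1,
    dispersion: float = 50.0,
) -> CommunitySurvey:
    """Assemble communities under a neutral or selection scenario.

    *neutral*: each taxon's relative abundance per sample is drawn from the
    stationary Sloan approximation Beta(N·m·p̄, N·m·(1−p̄)) around the
    meta-community frequency p̄, then renormalized — immigration-drift
    balance with no phylogenetic structure.

    *selection*: a Brownian trait on the tree defines phylogenetically
    conserved environmental optima; samples alternate between a low and a
    high optimum (heterogeneous selection) and taxa are weighted by a
    Gaussian filter of width ``selection_sd`` around the sample's optimum.
    Communities assembled under opposite optima occupy divergent clades,
    pushing pairwise |βNTI| beyond ±2.
    """
    if not (0 < m <= 1):
        raise MtsError("migration m must be in (0, 1]")
    if N < 100:
        raise MtsError("community size N must be >= 100")
    rng = np.random.default_rng(seed)
    taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    n_taxa = len(taxa)
    if meta_abundance is None:
        meta_abundance = rng.lognormal(0.0, 1.5, n_taxa)
        meta_abundance /= meta_abundance.sum()
    p_bar = np.asarray(meta_abundance, dtype=float)
    p_bar = p_bar / p_bar.sum()

    rows = {}
    if scenario == "neutral":
        a = N * m * p_bar
        b = N * m * (1.0 - p_bar)
        for s in range(n_samples):
            x = rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9))
            # discretize at the detection scale of N individuals
            counts = rng.binomial(N, np.minimum(x, 1.0))
            if counts.sum() == 0:
                counts[rng.integers(n_taxa)] = 1
            rows[f"n{s:03d}"] = counts / counts.sum()
    elif scenario == "selection":
        trait = brownian_trait(tree, seed=seed + 1).loc[taxa].to_numpy()
        optima = (float(np.quantile(trait, 0.1)), float(np.quantile(trait, 0.9)))
        # temper meta-community dominance so the phylogenetic filter, not a
        # handful of hyper-abundant taxa, shapes the communities
        base = p_bar**0.3
        for s in range(n_samples):
            optimum = optima[s % 2]
            w = base * np.exp(-((trait - optimum) ** 2) / (2 * selection_sd**2))
            if w.sum() <= 0:
                raise MtsError("selection filter removed all taxa")
            w = w / w.sum()
            p_s = rng.dirichlet(np.maximum(dispersion * w, 1e-6))
            counts = rng.multinomial(N, p_s)
            if counts.sum() == 0:
                counts[int(np.argmax(p_s))] = 1
            rows[f"s{s:03d}"] = counts / counts.sum()
    else:
        raise MtsError(f"unknown scenario {scenario!r}; use 'neutral' or 'selection'")

    abundance = pd.DataFrame.from_dict(rows, orient="index", columns=taxa)
    abundance = abundance.div(abundance.sum(axis=1), axis=0)
    meta = pd.DataFrame(
        {
            "site_id": [f"asite{i}" for i in range(len(abundance))],
            "system": "OF",
            "latitude": rng.uniform(20, 45, len(abundance)),
            "longitude": rng.uniform(100, 125, len(abundance)),
            "pH": 7.0, "EC": 150.0, "SOM": 20.0,
            "NH4": 10.0, "NO3": 20.0, "AP": 30.0, "AK": 120.0,
        },
        index=abundance.index,
    )
    return CommunitySurvey(abundance, meta)
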