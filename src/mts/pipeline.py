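"""End-to-end orchestration: simulate → traits → assembly → contrasts → PLS-SEM.

``run_pipeline`` executes every stage on a single configuration, writes
per-stage TSV/JSON outputs plus a machine-readable ``summary.json``, and
is deterministic given the configured seeds (rerunning with the same
config is byte-identical).  Stage outputs are cached by a content hash of
the configuration: when the output directory already holds a summary
produced from the same hash, the run is skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly as asm
from . import contrasts as con
from . import plssem
from . import synthetic as syn
from . import traits as tr
from .core_io import (
    CommunitySurvey,
    MtsError,
    NUTRIENT_VARS,
    write_survey,
    write_trait_reference,
    write_tree,
)

logger = logging.getLogger("mts")

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Validated pipeline configuration with seeds and thresholds."""

    seed: int = 0
    outdir: str = "mts_report"
    survey: dict = field(default_factory=dict)  # SyntheticSpec overrides
    stages: dict = field(default_factory=lambda: {
        "traits": True, "assembly": True, "contrasts": True, "plssem": True,
    })
    use_tree: bool = True
    n_null: int = 999
    n_perm: int = 999
    n_boot: int = 199
    ncm_N: float = 1000.0
    bnti_threshold: float = 2.0
    lfc_threshold: float = 1.0
    q_threshold: float = 0.05
    growth_calibration: tuple[float, float] = (1.5, -3.0)
    metagenome_noise_sd: float = 0.05
    cds_genes: int = 20  # background and highly expressed genes per sample
    cds_length_codons: int = 200

    def __post_init__(self) -> None:
        for name in ("bnti_threshold", "lfc_threshold", "q_threshold"):
            if getattr(self, name) <= 0:
                raise MtsError(f"threshold {name} must be positive")
        if self.seed is None:
            raise MtsError("pipeline seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "growth_calibration" in raw:
            raw["growth_calibration"] = tuple(raw["growth_calibration"])
        return cls(**raw)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _pbb_abundance(survey: CommunitySurvey, taxonomy, reference) -> pd.Series:
    """Per-sample summed abundance of plant-beneficial genera."""
    pbb = reference.entries("plant_beneficial")
    genera = set(pbb.loc[pbb["rank"] == "genus", "name"])
    taxa = [t for t in survey.taxa if taxonomy.lineage.loc[t, "genus"] in genera]
    if not taxa:
        return pd.Series(0.0, index=survey.abundance.index, name="pbb")
    return survey.abundance[taxa].sum(axis=1).rename("pbb")


def _sample_traits(
    survey: CommunitySurvey, taxon_truth: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    """Metagenome-route traits per sample (AGS, ACN, CUB, μmax).

    Per-sample genome coverages are proportional to taxon relative
    abundances; coding-sequence bias tracks the community's expected
    growth potential so the full coverage→marker→MILC→μmax chain is
    exercised.
    """
    sizes = taxon_truth["genome_size_bp"].to_numpy()
    copies = taxon_truth["rrn_copy_number"].to_numpy()
    inv_dt = 1.0 / taxon_truth["doubling_time_h"].to_numpy()
    p = survey.abundance[list(taxon_truth.index)].to_numpy(dtype=float)
    growth_potential = p @ inv_dt
    lo, hi = growth_potential.min(), growth_potential.max()
    span = hi - lo if hi > lo else 1.0

    rows = {}
    for i, sample in enumerate(survey.samples):
        seed_i = (config.seed * 100003 + i) % (2**31 - 1)
        cov = np.maximum(p[i] * 200.0, 1e-3)
        summary, truth = syn.simulate_metagenome_summary(
            sizes, copies, cov, noise_sd=config.metagenome_noise_sd,
            seed=seed_i, sample_id=sample,
        )
        bias = 0.2 + 0.6 * (growth_potential[i] - lo) / span
        cds = syn.simulate_coding_sequences(
            n_background=config.cds_genes, n_heg=config.cds_genes,
            bias=float(bias), length_codons=config.cds_length_codons, seed=seed_i,
        )
        _, community_cub = tr.codon_usage_bias(cds)
        growth = tr.max_growth_rate(community_cub, config.growth_calibration, sample)
        rows[sample] = {
            "ags_bp": tr.average_genome_size(summary),
            "acn": tr.average_16S_copy_number(summary),
            "true_ags_bp": truth["true_ags_bp"],
            "true_acn": truth["true_acn"],
            "cub": growth.cub,
            "min_generation_h": growth.min_generation_h,
            "max_growth_rate_per_h": growth.max_growth_rate_per_h,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


def run_pipeline(config: RunConfig, force: bool = False) -> Path:
    """Run every enabled stage and write the report directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.content_hash()
    summary_path = outdir / "summary.json"
    if summary_path.exists() and not force:
        try:
            existing = json.loads(summary_path.read_text())
            if existing.get("config_hash") == chash:
                logger.info("cache hit (%s): reusing %s", chash, outdir)
                return outdir
        except json.JSONDecodeError:
            pass

    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION, "config_hash": chash,
                     "seed": config.seed, "stages": {}}

    # --- simulate --------------------------------------------------------
    spec = syn.SyntheticSpec(seed=config.seed, **config.survey)
    survey, taxonomy, reference, truth, taxon_truth = syn.simulate_survey_with_taxon_truth(spec)
    write_survey(survey, outdir / "abundance.tsv", outdir / "metadata.tsv",
                 taxonomy, outdir / "taxonomy.tsv")
    write_trait_reference(reference, outdir / "trait_reference.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    taxon_truth.rename_axis("taxon_id").to_csv(outdir / "taxon_truth.tsv", sep="\t")
    system = survey.meta["system"]
    summary["stages"]["simulate"] = {
        "n_samples": len(survey.samples), "n_taxa": len(survey.taxa),
        "n_pairs": len(survey.pairs()),
    }

    tree = None
    if config.use_tree:
        tree = syn.simulate_tree(len(survey.taxa), seed=config.seed, labels=survey.taxa)
        write_tree(tree, outdir / "tree.nwk")

    per_sample = pd.DataFrame(index=survey.abundance.index)
    per_sample["shannon"] = con.shannon_per_sample(survey)

    # --- traits ----------------------------------------------------------
    if config.stages.get("traits", True):
        assignment = tr.impute_trait(taxonomy, reference, "rrn_copy_number")
        assignment.table.rename_axis("taxon_id").to_csv(outdir / "rrn_assignment.tsv", sep="\t")
        per_sample["community_rrn"] = tr.community_weighted_trait(survey, assignment)
        mg = _sample_traits(survey, taxon_truth, config)
        per_sample = per_sample.join(mg)
        per_sample["pbb"] = _pbb_abundance(survey, taxonomy, reference)
        strategy = tr.classify_strategy(taxonomy)
        cop_taxa = [t for t in survey.taxa if strategy.get(t) == "copiotroph"]
        per_sample["copiotroph_abundance"] = survey.abundance[cop_taxa].sum(axis=1)
        per_sample.rename_axis("sample_id").to_csv(outdir / "sample_traits.tsv", sep="\t")
        trait_tests = con.group_tests(
            per_sample[["shannon", "community_rrn", "ags_bp", "acn",
                        "max_growth_rate_per_h", "pbb", "copiotroph_abundance"]],
            system,
        )
        trait_tests.to_csv(outdir / "trait_tests.tsv", sep="\t", index=False)
        summary["stages"]["traits"] = {
            row["variable"]: {
                "percent_difference_gh_vs_of": row["percent_difference"],
                "p": row["p"], "q": row["q"], "direction": row["direction"],
            }
            for _, row in trait_tests.iterrows()
        }
    else:
        summary["stages"]["traits"] = {"skipped": True}

    # --- assembly --------------------------------------------------------
    if config.stages.get("assembly", True):
        assembly_summary: dict = {}
        if tree is None:
            assembly_summary["bnti"] = {"skipped": True, "reason": "tree input disabled"}
        else:
            result = asm.beta_nti(survey, tree, n_null=config.n_null, seed=config.seed)
            result.bnti.to_csv(outdir / "bnti.tsv", sep="\t")
            result.bmntd.to_csv(outdir / "bmntd.tsv", sep="\t")
            assembly_summary["bnti"] = {
                "fraction_stochastic": result.fraction_stochastic,
                "n_null": result.n_null,
            }
            for sys_label in ("OF", "GH"):
                sub = survey.subset(system[system == sys_label].index)
                res_s = asm.beta_nti(sub, tree, n_null=config.n_null, seed=config.seed + 1)
                assembly_summary["bnti"][f"fraction_stochastic_{sys_label}"] = (
                    res_s.fraction_stochastic
                )
        ncm = {}
        for sys_label in ("OF", "GH"):
            sub = survey.subset(system[system == sys_label].index)
            fit = asm.fit_ncm(sub, N=config.ncm_N, seed=config.seed)
            ncm[sys_label] = {"m": fit.m, "Nm": fit.Nm, "r_squared": fit.r_squared}
        assembly_summary["ncm"] = ncm

        ddr_fits = {}
        for sys_label in ("OF", "GH"):
            sub = survey.subset(system[system == sys_label].index)
            ddr_fits[sys_label] = asm.ddr(sub, kind="geographic", group=sys_label)
        slope_p = asm.ddr_slope_difference(
            ddr_fits["OF"], ddr_fits["GH"], n_perm=config.n_perm, seed=config.seed
        )
        assembly_summary["ddr_geographic"] = {
            "slope_OF": ddr_fits["OF"].slope, "slope_GH": ddr_fits["GH"].slope,
            "r_squared_OF": ddr_fits["OF"].r_squared, "r_squared_GH": ddr_fits["GH"].r_squared,
            "slope_difference_p": slope_p,
        }
        bc = con.bray_curtis_matrix(survey)
        f_stat, p_val = asm.permanova(bc, system, n_perm=config.n_perm, seed=config.seed)
        assembly_summary["permanova"] = {"pseudo_F": f_stat, "p": p_val}
        summary["stages"]["assembly"] = assembly_summary
        with open(outdir / "assembly.json", "w") as fh:
            json.dump(assembly_summary, fh, indent=2, sort_keys=True)
    else:
        summary["stages"]["assembly"] = {"skipped": True}

    # --- contrasts -------------------------------------------------------
    deltas = None
    if config.stages.get("contrasts", True):
        extra = per_sample.select_dtypes("number") if config.stages.get("traits", True) else None
        variables = survey.meta.select_dtypes("number").drop(
            columns=["latitude", "longitude"], errors="ignore"
        )
        if extra is not None:
            variables = variables.join(extra)
        deltas = con.delta_table(survey, variables)
        deltas.to_csv(outdir / "deltas.tsv", sep="\t")
        volcano = con.volcano_enrichment(
            survey.abundance, system,
            lfc_threshold=config.lfc_threshold, q_threshold=config.q_threshold,
        )
        volcano.to_csv(outdir / "volcano.tsv", sep="\t", index=False)
        counts = volcano["enriched_in"].value_counts()
        summary["stages"]["contrasts"] = {
            "n_pairs": len(deltas),
            "mean_delta_NPK": float(deltas["delta_NPK"].mean()),
            "taxa_enriched_GH": int(counts.get("GH", 0)),
            "taxa_enriched_OF": int(counts.get("OF", 0)),
        }
    else:
        summary["stages"]["contrasts"] = {"skipped": True}

    # --- PLS-SEM ---------------------------------------------------------
    if config.stages.get("plssem", True) and deltas is not None and config.stages.get("traits", True):
        data = deltas[list(NUTRIENT_VARS) + ["ags_bp", "community_rrn",
                                             "max_growth_rate_per_h", "pbb"]].dropna()
        spec_pm = plssem.ModelSpec(
            blocks={
                "nutrients": list(NUTRIENT_VARS),
                "function": ["ags_bp"],
                "growth": ["community_rrn", "max_growth_rate_per_h"],
                "beneficial": ["pbb"],
            },
            inner=[("nutrients", "function"), ("nutrients", "growth"),
                   ("nutrients", "beneficial"), ("growth", "beneficial"),
                   ("function", "beneficial")],
        )
        # classic composite paths: the delta-scale blocks are dominated by
        # single indicators and n is the pair count, too small for stable
        # reliability-based disattenuation
        model = plssem.fit_plspm(data, spec_pm, consistent=False)
        try:
            boot = plssem.bootstrap_paths(data, spec_pm, n_boot=config.n_boot,
                                          seed=config.seed, consistent=False)
            path_records = boot.to_dict(orient="records")
        except MtsError as exc:
            # tiny pair counts can make resamples degenerate; keep the
            # point estimates and record the failed inference
            logger.warning("plssem bootstrap failed (%s); reporting point estimates only", exc)
            path_records = model.paths.to_dict(orient="records")
        dump = {
            "paths": path_records,
            "r_squared": model.r_squared,
            "outer_weights": {l: w.to_dict() for l, w in model.outer_weights.items()},
            "iterations": model.iterations,
        }
        with open(outdir / "plssem.json", "w") as fh:
            json.dump(dump, fh, indent=2, sort_keys=True)
        summary["stages"]["plssem"] = {
            "r_squared": model.r_squared,
            "paths": {f"{r.source}->{r.target}": r.coefficient
                      for r in model.paths.itertuples()},
        }
    else:
        summary["stages"]["plssem"] = {"skipped": True}

    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", outdir)
    return outdir
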