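"""Diversity, paired log-ratio deltas, rank tests with FDR control,
enrichment filters and correlation screens for OF/GH soil contrasts.

The paired-contrast framework expresses each variable X measured in both
members of a site pair as delta = log10(X_GH / X_OF); the composite
delta-NPK averages the deltas of the four plant-available nutrient pools
(NH4, NO3, AP, AK).  Group differences use the Wilcoxon rank-sum test
with Benjamini-Hochberg correction across variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis as _braycurtis
from statsmodels.stats.multitest import multipletests

from .core_io import CommunitySurvey, MtsError, NUTRIENT_VARS

logger = logging.getLogger("mts")


def shannon(row: np.ndarray, base: float | None = None) -> float:
    """Shannon diversity H = −Σ p·log p (natural log by default)."""
    p = np.asarray(row, dtype=float)
    if (p < 0).any():
        raise MtsError("negative abundance in Shannon input")
    total = p.sum()
    if total <= 0:
        raise MtsError("all-zero abundance row")
    p = p / total
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def shannon_per_sample(survey: CommunitySurvey, base: float | None = None) -> pd.Series:
    return pd.Series(
        [shannon(r, base=base) for r in survey.abundance.to_numpy()],
        index=survey.abundance.index,
        name="shannon",
    )


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity Σ|x−y| / Σ(x+y) ∈ [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise MtsError("rows must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise MtsError("Bray-Curtis requires nonnegative rows")
    if x.sum() == 0 and y.sum() == 0:
        raise MtsError("both rows all-zero")
    return float(_braycurtis(x, y))


def bray_curtis_matrix(survey: CommunitySurvey) -> pd.DataFrame:
    from scipy.spatial.distance import pdist, squareform

    mat = squareform(pdist(survey.abundance.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(mat, index=survey.samples, columns=survey.samples)


# ---------------------------------------------------------------------------
# Paired log-ratio deltas
# ---------------------------------------------------------------------------

def delta_table(
    survey: CommunitySurvey,
    variables: pd.DataFrame | None = None,
    base: float = 10.0,
) -> pd.DataFrame:
    """Per-pair log-ratio deltas, delta = log_base(X_GH / X_OF).

    ``variables`` is a per-sample table (defaults to the soil metadata
    columns); rows are indexed by the GH sample of each pair.  Pairs where
    either member is zero or non-finite for a variable yield NaN with a
    logged count.  A ``delta_NPK`` column averages the four nutrient
    deltas when all are available.
    """
    if variables is None:
        variables = survey.meta.select_dtypes("number").drop(
            columns=["latitude", "longitude"], errors="ignore"
        )
    pairs = survey.pairs()
    if not pairs:
        raise MtsError("no resolvable GH/OF pairs")
    rows = {}
    n_dropped = 0
    for gh, of in pairs:
        rec = {"site_id": survey.meta.loc[gh, "site_id"], "of_sample": of}
        for var in variables.columns:
            x_gh = float(variables.loc[gh, var])
            x_of = float(variables.loc[of, var])
            if x_gh <= 0 or x_of <= 0 or not (np.isfinite(x_gh) and np.isfinite(x_of)):
                rec[var] = np.nan
                n_dropped += 1
            else:
                rec[var] = np.log(x_gh / x_of) / np.log(base)
        rows[gh] = rec
    if n_dropped:
        logger.warning("delta_table: %d variable/pair cells dropped (zero or non-finite)", n_dropped)
    out = pd.DataFrame.from_dict(rows, orient="index").rename_axis("gh_sample")
    nutrient_cols = [v for v in NUTRIENT_VARS if v in out.columns]
    if len(nutrient_cols) == len(NUTRIENT_VARS):
        out["delta_NPK"] = out[list(NUTRIENT_VARS)].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# Rank tests and FDR
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, exact_threshold: int = 20
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both samples have at most ``exact_threshold``
    observations and the pooled data are tie-free; otherwise the normal
    approximation with tie and continuity corrections.
    Returns (W, p) where W is the rank-sum statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise MtsError("empty sample in rank-sum test")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(x) <= exact_threshold) and (len(y) <= exact_threshold) and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0  # U -> rank sum of x
    return w, float(res.pvalue)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise MtsError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class TestResult:
    """One variable's OF-vs-GH rank test with direction and effect size."""

    variable: str
    statistic: float
    p: float
    q: float
    direction: str  # 'GH' if mean higher in GH, else 'OF'
    percent_difference: float  # 100·(mean_GH − mean_OF)/mean_OF


def group_tests(
    values: pd.DataFrame, system: pd.Series, exact_threshold: int = 20
) -> pd.DataFrame:
    """Wilcoxon rank-sum per column of ``values`` between GH and OF samples,
    BH-corrected across columns."""
    gh = values.loc[system == "GH"]
    of = values.loc[system == "OF"]
    rows = []
    for var in values.columns:
        w, p = wilcoxon_rank_sum(gh[var].dropna().to_numpy(), of[var].dropna().to_numpy(),
                                 exact_threshold=exact_threshold)
        mean_gh, mean_of = float(gh[var].mean()), float(of[var].mean())
        pct = 100.0 * (mean_gh - mean_of) / mean_of if mean_of != 0 else np.nan
        rows.append({"variable": var, "statistic": w, "p": p,
                     "direction": "GH" if mean_gh >= mean_of else "OF",
                     "percent_difference": pct})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out[["variable", "statistic", "p", "q", "direction", "percent_difference"]]


# ---------------------------------------------------------------------------
# Enrichment and functional summaries
# ---------------------------------------------------------------------------

def volcano_enrichment(
    features: pd.DataFrame,
    system: pd.Series,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    exact_threshold: int = 20,
) -> pd.DataFrame:
    """Partition features into GH-enriched / OF-enriched / neither.

    Per feature (column): log2 fold change of the GH group mean over the
    OF group mean and a BH-corrected Wilcoxon p.  Enrichment requires
    |log2 FC| > ``lfc_threshold`` and q < ``q_threshold``.  Features with
    zero mean in both groups are dropped with a warning.
    """
    gh = features.loc[system == "GH"]
    of = features.loc[system == "OF"]
    both_zero = [c for c in features.columns if gh[c].mean() == 0 and of[c].mean() == 0]
    if both_zero:
        logger.warning("volcano: dropping %d features with zero mean in both groups", len(both_zero))
        features = features.drop(columns=both_zero)
        gh, of = gh.drop(columns=both_zero), of.drop(columns=both_zero)
    rows = []
    for var in features.columns:
        mean_gh, mean_of = float(gh[var].mean()), float(of[var].mean())
        if mean_gh > 0 and mean_of > 0:
            lfc = float(np.log2(mean_gh / mean_of))
        else:
            lfc = np.inf if mean_gh > 0 else -np.inf
        _, p = wilcoxon_rank_sum(gh[var].to_numpy(), of[var].to_numpy(),
                                 exact_threshold=exact_threshold)
        rows.append({"feature": var, "log2_fc": lfc, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    significant = (out["q"] < q_threshold) & (out["log2_fc"].abs() > lfc_threshold)
    out["enriched_in"] = "neither"
    out.loc[significant & (out["log2_fc"] > 0), "enriched_in"] = "GH"
    out.loc[significant & (out["log2_fc"] < 0), "enriched_in"] = "OF"
    return out


def functional_summary(genes: pd.DataFrame) -> tuple[float, int]:
    """(annotated fraction, KO richness) of one sample's gene table.

    ``genes`` has columns ``ko`` (empty string = unannotated) and
    ``abundance``.  Annotated fraction is the abundance share carried by
    KO-labeled genes; richness counts distinct KO labels with abundance
    above zero.
    """
    if genes.empty:
        raise MtsError("empty gene table")
    abundance = genes["abundance"].astype(float)
    if (abundance < 0).any():
        raise MtsError("negative gene abundance")
    total = abundance.sum()
    labeled = genes["ko"].astype(str) != ""
    fraction = float(abundance[labeled].sum() / total) if total > 0 else 0.0
    richness = int(genes.loc[labeled & (abundance > 0), "ko"].nunique())
    return fraction, richness


# ---------------------------------------------------------------------------
# Correlation screens
# ---------------------------------------------------------------------------

def correlation_screen(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Pairwise correlations of every feature against every covariate.

    Returns a long table (feature, covariate, r, p, q) with BH correction
    across the whole matrix.  Zero-variance columns give NA with a
    warning; each cell needs at least 4 complete pairs.
    """
    if method not in ("pearson", "spearman"):
        raise MtsError("method must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for f in features.columns:
        for c in covariates.columns:
            merged = pd.concat([features[f], covariates[c]], axis=1, join="inner").dropna()
            if len(merged) < 4:
                raise MtsError(f"fewer than 4 complete pairs for ({f}, {c})")
            x = merged.iloc[:, 0].to_numpy(dtype=float)
            y = merged.iloc[:, 1].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                logger.warning("correlation_screen: zero variance for (%s, %s); NA", f, c)
                rows.append({"feature": f, "covariate": c, "r": np.nan, "p": np.nan})
                continue
            r, p = corr(x, y)
            rows.append({"feature": f, "covariate": c, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    return out
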