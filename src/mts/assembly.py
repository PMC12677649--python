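"""Community assembly and biogeography inference.

Implements the null-model toolkit used to partition deterministic versus
stochastic assembly: abundance-weighted β-mean-nearest-taxon distance
(βMNTD) and its tip-shuffling z-score (βNTI), the abundance-based
Raup-Crick index on Bray-Curtis dissimilarity, the Sloan neutral community
model, distance-decay regressions with a permutation slope-difference
test, and one-way PERMANOVA.

Conventions: |βNTI| < 2 is read as stochastic assembly; Raup-Crick values
live in [−1, 1]; all permutation p-values use the add-one rule so p is
never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import braycurtis

from .core_io import CommunitySurvey, MtsError, SOIL_VARS, tree_distance_matrix

logger = logging.getLogger("mts")

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# βMNTD / βNTI
# ---------------------------------------------------------------------------

def _bmntd_from_matrix(p: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """All-pairs abundance-weighted βMNTD given relative abundances
    ``p`` (samples × taxa) and a taxon distance matrix."""
    n_samples, n_taxa = p.shape
    present = p > 0
    if not present.any(axis=1).all():
        raise MtsError("empty community in βMNTD")
    # dmin[i, s] = distance from taxon i to its nearest taxon present in sample s
    dmin = np.empty((n_taxa, n_samples))
    for s in range(n_samples):
        dmin[:, s] = dist[:, present[s]].min(axis=1)
    half = p @ dmin  # half[k, s] = Σ_i p_ik · min_{j∈s} d(i, j)
    return 0.5 * (half + half.T)


def beta_mntd(
    survey: CommunitySurvey, tree: dendropy.Tree, pair: tuple[str, str] | None = None
) -> float | pd.DataFrame:
    """Abundance-weighted β-mean-nearest-taxon distance.

    βMNTD(k, m) = ½[Σᵢ p_ik·min_{j∈m} d(i,j) + Σⱼ p_jm·min_{i∈k} d(j,i)]
    with minima over taxa present (p > 0) in the *other* sample; taxa
    shared between the two samples contribute distance zero.

    With ``pair`` given, returns that single value; otherwise the full
    symmetric matrix as a DataFrame.
    """
    dist = tree_distance_matrix(tree, survey.taxa)
    mat = _bmntd_from_matrix(survey.abundance.to_numpy(dtype=float), dist)
    frame = pd.DataFrame(mat, index=survey.samples, columns=survey.samples)
    if pair is not None:
        return float(frame.loc[pair[0], pair[1]])
    return frame


@dataclass
class AssemblyResult:
    """Pairwise βMNTD/βNTI (and optionally Raup-Crick) with process fractions."""

    bmntd: pd.DataFrame
    bnti: pd.DataFrame
    n_null: int
    rc: pd.DataFrame | None = None
    partition: dict[str, float] | None = None

    @property
    def fraction_stochastic(self) -> float:
        vals = _upper(self.bnti)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            return float("nan")
        return float((np.abs(vals) < 2).mean())

    @property
    def fractions(self) -> dict[str, float]:
        f = self.fraction_stochastic
        return {"stochastic": f, "deterministic": 1.0 - f}


def _upper(frame: pd.DataFrame) -> np.ndarray:
    arr = frame.to_numpy(dtype=float)
    iu = np.triu_indices_from(arr, k=1)
    return arr[iu]


def beta_nti(
    survey: CommunitySurvey,
    tree: dendropy.Tree,
    n_null: int = 999,
    seed: int = 0,
    compute_partition: bool = False,
    rc: pd.DataFrame | None = None,
) -> AssemblyResult:
    """βNTI: z-score of observed βMNTD against a taxa-shuffle null.

    The null shuffles taxon labels across all tree tips (equivalently,
    permutes rows/columns of the taxon distance matrix jointly) and
    recomputes βMNTD, ``n_null`` times.  βNTI = (obs − mean_null)/sd_null
    per sample pair; pairs with a degenerate null (sd = 0) are NA.
    """
    if len(survey.samples) < 2:
        raise MtsError("βNTI needs at least 2 samples")
    logger.info("beta_nti: %d samples, %d nulls, seed=%d", len(survey.samples), n_null, seed)
    rng = np.random.default_rng(seed)
    dist = tree_distance_matrix(tree, survey.taxa)
    p = survey.abundance.to_numpy(dtype=float)
    obs = _bmntd_from_matrix(p, dist)

    n_taxa = p.shape[1]
    null_sum = np.zeros_like(obs)
    null_sumsq = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        null = _bmntd_from_matrix(p, dist[np.ix_(perm, perm)])
        null_sum += null
        null_sumsq += null * null
    mean_null = null_sum / n_null
    var_null = null_sumsq / n_null - mean_null**2
    sd_null = np.sqrt(np.maximum(var_null, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = (obs - mean_null) / sd_null
    degenerate = sd_null == 0
    np.fill_diagonal(degenerate, False)
    if degenerate.any():
        logger.warning("βNTI: %d pairs with zero null sd reported NA", int(degenerate.sum() // 2))
        bnti[degenerate] = np.nan
    np.fill_diagonal(bnti, np.nan)
    samples = survey.samples
    result = AssemblyResult(
        bmntd=pd.DataFrame(obs, index=samples, columns=samples),
        bnti=pd.DataFrame(bnti, index=samples, columns=samples),
        n_null=n_null,
        rc=rc,
    )
    if compute_partition:
        result.partition = partition_processes(result.bnti, rc)
    return result


def partition_processes(
    bnti: pd.DataFrame, rc: pd.DataFrame | None
) -> dict[str, float]:
    """Five-way assembly-process partition over sample pairs.

    βNTI > +2: heterogeneous selection; βNTI < −2: homogeneous selection;
    |βNTI| < 2 with RC > +0.95: dispersal limitation; RC < −0.95:
    homogenizing dispersal; otherwise drift (undominated).  Without a
    Raup-Crick matrix, the stochastic mass is reported as drift.
    """
    b = _upper(bnti)
    ok = ~np.isnan(b)
    b = b[ok]
    n = len(b)
    out = {
        "heterogeneous_selection": float((b > 2).sum()) / n,
        "homogeneous_selection": float((b < -2).sum()) / n,
    }
    stoch = np.abs(b) < 2
    if rc is not None:
        r = _upper(rc)[ok]
        out["dispersal_limitation"] = float((stoch & (r > 0.95)).sum()) / n
        out["homogenizing_dispersal"] = float((stoch & (r < -0.95)).sum()) / n
        out["drift"] = float((stoch & (np.abs(r) <= 0.95)).sum()) / n
    else:
        out["dispersal_limitation"] = 0.0
        out["homogenizing_dispersal"] = 0.0
        out["drift"] = float(stoch.sum()) / n
    return out


# ---------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis)
# ---------------------------------------------------------------------------

def raup_crick_bray(
    survey: CommunitySurvey,
    pair: tuple[str, str] | None = None,
    n_null: int = 999,
    seed: int = 0,
    n_individuals: int = 1000,
) -> float | pd.DataFrame:
    """Abundance-based Raup-Crick index on Bray-Curtis dissimilarity.

    For each sample a null community keeps the observed richness, drawing
    which taxa occur with probability proportional to regional occupancy
    and filling the observed total abundance (discretized to
    ``n_individuals``) proportionally to regional mean relative abundance.
    RC = 2·[(#null < obs) + ½(#null = obs)]/n_null − 1 ∈ [−1, 1].
    """
    p = survey.abundance.to_numpy(dtype=float)
    n_samples, n_taxa = p.shape
    if n_taxa < 2:
        raise MtsError("Raup-Crick needs at least 2 taxa in the region")
    occupancy = (p > 0).mean(axis=0)
    regional = p.mean(axis=0)
    regional = regional / regional.sum()
    richness = (p > 0).sum(axis=1)
    counts = np.rint(p * n_individuals).astype(int)
    counts[(p > 0) & (counts == 0)] = 1  # keep detected taxa detected

    rng = np.random.default_rng(seed)

    def null_community(sample_idx: int) -> np.ndarray:
        k = richness[sample_idx]
        occ_p = occupancy / occupancy.sum()
        chosen = rng.choice(n_taxa, size=k, replace=False, p=occ_p)
        fill_p = regional[chosen]
        fill_p = fill_p / fill_p.sum()
        total = counts[sample_idx].sum()
        filled = np.zeros(n_taxa)
        filled[chosen] = 1  # guarantee presence
        extra = rng.multinomial(max(total - k, 0), fill_p)
        filled[chosen] += extra
        return filled / filled.sum()

    def rc_pair(i: int, j: int) -> float:
        i, j = min(i, j), max(i, j)  # exchangeable in pair order
        obs = braycurtis(p[i], p[j])
        below = equal = 0
        for _ in range(n_null):
            null_bc = braycurtis(null_community(i), null_community(j))
            if null_bc < obs - 1e-12:
                below += 1
            elif abs(null_bc - obs) <= 1e-12:
                equal += 1
        return 2.0 * (below + 0.5 * equal) / n_null - 1.0

    samples = survey.samples
    if pair is not None:
        i, j = samples.index(pair[0]), samples.index(pair[1])
        return rc_pair(i, j)
    out = np.full((n_samples, n_samples), np.nan)
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            out[i, j] = out[j, i] = rc_pair(i, j)
    return pd.DataFrame(out, index=samples, columns=samples)


# ---------------------------------------------------------------------------
# Sloan neutral community model
# ---------------------------------------------------------------------------

@dataclass
class NCMFit:
    """Fitted Sloan neutral model: migration m, fit quality and envelope."""

    m: float
    N: float
    r_squared: float
    detection_limit: float
    taxa: pd.DataFrame  # p_bar, freq_obs, freq_pred, ci_low, ci_high

    @property
    def Nm(self) -> float:
        return self.N * self.m


def ncm_predicted_frequency(p_bar: np.ndarray, N: float, m: float, d: float) -> np.ndarray:
    """Occurrence frequency predicted by the Sloan model:
    1 − BetaCDF(d; N·m·p̄, N·m·(1 − p̄))."""
    a = N * m * p_bar
    b = N * m * (1.0 - p_bar)
    return 1.0 - stats.beta.cdf(d, np.maximum(a, 1e-12), np.maximum(b, 1e-12))


def fit_ncm(
    survey: CommunitySurvey,
    N: float = 1000.0,
    detection_limit: float | None = None,
    seed: int = 0,
) -> NCMFit:
    """Fit the Sloan neutral community model by bounded least squares.

    Taxon occurrence frequency (fraction of samples above the detection
    limit) is regressed on the neutral prediction as a function of the
    regional mean relative abundance p̄; the single free parameter is the
    migration rate m.  R² = 1 − SSE/SST; the 95% envelope uses Wilson
    score intervals on the predicted frequencies.
    """
    from statsmodels.stats.proportion import proportion_confint

    d = 1.0 / N if detection_limit is None else detection_limit
    p = survey.abundance.to_numpy(dtype=float)
    n_samples = p.shape[0]
    p_bar = p.mean(axis=0)
    keep = p_bar > 0
    if keep.sum() < 10:
        raise MtsError("NCM needs at least 10 taxa with nonzero regional mean")
    p_bar = p_bar[keep]
    freq_obs = (p[:, keep] > d).mean(axis=0)

    def residuals(log_m: np.ndarray) -> np.ndarray:
        return ncm_predicted_frequency(p_bar, N, float(np.exp(log_m[0])), d) - freq_obs

    result = optimize.least_squares(residuals, x0=[np.log(0.1)],
                                    bounds=([np.log(1e-6)], [0.0]), method="trf")
    if not result.success:
        raise MtsError(f"NCM fit did not converge: {result.message}")
    m = float(np.exp(result.x[0]))
    if m >= 0.999999:
        logger.warning("NCM migration estimate at the upper bound (m ≈ 1)")
    pred = ncm_predicted_frequency(p_bar, N, m, d)
    sse = float(((freq_obs - pred) ** 2).sum())
    sst = float(((freq_obs - freq_obs.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    ci_low, ci_high = proportion_confint(
        np.rint(pred * n_samples).astype(int), n_samples, alpha=0.05, method="wilson"
    )
    taxa = pd.DataFrame(
        {
            "p_bar": p_bar,
            "freq_obs": freq_obs,
            "freq_pred": pred,
            "ci_low": ci_low,
            "ci_high": ci_high,
        },
        index=np.array(survey.taxa)[keep],
    ).sort_values("p_bar")
    return NCMFit(m=m, N=N, r_squared=r2, detection_limit=d, taxa=taxa)


# ---------------------------------------------------------------------------
# Distance-decay relationships
# ---------------------------------------------------------------------------

@dataclass
class DDRFit:
    """OLS fit of community similarity on pairwise distance for one group."""

    slope: float
    intercept: float
    r_squared: float
    group: str
    kind: str
    points: pd.DataFrame  # distance, similarity


def haversine_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix (km) from decimal-degree coordinates."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def _pairwise_points(survey: CommunitySurvey, kind: str) -> pd.DataFrame:
    p = survey.abundance.to_numpy(dtype=float)
    n = len(survey.samples)
    if kind == "geographic":
        dmat = haversine_km(survey.meta["latitude"].to_numpy(), survey.meta["longitude"].to_numpy())
    elif kind == "edaphic":
        soil = survey.meta[list(SOIL_VARS)].to_numpy(dtype=float)
        sd = soil.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        z = (soil - soil.mean(axis=0)) / sd
        dmat = np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2))
    else:
        raise MtsError(f"unknown distance kind {kind!r}")
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            rows.append({"distance": dmat[i, j], "similarity": 1.0 - braycurtis(p[i], p[j])})
    return pd.DataFrame(rows)


def ddr(survey: CommunitySurvey, kind: str = "geographic", group: str = "all") -> DDRFit:
    """Distance-decay regression: similarity (1 − Bray-Curtis) ~ distance.

    Geographic distances are great-circle km; edaphic distances are
    Euclidean on z-scored soil variables.
    """
    if len(survey.samples) < 3:
        raise MtsError("DDR needs at least 3 samples")
    points = _pairwise_points(survey, kind)
    x = points["distance"].to_numpy()
    y = points["similarity"].to_numpy()
    if np.ptp(x) == 0:
        raise MtsError("zero distance variance: all samples co-located")
    res = stats.linregress(x, y)
    return DDRFit(slope=float(res.slope), intercept=float(res.intercept),
                  r_squared=float(res.rvalue**2), group=group, kind=kind, points=points)


def ddr_slope_difference(
    fit_a: DDRFit, fit_b: DDRFit, n_perm: int = 999, seed: int = 0
) -> float:
    """Permutation test for a difference in distance-decay slopes.

    The two groups' (distance, similarity) point clouds are pooled, group
    labels permuted over points, and the absolute slope difference
    recomputed; p = [1 + #(|Δ_perm| ≥ |Δ_obs|)] / (n_perm + 1).
    """
    if fit_a.kind != fit_b.kind:
        raise MtsError("slope difference requires fits on the same distance kind")
    if n_perm < 99:
        logger.warning("ddr_slope_difference: n_perm=%d is small; p resolution is coarse", n_perm)
    xa, ya = fit_a.points["distance"].to_numpy(), fit_a.points["similarity"].to_numpy()
    xb, yb = fit_b.points["distance"].to_numpy(), fit_b.points["similarity"].to_numpy()
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    na = len(xa)
    obs = abs(fit_a.slope - fit_b.slope)
    if obs == 0:
        return 1.0

    def slope(xs: np.ndarray, ys: np.ndarray) -> float:
        xc = xs - xs.mean()
        denom = (xc**2).sum()
        if denom == 0:
            return 0.0
        return float((xc * (ys - ys.mean())).sum() / denom)

    rng = np.random.default_rng(seed)
    hits = 0
    idx = np.arange(len(x))
    for _ in range(n_perm):
        rng.shuffle(idx)
        a, b = idx[:na], idx[na:]
        delta = abs(slope(x[a], y[a]) - slope(x[b], y[b]))
        if delta >= obs - 1e-15:
            hits += 1
    return (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def permanova(
    distance: pd.DataFrame, labels: pd.Series, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """One-way PERMANOVA: pseudo-F from among/within sums of squared
    distances with a label-permutation p-value (add-one rule)."""
    labels = labels.loc[distance.index]
    groups, counts = np.unique(labels.to_numpy(), return_counts=True)
    if len(groups) < 2:
        raise MtsError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        bad = groups[counts < 2]
        raise MtsError(f"singleton group(s): {list(bad)}")
    d2 = distance.to_numpy(dtype=float) ** 2
    n = d2.shape[0]
    codes = pd.Categorical(labels).codes

    def pseudo_f(codes: np.ndarray) -> float:
        sst = d2[np.triu_indices(n, 1)].sum() / n
        ssw = 0.0
        for g in range(len(groups)):
            idx = np.flatnonzero(codes == g)
            if len(idx) > 1:
                sub = d2[np.ix_(idx, idx)]
                ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ssa = sst - ssw
        dfa = len(groups) - 1
        dfw = n - len(groups)
        return (ssa / dfa) / (ssw / dfw)

    f_obs = pseudo_f(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(codes)) >= f_obs - 1e-15:
            hits += 1
    return f_obs, (1 + hits) / (n_perm + 1)
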