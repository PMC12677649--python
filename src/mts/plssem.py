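"""Partial-least-squares path modeling (PLS-SEM) over composite latents.

Estimates a directed acyclic system of latent variables, each measured by
a block of indicators, with the classic Lohmöller iteration: outer proxies
from weights, inner proxies by the centroid / factor / path scheme,
mode-A (or B) weight updates, iterated to convergence.  Path coefficients
come from ordinary least squares of each endogenous latent on its
predecessors over standardized scores; inference is by row-resampling
bootstrap with percentile intervals.

Typical use here: four latent blocks — soil nutrients, bacterial
functional potential, bacterial growth-rate potential, and
plant-beneficial species and genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import MtsError

logger = logging.getLogger("mts")


@dataclass
class ModelSpec:
    """Block structure and inner (structural) graph of a path model."""

    blocks: dict[str, list[str]]  # latent -> indicator columns
    inner: list[tuple[str, str]]  # directed (source, target) edges
    modes: dict[str, str] = field(default_factory=dict)  # latent -> 'A'|'B'
    scheme: str = "centroid"

    def __post_init__(self) -> None:
        latents = set(self.blocks)
        for src, dst in self.inner:
            if src not in latents or dst not in latents:
                raise MtsError(f"inner edge ({src}, {dst}) references unknown latent")
        if self.scheme not in ("centroid", "factor", "path"):
            raise MtsError(f"unknown inner scheme {self.scheme!r}")
        for latent, mode in self.modes.items():
            if mode not in ("A", "B"):
                raise MtsError(f"mode for {latent!r} must be 'A' or 'B'")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        indeg = {l: 0 for l in self.blocks}
        for _, dst in self.inner:
            indeg[dst] += 1
        queue = [l for l, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            node = queue.pop()
            seen += 1
            for src, dst in self.inner:
                if src == node:
                    indeg[dst] -= 1
                    if indeg[dst] == 0:
                        queue.append(dst)
        if seen != len(self.blocks):
            raise MtsError("inner graph must be acyclic")

    def predecessors(self, latent: str) -> list[str]:
        return [src for src, dst in self.inner if dst == latent]

    def mode(self, latent: str) -> str:
        return self.modes.get(latent, "A")


@dataclass
class PathModel:
    """Fitted path model: weights, loadings, scores, paths and R²."""

    spec: ModelSpec
    outer_weights: dict[str, pd.Series]
    loadings: dict[str, pd.Series]
    scores: pd.DataFrame  # standardized latent scores
    paths: pd.DataFrame  # columns: source, target, coefficient
    r_squared: dict[str, float]
    iterations: int
    boot: pd.DataFrame | None = None  # columns: source, target, ci_low, ci_high, p

    def path(self, source: str, target: str) -> float:
        hit = self.paths[(self.paths["source"] == source) & (self.paths["target"] == target)]
        if hit.empty:
            raise MtsError(f"no path {source} -> {target}")
        return float(hit["coefficient"].iloc[0])


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise MtsError("zero-variance indicator")
    return (x - x.mean(axis=0)) / sd


def _reliability(X: np.ndarray, w: np.ndarray) -> float:
    """Dijkstra's rho_A composite reliability of a mode-A block.

    Assumes loadings proportional to the converged weights; the
    proportionality constant reproduces the off-diagonal indicator
    correlations.  Single-indicator blocks are taken as error-free.
    """
    if len(w) == 1:
        return 1.0
    n = X.shape[0]
    S = X.T @ X / n
    num = float(w @ (S - np.diag(np.diag(S))) @ w)
    den = float(w @ (np.outer(w, w) - np.diag(w**2)) @ w)
    if den <= 0 or num <= 0:
        return 1.0
    c2 = num / den
    sd2 = float(w @ S @ w)
    rho = c2 * float(w @ w) ** 2 / sd2
    return float(np.clip(rho, 1e-6, 1.0))


def fit_plspm(
    data: pd.DataFrame,
    spec: ModelSpec,
    tol: float = 1e-6,
    max_iter: int = 300,
    consistent: bool = True,
    warn_small_n: bool = True,
) -> PathModel:
    """Fit a PLS path model by the Lohmöller algorithm.

    Indicators are standardized internally; latent scores are standardized
    at every step.  Each latent is oriented to correlate positively with
    its first indicator.  With ``consistent=True`` (default) the
    inter-composite correlations are disattenuated by Dijkstra's rho_A
    reliabilities before path estimation, removing the downward bias that
    raw composites impose on structural coefficients; set it to False for
    classic (attenuated) composite paths.  Raises on non-convergence.
    """
    latents = list(spec.blocks)
    n_indicators = sum(len(v) for v in spec.blocks.values())
    data = data.dropna(axis=0)
    if warn_small_n and len(data) < 2 * n_indicators:
        logger.warning("plssem: n=%d rows < 2x indicators (%d); estimates may be unstable",
                       len(data), n_indicators)
    blocks = {}
    for latent, cols in spec.blocks.items():
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise MtsError(f"block {latent!r}: missing indicator columns {missing}")
        blocks[latent] = _standardize(data[cols].to_numpy(dtype=float))
    n = len(data)

    neighbors = {l: set() for l in latents}
    for src, dst in spec.inner:
        neighbors[src].add(dst)
        neighbors[dst].add(src)

    weights = {l: np.ones(blocks[l].shape[1]) for l in latents}

    def scores_from(wts: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for l in latents:
            y = blocks[l] @ wts[l]
            sd = y.std(ddof=0)
            if sd == 0:
                raise MtsError(f"degenerate latent score for {l!r}")
            out[l] = y / sd
        return out

    it = 0
    for it in range(1, max_iter + 1):
        Y = scores_from(weights)
        # inner proxies
        Z = {}
        for l in latents:
            z = np.zeros(n)
            for other in neighbors[l]:
                r = float(np.dot(Y[l], Y[other]) / n)
                if spec.scheme == "centroid":
                    e = np.sign(r) if r != 0 else 1.0
                elif spec.scheme == "factor":
                    e = r
                else:  # path scheme
                    e = r  # successors weighted by correlation
                z += e * Y[other]
            if spec.scheme == "path":
                preds = spec.predecessors(l)
                if preds:
                    Xp = np.column_stack([Y[p] for p in preds])
                    beta, *_ = np.linalg.lstsq(Xp, Y[l], rcond=None)
                    z = Xp @ beta
                    for other in neighbors[l] - set(preds):
                        z += float(np.dot(Y[l], Y[other]) / n) * Y[other]
            sd = z.std(ddof=0)
            Z[l] = z / sd if sd > 0 else Y[l]
        # outer weight update
        new_weights = {}
        max_change = 0.0
        for l in latents:
            X = blocks[l]
            if spec.mode(l) == "A":
                w = X.T @ Z[l] / n  # indicator-inner-proxy covariances
            else:
                w, *_ = np.linalg.lstsq(X, Z[l], rcond=None)
            norm = np.linalg.norm(w)
            if norm == 0:
                raise MtsError(f"zero outer weights for {l!r}")
            w = w / norm
            ref = weights[l] / np.linalg.norm(weights[l])
            max_change = max(max_change, float(np.abs(np.abs(w) - np.abs(ref)).max()))
            new_weights[l] = w
        weights = new_weights
        if max_change < tol:
            break
    else:
        raise MtsError(f"PLS-PM did not converge in {max_iter} iterations "
                       f"(last weight change {max_change:.2e})")

    Y = scores_from(weights)
    # orient each latent positively with its first indicator
    for l in latents:
        r = float(np.dot(blocks[l][:, 0], Y[l]) / n)
        if r < 0:
            Y[l] = -Y[l]
            weights[l] = -weights[l]

    # latent correlation matrix, disattenuated by block reliabilities when
    # consistent estimation is requested
    rho = {l: (_reliability(blocks[l], weights[l]) if consistent else 1.0)
           for l in latents}
    R = pd.DataFrame(np.eye(len(latents)), index=latents, columns=latents)
    for i, a in enumerate(latents):
        for b in latents[i + 1:]:
            r = float(np.dot(Y[a], Y[b]) / n) / np.sqrt(rho[a] * rho[b])
            R.loc[a, b] = R.loc[b, a] = float(np.clip(r, -1.0, 1.0))

    paths_rows = []
    r_squared = {}
    for l in latents:
        preds = spec.predecessors(l)
        if not preds:
            continue
        R_pred = R.loc[preds, preds].to_numpy()
        r_vec = R.loc[preds, l].to_numpy()
        beta, *_ = np.linalg.lstsq(R_pred, r_vec, rcond=None)
        r_squared[l] = float(np.clip(beta @ r_vec, -np.inf, 1.0))
        for p_name, b in zip(preds, beta):
            paths_rows.append({"source": p_name, "target": l, "coefficient": float(b)})

    outer_weights = {l: pd.Series(weights[l], index=spec.blocks[l]) for l in latents}
    loadings = {
        l: pd.Series(blocks[l].T @ Y[l] / n, index=spec.blocks[l]) for l in latents
    }
    scores = pd.DataFrame({l: Y[l] for l in latents}, index=data.index)
    return PathModel(
        spec=spec,
        outer_weights=outer_weights,
        loadings=loadings,
        scores=scores,
        paths=pd.DataFrame(paths_rows),
        r_squared=r_squared,
        iterations=it,
    )


def bootstrap_paths(
    data: pd.DataFrame,
    spec: ModelSpec,
    n_boot: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 300,
    consistent: bool = True,
) -> pd.DataFrame:
    """Bootstrap path coefficients: percentile CIs and two-sided p-values.

    Rows are resampled with replacement and the model refit; the per-latent
    first-indicator sign convention keeps replicates aligned with the point
    estimates.  Fails if more than 5% of replicates cannot be refit.
    p-values invert the percentile interval with add-one smoothing.
    """
    point = fit_plspm(data, spec, tol=tol, max_iter=max_iter, consistent=consistent)
    rng = np.random.default_rng(seed)
    clean = data.dropna(axis=0)
    n = len(clean)
    draws: dict[tuple[str, str], list[float]] = {
        (r.source, r.target): [] for r in point.paths.itertuples()
    }
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = clean.iloc[idx].reset_index(drop=True)
        try:
            model = fit_plspm(sample, spec, tol=tol, max_iter=max_iter,
                              consistent=consistent, warn_small_n=False)
        except MtsError:
            failures += 1
            if failures > 0.05 * n_boot:
                raise MtsError(f"bootstrap: more than 5% of replicates failed ({failures})")
            continue
        for r in model.paths.itertuples():
            draws[(r.source, r.target)].append(r.coefficient)

    rows = []
    for r in point.paths.itertuples():
        values = np.array(draws[(r.source, r.target)])
        lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
        n_b = len(values)
        frac_le = (1 + (values <= 0).sum()) / (n_b + 1)
        frac_ge = (1 + (values >= 0).sum()) / (n_b + 1)
        rows.append({
            "source": r.source, "target": r.target, "coefficient": r.coefficient,
            "ci_low": float(lo), "ci_high": float(hi),
            "p": float(min(1.0, 2 * min(frac_le, frac_ge))),
        })
    out = pd.DataFrame(rows)
    point.boot = out
    return out
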