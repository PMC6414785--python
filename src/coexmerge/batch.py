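"""Platform batch-effect removal and variance auditing.

`combat` implements the parametric empirical-Bayes location/scale batch
adjustment: gene-wise standardization against a pooled model, per-batch
location (normal prior) and scale (inverse-gamma prior) estimates shrunk
by method-of-moments empirical Bayes, then removal and back-transformation.

`pvca` performs principal variance component analysis: a sample-space PCA
of the gene-standardized matrix followed by non-negative method-of-moments
variance-component estimation per retained component for each design
factor and pairwise interaction, averaged with eigenvalue weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .merge import MergedStudy

__all__ = ["combat", "pvca", "PVCAResult", "BatchModel"]

_EB_TOL = 1e-4
_EB_MAX_ITER = 100


@dataclass
class BatchModel:
    """Fitted batch model: per-batch EB-shrunk location/scale estimates."""

    batches: list[str]
    gamma_hat: pd.DataFrame        # batch × gene, raw locations
    delta_hat: pd.DataFrame        # batch × gene, raw scales
    gamma_star: pd.DataFrame       # batch × gene, shrunk locations
    delta_star: pd.DataFrame       # batch × gene, shrunk scales
    hyper: dict = field(default_factory=dict)


def _design_matrix(meta: pd.DataFrame, batch_factor: str,
                   covariates: list[str] | None) -> tuple[np.ndarray, list, np.ndarray]:
    batch = meta[batch_factor].astype(str)
    levels = sorted(batch.unique())
    onehot = np.column_stack([(batch == b).to_numpy(float) for b in levels])
    cov_cols = []
    if covariates:
        for cov in covariates:
            vals = meta[cov].astype(str)
            for lev in sorted(vals.unique())[1:]:  # drop first level
                cov_cols.append((vals == lev).to_numpy(float))
    cov = np.column_stack(cov_cols) if cov_cols else np.empty((len(meta), 0))
    design = np.hstack([onehot, cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            f"design is rank deficient: covariates {covariates} are confounded "
            f"with batch factor {batch_factor!r}")
    return design, levels, onehot


def _aprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (2 * s2 + m ** 2) / s2


def _bprior(d: np.ndarray) -> float:
    m, s2 = d.mean(), d.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _it_sol(z_batch: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-point solution of the EB conditional posterior means."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(_EB_MAX_ITER):
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2 + a - 1)
        change = max((np.abs(g_new - g_old) / np.abs(g_old)).max(),
                     (np.abs(d_new - d_old) / d_old).max())
        g_old, d_old = g_new, d_new
        if change < _EB_TOL:
            break
    return g_old, d_old


def combat(ms: MergedStudy, batch_factor: str = "platform",
           covariates: list[str] | None = None,
           return_model: bool = False):
    """Remove batch effects with the parametric EB location/scale model.

    Parameters
    ----------
    ms
        Merged study; ``batch_factor`` names a metadata column with ≥ 2
        batches of ≥ 2 samples each.
    covariates
        Optional metadata factors whose effects are preserved during
        standardization (must not be confounded with batch).
    return_model
        Also return the fitted :class:`BatchModel`.
    """
    meta = ms.metadata
    batch = meta[batch_factor].astype(str)
    counts = batch.value_counts()
    if len(counts) < 2:
        raise ValueError(f"need >= 2 batches in {batch_factor!r}, found {len(counts)}")
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"batch(es) with < 2 samples: {list(small.index)}")

    design, levels, onehot = _design_matrix(meta, batch_factor, covariates)
    y = ms.values.to_numpy(dtype=float)          # genes × samples
    n_array = y.shape[1]
    n_batches = onehot.sum(axis=0)

    # pooled model fit; batch means constrained by sample-size weighting
    beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)   # params × genes
    grand_mean = (n_batches / n_array) @ beta[: len(levels)]
    var_pooled = ((y - (design @ beta).T) ** 2).mean(axis=1)
    if np.any(var_pooled <= 0):
        bad = ms.genes[np.flatnonzero(var_pooled <= 0)]
        raise ValueError(f"zero pooled variance for genes: {list(bad)[:5]}")
    stand_mean = grand_mean[:, None] + (design[:, len(levels):] @ beta[len(levels):]).T
    z = (y - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat, delta_hat, gamma_star, delta_star = {}, {}, {}, {}
    hyper = {}
    for i, b in enumerate(levels):
        idx = onehot[:, i].astype(bool)
        zb = z[:, idx]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        a_pr, b_pr = _aprior(d_hat), _bprior(d_hat)
        g_star, d_star = _it_sol(zb, g_hat, d_hat, g_bar, t2, a_pr, b_pr)
        gamma_hat[b], delta_hat[b] = g_hat, d_hat
        gamma_star[b], delta_star[b] = g_star, d_star
        hyper[b] = {"gamma_bar": g_bar, "t2": t2, "a_prior": a_pr, "b_prior": b_pr}

    adjusted = z.copy()
    for i, b in enumerate(levels):
        idx = onehot[:, i].astype(bool)
        adjusted[:, idx] = (z[:, idx] - gamma_star[b][:, None]) / \
            np.sqrt(delta_star[b])[:, None]
    adjusted = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean

    values = pd.DataFrame(adjusted, index=ms.genes, columns=ms.samples)
    out = ms.copy_with(values, combat={"batch_factor": batch_factor,
                                       "covariates": list(covariates or []),
                                       "batches": {b: int(c) for b, c in counts.items()}})
    if return_model:
        genes = ms.genes
        model = BatchModel(
            batches=levels,
            gamma_hat=pd.DataFrame(gamma_hat, index=genes).T,
            delta_hat=pd.DataFrame(delta_hat, index=genes).T,
            gamma_star=pd.DataFrame(gamma_star, index=genes).T,
            delta_star=pd.DataFrame(delta_star, index=genes).T,
            hyper=hyper,
        )
        return out, model
    return out


@dataclass
class PVCAResult:
    """Eigenvalue-weighted variance proportions per design factor."""

    proportions: pd.Series          # factor (incl. interactions, residual) -> fraction
    n_components: int
    variance_threshold: float
    per_component: pd.DataFrame | None = None

    def top_factor(self) -> str:
        return self.proportions.idxmax()


def _oneway_vc(y: np.ndarray, groups: pd.Series) -> float:
    """Non-negative method-of-moments variance component, one-way layout."""
    levels = groups.unique()
    k = len(levels)
    if k < 2 or k == len(y):
        return 0.0
    n = len(y)
    ssb = ssw = 0.0
    sizes = []
    gbar = y.mean()
    for lev in levels:
        yi = y[(groups == lev).to_numpy()]
        sizes.append(len(yi))
        ssb += len(yi) * (yi.mean() - gbar) ** 2
        ssw += ((yi - yi.mean()) ** 2).sum()
    msb = ssb / (k - 1)
    msw = ssw / (n - k) if n > k else 0.0
    n0 = (n - sum(s * s for s in sizes) / n) / (k - 1)
    return max(0.0, (msb - msw) / n0)


def pvca(ms: MergedStudy, factors: list[str],
         variance_threshold: float = 0.6,
         keep_per_component: bool = False) -> PVCAResult:
    """Principal variance component analysis of a merged study.

    Gene rows are standardized, samples are projected onto principal
    components retaining the smallest set whose cumulative variance
    reaches ``variance_threshold``; per component, variance components
    for each factor, each pairwise interaction and the residual are
    estimated (negative estimates truncated at zero) and the
    eigenvalue-weighted average of per-component proportions is reported.
    """
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    usable = []
    for f in factors:
        if f not in ms.metadata.columns:
            raise ValueError(f"factor {f!r} not in metadata")
        if ms.metadata[f].astype(str).nunique() < 2:
            warnings.warn(f"factor {f!r} has a single level; excluded from PVCA")
        else:
            usable.append(f)
    if not usable:
        raise ValueError("no usable factors (all single-level)")

    x = ms.values.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    if np.all(sd == 0):
        raise ValueError("all genes constant; PVCA model singular")
    xs = (x[sd > 0] - x[sd > 0].mean(axis=1, keepdims=True)) / sd[sd > 0][:, None]
    # sample-space PCA
    obs = xs.T                                        # samples × genes
    obs = obs - obs.mean(axis=0)
    _, s, vt = np.linalg.svd(obs, full_matrices=False)
    eig = s ** 2
    frac = eig / eig.sum()
    k = int(np.searchsorted(np.cumsum(frac), variance_threshold) + 1)
    k = min(k, len(eig))
    scores = obs @ vt[:k].T                           # samples × k

    meta = ms.metadata
    effects: dict[str, pd.Series] = {f: meta[f].astype(str) for f in usable}
    inter_names = []
    for a, b in combinations(usable, 2):
        name = f"{a}:{b}"
        inter_names.append(name)
        effects[name] = meta[a].astype(str) + "\x1f" + meta[b].astype(str)
    finest = meta[usable[0]].astype(str)
    for f in usable[1:]:
        finest = finest + "\x1f" + meta[f].astype(str)

    rows = []
    for j in range(k):
        y = scores[:, j]
        comp: dict[str, float] = {}
        for f in usable:
            comp[f] = _oneway_vc(y, effects[f])
        for name in inter_names:
            a, b = name.split(":")
            raw = _oneway_vc(y, effects[name])
            comp[name] = max(0.0, raw - comp[a] - comp[b])
        # residual: within-cell variance at the finest factor cross
        resid_num = resid_den = 0.0
        for lev in finest.unique():
            yi = y[(finest == lev).to_numpy()]
            if len(yi) >= 2:
                resid_num += ((yi - yi.mean()) ** 2).sum()
                resid_den += len(yi) - 1
        resid = resid_num / resid_den if resid_den > 0 else \
            max(0.0, y.var(ddof=1) - sum(comp.values()))
        comp["residual"] = resid
        total = sum(comp.values())
        if total == 0:
            comp = {name: 0.0 for name in comp}
            comp["residual"] = 1.0
            total = 1.0
        rows.append({name: v / total for name, v in comp.items()})

    per_comp = pd.DataFrame(rows)
    weights = frac[:k] / frac[:k].sum()
    proportions = per_comp.mul(weights, axis=0).sum()
    proportions = proportions / proportions.sum()
    return PVCAResult(
        proportions=proportions,
        n_components=k,
        variance_threshold=variance_threshold,
        per_component=per_comp if keep_per_component else None,
    )
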