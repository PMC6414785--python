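"""Weighted gene co-expression network analysis core.

Builds an unsigned weighted network (adjacency ``|cor|^beta``), derives the
topological overlap measure (TOM), detects modules by average-linkage
clustering of ``1 - TOM`` with a static tree cut, merges modules with
correlated eigengenes, and provides hub/connectivity analysis, thresholded
edge export and cross-network module overlap statistics.

Module labels are size-ranked (1 = largest) and carry the conventional
color names (turquoise, blue, brown, ...); label 0 ("grey") collects
unassigned genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

__all__ = [
    "NetworkModel", "SoftThresholdFit", "ModuleAssignment", "EigengeneMatrix",
    "adjacency", "pick_soft_threshold", "tom_similarity", "detect_modules",
    "module_eigengenes", "merge_close_modules", "intramodular_connectivity",
    "export_module_edges", "module_overlap",
]

# conventional module color order, by decreasing module size rank
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)
GREY = "grey"


def _expr_matrix(data) -> pd.DataFrame:
    """Accept a MergedStudy or a bare gene × sample DataFrame."""
    return data.values if hasattr(data, "metadata") else data


@dataclass
class NetworkModel:
    """Unsigned weighted network over a fixed gene list."""

    genes: pd.Index
    beta: float
    adjacency: np.ndarray
    tom: np.ndarray | None = None
    network_type: str = "unsigned"

    def tom_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tom, index=self.genes, columns=self.genes)


@dataclass
class SoftThresholdFit:
    """Scale-free-topology fit across candidate soft-thresholding powers."""

    table: pd.DataFrame          # beta, r2_signed, slope, k_mean, k_median, k_max
    recommended: float
    target_r2: float


@dataclass
class ModuleAssignment:
    """Gene → module labels, size-ranked, with conventional color names."""

    labels: pd.Series            # gene -> int, 0 = unassigned
    colors: pd.Series            # gene -> color name
    min_module_size: int
    cut_height: float | None = None
    merge_distance: float | None = None

    def module_genes(self, label) -> pd.Index:
        if isinstance(label, str):
            mask = self.colors == label
        else:
            mask = self.labels == label
        if not mask.any():
            raise KeyError(f"no module {label!r}")
        return self.labels.index[mask]

    def sizes(self) -> pd.Series:
        counts = self.labels[self.labels > 0].value_counts().sort_index()
        return counts

    @property
    def n_modules(self) -> int:
        return int((self.labels.unique() > 0).sum())


@dataclass
class EigengeneMatrix:
    """Module eigengenes (first PC of each module's standardized genes)."""

    eigengenes: pd.DataFrame         # module label × sample, rows unit norm
    variance_explained: pd.Series    # module label -> fraction
    colors: dict = field(default_factory=dict)


def adjacency(data, beta: float = 9.0) -> NetworkModel:
    """Unsigned adjacency ``a_ij = |cor(x_i, x_j)|**beta`` with unit diagonal."""
    expr = _expr_matrix(data)
    if beta < 1:
        raise ValueError("beta must be >= 1")
    x = expr.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = expr.index[np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance genes (filter upstream): {list(bad)[:10]}")
    cor = np.corrcoef(x)
    a = np.abs(np.clip(cor, -1, 1)) ** beta
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return NetworkModel(genes=expr.index, beta=float(beta), adjacency=a)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float] | None:
    """Signed R² and slope of log10 p(k) vs log10 mean-k over
    equal-occupancy bins; None when fewer than 3 usable bins."""
    k = k[k > 0]
    if len(k) < 3:
        return None
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 4:
        return None
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    xs, ys = [], []
    total = len(k)
    for b in range(len(edges) - 1):
        sel = idx == b
        width = edges[b + 1] - edges[b]
        if sel.sum() == 0 or width <= 0:
            continue
        # equal-occupancy bins: p(k) is the empirical density, not the
        # (constant) bin proportion
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.sum() / (total * width)))
    if len(xs) < 3:
        return None
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = ((ys - pred) ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    signed = -r2 if slope > 0 else r2
    return signed, slope


def pick_soft_threshold(data, candidate_betas=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
                                               12, 14, 16, 18, 20),
                        target_r2: float = 0.85) -> SoftThresholdFit:
    """Scan candidate powers for approximate scale-free topology.

    Recommends the smallest power whose signed fit R² reaches ``target_r2``,
    falling back to the power with the best signed R².
    """
    expr = _expr_matrix(data)
    if len(candidate_betas) < 1:
        raise ValueError("need at least one candidate power")
    x = expr.to_numpy(dtype=float)
    cor = np.abs(np.corrcoef(x))
    np.fill_diagonal(cor, 0.0)
    rows = []
    for b in candidate_betas:
        a = cor ** b
        k = a.sum(axis=1)
        fit = _scale_free_fit(k)
        if fit is None:
            warnings.warn(f"beta={b}: fewer than 3 usable connectivity bins; skipped")
            r2, slope = np.nan, np.nan
        else:
            r2, slope = fit
        rows.append({"beta": float(b), "r2_signed": r2, "slope": slope,
                     "k_mean": k.mean(), "k_median": np.median(k), "k_max": k.max()})
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["r2_signed"])
    passing = ok[ok["r2_signed"] >= target_r2]
    if not passing.empty:
        recommended = float(passing["beta"].iloc[0])
    elif not ok.empty:
        recommended = float(ok.loc[ok["r2_signed"].idxmax(), "beta"])
    else:
        raise ValueError("scale-free fit failed for every candidate power")
    return SoftThresholdFit(table=table, recommended=recommended, target_r2=target_r2)


def tom_similarity(nm: NetworkModel) -> NetworkModel:
    """Fill the unsigned topological overlap matrix.

    ``w_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``L_ij = sum_u a_iu a_uj`` over ``u != i, j`` and ``k_i = sum_u a_iu``
    over ``u != i``; diagonal fixed at 1.
    """
    a = nm.adjacency
    n = a.shape[0]
    # (A @ A)_ij includes u = i and u = j terms a_ii*a_ij + a_ij*a_jj = 2 a_ij
    l_mat = a @ a - 2 * a
    k = a.sum(axis=1) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l_mat + a) / denom
    tom = np.where(denom <= 0, 0.0, tom)
    tom = np.clip((tom + tom.T) / 2, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return NetworkModel(genes=nm.genes, beta=nm.beta, adjacency=a, tom=tom,
                        network_type=nm.network_type)


def _rank_labels(raw: pd.Series, min_module_size: int) -> tuple[pd.Series, pd.Series]:
    """Prune small branches to 0, rank modules by size, attach colors."""
    labels = raw.copy()
    counts = labels.value_counts()
    for lab, cnt in counts.items():
        if lab != 0 and cnt < min_module_size:
            labels[labels == lab] = 0
    sizes = labels[labels > 0].value_counts()
    # deterministic rank: size desc, then smallest member symbol
    order = sorted(sizes.index,
                   key=lambda lab: (-sizes[lab], min(labels.index[labels == lab])))
    remap = {old: i + 1 for i, old in enumerate(order)}
    remap[0] = 0
    ranked = labels.map(remap)
    colors = ranked.map(lambda r: GREY if r == 0 else (
        MODULE_COLORS[r - 1] if r <= len(MODULE_COLORS) else f"module_{r}"))
    return ranked, colors


def detect_modules(nm: NetworkModel, min_module_size: int = 30,
                   cut_height: float = 0.998) -> ModuleAssignment:
    """Average-linkage clustering of ``1 - TOM`` with a static cut.

    The tree is cut at ``cut_height`` times the maximum merge height;
    branches smaller than ``min_module_size`` fall back to label 0.
    Under high soft powers the adjacency is strongly compressed and all
    informative splits sit in the top percent of merge heights, so the
    default cut (0.998) is close to the root; lower cuts strip the
    peripheral members of weakly correlated but real modules.
    """
    if nm.tom is None:
        raise ValueError("TOM not computed; call tom_similarity first")
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    diss = 1.0 - nm.tom
    np.fill_diagonal(diss, 0.0)
    diss = np.maximum(diss, 0.0)
    z = hierarchy.linkage(squareform(diss, checks=False), method="average")
    h = cut_height * z[:, 2].max()
    raw = pd.Series(hierarchy.fcluster(z, t=h, criterion="distance"),
                    index=nm.genes)
    ranked, colors = _rank_labels(raw, min_module_size)
    if (ranked == 0).all():
        warnings.warn("no module reached min_module_size; all genes unassigned")
    return ModuleAssignment(labels=ranked, colors=colors,
                            min_module_size=min_module_size, cut_height=cut_height)


def module_eigengenes(data, assignment: ModuleAssignment) -> EigengeneMatrix:
    """First principal component per module on gene-standardized profiles.

    Eigengenes have unit norm across samples and are oriented so the mean
    correlation with their module's genes is non-negative.
    """
    expr = _expr_matrix(data)
    rows, var_expl = {}, {}
    for lab in sorted(assignment.sizes().index):
        genes = assignment.module_genes(lab)
        if len(genes) < 2:
            raise ValueError(f"module {lab} has < 2 genes")
        x = expr.loc[genes].to_numpy(dtype=float)
        sd = x.std(axis=1, ddof=1)
        if np.any(sd == 0):
            raise ValueError(f"module {lab}: constant gene(s), eigengene undefined")
        xs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        u, s, vt = np.linalg.svd(xs, full_matrices=False)
        e = vt[0]
        cors = np.array([np.corrcoef(e, row)[0, 1] for row in xs])
        if cors.mean() < 0:
            e = -e
        rows[lab] = e
        var_expl[lab] = float(s[0] ** 2 / (s ** 2).sum())
    eig = pd.DataFrame(rows, index=expr.columns).T
    eig.index.name = "module"
    colors = {lab: assignment.colors[assignment.module_genes(lab)[0]]
              for lab in eig.index}
    return EigengeneMatrix(eigengenes=eig,
                           variance_explained=pd.Series(var_expl),
                           colors=colors)


def merge_close_modules(data, assignment: ModuleAssignment,
                        merge_distance: float = 0.25) -> ModuleAssignment:
    """Iteratively merge module pairs whose eigengene dissimilarity
    ``1 - cor`` falls below ``merge_distance`` (closest pair first,
    eigengenes recomputed after each merge)."""
    if not 0 < merge_distance < 1:
        raise ValueError("merge_distance must be in (0, 1)")
    expr = _expr_matrix(data)
    labels = assignment.labels.copy()
    while True:
        active = sorted(set(labels[labels > 0]))
        if len(active) < 2:
            break
        eig = module_eigengenes(expr, ModuleAssignment(
            labels=labels, colors=assignment.colors,
            min_module_size=assignment.min_module_size))
        e = eig.eigengenes.loc[active].to_numpy()
        cor = np.corrcoef(e)
        diss = 1 - cor
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_distance:
            break
        keep, drop = sorted((active[i], active[j]))
        labels[labels == drop] = keep
    ranked, colors = _rank_labels(labels, assignment.min_module_size)
    return ModuleAssignment(labels=ranked, colors=colors,
                            min_module_size=assignment.min_module_size,
                            cut_height=assignment.cut_height,
                            merge_distance=merge_distance)


def intramodular_connectivity(nm: NetworkModel,
                              assignment: ModuleAssignment) -> pd.DataFrame:
    """Per-gene total and within-module connectivity plus per-module hubs.

    Returns a table (gene, module, color, kTotal, kWithin, is_hub); the hub
    of a module is its maximum-kWithin gene, ties broken lexicographically.
    """
    if not assignment.labels.index.equals(nm.genes):
        raise ValueError("assignment does not match network genes")
    a = nm.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k_total = a.sum(axis=1)
    labels = assignment.labels.to_numpy()
    k_within = np.zeros_like(k_total)
    for lab in np.unique(labels):
        idx = labels == lab
        k_within[idx] = a[np.ix_(idx, idx)].sum(axis=1)
    table = pd.DataFrame({
        "module": assignment.labels,
        "color": assignment.colors,
        "kTotal": k_total,
        "kWithin": k_within,
    }, index=nm.genes)
    table["is_hub"] = False
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sub = table[table["module"] == lab]
        table.loc[_first_lex_max(sub), "is_hub"] = True
    return table


def _first_lex_max(sub: pd.DataFrame) -> str:
    mx = sub["kWithin"].max()
    return min(sub.index[sub["kWithin"] == mx])


def export_module_edges(nm: NetworkModel, assignment: ModuleAssignment,
                        module_label, weight_threshold: float = 0.0
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """TOM edges within a module with weight strictly above threshold.

    Returns (edge table sorted by descending weight, per-gene exported
    degree). Each undirected pair appears once.
    """
    if nm.tom is None:
        raise ValueError("TOM not computed")
    genes = assignment.module_genes(module_label)
    pos = pd.Series(np.arange(len(nm.genes)), index=nm.genes)
    idx = pos[genes].to_numpy()
    sub = nm.tom[np.ix_(idx, idx)]
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            w = sub[i, j]
            if w > weight_threshold:
                ga, gb = sorted((genes[i], genes[j]))
                rows.append((ga, gb, w))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
    edges = edges.sort_values(["weight", "gene_a", "gene_b"],
                              ascending=[False, True, True]).reset_index(drop=True)
    degree = pd.Series(0, index=genes, dtype=int)
    for col in ("gene_a", "gene_b"):
        vc = edges[col].value_counts()
        degree.loc[vc.index] += vc
    return edges, degree


def module_overlap(assign_a: ModuleAssignment, assign_b: ModuleAssignment,
                   universe, label_a, label_b,
                   restrict_to=None) -> dict:
    """Overlap statistics between one module of each assignment.

    Reports set sizes, intersection, Jaccard and per-set fractions, and
    the upper-tail hypergeometric p-value of the intersection given the
    shared ``universe``. ``restrict_to`` (e.g. a transcription-factor list)
    is intersected with everything first.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(assign_a.module_genes(label_a)) & universe
    b = set(assign_b.module_genes(label_b)) & universe
    if restrict_to is not None:
        restrict = set(restrict_to)
        universe &= restrict
        a &= restrict
        b &= restrict
    inter = a & b
    union = a | b
    m, n_a, n_b, k = len(universe), len(a), len(b), len(inter)
    p = float(hypergeom.sf(k - 1, m, n_a, n_b)) if k > 0 else 1.0
    return {
        "n_a": n_a, "n_b": n_b, "n_overlap": k, "n_universe": m,
        "jaccard": k / len(union) if union else 0.0,
        "fraction_of_a": k / n_a if n_a else 0.0,
        "fraction_of_b": k / n_b if n_b else 0.0,
        "p_hypergeometric": min(p, 1.0),
    }
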