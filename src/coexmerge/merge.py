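"""Cross-platform merging of probe-level expression matrices.

Collapses many-to-one probe→gene-symbol maps to one row per gene (the
"max signal probe" convention: the probe with the highest mean intensity
represents its gene), intersects gene universes across platforms, and
offers post-merge renormalization, variance (IQR) filtering and explicit
sample exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProbeMatrix",
    "GeneMatrix",
    "MergedStudy",
    "collapse_probes",
    "intersect_and_merge",
    "renormalize",
    "iqr_filter",
    "exclude_samples",
]

#: columns every sample-metadata table must carry
METADATA_COLUMNS = ("platform", "state", "group", "timepoint")


@dataclass
class ProbeMatrix:
    """Probe-level log2 intensities plus a probe→gene-symbol annotation.

    Parameters
    ----------
    values
        probe × sample matrix, index = probe ids (unique), finite log2
        intensities.
    annotation
        Series mapping probe id → gene symbol. Probes absent from the
        annotation (or mapped to NaN/empty) are treated as unannotated
        and dropped at collapse time.
    platform_id
        Free-text platform label (e.g. ``"illumina"``).
    """

    values: pd.DataFrame
    annotation: pd.Series
    platform_id: str = "platform"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("probe ids must be unique")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("probe matrix contains non-finite values")
        self.annotation = self.annotation.dropna()
        self.annotation = self.annotation[self.annotation.astype(str) != ""]

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class GeneMatrix:
    """Gene-level matrix: one row per symbol, with winning-probe provenance."""

    values: pd.DataFrame
    source: str
    provenance: pd.Series  # gene symbol -> winning probe id

    @property
    def gene_symbols(self) -> pd.Index:
        return self.values.index


@dataclass
class MergedStudy:
    """Gene × sample matrix over an intersected gene universe.

    ``metadata`` is indexed by sample id and covers every column exactly
    once; ``report`` accumulates provenance (counts, exclusions, warnings)
    across pipeline stages.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata lacks columns: {missing}")
        if set(self.metadata.index) != set(self.values.columns):
            raise ValueError("metadata must cover every sample exactly once")
        if self.metadata.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        # align metadata row order to column order
        self.metadata = self.metadata.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def copy_with(self, values: pd.DataFrame, metadata: pd.DataFrame | None = None,
                  **report_updates) -> "MergedStudy":
        rep = dict(self.report)
        rep.update(report_updates)
        return MergedStudy(values, self.metadata if metadata is None else metadata, rep)


def collapse_probes(pm: ProbeMatrix) -> GeneMatrix:
    """Collapse a probe matrix to one row per gene symbol.

    For each symbol the probe with the highest mean intensity across all
    samples wins (ties broken by lexicographically smallest probe id);
    unannotated probes are dropped. Rows come out sorted by symbol.
    """
    if pm.annotation.empty:
        raise ValueError(f"platform {pm.platform_id!r}: annotation is empty, unusable")
    annotated = pm.values.index.intersection(pm.annotation.index)
    if annotated.empty:
        raise ValueError(f"platform {pm.platform_id!r}: no annotated probes")
    vals = pm.values.loc[annotated]
    means = vals.mean(axis=1)
    picker = pd.DataFrame({
        "symbol": pm.annotation.loc[annotated].astype(str).to_numpy(),
        "mean": means.to_numpy(),
        "probe": annotated.to_numpy(),
    })
    # highest mean first; ties -> smallest probe id
    picker = picker.sort_values(["symbol", "mean", "probe"],
                                ascending=[True, False, True], kind="mergesort")
    winners = picker.drop_duplicates("symbol", keep="first")
    out = vals.loc[winners["probe"]].copy()
    out.index = pd.Index(winners["symbol"], name="gene")
    provenance = pd.Series(winners["probe"].to_numpy(), index=out.index, name="probe")
    return GeneMatrix(values=out, source=pm.platform_id, provenance=provenance)


def intersect_and_merge(gm_a: GeneMatrix, gm_b: GeneMatrix,
                        meta: pd.DataFrame) -> MergedStudy:
    """Merge two collapsed platforms on their shared gene symbols.

    Rows are the sorted intersection of symbols; columns are platform-A
    samples followed by platform-B samples, values copied unchanged.
    Genes private to one platform are discarded and counted in the report.
    """
    shared = gm_a.gene_symbols.intersection(gm_b.gene_symbols).sort_values()
    if shared.empty:
        raise ValueError("gene universes are disjoint: nothing to merge")
    dup = gm_a.values.columns.intersection(gm_b.values.columns)
    if not dup.empty:
        raise ValueError(f"duplicate sample ids across platforms: {list(dup)[:5]}")
    merged = pd.concat([gm_a.values.loc[shared], gm_b.values.loc[shared]], axis=1)
    report = {
        "intersected_genes": int(len(shared)),
        "discarded_private_genes": {
            gm_a.source: int(len(gm_a.gene_symbols) - len(shared)),
            gm_b.source: int(len(gm_b.gene_symbols) - len(shared)),
        },
        "source_platform": {
            **{s: gm_a.source for s in gm_a.values.columns},
            **{s: gm_b.source for s in gm_b.values.columns},
        },
    }
    return MergedStudy(values=merged, metadata=meta.loc[merged.columns], report=report)


def renormalize(ms: MergedStudy, method: str = "none") -> MergedStudy:
    """Post-merge renormalization: ``scale``, ``quantile`` or ``none``.

    scale
        per-sample centering to zero mean and unit standard deviation.
    quantile
        classic quantile normalization: each column's sorted values are
        replaced by the cross-column mean of sorted values; ties within a
        column receive the mean of the candidate values.
    """
    if method == "none":
        return ms.copy_with(ms.values.copy(), renormalize="none")
    x = ms.values.to_numpy(dtype=float)
    if method == "scale":
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = ms.samples[np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance sample(s) under 'scale': {list(bad)}")
        out = (x - x.mean(axis=0)) / sd
    elif method == "quantile":
        order = np.argsort(x, axis=0, kind="mergesort")
        ref = np.sort(x, axis=0).mean(axis=1)
        out = np.empty_like(x)
        for j in range(x.shape[1]):
            col = np.empty(x.shape[0])
            col[order[:, j]] = ref
            # ties: average the reference values the tied group spans
            colvals = x[:, j]
            srt = colvals[order[:, j]]
            ties = pd.Series(ref).groupby(srt).transform("mean").to_numpy()
            col[order[:, j]] = ties
            out[:, j] = col
    else:
        raise ValueError(f"unknown renormalization method {method!r}")
    values = pd.DataFrame(out, index=ms.genes, columns=ms.samples)
    return ms.copy_with(values, renormalize=method)


def _row_iqr(x: np.ndarray) -> np.ndarray:
    q1, q3 = np.quantile(x, [0.25, 0.75], axis=1, method="linear")
    return q3 - q1


def iqr_filter(ms: MergedStudy, threshold: float = 0.5) -> MergedStudy:
    """Keep genes whose across-sample interquartile range strictly exceeds
    ``threshold`` (linear-interpolation quantiles); order preserved."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    iqr = _row_iqr(ms.values.to_numpy(dtype=float))
    keep = iqr > threshold
    values = ms.values.loc[keep]
    return ms.copy_with(values, iqr_filter={
        "threshold": float(threshold),
        "kept": int(keep.sum()),
        "dropped": int((~keep).sum()),
    })


def exclude_samples(ms: MergedStudy, sample_ids: list[str]) -> MergedStudy:
    """Drop the listed samples (an explicit outlier list) and their metadata."""
    unknown = [s for s in sample_ids if s not in ms.samples]
    if unknown:
        raise ValueError(f"unknown sample ids: {unknown}")
    keep = [s for s in ms.samples if s not in set(sample_ids)]
    values = ms.values[keep]
    meta = ms.metadata.loc[keep]
    report_update: dict = {"excluded_samples": list(sample_ids)}
    if len(sample_ids) and meta["platform"].nunique() < 2 <= ms.metadata["platform"].nunique():
        report_update["warnings"] = ms.report.get("warnings", []) + [
            "exclusion left a single platform"]
    return ms.copy_with(values, metadata=meta, **report_update)
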