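"""ChIP-seq peak → gene assignment and module enrichment testing.

Peaks (scored BED intervals) are assigned to genes when the peak midpoint
lies within a distance cutoff of the gene's TSS (strict inequality, same
chromosome); module enrichment is a two-sided Fisher exact test of
peak-bearing gene counts in one module against a comparison module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

__all__ = [
    "read_bed", "write_bed", "read_loci",
    "annotate_peaks_to_genes", "module_peak_enrichment", "EnrichmentResult",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score"]
LOCI_COLUMNS = ["symbol", "chrom", "tss", "strand"]


def read_bed(path) -> pd.DataFrame:
    peaks = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS,
                        comment="#")
    validate_peaks(peaks)
    return peaks


def write_bed(peaks: pd.DataFrame, path) -> None:
    peaks[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_loci(path) -> pd.DataFrame:
    loci = pd.read_csv(path, sep="\t")
    validate_loci(loci)
    return loci


def validate_peaks(peaks: pd.DataFrame) -> None:
    if not (peaks["start"] < peaks["end"]).all():
        raise ValueError("malformed peaks: require start < end (0-based, half-open)")
    if (peaks["score"] < 0).any():
        raise ValueError("malformed peaks: negative scores")


def validate_loci(loci: pd.DataFrame) -> None:
    missing = [c for c in LOCI_COLUMNS if c not in loci.columns]
    if missing:
        raise ValueError(f"loci table lacks columns: {missing}")
    if loci["symbol"].duplicated().any():
        raise ValueError("duplicate gene symbols in loci")
    bad = set(loci["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"invalid strand values: {bad}")


def annotate_peaks_to_genes(peaks: pd.DataFrame, loci: pd.DataFrame,
                            max_distance: int = 1000,
                            min_score: float = 0.0) -> pd.DataFrame:
    """Flag genes with a retained peak midpoint within ``max_distance`` of
    their TSS.

    Peaks scoring below ``min_score`` are dropped first. Distance is the
    absolute genomic distance between the peak midpoint and the annotated
    TSS (strand enters only through the TSS coordinate); the cutoff is a
    strict inequality. Returns a table (symbol, has_peak,
    nearest_distance) covering every gene in ``loci``.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be > 0")
    validate_peaks(peaks)
    validate_loci(loci)
    kept = peaks[peaks["score"] >= min_score]
    shared = set(kept["chrom"]) & set(loci["chrom"])
    if not shared and len(kept) and len(loci):
        raise ValueError("no shared chromosomes between peaks and loci")
    mids = kept["start"].to_numpy() + (kept["end"].to_numpy()
                                       - kept["start"].to_numpy()) / 2.0
    by_chrom = {c: np.sort(mids[(kept["chrom"] == c).to_numpy()])
                for c in shared}
    rows = []
    for sym, chrom, tss in loci[["symbol", "chrom", "tss"]].itertuples(index=False):
        m = by_chrom.get(chrom)
        if m is None or len(m) == 0:
            rows.append((sym, False, np.nan))
            continue
        i = np.searchsorted(m, tss)
        cand = [abs(m[j] - tss) for j in (i - 1, i) if 0 <= j < len(m)]
        nearest = float(min(cand))
        rows.append((sym, nearest < max_distance, nearest))
    return pd.DataFrame(rows, columns=["symbol", "has_peak", "nearest_distance"]
                        ).set_index("symbol")


@dataclass
class EnrichmentResult:
    """2×2 peak enrichment of a module against a comparison module."""

    table: np.ndarray            # [[module_with, module_without],
    #                              [comparison_with, comparison_without]]
    odds_ratio: float
    p_value: float
    continuity_corrected: bool

    def counts(self) -> dict:
        (a, b), (c, d) = self.table
        return {"module_with_peak": int(a), "module_without_peak": int(b),
                "comparison_with_peak": int(c), "comparison_without_peak": int(d)}


def module_peak_enrichment(flags: pd.Series, module_genes,
                           comparison_genes) -> EnrichmentResult:
    """Two-sided Fisher exact test: peak-bearing genes in a module vs a
    disjoint comparison module.

    ``flags`` maps gene symbol → bool (has peak) and must cover both sets.
    The odds ratio is the unconditional sample odds ratio ``ad/bc``, with
    a 0.5 continuity correction applied (and flagged) only when a zero
    cell occurs.
    """
    module_genes, comparison_genes = set(module_genes), set(comparison_genes)
    if not module_genes or not comparison_genes:
        raise ValueError("empty gene set")
    if module_genes & comparison_genes:
        raise ValueError("module and comparison sets must be disjoint")
    uncovered = (module_genes | comparison_genes) - set(flags.index)
    if uncovered:
        raise ValueError(f"flags missing genes: {sorted(uncovered)[:10]}")
    a = int(sum(bool(flags[g]) for g in module_genes))
    b = len(module_genes) - a
    c = int(sum(bool(flags[g]) for g in comparison_genes))
    d = len(comparison_genes) - c
    table = np.array([[a, b], [c, d]], dtype=int)
    _, p = fisher_exact(table, alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    if corrected:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    return EnrichmentResult(table=table, odds_ratio=(aa * dd) / (bb * cc),
                            p_value=float(p), continuity_corrected=corrected)
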