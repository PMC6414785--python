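"""Pavlidis template matching.

Selects genes whose expression trajectory correlates with a template
gene's own observed profile above a fixed Pearson threshold (signed,
strict). The template is excluded from its own match set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TemplateMatchResult", "pavlidis_template_match"]


@dataclass
class TemplateMatchResult:
    template_gene: str
    correlations: pd.Series      # gene -> Pearson R with the template
    threshold: float
    matched: pd.Index            # genes with R > threshold (template excluded)
    template_z: pd.Series        # z-scored template profile, sample-ordered
    matched_mean: pd.Series      # mean profile of matched genes

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def _sample_order(data) -> list:
    """Fixed sample order: by (group, timepoint) when metadata is present."""
    if hasattr(data, "metadata"):
        meta = data.metadata
        return list(meta.sort_values(["group", "timepoint"],
                                     kind="mergesort").index)
    return list(data.columns)


def pavlidis_template_match(data, template_gene: str, r_threshold: float = 0.8,
                            gene_subset=None) -> TemplateMatchResult:
    """Match genes to a template gene's expression trajectory.

    Parameters
    ----------
    data
        MergedStudy or gene × sample DataFrame. With metadata present the
        profile order follows (group, timepoint).
    template_gene
        Symbol whose observed profile is the template.
    r_threshold
        Genes with Pearson ``R > r_threshold`` (strict, signed) match.
    gene_subset
        Optional candidate restriction (e.g. one module's genes); the
        template itself need not be in the subset.
    """
    expr = data.values if hasattr(data, "metadata") else data
    if template_gene not in expr.index:
        raise KeyError(f"template gene {template_gene!r} absent")
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    order = _sample_order(data)
    expr = expr[order]
    t = expr.loc[template_gene].to_numpy(dtype=float)
    if t.std() == 0:
        raise ValueError("template profile has zero variance")
    if gene_subset is not None:
        missing = [g for g in gene_subset if g not in expr.index]
        if missing:
            raise KeyError(f"unknown genes in subset: {missing[:10]}")
        candidates = pd.Index(gene_subset)
    else:
        candidates = expr.index
    x = expr.loc[candidates].to_numpy(dtype=float)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        warnings.warn(f"{int((sd == 0).sum())} zero-variance gene(s) excluded")
        candidates = candidates[sd > 0]
        x = x[sd > 0]
    tz = (t - t.mean()) / t.std()
    xz = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    r = xz @ tz / len(t)
    correlations = pd.Series(np.clip(r, -1, 1), index=candidates)
    matched = correlations.index[(correlations > r_threshold)
                                 & (correlations.index != template_gene)]
    matched_mean = (expr.loc[matched].mean(axis=0) if len(matched)
                    else pd.Series(np.nan, index=expr.columns))
    return TemplateMatchResult(
        template_gene=template_gene,
        correlations=correlations,
        threshold=r_threshold,
        matched=matched,
        template_z=pd.Series(tz, index=expr.columns),
        matched_mean=matched_mean,
    )
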