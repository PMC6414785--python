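"""Shared fixtures: tiny hand-built studies and cached pipeline runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coexmerge import default_design, dual_factor_design
from coexmerge.merge import MergedStudy
from coexmerge.workflow import RunConfig, run_pipeline


def make_study(values: np.ndarray | pd.DataFrame,
               genes=None, samples=None,
               platform=None, state=None, group=None, timepoint=None
               ) -> MergedStudy:
    """Build a MergedStudy from a bare array plus optional metadata columns."""
    if isinstance(values, pd.DataFrame):
        df = values
    else:
        values = np.asarray(values, dtype=float)
        genes = genes or [f"g{i}" for i in range(values.shape[0])]
        samples = samples or [f"s{j}" for j in range(values.shape[1])]
        df = pd.DataFrame(values, index=genes, columns=samples)
    n = df.shape[1]
    meta = pd.DataFrame({
        "platform": platform if platform is not None else ["p0"] * n,
        "state": state if state is not None else ["x"] * n,
        "group": group if group is not None else ["g"] * n,
        "timepoint": timepoint if timepoint is not None else [0] * n,
    }, index=df.columns)
    return MergedStudy(df, meta)


def clade_sets(tree):
    """All tip-label sets of internal nodes of a SampleTree."""
    n = len(tree.labels)
    sets = {i: frozenset([tree.labels[i]]) for i in range(n)}
    out = []
    for r, (a, b, _, _) in enumerate(tree.linkage):
        sets[n + r] = sets[int(a)] | sets[int(b)]
        out.append(sets[n + r])
    return out


N_SEED_RUNS = 20


@pytest.fixture(scope="session")
def default_result():
    """One full pipeline run on the bundled single-hub design."""
    return run_pipeline(RunConfig(seed=0))


@pytest.fixture(scope="session")
def dual_result():
    """One full pipeline run on the exhaustion-like two-factor design."""
    return run_pipeline(RunConfig(design=dual_factor_design(), seed=0))


@pytest.fixture(scope="session")
def seed_runs():
    """Pipeline runs on the default design across seeds (shared cache)."""
    return [run_pipeline(RunConfig(seed=s)) for s in range(N_SEED_RUNS)]


@pytest.fixture(scope="session")
def dual_seed_runs():
    """Pipeline runs on the two-factor design across seeds (shared cache)."""
    return [run_pipeline(RunConfig(design=dual_factor_design(), seed=s))
            for s in range(N_SEED_RUNS)]
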