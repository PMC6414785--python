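"""Two-platform synthetic expression studies with planted structure.

The generator emulates the layout of a merged two-platform (Illumina +
Affymetrix) CD8+ T-cell time-course study: a three-level sample "state"
design (naive / resolving / extreme), planted co-expression modules
including one hub-driven module whose hub doubles as the template
regulator, additive + multiplicative platform batch effects of exactly
the location/scale form the empirical-Bayes correction assumes,
many-to-one probe maps with an unambiguous max-signal probe, and a
ChIP-peak table enriched near one planted module's TSSs.

Latent model (standardized scale): each module ``m`` has a per-sample
factor ``f_m``; a member with target correlation ``rho`` is
``c*f_m + noise_sd*eps`` with ``c = noise_sd*sqrt(rho/(1-rho))``, so the
planted member–member correlation is exactly ``rho``. The hub gene is its
module's factor plus small noise; hub–member correlation is calibrated to
``hub_strength``. State enters as a mean shift of module factors, so
state separates in expression space the way the batch model cannot mimic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .merge import ProbeMatrix

__all__ = [
    "SyntheticDesign", "SyntheticTruth",
    "generate_two_platform_study", "generate_gene_loci", "generate_peak_table",
    "default_design", "dual_factor_design",
]

HUB_SYMBOL = "Tbx21"
_HUB_NOISE = 0.05          # residual sd of the hub gene around its factor
_PROBE_LADDER = 0.6        # fixed per-probe baseline offset step (log2)
_PROBE_NOISE = 0.05


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of a planted two-platform study.

    ``timepoints`` maps each state to its day labels; one design cell is a
    (platform × state × timepoint) combination with ``samples_per_cell``
    samples. ``hub_module_mode`` selects between a single-hub module
    ("single": one latent factor, the hub gene nearly equals it) and a
    two-factor module ("dual": two correlated factors, no single hub —
    the regulator is an ordinary member), emulating the inflation-like
    vs exhaustion-like co-regulation regimes.
    """

    n_genes: int = 1000
    shared_gene_fraction: float = 0.85
    probes_per_gene: tuple[int, int] = (1, 3)
    samples_per_cell: int = 6
    states: tuple[str, ...] = ("naive", "resolving", "extreme")
    timepoints: dict = field(default_factory=lambda: {
        "naive": (0,), "resolving": (7, 50), "extreme": (7, 50)})
    module_sizes: tuple[int, ...] = (100, 60, 40)
    hub_module_index: int = 0
    hub_strength: float = 0.9
    within_module_cor: float = 0.7
    batch_shift: float = 1.0
    batch_scale: float = 2.0
    noise_sd: float = 0.3
    template_gene: str = HUB_SYMBOL
    n_template_followers: int = 50
    follower_cor: float = 0.95
    seed: int = 0
    state_effect: float = 10.0
    hub_module_mode: str = "single"
    dual_within_cor: float = 0.75
    dual_factor_cor: float = 0.8

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed gene count")
        if not 0 <= self.hub_module_index < len(self.module_sizes):
            raise ValueError("hub_module_index out of range")
        for name in ("hub_strength", "within_module_cor", "follower_cor",
                     "dual_within_cor"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie strictly in (0,1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.shared_gene_fraction <= 1:
            raise ValueError("shared_gene_fraction must be in [0,1]")
        if self.probes_per_gene[0] < 1 or self.probes_per_gene[0] > self.probes_per_gene[1]:
            raise ValueError("probes_per_gene must be (min>=1, max>=min)")
        if self.hub_module_mode not in ("single", "dual"):
            raise ValueError("hub_module_mode must be 'single' or 'dual'")
        # attainability of target correlations given the hub's own noise
        scale = np.sqrt(1 + _HUB_NOISE ** 2)
        for name in ("hub_strength", "follower_cor"):
            if getattr(self, name) * scale >= 1:
                raise ValueError(
                    f"{name}={getattr(self, name)} unattainable given hub noise")
        n_shared = round(self.shared_gene_fraction * self.n_genes)
        needed = sum(self.module_sizes) + self.n_template_followers + 1
        if needed > n_shared:
            raise ValueError(
                f"planted structure ({needed} genes) exceeds shared universe "
                f"({n_shared}); raise shared_gene_fraction or n_genes")


@dataclass
class SyntheticTruth:
    """Planted structure accompanying a generated study.

    ``module_membership`` assigns 1-based module indices (0 = background);
    template followers that track the hub's factor are counted in the hub
    module (they genuinely belong to its correlation cluster) and also
    listed in ``follower_genes``.
    """

    module_membership: pd.Series
    hub_gene: str
    batch_offsets: pd.Series          # platform-B additive offsets per gene
    follower_genes: set
    peak_enriched_module: int
    probe_map_truth: pd.DataFrame     # probe -> (gene, is_max_signal)
    template_gene: str = HUB_SYMBOL

    def module_genes(self, index: int) -> pd.Index:
        return self.module_membership.index[self.module_membership == index]


def default_design(**overrides) -> SyntheticDesign:
    """The bundled study conditions (single-hub, inflation-like)."""
    return replace(SyntheticDesign(), **overrides)


def dual_factor_design(**overrides) -> SyntheticDesign:
    """Exhaustion-like variant: the regulator's module is driven by two
    correlated latent factors and has no single dominant hub."""
    base = dict(hub_module_mode="dual", n_template_followers=0)
    base.update(overrides)
    return replace(SyntheticDesign(), **base)


def _member_loading(rho: float, noise_sd: float) -> float:
    """Loading c with cor(c*f + noise_sd*eps, f)**2 = rho for unit-var f."""
    return noise_sd * np.sqrt(rho / (1 - rho))


def _hub_target_loading(target: float, noise_sd: float) -> float:
    """Loading so cor(member, hub) equals target when hub = f + tau*eps."""
    q = target * np.sqrt(1 + _HUB_NOISE ** 2)
    if q >= 1:
        raise ValueError(f"target correlation {target} unattainable")
    return noise_sd * q / np.sqrt(1 - q ** 2)


def _sample_frame(design: SyntheticDesign) -> pd.DataFrame:
    rows = []
    group_names = {
        ("illumina", "naive"): "naive_ilmn", ("illumina", "resolving"): "M45",
        ("illumina", "extreme"): "M38", ("affymetrix", "naive"): "naive_affy",
        ("affymetrix", "resolving"): "Arm", ("affymetrix", "extreme"): "Cl13",
    }
    for platform, tag in (("illumina", "ilmn"), ("affymetrix", "affy")):
        i = 0
        for state in design.states:
            for day in design.timepoints[state]:
                for _ in range(design.samples_per_cell):
                    i += 1
                    rows.append({
                        "sample_id": f"{tag}_s{i:02d}",
                        "platform": platform,
                        "state": state,
                        "group": group_names.get((platform, state),
                                                 f"{tag}_{state}"),
                        "timepoint": day,
                    })
    return pd.DataFrame(rows).set_index("sample_id")


def _module_trajectory(design: SyntheticDesign, meta: pd.DataFrame,
                       m: int) -> np.ndarray:
    """Per-sample mean shift of module ``m``'s latent factor.

    The hub module follows a monotone differentiation trajectory
    (naive < resolving < extreme, the inflating program); the next
    module follows an acute-phase profile (high at the earliest
    post-infection timepoint, resolved later); every third module is a
    design-independent latent program. Distinct trajectories keep the
    planted modules separable in an unsigned (|cor|-based) network.
    """
    state = meta["state"]
    day = meta["timepoint"]
    kind = "monotone" if m == design.hub_module_index else \
        ("acute", "latent")[(m - (m > design.hub_module_index)) % 2]
    if kind == "monotone":
        levels = {design.states[0]: 0.0, design.states[-1]: 1.0}
        mid = {s: 0.35 for s in design.states[1:-1]}
        w = state.map({**mid, **levels}).to_numpy(float)
        scale = 1.0
    elif kind == "acute":
        early = {s: min(design.timepoints[s]) for s in design.states[1:]}
        w = np.array([1.0 if (s != design.states[0] and d == early.get(s))
                      else 0.0 for s, d in zip(state, day)])
        scale = 0.7
    else:
        w = np.zeros(len(meta))
        scale = 0.0
    return design.state_effect * scale * w


def generate_two_platform_study(design: SyntheticDesign
                                ) -> tuple[ProbeMatrix, ProbeMatrix,
                                           pd.DataFrame, SyntheticTruth]:
    """Generate probe-level matrices for two platforms plus ground truth.

    Returns ``(probes_platform_a, probes_platform_b, metadata, truth)``.
    Identical designs (same seed) give bit-identical outputs.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    meta = _sample_frame(design)
    n_samples = len(meta)
    ns = design.noise_sd

    # ---- gene universe ---------------------------------------------------
    n_planted = sum(design.module_sizes) + design.n_template_followers
    symbols = []
    gi = 0
    for m, size in enumerate(design.module_sizes):
        for j in range(size):
            if m == design.hub_module_index and j == 0:
                symbols.append(HUB_SYMBOL)
            else:
                gi += 1
                symbols.append(f"G{gi:05d}")
    for _ in range(design.n_template_followers):
        gi += 1
        symbols.append(f"G{gi:05d}")
    while len(symbols) < design.n_genes:
        gi += 1
        symbols.append(f"G{gi:05d}")
    standalone_template = design.template_gene != HUB_SYMBOL
    if standalone_template:
        # convert one background gene into the standalone template
        symbols[n_planted] = design.template_gene

    n_shared = round(design.shared_gene_fraction * design.n_genes)
    shared = symbols[:n_shared]
    private = symbols[n_shared:]
    private_a = private[: len(private) // 2]
    private_b = private[len(private) // 2:]
    genes_a = shared + private_a
    genes_b = shared + private_b

    # ---- latent signals (genes × samples, mean-zero log2 scale) ---------
    # biology (factor loadings + trajectories) and per-gene residual noise
    # are kept separate: the platform batch model inflates only the noise,
    # matching the location/scale form the EB correction assumes
    signal = pd.DataFrame(0.0, index=pd.Index(symbols, name="gene"),
                          columns=meta.index)
    noise = pd.DataFrame(0.0, index=signal.index, columns=meta.index)
    membership = pd.Series(0, index=signal.index, dtype=int)

    hub_idx = design.hub_module_index
    pos = 0
    for m, size in enumerate(design.module_sizes):
        mod_genes = symbols[pos: pos + size]
        pos += size
        membership[mod_genes] = m + 1
        mu = _module_trajectory(design, meta, m)
        if m == hub_idx and design.hub_module_mode == "dual":
            # exhaustion-like regime: the module decouples from the single
            # coordinated state trajectory and splits into two sub-programs
            rc = design.dual_factor_cor
            g = rng.standard_normal(n_samples)
            h1 = rng.standard_normal(n_samples)
            h2 = rng.standard_normal(n_samples)
            f1 = np.sqrt(rc) * g + np.sqrt(1 - rc) * h1
            f2 = np.sqrt(rc) * g + np.sqrt(1 - rc) * h2
            c = _member_loading(design.dual_within_cor, ns)
            # the regulator tracks only the shared component of the two
            # sub-programs: correlated with everything, hub of nothing
            signal.loc[mod_genes[0]] = c * g
            noise.loc[mod_genes[0]] = ns * rng.standard_normal(n_samples)
            for j, gene in enumerate(mod_genes[1:]):
                f = f1 if j % 2 == 0 else f2
                signal.loc[gene] = c * f
                noise.loc[gene] = ns * rng.standard_normal(n_samples)
        else:
            f = mu + rng.standard_normal(n_samples)
            if m == hub_idx:
                signal.loc[mod_genes[0]] = f
                noise.loc[mod_genes[0]] = _HUB_NOISE * \
                    rng.standard_normal(n_samples)
                c = _hub_target_loading(design.hub_strength, ns)
                members = mod_genes[1:]
            else:
                c = _member_loading(design.within_module_cor, ns)
                members = mod_genes
            for gene in members:
                signal.loc[gene] = c * f
                noise.loc[gene] = ns * rng.standard_normal(n_samples)
            if m == hub_idx:
                hub_factor = f

    followers = set()
    if design.n_template_followers:
        if standalone_template:
            mu_t = _module_trajectory(design, meta, design.hub_module_index)
            t_factor = mu_t + rng.standard_normal(n_samples)
            signal.loc[design.template_gene] = t_factor
            noise.loc[design.template_gene] = _HUB_NOISE * \
                rng.standard_normal(n_samples)
        else:
            t_factor = hub_factor
        cf = _hub_target_loading(design.follower_cor, ns)
        fol_genes = symbols[sum(design.module_sizes):
                            sum(design.module_sizes) + design.n_template_followers]
        for gene in fol_genes:
            signal.loc[gene] = cf * t_factor
            noise.loc[gene] = ns * rng.standard_normal(n_samples)
        followers = set(fol_genes)
        if not standalone_template:
            membership[fol_genes] = hub_idx + 1
    elif standalone_template:
        mu_t = _module_trajectory(design, meta, design.hub_module_index)
        t_factor = mu_t + rng.standard_normal(n_samples)
        signal.loc[design.template_gene] = t_factor
        noise.loc[design.template_gene] = _HUB_NOISE * \
            rng.standard_normal(n_samples)

    planted = set(membership.index[membership > 0]) | followers
    if design.template_gene in signal.index:
        planted.add(design.template_gene)
    background = [g for g in signal.index if g not in planted]
    noise.loc[background] = ns * rng.standard_normal((len(background),
                                                      n_samples))

    baseline = pd.Series(rng.uniform(6.0, 12.0, design.n_genes),
                         index=signal.index)

    # ---- platform batch effects on platform B ---------------------------
    is_b = (meta["platform"] == "affymetrix").to_numpy()
    offsets = pd.Series(rng.normal(0.0, design.batch_shift, design.n_genes)
                        if design.batch_shift > 0 else np.zeros(design.n_genes),
                        index=signal.index)
    full = signal.add(noise).add(baseline, axis=0)
    expr_b = signal.add(noise.mul(np.sqrt(design.batch_scale))).add(
        baseline + offsets, axis=0)
    full.loc[:, is_b] = expr_b.loc[:, is_b]

    # ---- expand genes to probes -----------------------------------------
    def probes_for(genes: list[str], tag: str) -> ProbeMatrix:
        counts = rng.integers(design.probes_per_gene[0],
                              design.probes_per_gene[1] + 1, len(genes))
        cols = meta.index[~is_b] if tag == "ilmn" else meta.index[is_b]
        sub = full.loc[genes, cols]
        rows, ids, ann, flags = [], [], [], []
        for gene, k in zip(genes, counts):
            base_row = sub.loc[gene].to_numpy()
            for j in range(int(k)):
                ids.append(f"{tag}_{gene}_p{j}")
                ann.append(gene)
                flags.append(j == 0)
                rows.append(base_row - _PROBE_LADDER * j
                            + _PROBE_NOISE * rng.standard_normal(len(cols)))
        values = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="probe"),
                              columns=cols)
        annotation = pd.Series(ann, index=values.index, name="symbol")
        truth = pd.DataFrame({"gene": ann, "is_max_signal": flags},
                             index=values.index)
        platform = "illumina" if tag == "ilmn" else "affymetrix"
        return ProbeMatrix(values, annotation, platform), truth

    pm_a, probe_truth_a = probes_for(genes_a, "ilmn")
    pm_b, probe_truth_b = probes_for(genes_b, "affy")

    truth = SyntheticTruth(
        module_membership=membership,
        hub_gene=HUB_SYMBOL,
        batch_offsets=offsets,
        follower_genes=followers,
        peak_enriched_module=hub_idx + 1,
        probe_map_truth=pd.concat([probe_truth_a, probe_truth_b]),
        template_gene=design.template_gene,
    )
    return pm_a, pm_b, meta, truth


def generate_gene_loci(symbols, n_chromosomes: int = 19,
                       spacing: int = 100_000) -> pd.DataFrame:
    """Deterministic TSS coordinates: genes laid out round-robin across
    chromosomes, ``spacing`` bp apart, alternating strand."""
    rows = []
    for i, sym in enumerate(symbols):
        rows.append({
            "symbol": sym,
            "chrom": f"chr{1 + i % n_chromosomes}",
            "tss": 1_000_000 + (i // n_chromosomes) * spacing,
            "strand": "+" if i % 2 == 0 else "-",
        })
    return pd.DataFrame(rows)


def generate_peak_table(truth: SyntheticTruth, loci: pd.DataFrame,
                        enrich_fraction_in: float = 0.5,
                        enrich_fraction_out: float = 0.05,
                        score_range: tuple[float, float] = (20.0, 100.0),
                        seed: int = 0, peak_width: int = 200) -> pd.DataFrame:
    """Scored BED peak table enriched near one planted module's TSSs.

    A fraction ``enrich_fraction_in`` of the peak-enriched module's genes
    (and ``enrich_fraction_out`` of all other genes) receive one peak whose
    midpoint lies strictly within 1 kbp of their TSS. Intervals are valid
    0-based half-open BED records.
    """
    if not enrich_fraction_in > enrich_fraction_out:
        raise ValueError("enrich_fraction_in must exceed enrich_fraction_out")
    missing = set(truth.module_membership.index) - set(loci["symbol"])
    if missing:
        raise ValueError(f"loci do not cover all genes: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    loci_ix = loci.set_index("symbol")
    module = list(truth.module_genes(truth.peak_enriched_module))
    other = [g for g in truth.module_membership.index if g not in set(module)]
    chosen = []
    for pool, frac in ((module, enrich_fraction_in), (other, enrich_fraction_out)):
        k = int(round(frac * len(pool)))
        if k > 0:
            chosen.extend(rng.choice(pool, size=k, replace=False))
    rows = []
    half = peak_width // 2
    for i, gene in enumerate(chosen):
        row = loci_ix.loc[gene]
        offset = int(rng.integers(-999, 1000))
        mid = int(row["tss"]) + offset
        rows.append({
            "chrom": row["chrom"],
            "start": mid - half,
            "end": mid + half,
            "name": f"peak_{i + 1:05d}",
            "score": float(rng.uniform(*score_range)),
        })
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    if not peaks.empty and (peaks["start"] >= peaks["end"]).any():
        raise AssertionError("generated malformed interval")
    return peaks
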