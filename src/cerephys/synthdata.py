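"""Synthetic cerebellar recordings with controllable firing statistics.

Real Purkinje cells emit two spike types: high-rate simple spikes (tens of
Hz, intrinsically generated) and rare complex spikes (~1 Hz, climbing-fiber
evoked, followed by a ~20 ms pause in simple-spike firing).  Cerebellar
nuclear neurons emit a single spike type.  This module generates spike
trains, whole cohorts of cells, and raw extracellular voltage traces whose
summary statistics (rate, ISI CV, CV2) can be dialed to the values observed
in vivo, so that every downstream stage — detection, sorting, metrics,
group inference — can be validated against known ground truth.

Generative model
----------------
Interspike intervals are drawn from a gamma renewal process with shape
``k = 1/CV**2`` and scale ``1/(rate * k)``; this spans any (rate, CV) pair.
To control the *local* irregularity CV2 independently of the global CV, the
gamma scale is modulated by a symmetric two-state Markov chain (states hold
reciprocal scale factors ``r`` and ``1/r`` and switch with probability
``q`` per interval).  Slow switching (small ``q``) concentrates variance in
long-timescale rate drift, lowering CV2 below the renewal value at the same
CV; per-interval alternation (``q = 1``) raises it.  The calibration that
maps a target (CV, CV2) to ``(r, q, within-state CV)`` is closed-form for
CV and uses 1-D quadrature over a Beta distribution for CV2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field  # field used in WaveformTemplate

import numpy as np
from scipy import integrate, optimize, signal, stats

from .types import CellRecord, CohortTable, InvalidSpecification, SpikeTrain, VoltageTrace

__all__ = [
    "ProcessSpec",
    "PurkinjeSpec",
    "GroupEffect",
    "CohortSpec",
    "WaveformTemplate",
    "InfeasibleTarget",
    "gen_renewal_train",
    "gen_cv2_train",
    "apply_cs_pause",
    "gen_cohort",
    "synth_trace",
    "default_templates",
    "noise_sd_for_snr",
    "awake_purkinje_cohort",
    "anesthetized_purkinje_cohort",
    "awake_nuclear_cohort",
]

# Shape parameter cap: CV below 1/sqrt(_K_CAP) is generated as a perfectly
# regular train.
_K_CAP = 1e6


class InfeasibleTarget(ValueError):
    """Requested (CV, CV2) pair lies outside the generator's achievable range."""


@dataclass(frozen=True)
class ProcessSpec:
    """Parameters of one spike-generating point process.

    ``target_cv2`` unset means plain gamma renewal (CV2 is then implied by
    the CV); set, the two-state modulation is calibrated to reach it.
    """

    mean_rate: float
    target_cv: float
    duration: float
    seed: int
    target_cv2: float | None = None

    def __post_init__(self) -> None:
        if self.mean_rate <= 0:
            raise InvalidSpecification("mean_rate must be positive")
        if self.duration <= 0:
            raise InvalidSpecification("duration must be positive")
        if self.target_cv < 0:
            raise InvalidSpecification("target_cv must be non-negative")
        if self.target_cv2 is not None and not (0 <= self.target_cv2 < 2):
            raise InvalidSpecification("target_cv2 must lie in [0, 2)")

    def scaled(self, rate_mult: float = 1.0, cv_mult: float = 1.0,
               cv2_mult: float = 1.0, seed: int | None = None) -> "ProcessSpec":
        if min(rate_mult, cv_mult, cv2_mult) <= 0:
            raise InvalidSpecification("effect multipliers must be positive")
        return ProcessSpec(
            mean_rate=self.mean_rate * rate_mult,
            target_cv=self.target_cv * cv_mult,
            duration=self.duration,
            seed=self.seed if seed is None else seed,
            target_cv2=None if self.target_cv2 is None else self.target_cv2 * cv2_mult,
        )


@dataclass(frozen=True)
class PurkinjeSpec:
    """Joint spec for a Purkinje cell: simple-spike and complex-spike processes
    plus the post-complex-spike pause applied to the simple-spike train."""

    ss: ProcessSpec
    cs: ProcessSpec
    pause_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.cs.mean_rate >= self.ss.mean_rate:
            raise InvalidSpecification("complex-spike rate must be below simple-spike rate")
        if self.pause_ms < 0:
            raise InvalidSpecification("pause_ms must be non-negative")


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative genotype/condition effect on a group's firing statistics."""

    rate_mult: float = 1.0
    cv_mult: float = 1.0
    cv2_mult: float = 1.0
    cs_rate_mult: float = 1.0
    cs_cv_mult: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.rate_mult, self.cv_mult, self.cv2_mult,
                  self.cs_rate_mult, self.cs_cv_mult):
            if v <= 0:
                raise InvalidSpecification("effect multipliers must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a simulated cohort.

    ``effects`` maps each group label (e.g. genotype) to its multiplicative
    deviation from ``base``; the label order defines group order.  Per-cell
    seeds are spawned deterministically from ``master_seed``.
    """

    n_cells_per_group: int
    base: PurkinjeSpec | ProcessSpec
    effects: dict[str, GroupEffect]
    master_seed: int
    state: str = "awake"
    cell_type: str = "purkinje"
    depth_range_mm: tuple[float, float] = (0.3, 2.9)
    days_range: tuple[int, int] = (3, 21)

    def __post_init__(self) -> None:
        if self.n_cells_per_group < 1:
            raise InvalidSpecification("n_cells_per_group must be >= 1")
        if not self.effects:
            raise InvalidSpecification("at least one group is required")

    def group_spec(self, label: str) -> PurkinjeSpec | ProcessSpec:
        eff = self.effects[label]
        if isinstance(self.base, PurkinjeSpec):
            return PurkinjeSpec(
                ss=self.base.ss.scaled(eff.rate_mult, eff.cv_mult, eff.cv2_mult),
                cs=self.base.cs.scaled(eff.cs_rate_mult, eff.cs_cv_mult),
                pause_ms=self.base.pause_ms,
            )
        return self.base.scaled(eff.rate_mult, eff.cv_mult, eff.cv2_mult)


# ---------------------------------------------------------------------------
# renewal / two-state generators
# ---------------------------------------------------------------------------

def _draw_times(rng: np.random.Generator, isi_sampler, duration: float,
                expected_rate: float) -> np.ndarray:
    """Accumulate ISIs until the duration is covered."""
    times: list[np.ndarray] = []
    t_end = 0.0
    block = max(int(expected_rate * duration * 1.1) + 32, 64)
    while t_end <= duration:
        isis = isi_sampler(block)
        t = t_end + np.cumsum(isis)
        times.append(t)
        t_end = t[-1]
        block = max(int(expected_rate * (duration - t_end) * 1.2) + 32, 64)
    t = np.concatenate(times)
    return t[t <= duration]


def gen_renewal_train(spec: ProcessSpec) -> SpikeTrain:
    """Draw a gamma-renewal spike train.

    ISI ~ Gamma(shape ``k = 1/CV**2``, scale ``1/(rate*k)``), so the mean ISI
    is ``1/rate`` and the ISI coefficient of variation is the target CV.
    ``CV = 0`` produces a perfectly regular train.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.target_cv == 0 or 1.0 / spec.target_cv**2 > _K_CAP:
        period = 1.0 / spec.mean_rate
        n = int(math.floor(spec.duration / period))
        return SpikeTrain(period * np.arange(1, n + 1), spec.duration)
    k = 1.0 / spec.target_cv**2
    theta = 1.0 / (spec.mean_rate * k)
    t = _draw_times(rng, lambda n: rng.gamma(k, theta, n), spec.duration, spec.mean_rate)
    return SpikeTrain(t, spec.duration)


def _pair_cv2(a: float, k: float) -> float:
    """E[2|aX - Y| / (aX + Y)] for X, Y iid Gamma(k, 1).

    Depends only on X/Y; with U = X/(X+Y) ~ Beta(k, k) the expectation is a
    1-D integral over the Beta density.
    """
    if k > 1e5:  # deterministic ISI limit
        return 2.0 * abs(a - 1.0) / (a + 1.0)
    b = stats.beta(k, k)
    val, _ = integrate.quad(
        lambda u: 2.0 * abs(a * u - (1 - u)) / (a * u + (1 - u)) * b.pdf(u),
        0.0, 1.0, limit=200,
    )
    return val


def _cv_within_sq(r: float, cv: float) -> float:
    """Within-state squared CV implied by the global CV at scale ratio ``r``.

    With scales r and 1/r equally occupied, the ISI marginal has
    CV^2 = (1 + cv_w^2) * m2/m1^2 - 1 where m1, m2 are the scale moments.
    """
    h = r + 1.0 / r
    m2_over_m1sq = 2.0 - 4.0 / h**2
    return (1.0 + cv**2) / m2_over_m1sq - 1.0


@dataclass(frozen=True)
class _TwoStateParams:
    ratio: float
    switch_prob: float
    cv_within: float


def calibrate_two_state(cv: float, cv2: float, q_slow: float = 0.02) -> _TwoStateParams:
    """Find (scale ratio, switch probability, within-state CV) hitting (CV, CV2).

    Raises :class:`InfeasibleTarget` (reporting the achievable CV2 range)
    when no parameterization reaches the requested pair.
    """
    k_cv = _K_CAP if cv == 0 else 1.0 / cv**2
    cv2_renewal = _pair_cv2(1.0, k_cv)
    if abs(cv2 - cv2_renewal) < 1e-3:
        return _TwoStateParams(1.0, 0.0, cv)
    if cv < 1.0:
        h2 = 4.0 / (1.0 - cv**2)
        r_max = (math.sqrt(h2) + math.sqrt(h2 - 4.0)) / 2.0 * (1 - 1e-9)
    else:
        r_max = 50.0

    def model(r: float, q: float) -> float:
        v = _cv_within_sq(r, cv)
        kw = _K_CAP if v <= 1e-12 else min(1.0 / v, _K_CAP)
        return (1 - q) * _pair_cv2(1.0, kw) + q * _pair_cv2(r**2, kw)

    if cv2 < cv2_renewal:
        q = q_slow
        lo = model(r_max, q)
        if cv2 < lo:
            # push residual CV2 down by switching even more rarely
            r = r_max
            c_diff = _pair_cv2(r**2, _K_CAP)
            q = cv2 / c_diff if c_diff > 0 else 0.0
            return _TwoStateParams(r, q, math.sqrt(max(_cv_within_sq(r, cv), 0.0)))
        r = optimize.brentq(lambda r: model(r, q) - cv2, 1 + 1e-9, r_max, xtol=1e-10)
    else:
        q = 1.0
        hi = model(r_max, q)
        if cv2 > hi:
            raise InfeasibleTarget(
                f"target CV2={cv2:.3f} unreachable at CV={cv:.3f}; "
                f"achievable range is about [0, {hi:.3f}]"
            )
        r = optimize.brentq(lambda r: model(r, q) - cv2, 1 + 1e-9, r_max, xtol=1e-10)
    return _TwoStateParams(r, q, math.sqrt(max(_cv_within_sq(r, cv), 0.0)))


def gen_cv2_train(spec: ProcessSpec) -> SpikeTrain:
    """Draw a spike train with independently targeted CV and CV2.

    Uses the two-state Markov-modulated gamma renewal process described in
    the module docstring.  ``target_cv2 = 0`` yields a regular train.
    """
    if spec.target_cv2 is None:
        raise InvalidSpecification("gen_cv2_train requires target_cv2 to be set")
    if spec.target_cv2 == 0:
        return gen_renewal_train(
            ProcessSpec(spec.mean_rate, 0.0, spec.duration, spec.seed)
        )
    par = calibrate_two_state(spec.target_cv, spec.target_cv2)
    r, q = par.ratio, par.switch_prob
    if r == 1.0:  # plain renewal already matches
        return gen_renewal_train(spec)
    vw = par.cv_within**2
    kw = _K_CAP if vw <= 1e-12 else min(1.0 / vw, _K_CAP)
    rng = np.random.default_rng(spec.seed)
    m1 = (r + 1.0 / r) / 2.0
    theta = 1.0 / (spec.mean_rate * m1 * kw)
    start_state = int(rng.integers(2))

    state_carry = [start_state]

    def sampler(n: int) -> np.ndarray:
        if q >= 1.0:
            s = (np.arange(n) + state_carry[0]) % 2
            state_carry[0] = (state_carry[0] + n) % 2
        else:
            switches = rng.random(n) < q
            s = (state_carry[0] + np.cumsum(switches)) % 2
            state_carry[0] = int(s[-1])
        scales = np.where(s == 0, r, 1.0 / r)
        return rng.gamma(kw, theta, n) * scales

    t = _draw_times(rng, sampler, spec.duration, spec.mean_rate)
    return SpikeTrain(t, spec.duration)


def apply_cs_pause(ss: SpikeTrain, cs: SpikeTrain, pause_ms: float = 20.0) -> SpikeTrain:
    """Delete simple spikes falling inside the post-complex-spike pause.

    A simple spike at time t is removed when some complex spike at t_cs
    satisfies ``t_cs <= t <= t_cs + pause``; a simple spike coincident with
    a complex spike is treated as part of the complex spike.
    """
    if pause_ms < 0:
        raise InvalidSpecification("pause_ms must be non-negative")
    if ss.n_spikes == 0 or cs.n_spikes == 0:
        return ss
    pause = pause_ms / 1000.0
    idx = np.searchsorted(cs.times, ss.times, side="right") - 1
    prev_cs = np.where(idx >= 0, cs.times[np.clip(idx, 0, None)], -np.inf)
    keep = (ss.times - prev_cs) > pause
    return SpikeTrain(ss.times[keep], ss.duration_s)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _gen_cell(label: str, idx: int, spec: CohortSpec,
              child: np.random.SeedSequence) -> CellRecord:
    gspec = spec.group_spec(label)
    seeds = child.generate_state(3) % (2**31)
    meta_rng = np.random.default_rng(seeds[2])
    depth = float(meta_rng.uniform(*spec.depth_range_mm))
    days = int(meta_rng.integers(spec.days_range[0], spec.days_range[1] + 1))
    cell_id = f"{label}_{spec.state}_{spec.cell_type}_{idx:03d}"
    if isinstance(gspec, PurkinjeSpec):
        # the nominal simple-spike rate is the *observed* rate of the final
        # train; the post-complex-spike pause deletes a fraction of about
        # cs_rate * pause, so the underlying process runs slightly faster
        pause_s = gspec.pause_ms / 1000.0
        deleted = min(gspec.cs.mean_rate * pause_s, 0.5)
        ss_spec = ProcessSpec(gspec.ss.mean_rate / (1.0 - deleted),
                              gspec.ss.target_cv,
                              gspec.ss.duration, int(seeds[0]), gspec.ss.target_cv2)
        cs_spec = ProcessSpec(gspec.cs.mean_rate, gspec.cs.target_cv,
                              gspec.cs.duration, int(seeds[1]), gspec.cs.target_cv2)
        ss = (gen_cv2_train(ss_spec) if ss_spec.target_cv2 is not None
              else gen_renewal_train(ss_spec))
        cs = (gen_cv2_train(cs_spec) if cs_spec.target_cv2 is not None
              else gen_renewal_train(cs_spec))
        ss = apply_cs_pause(ss, cs, gspec.pause_ms)
        trains = {"ss": ss, "cs": cs}
        duration = gspec.ss.duration
    else:
        pspec = ProcessSpec(gspec.mean_rate, gspec.target_cv, gspec.duration,
                            int(seeds[0]), gspec.target_cv2)
        train = (gen_cv2_train(pspec) if pspec.target_cv2 is not None
                 else gen_renewal_train(pspec))
        trains = {"cn": train}
        duration = gspec.duration
    return CellRecord(
        cell_id=cell_id, genotype=label, state=spec.state,
        cell_type=spec.cell_type, depth_mm=round(depth, 3),
        days_post_surgery=days, duration_s=duration,
        seed=int(seeds[0]), trains=trains,
    )


def gen_cohort(spec: CohortSpec) -> CohortTable:
    """Generate one cohort; bit-identical under the same ``master_seed``."""
    root = np.random.SeedSequence(spec.master_seed)
    children = root.spawn(spec.n_cells_per_group * len(spec.effects))
    cells = []
    i = 0
    for label in spec.effects:
        for idx in range(spec.n_cells_per_group):
            cells.append(_gen_cell(label, idx, spec, children[i]))
            i += 1
    return CohortTable(cells)


# ---------------------------------------------------------------------------
# default cohort conditions (in vivo study design)
# ---------------------------------------------------------------------------

def awake_purkinje_cohort(master_seed: int, n_cells_per_group: int = 24,
                          duration_s: float = 71.0) -> CohortSpec:
    """Awake head-fixed Purkinje recordings: control vs dystrophin-null (mdx).

    Control simple spikes at 85.3 Hz; the mdx group fires at a factor 0.81
    of that (a ~19% deficit).  Complex spikes near 1.2 Hz with CV 0.92 in
    controls and a factor 0.83 on CV in mdx (~17% lower variability).  The
    71 s duration is the median analyzed window for awake units.
    """
    base = PurkinjeSpec(
        ss=ProcessSpec(mean_rate=85.3, target_cv=0.55, duration=duration_s, seed=0),
        cs=ProcessSpec(mean_rate=1.2, target_cv=0.92, duration=duration_s, seed=0),
        pause_ms=20.0,
    )
    return CohortSpec(
        n_cells_per_group=n_cells_per_group, base=base,
        effects={
            "control": GroupEffect(),
            "mdx": GroupEffect(rate_mult=0.81, cs_cv_mult=0.83),
        },
        master_seed=master_seed, state="awake", cell_type="purkinje",
        depth_range_mm=(0.3, 2.9), days_range=(3, 21),
    )


def anesthetized_purkinje_cohort(master_seed: int, n_cells_per_group: int = 47,
                                 duration_s: float = 200.0) -> CohortSpec:
    """Anesthetized Purkinje recordings: control 30.8 Hz simple spikes, the
    mdx group at a factor 0.87 (~13% deficit); complex spikes are sparser
    under anesthesia (0.6 Hz here).  200 s is the median analyzed window."""
    base = PurkinjeSpec(
        ss=ProcessSpec(mean_rate=30.8, target_cv=0.8, duration=duration_s, seed=0),
        cs=ProcessSpec(mean_rate=0.6, target_cv=1.0, duration=duration_s, seed=0),
        pause_ms=20.0,
    )
    return CohortSpec(
        n_cells_per_group=n_cells_per_group, base=base,
        effects={
            "control": GroupEffect(),
            "mdx": GroupEffect(rate_mult=0.87),
        },
        master_seed=master_seed, state="anesthetized", cell_type="purkinje",
        depth_range_mm=(0.2, 2.4), days_range=(0, 0),
    )


def awake_nuclear_cohort(master_seed: int, n_cells_per_group: int = 25,
                         duration_s: float = 71.0) -> CohortSpec:
    """Awake cerebellar-nuclear recordings: one spike type, rate and global
    CV unchanged between genotypes, local variability (CV2) a factor 1.19
    higher in mdx (0.39 -> ~0.46)."""
    base = ProcessSpec(mean_rate=60.0, target_cv=0.5, duration=duration_s,
                       seed=0, target_cv2=0.39)
    return CohortSpec(
        n_cells_per_group=n_cells_per_group, base=base,
        effects={
            "control": GroupEffect(),
            "mdx": GroupEffect(cv2_mult=1.19),
        },
        master_seed=master_seed, state="awake", cell_type="nuclear",
        depth_range_mm=(1.8, 4.0), days_range=(3, 21),
    )


# ---------------------------------------------------------------------------
# voltage-trace synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveformTemplate:
    """A spike waveform (μV) sampled at ``fs_hz``; ``kind`` is simple or complex.

    ``trough_index`` marks the sample aligned to the nominal spike time.
    """

    samples: np.ndarray
    fs_hz: float
    kind: str
    trough_index: int = field(default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.kind not in ("simple", "complex"):
            raise InvalidSpecification("kind must be 'simple' or 'complex'")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.fs_hz


def _gauss_spike(fs: float, amp: float, width_ms: float, t0_ms: float,
                 n: int) -> np.ndarray:
    t = np.arange(n) / fs * 1000.0
    w = width_ms / 2.355  # FWHM -> sigma
    main = -amp * np.exp(-0.5 * ((t - t0_ms) / w) ** 2)
    # after-hyperpolarization rebound
    reb = 0.3 * amp * np.exp(-0.5 * ((t - t0_ms - 1.8 * width_ms) / (1.6 * w)) ** 2)
    return main + reb


def default_templates(fs_hz: float = 30_000.0, amp_uv: float = 100.0,
                      spikelet_rel: float = 0.45) -> dict[str, WaveformTemplate]:
    """Canonical somatic waveforms: a ~1.5 ms biphasic simple spike and a
    ~7 ms complex spike carrying three decaying spikelets.

    Spikelets are ``spikelet_rel`` of the main trough, deliberately below a
    4.5-sigma detection threshold at moderate SNR so they are recognized via
    their energy, not as separate threshold crossings.
    """
    n_ss = int(round(3.0e-3 * fs_hz))
    ss = _gauss_spike(fs_hz, amp_uv, 0.35, 0.8, n_ss)
    n_cs = int(round(7.0e-3 * fs_hz))
    cs = _gauss_spike(fs_hz, amp_uv, 0.4, 0.8, n_cs)
    for dt, rel in zip((1.7, 3.0, 4.3), (1.0, 0.85, 0.7)):
        cs += _gauss_spike(fs_hz, amp_uv * spikelet_rel * rel, 0.35, 0.8 + dt, n_cs)
    trough = int(round(0.8e-3 * fs_hz))
    return {
        "simple": WaveformTemplate(ss, fs_hz, "simple", trough),
        "complex": WaveformTemplate(cs, fs_hz, "complex", trough),
    }


def noise_sd_for_snr(templates: dict[str, WaveformTemplate], snr: float) -> float:
    """Noise sigma giving `snr` = simple-spike trough amplitude / noise sd."""
    return float(np.abs(templates["simple"].samples).max() / snr)


def synth_trace(cell: CellRecord, templates: dict[str, WaveformTemplate] | None = None,
                noise_sd: float = 0.0, fs_hz: float = 30_000.0,
                band_hz: tuple[float, float] = (300.0, 13_000.0),
                seed: int | None = None) -> VoltageTrace:
    """Render a cell's ground-truth trains into a band-passed voltage trace.

    Templates are added at spike times (trough-aligned; overlaps sum),
    Gaussian noise of ``noise_sd`` μV is added, and the sum is band-pass
    filtered with a zero-phase Butterworth (two second-order sections each
    way, i.e. fourth-order magnitude response), mimicking the 0.3-13 kHz
    analog chain of the recording rig.  Ground-truth spike times travel
    with the trace for detector validation.
    """
    if templates is None:
        templates = default_templates(fs_hz)
    if fs_hz < 2.0 * band_hz[1]:
        raise InvalidSpecification("sampling rate must be at least twice the upper band edge")
    n = int(round(cell.duration_s * fs_hz))
    x = np.zeros(n)
    kind_of = {"ss": "simple", "cs": "complex", "cn": "simple"}
    gt: dict[str, np.ndarray] = {}
    for unit, train in cell.trains.items():
        tpl = templates[kind_of[unit]]
        gt[unit] = train.times.copy()
        idx = np.round(train.times * fs_hz).astype(int) - tpl.trough_index
        for i0 in idx:
            a, b = max(i0, 0), min(i0 + tpl.samples.size, n)
            if b > a:
                x[a:b] += tpl.samples[a - i0:b - i0]
    if noise_sd > 0:
        rng = np.random.default_rng(cell.seed if seed is None else seed)
        x = x + rng.normal(0.0, noise_sd, n)
    sos = signal.butter(2, band_hz, btype="bandpass", fs=fs_hz, output="sos")
    y = signal.sosfiltfilt(sos, x)
    return VoltageTrace(y.astype(np.float32), fs_hz, band_hz, gt)
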