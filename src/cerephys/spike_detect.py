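"""Spike detection and simple/complex sorting for extracellular traces.

Detection thresholds negative-going excursions at a multiple of the robust
noise estimate (median absolute deviation / 0.6745) and aligns events on
their troughs.  Sorting exploits the physiology: complex spikes carry
spikelets, i.e. substantial post-trough energy over several milliseconds,
while simple spikes do not.  Events are split into two classes on that
energy with an unsupervised threshold; the minority high-energy class is
labeled complex.  Spikelet threshold crossings within the complex-spike
window are absorbed into their parent event rather than double-counted as
simple spikes.  The ~20 ms post-complex-spike pause in simple-spike firing
serves as an independent sanity check on the sorting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage.filters import threshold_otsu

from .types import InvalidSpecification, SpikeTrain, VoltageTrace

__all__ = [
    "DetectionParams",
    "SortedTrain",
    "detect_events",
    "extract_waveforms",
    "classify_events",
    "verify_cs_pause",
    "sort_trace",
    "match_events",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the detector/sorter.

    ``threshold_mult`` is in multiples of the MAD-based noise sigma;
    windows are milliseconds.  ``cs_spikelet_window_ms`` bounds both the
    energy-feature window and the spikelet-absorption window after a
    complex-spike trough.
    """

    threshold_mult: float = 4.5
    refractory_ms: float = 1.0
    waveform_window_ms: tuple[float, float] = (1.0, 3.0)
    cs_spikelet_window_ms: float = 6.0
    cs_energy_gap_ms: float = 1.5  # skip the event's own repolarization
    min_amplitude_frac: float = 0.35  # threshold floor vs largest excursion

    def __post_init__(self) -> None:
        if self.threshold_mult <= 0 or self.refractory_ms <= 0:
            raise InvalidSpecification("threshold_mult and refractory_ms must be positive")
        if min(self.waveform_window_ms) <= 0 or self.cs_spikelet_window_ms <= 0:
            raise InvalidSpecification("windows must be positive")


@dataclass
class SortedTrain:
    """Result of sorting one trace: disjoint ss/cs trains plus diagnostics."""

    ss_times: SpikeTrain
    cs_times: SpikeTrain
    mean_ss_waveform: np.ndarray
    mean_cs_waveform: np.ndarray
    pause_verified_fraction: float | None
    no_complex_spikes: bool
    threshold_uv: float
    n_detected: int


def noise_sigma(trace: VoltageTrace) -> float:
    """Robust noise scale: median absolute deviation / 0.6745."""
    x = np.asarray(trace.samples, dtype=float)
    return float(np.median(np.abs(x - np.median(x))) / 0.6745)


def detect_events(trace: VoltageTrace, params: DetectionParams | None = None
                  ) -> np.ndarray:
    """Times (s) of negative-going threshold crossings, trough-aligned.

    No two events are closer than the refractory window.  A trace shorter
    than one waveform window yields an empty result with a warning.
    """
    params = params or DetectionParams()
    x = np.asarray(trace.samples, dtype=float)
    win = sum(params.waveform_window_ms) * 1e-3
    if trace.duration_s < win:
        warnings.warn("trace shorter than one waveform window; no events")
        return np.zeros(0)
    sigma = noise_sigma(trace)
    ax = np.abs(x)
    peak = ax.max()
    if peak == 0:
        return np.zeros(0)
    # amplitude floors keep filter ringing and rebound lobes out on clean,
    # low-noise traces where the MAD estimate collapses; both sit far below
    # any spike trough (ringing is only a few percent of it)
    height = max(params.threshold_mult * sigma,
                 params.min_amplitude_frac * float(np.quantile(ax, 0.999)),
                 0.15 * peak)
    distance = max(int(round(params.refractory_ms * 1e-3 * trace.fs_hz)), 1)
    peaks, _ = signal.find_peaks(-x, height=height, distance=distance)
    return peaks / trace.fs_hz


def extract_waveforms(trace: VoltageTrace, times: np.ndarray,
                      window_ms: tuple[float, float] = (1.0, 3.0)
                      ) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-event waveform matrix aligned on the trough.

    Returns (matrix [n_kept x n_samples], kept event times, n_dropped);
    events whose window is clipped by the trace edges are dropped.
    """
    times = np.asarray(times, dtype=float)
    pre = int(round(window_ms[0] * 1e-3 * trace.fs_hz))
    post = int(round(window_ms[1] * 1e-3 * trace.fs_hz))
    n = trace.samples.size
    if times.size == 0:
        return np.zeros((0, pre + post)), times, 0
    idx = np.round(times * trace.fs_hz).astype(int)
    ok = (idx - pre >= 0) & (idx + post <= n)
    kept = idx[ok]
    rows = np.stack([trace.samples[i - pre:i + post] for i in kept]) if kept.size \
        else np.zeros((0, pre + post))
    return rows.astype(float), times[ok], int((~ok).sum())


def _post_trough_energy(trace: VoltageTrace, times: np.ndarray,
                        params: DetectionParams) -> np.ndarray:
    """Above-noise energy in (t + gap, t + spikelet window] per event.

    The squared signal is smoothed at roughly the spikelet width and the
    expected noise level subtracted, so band-limited noise contributes
    almost nothing while sub-threshold spikelets contribute strongly.
    Samples near other full-amplitude events are masked out, so a
    neighboring spike inside the window does not masquerade as spikelet
    energy.
    """
    fs = trace.fs_hz
    a = int(round(params.cs_energy_gap_ms * 1e-3 * fs))
    b = int(round(params.cs_spikelet_window_ms * 1e-3 * fs))
    idx = np.round(np.asarray(times) * fs).astype(int)
    n = trace.samples.size
    x = np.asarray(trace.samples, dtype=float)
    width = max(int(round(0.35e-3 * fs)), 1)
    # only full-amplitude events mask windows: a detected spikelet (smaller
    # trough) must not blank out its own parent's energy window; amplitudes
    # are read off the smoothed negative-part energy so single-sample noise
    # cannot promote a spikelet to full amplitude
    neg_energy = ndimage.uniform_filter1d(np.minimum(x, 0.0) ** 2, size=width,
                                          mode="nearest")
    amp = np.sqrt(np.maximum(ndimage.maximum_filter1d(neg_energy, size=5),
                             0.0))[np.clip(idx, 0, n - 1)]
    big = amp >= 0.7 * np.median(amp) if idx.size else np.zeros(0, dtype=bool)
    occupied = np.zeros(n, dtype=bool)
    for i in idx[big]:
        occupied[max(i - a, 0):min(i + a + 1, n)] = True
    # spikelets are negative troughs; using only the negative part of the
    # signal keeps positive rebound lobes of nearby spikes out of the feature
    xm = np.where(occupied, 0.0, np.minimum(x, 0.0))
    # matched smoothing at roughly spikelet width concentrates spikelet
    # energy before the noise floor is subtracted
    sm = ndimage.uniform_filter1d(xm**2, size=width, mode="nearest")
    # empirical noise floor from the spike-free portion of the trace
    bg = sm[~occupied][::4]
    med = float(np.median(bg)) if bg.size else 0.0
    mad = float(np.median(np.abs(bg - med))) if bg.size else 0.0
    floor = med + 6.0 * 1.4826 * mad
    e = np.clip(sm - floor, 0.0, None)
    big_idx = np.sort(idx[big])
    out = np.empty(idx.size)
    follower = np.zeros(idx.size, dtype=bool)
    for j, i in enumerate(idx):
        # small events shortly after a full-amplitude one are its spikelets
        # (or stragglers), not candidate parents
        kp = np.searchsorted(big_idx, i) - 1
        if not big[j] and kp >= 0 and i - big_idx[kp] <= b:
            follower[j] = True
        # another full-amplitude spike inside the window disqualifies the
        # event: a true complex spike is followed only by small spikelets
        # (the simple-spike pause), so any energy here is contamination
        k = np.searchsorted(big_idx, i + 1)
        if k < big_idx.size and big_idx[k] <= i + b + a:
            out[j] = 0.0
            continue
        lo, hi = min(i + a, n), min(i + b, n)
        free = ~occupied[lo:hi]
        out[j] = float(e[lo:hi][free].mean()) if free.any() else 0.0
    return out, follower


def classify_events(trace: VoltageTrace, times: np.ndarray,
                    params: DetectionParams | None = None
                    ) -> tuple[np.ndarray, bool]:
    """Label each event simple/complex from post-trough spikelet energy.

    An unsupervised two-class split (Otsu threshold on the energy feature)
    is applied; the high-energy class must be the minority, clearly bimodal
    and carry real above-noise energy, otherwise the split is declared
    degenerate: all events are labeled simple and the no-complex-spikes
    flag is raised.
    """
    params = params or DetectionParams()
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise InvalidSpecification("classification needs at least one event")
    feat, follower = _post_trough_energy(trace, times, params)
    labels = np.full(times.size, "simple", dtype=object)
    scale = np.abs(trace.samples).max() ** 2
    # known followers (spikelets of an earlier full-amplitude event) are
    # excluded from the split: they see the remaining spikelets and would
    # otherwise form a spurious third cluster
    cand = ~follower
    fc = feat[cand]
    if fc.size < 3 or np.ptp(fc) < 1e-9 * scale:
        return labels, True
    try:
        thr = threshold_otsu(fc, nbins=256)
    except ValueError:
        return labels, True
    hic = fc > thr
    if not hic.any() or hic.all():
        return labels, True
    lo_m, hi_m = fc[~hic].mean(), fc[hic].mean()
    lo_s, hi_s = fc[~hic].std(), fc[hic].std()
    # accept the split only if it looks like true bimodality (Ashman's D)
    # and the high class carries real above-noise energy, not just the
    # upper tail of the simple-spike feature distribution
    d = (hi_m - lo_m) / np.sqrt(2.0 * (lo_s**2 + hi_s**2) + 1e-12 * scale**2)
    var_band = noise_sigma(trace) ** 2
    energetic = hi_m - lo_m > 0.5 * var_band
    minority = hic.mean() <= 0.5
    if not (d >= 2.0 and energetic and minority):
        return labels, True
    labels[cand & (feat > thr)] = "complex"
    return labels, False


def _absorb_spikelets(times: np.ndarray, labels: np.ndarray,
                      window_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge any event within the spikelet window after a complex spike into it."""
    win = window_ms * 1e-3
    ss, cs = [], []
    last_cs = -np.inf
    for t, lab in zip(times, labels):
        if t - last_cs <= win and last_cs > -np.inf:
            continue  # spikelet of the previous complex spike
        if lab == "complex":
            cs.append(t)
            last_cs = t
        else:
            ss.append(t)
    return np.asarray(ss), np.asarray(cs)


def verify_cs_pause(ss_times: np.ndarray, cs_times: np.ndarray,
                    min_pause_ms: float = 20.0) -> float | None:
    """Fraction of complex spikes whose next simple spike comes > pause later.

    Near 1 for a correctly sorted Purkinje cell.  ``None`` when there are
    no complex spikes (undefined, flagged rather than an error).
    """
    cs = np.asarray(cs_times, dtype=float)
    ss = np.asarray(ss_times, dtype=float)
    if cs.size == 0:
        return None
    if ss.size == 0:
        return 1.0
    pause = min_pause_ms * 1e-3
    nxt = np.searchsorted(ss, cs, side="right")
    ok = np.ones(cs.size, dtype=bool)
    has_next = nxt < ss.size
    ok[has_next] = (ss[nxt[has_next]] - cs[has_next]) > pause
    return float(ok.mean())


def sort_trace(trace: VoltageTrace, params: DetectionParams | None = None,
               min_pause_ms: float = 20.0) -> SortedTrain:
    """Full detection + sorting pipeline for one trace."""
    params = params or DetectionParams()
    times = detect_events(trace, params)
    sigma = noise_sigma(trace)
    if times.size == 0:
        empty = SpikeTrain(np.zeros(0), trace.duration_s)
        return SortedTrain(empty, empty, np.zeros(0), np.zeros(0), None, True,
                           params.threshold_mult * sigma, 0)
    labels, no_cs = classify_events(trace, times, params)
    if no_cs:
        ss_t, cs_t = times, np.zeros(0)
    else:
        ss_t, cs_t = _absorb_spikelets(times, labels, params.cs_spikelet_window_ms)
    wf_ss, _, _ = extract_waveforms(trace, ss_t, params.waveform_window_ms)
    wf_cs, _, _ = extract_waveforms(
        trace, cs_t, (params.waveform_window_ms[0], params.cs_spikelet_window_ms))
    return SortedTrain(
        ss_times=SpikeTrain(ss_t, trace.duration_s),
        cs_times=SpikeTrain(cs_t, trace.duration_s),
        mean_ss_waveform=wf_ss.mean(axis=0) if wf_ss.size else np.zeros(0),
        mean_cs_waveform=wf_cs.mean(axis=0) if wf_cs.size else np.zeros(0),
        pause_verified_fraction=verify_cs_pause(ss_t, cs_t, min_pause_ms),
        no_complex_spikes=no_cs,
        threshold_uv=params.threshold_mult * sigma,
        n_detected=int(times.size),
    )


def match_events(detected: np.ndarray, truth: np.ndarray,
                 tol_ms: float = 0.5) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to ground-truth times.

    Returns (true positives, false positives, false negatives) with a
    ``tol_ms`` matching tolerance.
    """
    det = np.sort(np.asarray(detected, dtype=float))
    tru = np.sort(np.asarray(truth, dtype=float))
    tol = tol_ms * 1e-3
    i = j = tp = 0
    while i < det.size and j < tru.size:
        d = det[i] - tru[j]
        if abs(d) <= tol:
            tp += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return tp, det.size - tp, tru.size - tp
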