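"""Peak calling from the smoothed delta-mass histogram.

Candidates are local maxima (plateaus) of a flattened copy of the weight
vector; a candidate is called when its prominence - the normalized drop from
apex to its higher shoulder, ``(apex - shoulder)/apex`` - exceeds the
threshold.  Called peaks are ranked by signal-to-noise remainder (mean bin
height in a window around the apex minus mean height of the flanking
background) and the top N retained.  Peak boundaries follow the monotonic
descent from the apex, capped at +/- the precursor tolerance, and PSMs are
assigned to the peak whose boundaries contain their delta mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .histogram import MassShiftHistogram
from .model import ExperimentSet, PSMRecord, ShepherdConfig


@dataclass
class Peak:
    """A called mass shift."""

    apex_index: int
    apex_mass: float
    apex_height: float
    prominence: float
    snr: float
    left_bound: float
    right_bound: float
    # experiment label -> list of assigned PSMRecord
    assigned: dict[str, list[PSMRecord]] = field(default_factory=dict)
    reported_mass: float = float("nan")

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())

    def assigned_psms(self) -> list[PSMRecord]:
        out: list[PSMRecord] = []
        for psms in self.assigned.values():
            out.extend(psms)
        return out


@dataclass
class PeakSet:
    """Peaks ordered by descending SNR, plus the config snapshot."""

    peaks: list[Peak]
    config: ShepherdConfig

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def flatten_for_prominence(weights: np.ndarray, set_size: int) -> np.ndarray:
    """Replace each consecutive group of ``set_size`` bins by the group min.

    The trailing partial group is flattened to its own minimum.  Used only
    inside the prominence computation.
    """
    if set_size < 1:
        raise InputError("set_size must be >= 1")
    w = np.asarray(weights, dtype=float)
    if set_size == 1:
        return w.copy()
    n = w.size
    n_full = (n // set_size) * set_size
    out = np.empty(n)
    if n_full:
        mins = w[:n_full].reshape(-1, set_size).min(axis=1)
        out[:n_full] = np.repeat(mins, set_size)
    if n_full < n:
        out[n_full:] = w[n_full:].min()
    return out


def _walk_shoulder(flat: np.ndarray, apex: int, step: int) -> float:
    """Follow the peak downward monotonically; return the height where the
    descent stops (local minimum before a rise, or the vector end)."""
    i = apex
    current = flat[apex]
    n = flat.size
    while True:
        j = i + step
        if j < 0 or j >= n:
            return float(current)
        nxt = flat[j]
        if nxt > current:
            return float(current)
        i, current = j, nxt
        if current == 0.0:  # cannot descend further; shoulder is 0
            return 0.0


def compute_prominence(weights: np.ndarray, apex_index: int) -> float:
    """Normalized apex-to-shoulder drop, in [0, 1].

    ``(apex - max(left_shoulder, right_shoulder)) / apex``; shoulders found
    by walking from the apex while heights are non-increasing.
    """
    flat = np.asarray(weights, dtype=float)
    apex = float(flat[apex_index])
    if apex <= 0:
        raise InputError("apex height must be > 0")
    left = _walk_shoulder(flat, apex_index, -1)
    right = _walk_shoulder(flat, apex_index, +1)
    return (apex - max(left, right)) / apex


def compute_snr(
    weights: np.ndarray,
    apex_index: int,
    signal_window: float,
    background_flank: float,
    bin_width: float,
) -> float:
    """Signal remainder: mean bin height in the signal window centered on the
    apex minus the mean over the two adjacent background flanks (truncated at
    the histogram ends)."""
    w = np.asarray(weights, dtype=float)
    n = w.size
    n_sig = int(round(signal_window / bin_width))
    n_bg = int(round(background_flank / bin_width))
    if n_sig < 1:
        raise ConfigurationError("signal window narrower than one bin")
    if n_bg < 1:
        raise ConfigurationError("background flank narrower than one bin")
    s_lo = apex_index - n_sig // 2
    s_hi = s_lo + n_sig  # exclusive
    sig = w[max(s_lo, 0) : min(s_hi, n)]
    left_bg = w[max(s_lo - n_bg, 0) : max(s_lo, 0)]
    right_bg = w[min(s_hi, n) : min(s_hi + n_bg, n)]
    n_bg_bins = left_bg.size + right_bg.size
    bg_mean = (left_bg.sum() + right_bg.sum()) / n_bg_bins if n_bg_bins else 0.0
    return float(sig.mean() - bg_mean)


def _plateaus(flat: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of equal value that are local maxima ((start, end)
    inclusive).  Runs touching a vector end qualify; their prominence is 0
    on that side, so the threshold removes them downstream."""
    n = flat.size
    out: list[tuple[int, int]] = []
    # boundaries of equal-value runs
    change = np.flatnonzero(np.diff(flat) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [n - 1]))
    for a, b in zip(starts, ends):
        v = flat[a]
        if v <= 0:
            continue
        left_ok = a == 0 or flat[a - 1] < v
        right_ok = b == n - 1 or flat[b + 1] < v
        if left_ok and right_ok:
            out.append((int(a), int(b)))
    return out


def _descend_bound(w: np.ndarray, apex: int, step: int, max_steps: int) -> int:
    """Index where monotonic descent from the apex on ``w`` ends, walking at
    most ``max_steps`` bins (beyond that the precursor-tolerance cap decides
    the boundary anyway)."""
    i = apex
    n = w.size
    steps = 0
    while steps < max_steps:
        j = i + step
        if j < 0 or j >= n or w[j] > w[i]:
            return i
        i = j
        steps += 1
    return i


def pick_peaks(hist: MassShiftHistogram, config: ShepherdConfig) -> PeakSet:
    """Call, rank and bound peaks on a smoothed histogram."""
    w = hist.weights
    set_size = max(1, int(round(config.flatten_mass_span / hist.bin_width)))
    flat = flatten_for_prominence(w, set_size)

    candidates: list[Peak] = []
    for a, b in _plateaus(flat):
        apex = a + int(np.argmax(w[a : b + 1]))  # ties -> leftmost
        prom = compute_prominence(flat, apex)
        if prom <= config.prominence_threshold:
            continue
        snr = compute_snr(
            w, apex, config.snr_signal_window, config.snr_background_flank,
            hist.bin_width,
        )
        apex_mass = hist.bin_center(apex)
        cap_bins = int(np.ceil(config.precursor_tol / hist.bin_width)) + 1
        li = _descend_bound(w, apex, -1, cap_bins)
        ri = _descend_bound(w, apex, +1, cap_bins)
        left = max(hist.lo + li * hist.bin_width, apex_mass - config.precursor_tol)
        right = min(hist.lo + (ri + 1) * hist.bin_width, apex_mass + config.precursor_tol)
        candidates.append(
            Peak(
                apex_index=apex,
                apex_mass=apex_mass,
                apex_height=float(w[apex]),
                prominence=prom,
                snr=snr,
                left_bound=left,
                right_bound=right,
            )
        )

    if not candidates:
        warnings.warn("no peaks called from histogram", stacklevel=2)
    candidates.sort(key=lambda p: (-p.snr, p.apex_mass))
    return PeakSet(peaks=candidates[: config.top_n_peaks], config=config)


def assign_psms_to_peaks(peakset: PeakSet, psms: list[PSMRecord]) -> PeakSet:
    """Assign each PSM to the peak whose boundaries contain its (raw) delta
    mass; where retained peaks overlap, the nearer apex wins.  Unmatched PSMs
    stay unassigned.  Sets ``reported_mass`` (mean raw delta mass of the
    assigned PSMs; apex mass if none)."""
    dm = np.array([p.delta_mass for p in psms], dtype=float)
    best_dist = np.full(dm.size, np.inf)
    best_peak = np.full(dm.size, -1, dtype=int)
    for k, peak in enumerate(peakset.peaks):
        inside = (dm >= peak.left_bound) & (dm <= peak.right_bound)
        dist = np.abs(dm - peak.apex_mass)
        take = inside & (dist < best_dist)
        best_dist[take] = dist[take]
        best_peak[take] = k

    for peak in peakset.peaks:
        peak.assigned = {}
    for i, k in enumerate(best_peak):
        if k < 0:
            continue
        peak = peakset.peaks[k]
        peak.assigned.setdefault(psms[i].experiment, []).append(psms[i])
    for peak in peakset.peaks:
        masses = [p.delta_mass for p in peak.assigned_psms()]
        peak.reported_mass = float(np.mean(masses)) if masses else peak.apex_mass
    return peakset


def quantify_peaks(peakset: PeakSet, experiment_set: ExperimentSet) -> pd.DataFrame:
    """Per-peak, per-experiment spectral counts plus size-normalized counts.

    Returns a tidy frame with one row per (peak, experiment) and pooled rows
    under experiment label ``"(all)"``.  Normalized count = count / total
    PSMs in that experiment (0 for an empty experiment).
    """
    totals = experiment_set.totals()
    grand_total = sum(totals.values())
    rows = []
    for k, peak in enumerate(peakset.peaks):
        pooled = 0
        for label, total in totals.items():
            count = len(peak.assigned.get(label, []))
            pooled += count
            rows.append(
                {
                    "peak": k,
                    "reported_mass": peak.reported_mass,
                    "experiment": label,
                    "count": count,
                    "normalized": (count / total) if total else 0.0,
                }
            )
        rows.append(
            {
                "peak": k,
                "reported_mass": peak.reported_mass,
                "experiment": "(all)",
                "count": pooled,
                "normalized": (pooled / grand_total) if grand_total else 0.0,
            }
        )
    return pd.DataFrame(
        rows, columns=["peak", "reported_mass", "experiment", "count", "normalized"]
    )
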