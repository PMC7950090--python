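"""Independent brute-force oracles used by the test suite.

These re-derive the peak-picking and fragment-matching rules with literal
loops straight from their definitions, deliberately sharing no code with the
package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_flatten(w, set_size):
    w = list(map(float, w))
    n = len(w)
    out = [0.0] * n
    i = 0
    while i < n:
        j = min(i + set_size, n)
        m = min(w[i:j])
        for k in range(i, j):
            out[k] = m
        i = j
    return out


def _oracle_shoulder(flat, apex, step):
    i = apex
    n = len(flat)
    while True:
        j = i + step
        if j < 0 or j >= n:
            return flat[i]
        if flat[j] > flat[i]:
            return flat[i]
        i = j


def oracle_prominence(flat, apex):
    a = flat[apex]
    left = _oracle_shoulder(flat, apex, -1)
    right = _oracle_shoulder(flat, apex, +1)
    return (a - max(left, right)) / a


def oracle_snr(w, apex, signal_window, background_flank, bin_width):
    n = len(w)
    n_sig = round(signal_window / bin_width)
    n_bg = round(background_flank / bin_width)
    s_lo = apex - n_sig // 2
    s_hi = s_lo + n_sig
    sig = [w[i] for i in range(max(s_lo, 0), min(s_hi, n))]
    bg = [w[i] for i in range(max(s_lo - n_bg, 0), max(s_lo, 0))]
    bg += [w[i] for i in range(min(s_hi, n), min(s_hi + n_bg, n))]
    bg_mean = sum(bg) / len(bg) if bg else 0.0
    return sum(sig) / len(sig) - bg_mean


def _oracle_descend(w, apex, step):
    i = apex
    n = len(w)
    while True:
        j = i + step
        if j < 0 or j >= n or w[j] > w[i]:
            return i
        i = j


def oracle_pick_peaks(hist, config):
    """Enumerate every bin, test plateau local-maximality and the prominence
    definition directly; returns rows sorted by (-snr, apex mass)."""
    w = list(map(float, hist.weights))
    n = len(w)
    set_size = max(1, round(config.flatten_mass_span / hist.bin_width))
    flat = oracle_flatten(w, set_size)
    rows = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and flat[j + 1] == flat[i]:
            j += 1
        v = flat[i]
        if v > 0 and (i == 0 or flat[i - 1] < v) and (j == n - 1 or flat[j + 1] < v):
            apex = i
            for k in range(i, j + 1):
                if w[k] > w[apex]:
                    apex = k
            prom = oracle_prominence(flat, apex)
            if prom > config.prominence_threshold:
                snr = oracle_snr(
                    w, apex, config.snr_signal_window,
                    config.snr_background_flank, hist.bin_width,
                )
                apex_mass = hist.lo + (apex + 0.5) * hist.bin_width
                li = _oracle_descend(w, apex, -1)
                ri = _oracle_descend(w, apex, +1)
                left = max(hist.lo + li * hist.bin_width, apex_mass - config.precursor_tol)
                right = min(
                    hist.lo + (ri + 1) * hist.bin_width,
                    apex_mass + config.precursor_tol,
                )
                rows.append((apex, apex_mass, prom, snr, left, right))
        i = j + 1
    rows.sort(key=lambda r: (-r[3], r[1]))
    return rows[: config.top_n_peaks]


def oracle_hyperscore(spectrum, fragments, config):
    """Naive matcher: fragments ascending within each series (b first), each
    scanning every spectrum peak for the nearest unused one in tolerance."""
    mz = list(map(float, spectrum.mz))
    inten = list(map(float, spectrum.intensity))
    used = [False] * len(mz)

    def match(frags):
        count, total = 0, 0.0
        for f in sorted(frags):
            tol = config.fragment_tol_da(f)
            best, best_key = None, None
            for k in range(len(mz)):
                if used[k]:
                    continue
                d = abs(mz[k] - f)
                if d <= tol and (best_key is None or (d, mz[k]) < best_key):
                    best, best_key = k, (d, mz[k])
            if best is not None:
                used[best] = True
                count += 1
                total += inten[best]
        return count, total

    b = [m for lbl, m in fragments if lbl.startswith("b")]
    y = [m for lbl, m in fragments if lbl.startswith("y")]
    nb, sib = match(b)
    ny, siy = match(y)
    score = (
        math.log10(math.factorial(nb))
        + math.log10(math.factorial(ny))
        + math.log10(max(sib, 1.0))
        + math.log10(max(siy, 1.0))
    )
    return nb, ny, sib, siy, score


def random_histogram(rng, max_bins=200, bin_width=0.0002):
    """Random nonnegative weight vector: smooth bumps + noise + zero runs."""
    from shiftprofiler import MassShiftHistogram

    n = int(rng.integers(30, max_bins + 1))
    w = rng.random(n) * rng.choice([0.0, 0.2, 1.0], size=n, p=[0.3, 0.3, 0.4])
    for _ in range(int(rng.integers(0, 4))):
        c = int(rng.integers(0, n))
        height = rng.uniform(2, 20)
        width = rng.uniform(1, 6)
        x = np.arange(n)
        w += height * np.exp(-0.5 * ((x - c) / width) ** 2)
    return MassShiftHistogram(lo=-(n // 2) * bin_width, bin_width=bin_width, weights=w)
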