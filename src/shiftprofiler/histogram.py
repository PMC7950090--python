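"""Delta-mass histogram: tie-break jitter, binning, Gaussian smoothing.

All experiments are pooled with unit PSM weight.  Pooling is arithmetically
identical (up to one global constant) to averaging per-experiment histograms
weighted by each experiment's share of the total PSM count, so a single
aggregate histogram serves the multi-experiment mode as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import EmptyInputError, InputError
from .model import PSMRecord, ShepherdConfig


@dataclass
class MassShiftHistogram:
    """Fixed-width binned weight vector over delta-mass space.

    Bin ``i`` covers ``[lo + i*bin_width, lo + (i+1)*bin_width)``; the bin
    index of mass ``m`` is ``floor((m - lo)/bin_width)``.
    """

    lo: float
    bin_width: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or self.weights.size < 1:
            raise InputError("weights must be a nonempty 1-D vector")

    @property
    def n_bins(self) -> int:
        return int(self.weights.size)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def index_of(self, mass: float) -> int:
        return int(np.floor((mass - self.lo) / self.bin_width))

    def bin_center(self, index: int) -> float:
        return self.lo + (index + 0.5) * self.bin_width

    def bin_centers(self) -> np.ndarray:
        return self.lo + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def dump_tsv(self, path) -> None:
        """Debug dump: two columns, bin center (Da) and weight."""
        with open(path, "w") as fh:
            fh.write("bin_center_da\tweight\n")
            for c, w in zip(self.bin_centers(), self.weights):
                fh.write(f"{c:.5f}\t{w:.6g}\n")


def apply_tiebreak_jitter(
    delta_masses: np.ndarray, half_width: float, seed: int
) -> np.ndarray:
    """Add uniform noise on [-half_width, +half_width] to break bin-edge ties.

    Order-preserving and reproducible for a fixed seed; ``half_width`` 0 is
    the identity.
    """
    if half_width < 0:
        raise InputError("half_width must be >= 0")
    masses = np.asarray(delta_masses, dtype=float)
    if half_width == 0:
        return masses.copy()
    rng = np.random.default_rng(seed)
    return masses + rng.uniform(-half_width, half_width, size=masses.size)


def build_histogram(
    psms: list[PSMRecord] | np.ndarray, config: ShepherdConfig
) -> MassShiftHistogram:
    """Bin jittered delta masses of all PSMs (all experiments pooled).

    The range spans [min - extension, max + extension] of the jittered
    masses; each PSM contributes weight 1 to exactly one bin, so
    ``total_weight`` equals the PSM count.
    """
    if isinstance(psms, np.ndarray):
        masses = psms.astype(float)
    else:
        masses = np.array([p.delta_mass for p in psms], dtype=float)
    if masses.size == 0:
        raise EmptyInputError("cannot build a histogram from zero PSMs")
    jittered = apply_tiebreak_jitter(masses, config.jitter_half_width, config.rng_seed)
    lo = float(jittered.min()) - config.histogram_extension
    hi = float(jittered.max()) + config.histogram_extension
    n_bins = int(np.ceil((hi - lo) / config.bin_width)) + 1
    idx = np.floor((jittered - lo) / config.bin_width).astype(np.int64)
    weights = np.bincount(idx, minlength=n_bins).astype(float)
    return MassShiftHistogram(lo=lo, bin_width=config.bin_width, weights=weights)


def gaussian_kernel(smoothing_bins: int, mass_fraction: float) -> np.ndarray:
    """Discrete smoothing kernel: per-bin integrals of a Gaussian.

    sigma is chosen so the central ``smoothing_bins`` bins cover
    ``mass_fraction`` of the Gaussian's mass:
    ``sigma = (smoothing_bins/2) / Phi^-1((1 + fraction)/2)`` in bin units
    (~1.2755 bins at the defaults of 5 bins / 0.95).  The kernel is the
    Gaussian integrated over each bin interval, renormalized to sum to 1.
    """
    if smoothing_bins < 1 or smoothing_bins % 2 == 0:
        raise InputError("smoothing_bins must be odd and >= 1")
    if not (0.0 < mass_fraction < 1.0):
        raise InputError("mass_fraction must be in (0, 1)")
    if smoothing_bins == 1:
        return np.array([1.0])
    sigma = (smoothing_bins / 2.0) / norm.ppf((1.0 + mass_fraction) / 2.0)
    half = smoothing_bins // 2
    offsets = np.arange(-half, half + 1)
    kernel = norm.cdf((offsets + 0.5) / sigma) - norm.cdf((offsets - 0.5) / sigma)
    return kernel / kernel.sum()


def smooth_histogram(
    hist: MassShiftHistogram,
    smoothing_bins: int = 5,
    smoothing_mass_fraction: float = 0.95,
) -> MassShiftHistogram:
    """Distribute each bin's weight over its neighbors with a Gaussian kernel.

    Total weight is conserved exactly: a source bin within half a kernel of
    either histogram end uses its kernel truncated to the valid range and
    renormalized, so no weight falls off the ends.
    """
    kernel = gaussian_kernel(smoothing_bins, smoothing_mass_fraction)
    w = hist.weights
    n = w.size
    half = smoothing_bins // 2
    if half == 0 or n == 1:
        return MassShiftHistogram(hist.lo, hist.bin_width, w.copy())

    # Per-source renormalization factor: sum of kernel entries that land
    # inside the vector.  Only the `half` bins at each end differ from 1.
    valid = np.ones(n)
    for i in range(min(half, n)):
        lo_off = max(-half, -i)
        hi_off = min(half, n - 1 - i)
        valid[i] = kernel[lo_off + half : hi_off + half + 1].sum()
        j = n - 1 - i
        lo_off = max(-half, -j)
        hi_off = min(half, n - 1 - j)
        valid[j] = kernel[lo_off + half : hi_off + half + 1].sum()
    source = w / valid

    out = np.zeros(n)
    for k, off in enumerate(range(-half, half + 1)):
        if off < 0:
            out[: n + off] += source[-off:] * kernel[k]
        elif off > 0:
            out[off:] += source[:-off] * kernel[k]
        else:
            out += source * kernel[k]
    return MassShiftHistogram(hist.lo, hist.bin_width, out)
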