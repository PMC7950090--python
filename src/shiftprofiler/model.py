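"""Shared data model: PSM records, spectra, experiment sets, configuration."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import RESIDUE_MASS
from .errors import ConfigurationError, InputError


@dataclass
class PSMRecord:
    """One FDR-filtered peptide-spectrum match from an open search.

    Parameters
    ----------
    spectrum_id:
        Opaque key resolving the fragmentation spectrum (run + scan composite).
    experiment:
        Label of the experiment (PSM table) this record came from.
    peptide:
        Upper-case amino-acid sequence (20-letter alphabet).
    delta_mass:
        Observed precursor mass minus theoretical peptide mass, signed, Da.
    retention_time:
        Seconds.
    charge:
        Precursor charge, >= 1.
    proteins:
        Protein accessions the peptide maps to.
    applied_mods:
        Fixed/variable modification masses already applied during the search,
        as (1-based position, Da) pairs.
    """

    spectrum_id: str
    experiment: str
    peptide: str
    delta_mass: float
    retention_time: float
    charge: int
    proteins: list[str] = field(default_factory=list)
    applied_mods: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.peptide) < 1:
            raise InputError("peptide must have length >= 1")
        if self.charge < 1:
            raise InputError("charge must be >= 1")
        if not math.isfinite(self.delta_mass):
            raise InputError("delta_mass must be finite")
        bad = set(self.peptide) - set(RESIDUE_MASS)
        if bad:
            raise InputError(f"unknown residue letter(s): {sorted(bad)}")


@dataclass
class Spectrum:
    """A fragmentation spectrum: peaks sorted ascending by m/z."""

    spectrum_id: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise InputError("mz and intensity must have equal length")
        if self.mz.size and np.any(self.mz <= 0):
            raise InputError("mz values must be strictly positive")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class ExperimentSet:
    """PSMs grouped by experiment plus a shared spectrum store.

    PSMs whose ``spectrum_id`` does not resolve in ``spectra`` stay in the
    experiment lists (they still count for the histogram and peak
    quantification) but are excluded from localization and similarity; their
    ids are collected in ``missing_spectra``.
    """

    experiments: dict[str, list[PSMRecord]] = field(default_factory=dict)
    spectra: dict[str, Spectrum] = field(default_factory=dict)
    missing_spectra: set[str] = field(default_factory=set)

    def all_psms(self) -> list[PSMRecord]:
        out: list[PSMRecord] = []
        for label in self.experiments:
            out.extend(self.experiments[label])
        return out

    def totals(self) -> dict[str, int]:
        return {label: len(psms) for label, psms in self.experiments.items()}

    def has_spectrum(self, psm: PSMRecord) -> bool:
        return psm.spectrum_id in self.spectra

    def get_spectrum(self, psm: PSMRecord) -> Spectrum | None:
        return self.spectra.get(psm.spectrum_id)


BACKGROUND_SCOPES = ("dataset_psm", "dataset_peptide", "bin_psm", "bin_peptide")


@dataclass
class ShepherdConfig:
    """All tunable parameters with their documented defaults.

    Masses and tolerances are in Da unless noted.  ``jitter_half_width``
    defaults to half a histogram bin; the historically printed 0.005 Da
    tie-break range remains selectable (it is 25x the default bin width and
    erases sub-millidalton structure, see docs/methods.md).
    """

    bin_width: float = 0.0002
    histogram_extension: float = 5.0
    jitter_half_width: float = 0.0001
    smoothing_bins: int = 5
    smoothing_mass_fraction: float = 0.95
    prominence_threshold: float = 0.3
    snr_signal_window: float = 0.004
    snr_background_flank: float = 0.005
    top_n_peaks: int = 500
    precursor_tol: float = 0.01
    annotation_tol: float = 0.01
    max_components: int = 2
    prioritize_user_mods: bool = False
    unmodified_threshold: float = 0.001
    unmodified_cap: int = 50
    isotope_spacing: float = 1.00235
    fragment_tol: float = 20.0
    fragment_tol_unit: str = "ppm"  # "ppm" or "da"
    flatten_mass_span: float = 0.0010
    similarity_grid_width: float = 0.05
    similarity_sqrt_intensity: bool = False
    same_run_only: bool = False
    background_scope: str = "dataset_psm"
    rng_seed: int = 42

    def __post_init__(self) -> None:
        positive = (
            "bin_width",
            "histogram_extension",
            "snr_signal_window",
            "snr_background_flank",
            "precursor_tol",
            "annotation_tol",
            "unmodified_threshold",
            "isotope_spacing",
            "fragment_tol",
            "flatten_mass_span",
            "similarity_grid_width",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.jitter_half_width < 0:
            raise ConfigurationError("jitter_half_width must be >= 0")
        if self.smoothing_bins < 1 or self.smoothing_bins % 2 == 0:
            raise ConfigurationError("smoothing_bins must be odd and >= 1")
        if not (0.0 < self.smoothing_mass_fraction < 1.0):
            raise ConfigurationError("smoothing_mass_fraction must be in (0, 1)")
        if not (0.0 < self.prominence_threshold < 1.0):
            raise ConfigurationError("prominence_threshold must be in (0, 1)")
        if self.top_n_peaks < 1:
            raise ConfigurationError("top_n_peaks must be >= 1")
        if self.unmodified_cap < 1:
            raise ConfigurationError("unmodified_cap must be >= 1")
        if self.max_components != 2:
            raise ConfigurationError("max_components is fixed at 2")
        if self.fragment_tol_unit not in ("ppm", "da"):
            raise ConfigurationError("fragment_tol_unit must be 'ppm' or 'da'")
        if self.background_scope not in BACKGROUND_SCOPES:
            raise ConfigurationError(
                f"background_scope must be one of {BACKGROUND_SCOPES}"
            )

    def fragment_tol_da(self, mz: float) -> float:
        """Absolute fragment tolerance at a given m/z."""
        if self.fragment_tol_unit == "ppm":
            return mz * self.fragment_tol * 1e-6
        return self.fragment_tol
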