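"""Synthetic datasets with known ground truth.

The generator emulates the statistical structure the profiling method
assumes: a dominant unmodified PSM population plus discrete delta-mass
populations implanted at configurable per-experiment frequencies, placed on
designated residues with configurable site fidelity, with retention-time
offsets separating pre-elution modifications (large positive shifts) from
in-source losses (zero shift).  Spectra are theoretical singly charged b/y
ladders with log-normal intensities plus uniform random noise peaks.  It
does not emulate chromatographic peak shape, isotope envelopes, higher
fragment charges, or reporter ions; a green test on these fixtures
establishes correctness of the bookkeeping and scoring, not instrument
realism.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_mgf, write_mzml, write_psm_table
from .localization import _fragment_arrays
from .model import ExperimentSet, PSMRecord, Spectrum


@dataclass(frozen=True)
class ImplantedShift:
    """One synthetic delta-mass population."""

    mass: float
    residue: str | None  # target residue, or None for untargeted placement
    frequency: float  # per-experiment fraction of PSMs carrying the shift
    rt_offset: float  # seconds added to the base elution time
    site_fidelity: float = 0.9  # probability the site is on the target residue


# Defaults model a TMT-era QC sample: oxidation, phospho, formylation,
# methylation, TMT overlabeling, deamidation, pyro-Glu and acetylation at
# low-percent frequencies over a ~70% unmodified background.
DEFAULT_SHIFTS: tuple[ImplantedShift, ...] = (
    ImplantedShift(15.9949, "M", 0.05, -30.0),
    ImplantedShift(79.9663, "S", 0.04, 90.0),
    ImplantedShift(27.9949, "K", 0.03, 60.0),
    ImplantedShift(14.0157, "K", 0.03, 45.0),
    ImplantedShift(229.1629, "S", 0.04, -70.0),
    ImplantedShift(0.9840, "N", 0.05, 5.0),
    ImplantedShift(-17.0265, "Q", 0.03, 450.0),
    ImplantedShift(42.0106, "K", 0.03, 120.0),
)


@dataclass
class FixtureSpec:
    """Stated world of a synthetic dataset; fixed seed => full reproducibility."""

    n_experiments: int = 3
    n_psms_per_experiment: int = 2000
    n_peptides_per_experiment: int = 250
    peptide_length: tuple[int, int] = (7, 16)
    shifts: tuple[ImplantedShift, ...] = DEFAULT_SHIFTS
    noise_peaks: int = 10
    mass_error_sigma: float = 0.0005  # Da; sharp relative to the 0.004 Da SNR window
    rt_noise_sigma: float = 10.0  # seconds
    intensity_log_mean: float = 5.0  # log-normal fragment intensity model
    intensity_log_sigma: float = 0.4
    noise_log_mean: float = 3.0
    noise_log_sigma: float = 0.5
    rng_seed: int = 42

    def __post_init__(self) -> None:
        for s in self.shifts:
            if not (0.0 <= s.frequency <= 1.0):
                raise ValueError("shift frequencies must be in [0, 1]")
            if not (0.0 <= s.site_fidelity <= 1.0):
                raise ValueError("site fidelity must be in [0, 1]")
        if sum(s.frequency for s in self.shifts) > 1.0:
            raise ValueError("shift frequencies must sum to <= 1")


_RESIDUES = "ACDEFGHILMNPQSTVWY"  # non-terminal draw; K/R reserved for the C terminus


def random_tryptic_peptide(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    body = "".join(rng.choice(list(_RESIDUES), size=length - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def generate_peptide_spectrum(
    peptide: str,
    shift_mass: float,
    site: int | None,
    noise_peaks: int,
    rng: np.random.Generator,
    intensity_log_mean: float = 5.0,
    intensity_log_sigma: float = 0.4,
    noise_log_mean: float = 3.0,
    noise_log_sigma: float = 0.5,
    spectrum_id: str = "synthetic",
    applied_mods: list[tuple[int, float]] = (),
) -> Spectrum:
    """Theoretical b/y ladder with the shift applied at ``site`` (1-based),
    log-normal intensities, plus uniform random noise peaks."""
    b, y = _fragment_arrays(peptide, applied_mods, shift_mass, site)
    frag_mz = np.concatenate([b, y])
    frag_int = rng.lognormal(intensity_log_mean, intensity_log_sigma, frag_mz.size)
    if noise_peaks > 0:
        hi = float(frag_mz.max()) + 50.0
        noise_mz = rng.uniform(100.0, hi, noise_peaks)
        noise_int = rng.lognormal(noise_log_mean, noise_log_sigma, noise_peaks)
        frag_mz = np.concatenate([frag_mz, noise_mz])
        frag_int = np.concatenate([frag_int, noise_int])
    return Spectrum(spectrum_id, frag_mz, frag_int)


def generate_experiment_set(spec: FixtureSpec) -> tuple[ExperimentSet, pd.DataFrame]:
    """In-memory fixture: (experiment set with spectra, truth manifest).

    Manifest columns: spectrum_id, experiment, peptide, charge, true_shift,
    true_site (1-based, -1 for none), rt_offset, delta_mass, retention_time.
    """
    rng = np.random.default_rng(spec.rng_seed)
    es = ExperimentSet()
    manifest_rows: list[dict] = []
    freqs = np.array([s.frequency for s in spec.shifts])
    cum = np.cumsum(freqs)

    for e in range(spec.n_experiments):
        label = f"exp{e + 1}"
        es.experiments[label] = []
        # Peptide pool shared within the experiment so modified PSMs have
        # unmodified counterparts; charge and base elution fixed per peptide.
        peptides = [
            random_tryptic_peptide(rng, spec.peptide_length)
            for _ in range(spec.n_peptides_per_experiment)
        ]
        charges = rng.integers(2, 4, size=len(peptides))
        base_rt = rng.uniform(600.0, 3000.0, size=len(peptides))

        for scan in range(1, spec.n_psms_per_experiment + 1):
            u = rng.random()
            shift_idx = int(np.searchsorted(cum, u)) if u < cum[-1] else -1
            shift = spec.shifts[shift_idx] if shift_idx >= 0 else None

            pep_idx = int(rng.integers(len(peptides)))
            if shift is not None and shift.residue is not None:
                for _ in range(50):
                    if shift.residue in peptides[pep_idx]:
                        break
                    pep_idx = int(rng.integers(len(peptides)))
            peptide = peptides[pep_idx]

            if shift is None:
                true_shift, site, rt_offset = 0.0, None, 0.0
            else:
                true_shift, rt_offset = shift.mass, shift.rt_offset
                positions = np.arange(1, len(peptide) + 1)
                on_target = (
                    shift.residue is not None
                    and shift.residue in peptide
                    and rng.random() < shift.site_fidelity
                )
                if on_target:
                    targets = positions[
                        np.array([aa == shift.residue for aa in peptide])
                    ]
                    site = int(rng.choice(targets))
                else:
                    site = int(rng.choice(positions))

            sid = f"{label}.{scan:05d}"
            spectrum = generate_peptide_spectrum(
                peptide,
                true_shift,
                site,
                spec.noise_peaks,
                rng,
                spec.intensity_log_mean,
                spec.intensity_log_sigma,
                spec.noise_log_mean,
                spec.noise_log_sigma,
                spectrum_id=sid,
            )
            es.spectra[sid] = spectrum

            delta = true_shift + rng.normal(0.0, spec.mass_error_sigma)
            rt = float(base_rt[pep_idx] + rt_offset + rng.normal(0.0, spec.rt_noise_sigma))
            psm = PSMRecord(
                spectrum_id=sid,
                experiment=label,
                peptide=peptide,
                delta_mass=float(delta),
                retention_time=rt,
                charge=int(charges[pep_idx]),
                proteins=[f"SYN|P{pep_idx:04d}"],
            )
            es.experiments[label].append(psm)
            manifest_rows.append(
                {
                    "spectrum_id": sid,
                    "experiment": label,
                    "peptide": peptide,
                    "charge": int(charges[pep_idx]),
                    "true_shift": true_shift,
                    "true_site": site if site is not None else -1,
                    "rt_offset": rt_offset,
                    "delta_mass": float(delta),
                    "retention_time": rt,
                }
            )
    return es, pd.DataFrame(manifest_rows)


def generate_dataset(
    spec: FixtureSpec,
    out_dir: str | os.PathLike,
    spectra_format: str = "mgf",
) -> dict[str, list[Path]]:
    """Write the fixture to disk: per-experiment PSM tables and spectra plus
    ``manifest.tsv``.  Same spec (and seed) => byte-identical files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    es, manifest = generate_experiment_set(spec)
    paths: dict[str, list[Path]] = {"psm_tables": [], "spectra": [], "manifest": []}
    for label, psms in es.experiments.items():
        tsv = out / f"{label}.psm.tsv"
        write_psm_table(tsv, psms)
        paths["psm_tables"].append(tsv)
        spectra = [es.spectra[p.spectrum_id] for p in psms]
        if spectra_format == "mgf":
            spath = out / f"{label}.mgf"
            write_mgf(spath, spectra)
        elif spectra_format == "mzml":
            spath = out / f"{label}.mzML"
            write_mzml(spath, spectra, run_id=label)
        else:
            raise ValueError("spectra_format must be 'mgf' or 'mzml'")
        paths["spectra"].append(spath)
    mpath = out / "manifest.tsv"
    manifest.to_csv(mpath, sep="\t", index=False, float_format="%.6f", lineterminator="\n")
    paths["manifest"].append(mpath)
    return paths
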