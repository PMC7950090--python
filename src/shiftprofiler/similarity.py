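"""Modified-unmodified comparisons: cosine spectral similarity and RT shift.

PSMs with |delta mass| below the unmodified threshold (0.001 Da by default)
are indexed by (experiment, peptide, charge); keys holding more than the cap
(50) are randomly subsampled with a seeded generator.  Each mass-shifted PSM
is compared with all counterparts of the same peptide and charge: the mean
cosine similarity on a fixed-width m/z grid and the RT difference
(PSM RT minus the counterparts' mean RT).  Per-peak, per-experiment means
form the comparison profile; a near-zero mean RT shift flags in-source
losses, which occur after column elution.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .model import ExperimentSet, PSMRecord, ShepherdConfig, Spectrum
from .peaks import PeakSet


def _run_of(spectrum_id: str) -> str:
    return spectrum_id.split(".", 1)[0]


@dataclass
class UnmodifiedIndex:
    """(experiment, peptide, charge) -> [(spectrum_id, retention_time)]."""

    entries: dict[tuple[str, str, int], list[tuple[str, float]]] = field(
        default_factory=dict
    )

    def lookup(
        self, experiment: str, peptide: str, charge: int, run: str | None = None
    ) -> list[tuple[str, float]]:
        hits = self.entries.get((experiment, peptide, charge), [])
        if run is not None:
            hits = [h for h in hits if _run_of(h[0]) == run]
        return hits


@dataclass
class ComparisonProfile:
    peak_index: int
    experiment: str
    n_assigned: int
    n_compared: int
    mean_similarity: float  # nan when n_compared == 0
    mean_delta_rt: float  # seconds; nan when n_compared == 0

    @property
    def fraction_with_counterpart(self) -> float:
        return self.n_compared / self.n_assigned if self.n_assigned else 0.0


def build_unmodified_index(
    psms: list[PSMRecord], config: ShepherdConfig
) -> UnmodifiedIndex:
    """Index unmodified PSMs, capping each key by seeded random subsample."""
    index = UnmodifiedIndex()
    for psm in psms:
        if abs(psm.delta_mass) < config.unmodified_threshold:
            key = (psm.experiment, psm.peptide, psm.charge)
            index.entries.setdefault(key, []).append(
                (psm.spectrum_id, psm.retention_time)
            )
    for key, hits in index.entries.items():
        if len(hits) > config.unmodified_cap:
            # stable per-key seed below 2**31
            key_seed = (
                zlib.crc32("/".join(map(str, key)).encode()) ^ config.rng_seed
            ) & 0x7FFFFFFF
            rng = np.random.default_rng(key_seed)
            chosen = rng.choice(len(hits), size=config.unmodified_cap, replace=False)
            index.entries[key] = [hits[i] for i in sorted(chosen)]
    return index


def spectrum_cosine(
    a: Spectrum,
    b: Spectrum,
    grid_width: float = 0.05,
    sqrt_intensity: bool = False,
) -> float:
    """Cosine similarity of two spectra on a shared fixed-width m/z grid.

    Intensities are summed per grid cell; returns 0 when either spectrum is
    empty.  Invariant to scaling either spectrum by a positive constant.
    """
    if grid_width <= 0:
        raise InputError("grid_width must be > 0")
    if len(a) == 0 or len(b) == 0:
        return 0.0

    def gridded(sp: Spectrum) -> tuple[np.ndarray, np.ndarray]:
        cells = np.floor(sp.mz / grid_width).astype(np.int64)
        inten = np.sqrt(sp.intensity) if sqrt_intensity else sp.intensity
        uniq, inv = np.unique(cells, return_inverse=True)
        sums = np.zeros(uniq.size)
        np.add.at(sums, inv, inten)
        return uniq, sums

    ca, va = gridded(a)
    cb, vb = gridded(b)
    na = float(np.linalg.norm(va))
    nb = float(np.linalg.norm(vb))
    if na == 0.0 or nb == 0.0:
        return 0.0
    # dot product over shared cells
    ia = np.isin(ca, cb)
    if not ia.any():
        return 0.0
    shared = ca[ia]
    pos_b = np.searchsorted(cb, shared)
    dot = float(np.dot(va[ia], vb[pos_b]))
    return dot / (na * nb)


def compare_modified_psm(
    psm: PSMRecord,
    index: UnmodifiedIndex,
    experiment_set: ExperimentSet,
    config: ShepherdConfig,
) -> tuple[float, float, int] | None:
    """Compare one mass-shifted PSM with its unmodified counterparts.

    Returns (mean cosine similarity, mean RT difference in seconds, number
    of counterparts), or None when no same-peptide same-charge counterpart
    exists (or the PSM's own spectrum is unresolvable).
    """
    run = _run_of(psm.spectrum_id) if config.same_run_only else None
    hits = index.lookup(psm.experiment, psm.peptide, psm.charge, run)
    if not hits:
        return None
    spectrum = experiment_set.get_spectrum(psm)
    if spectrum is None:
        return None
    sims = []
    rts = []
    for sid, rt in hits:
        other = experiment_set.spectra.get(sid)
        if other is None:
            continue
        sims.append(
            spectrum_cosine(
                spectrum,
                other,
                config.similarity_grid_width,
                config.similarity_sqrt_intensity,
            )
        )
        rts.append(rt)
    if not rts:
        return None
    return float(np.mean(sims)), psm.retention_time - float(np.mean(rts)), len(rts)


def compare_peakset(
    peakset: PeakSet,
    experiment_set: ExperimentSet,
    config: ShepherdConfig,
    index: UnmodifiedIndex | None = None,
) -> dict[int, list[tuple[PSMRecord, float, float]]]:
    """Per-peak lists of (psm, avg similarity, avg delta RT) for every
    assigned PSM with at least one counterpart."""
    if index is None:
        index = build_unmodified_index(experiment_set.all_psms(), config)
    out: dict[int, list[tuple[PSMRecord, float, float]]] = {}
    for k, peak in enumerate(peakset.peaks):
        rows: list[tuple[PSMRecord, float, float]] = []
        for psm in peak.assigned_psms():
            res = compare_modified_psm(psm, index, experiment_set, config)
            if res is not None:
                rows.append((psm, res[0], res[1]))
        out[k] = rows
    return out


def aggregate_comparison_profiles(
    comparisons: dict[int, list[tuple[PSMRecord, float, float]]],
    peakset: PeakSet,
    experiment_set: ExperimentSet,
) -> list[ComparisonProfile]:
    """Mean similarity / mean RT shift per peak for each experiment and
    pooled (``"(all)"``)."""
    labels = list(experiment_set.experiments) + ["(all)"]
    profiles: list[ComparisonProfile] = []
    for k, rows in comparisons.items():
        peak = peakset.peaks[k]
        for label in labels:
            if label == "(all)":
                sub = rows
                n_assigned = peak.n_assigned
            else:
                sub = [r for r in rows if r[0].experiment == label]
                n_assigned = len(peak.assigned.get(label, []))
            sims = [s for _, s, _ in sub]
            drts = [d for _, _, d in sub]
            profiles.append(
                ComparisonProfile(
                    peak_index=k,
                    experiment=label,
                    n_assigned=n_assigned,
                    n_compared=len(sub),
                    mean_similarity=float(np.mean(sims)) if sims else float("nan"),
                    mean_delta_rt=float(np.mean(drts)) if drts else float("nan"),
                )
            )
    return profiles
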