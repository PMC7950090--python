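"""Mass-shift localization by exhaustive single-site fragment rescoring.

For each PSM assigned to a peak, the peak's mass shift is placed at each
residue position in turn and the PSM is rescored against its spectrum with
an MSFragger-style hyperscore,

    score = log10( Nb! * Ny! * max(sum_Ib, 1) * max(sum_Iy, 1) ),

where Nb/Ny are matched singly charged b/y fragment counts and sum_Ib/sum_Iy
the summed matched intensities.  A PSM is localizable iff some placement
matches strictly more fragment ions than the unshifted baseline; the unit
localization weight is split uniformly over the top-scoring positions.
Per-peak, per-experiment residue counts are normalized against background
residue content to give enrichment ratios.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .constants import PROTON_MASS, RESIDUE_MASS, WATER_MASS
from .errors import InputError
from .model import ExperimentSet, PSMRecord, ShepherdConfig, Spectrum
from .peaks import PeakSet

_LN10 = math.log(10.0)


@dataclass
class ScoredMatch:
    nb: int
    ny: int
    sum_ib: float
    sum_iy: float

    @property
    def matched(self) -> int:
        return self.nb + self.ny

    @property
    def score(self) -> float:
        # Factorials in log space (log-gamma), exact for small counts and
        # overflow-free for large ones.
        return (
            (math.lgamma(self.nb + 1) + math.lgamma(self.ny + 1)) / _LN10
            + math.log10(max(self.sum_ib, 1.0))
            + math.log10(max(self.sum_iy, 1.0))
        )


@dataclass
class LocalizationResult:
    psm: PSMRecord
    localizable: bool
    site_weights: np.ndarray  # per position; sums to 1 iff localizable else 0
    best_score: float
    nterm_flag: bool


@dataclass
class LocalizationProfile:
    """Residue-enrichment aggregate for one peak in one experiment
    (``experiment`` is ``"(all)"`` for the pooled profile)."""

    peak_index: int
    experiment: str
    n_attempted: int
    n_localizable: int
    nterm_rate: float
    residue_counts: dict[str, float]
    background_counts: dict[str, float]
    enrichment: dict[str, float] = field(default_factory=dict)

    @property
    def localized_fraction(self) -> float:
        return self.n_localizable / self.n_attempted if self.n_attempted else 0.0

    def top_residues(self, n: int = 2) -> list[tuple[str, float]]:
        ranked = sorted(self.enrichment.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[:n]


def theoretical_fragments(
    peptide: str,
    applied_mods: list[tuple[int, float]] = (),
    shift_mass: float = 0.0,
    shift_pos: int | None = None,
) -> list[tuple[str, float]]:
    """Singly charged b1..b(L-1) and y1..y(L-1) ion m/z values.

    ``applied_mods`` are (1-based position, Da) fixed/variable search
    modifications, always applied.  With ``shift_pos`` = k (1-based), b_i for
    i >= k and y_j for j >= L-k+1 are shifted by ``shift_mass``.
    """
    b, y = _fragment_arrays(peptide, applied_mods, shift_mass, shift_pos)
    out = [(f"b{i + 1}", float(m)) for i, m in enumerate(b)]
    out += [(f"y{j + 1}", float(m)) for j, m in enumerate(y)]
    return out


def _residue_masses(peptide: str, applied_mods) -> np.ndarray:
    try:
        masses = np.array([RESIDUE_MASS[aa] for aa in peptide], dtype=float)
    except KeyError as exc:
        raise InputError(f"unknown residue letter {exc.args[0]!r}") from exc
    for pos, dm in applied_mods:
        if not (1 <= pos <= len(peptide)):
            raise InputError(f"modification position {pos} outside peptide")
        masses[pos - 1] += dm
    return masses


def _fragment_arrays(
    peptide: str,
    applied_mods=(),
    shift_mass: float = 0.0,
    shift_pos: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    length = len(peptide)
    if shift_pos is not None and not (1 <= shift_pos <= length):
        raise InputError(f"shift position {shift_pos} outside peptide")
    masses = _residue_masses(peptide, applied_mods)
    if shift_pos is not None:
        masses = masses.copy()
        masses[shift_pos - 1] += shift_mass
    prefix = np.cumsum(masses)
    b = prefix[:-1] + PROTON_MASS
    suffix = np.cumsum(masses[::-1])
    y = suffix[:-1] + WATER_MASS + PROTON_MASS
    return b, y


def _greedy_match(
    frag_mz: np.ndarray,
    spectrum: Spectrum,
    used: np.ndarray,
    config: ShepherdConfig,
) -> tuple[int, float]:
    """Greedy nearest-peak matching for one ion series: fragments in
    ascending m/z order each claim the nearest unused spectrum peak within
    tolerance (ties to the lower-m/z peak).  Returns (count, intensity)."""
    mz = spectrum.mz
    inten = spectrum.intensity
    count = 0
    total = 0.0
    for f in np.sort(frag_mz):
        tol = config.fragment_tol_da(f)
        lo = int(np.searchsorted(mz, f - tol, side="left"))
        hi = int(np.searchsorted(mz, f + tol, side="right"))
        best = -1
        best_key = (math.inf, math.inf)
        for j in range(lo, hi):
            if used[j]:
                continue
            key = (abs(mz[j] - f), mz[j])
            if key < best_key:
                best, best_key = j, key
        if best >= 0:
            used[best] = True
            count += 1
            total += float(inten[best])
    return count, total


def hyperscore(
    spectrum: Spectrum,
    fragments: list[tuple[str, float]],
    config: ShepherdConfig | None = None,
) -> ScoredMatch:
    """Score a fragment list against a spectrum.

    Each spectrum peak is usable once (b ions are matched first, then y, in
    ascending m/z within each series).
    """
    config = config or ShepherdConfig()
    b_mz = np.array([m for lbl, m in fragments if lbl.startswith("b")])
    y_mz = np.array([m for lbl, m in fragments if lbl.startswith("y")])
    if len(spectrum) == 0:
        return ScoredMatch(0, 0, 0.0, 0.0)
    used = np.zeros(len(spectrum), dtype=bool)
    nb, sib = _greedy_match(b_mz, spectrum, used, config)
    ny, siy = _greedy_match(y_mz, spectrum, used, config)
    return ScoredMatch(nb, ny, sib, siy)


def _score_arrays(
    b: np.ndarray, y: np.ndarray, spectrum: Spectrum, config: ShepherdConfig
) -> ScoredMatch:
    if len(spectrum) == 0:
        return ScoredMatch(0, 0, 0.0, 0.0)
    used = np.zeros(len(spectrum), dtype=bool)
    nb, sib = _greedy_match(b, spectrum, used, config)
    ny, siy = _greedy_match(y, spectrum, used, config)
    return ScoredMatch(nb, ny, sib, siy)


def localize_psm(
    psm: PSMRecord,
    spectrum: Spectrum,
    shift_mass: float,
    config: ShepherdConfig,
) -> LocalizationResult:
    """Place ``shift_mass`` at every position, rescore, and localize.

    Localizable iff the best placement matches strictly more fragment ions
    than the unshifted baseline.  Weight is split uniformly over positions
    tied at the best score; the N-terminal flag is set when position 1 is in
    that set.
    """
    length = len(psm.peptide)
    weights = np.zeros(length)
    baseline = _score_arrays(
        *_fragment_arrays(psm.peptide, psm.applied_mods), spectrum, config
    )
    scores = np.empty(length)
    matched = np.empty(length, dtype=int)
    for pos in range(1, length + 1):
        sm = _score_arrays(
            *_fragment_arrays(psm.peptide, psm.applied_mods, shift_mass, pos),
            spectrum,
            config,
        )
        scores[pos - 1] = sm.score
        matched[pos - 1] = sm.matched

    localizable = bool(matched.max() > baseline.matched) if length else False
    best_score = float(scores.max()) if length else 0.0
    nterm = False
    if localizable:
        top = np.flatnonzero(scores == scores.max())
        weights[top] = 1.0 / top.size
        nterm = bool(0 in top)
    return LocalizationResult(psm, localizable, weights, best_score, nterm)


def localize_peakset(
    peakset: PeakSet,
    experiment_set: ExperimentSet,
    config: ShepherdConfig,
    skip_zero_shift: bool = True,
) -> dict[int, list[LocalizationResult]]:
    """Localize every assigned PSM with a resolvable spectrum, per peak.

    Peaks whose reported mass is below the unmodified threshold carry no
    shift to place; they are skipped by default.
    """
    out: dict[int, list[LocalizationResult]] = {}
    for k, peak in enumerate(peakset.peaks):
        if skip_zero_shift and abs(peak.reported_mass) < config.unmodified_threshold:
            out[k] = []
            continue
        results: list[LocalizationResult] = []
        for psm in peak.assigned_psms():
            spectrum = experiment_set.get_spectrum(psm)
            if spectrum is None:
                continue
            results.append(localize_psm(psm, spectrum, peak.reported_mass, config))
        out[k] = results
    return out


def _residue_counter(results: list[LocalizationResult], unique_peptides: bool) -> Counter:
    counts: Counter = Counter()
    seen: set[str] = set()
    for r in results:
        if not r.localizable:
            continue
        if unique_peptides:
            if r.psm.peptide in seen:
                continue
            seen.add(r.psm.peptide)
        counts.update(r.psm.peptide)
    return counts


def aggregate_localization_profiles(
    localizations: dict[int, list[LocalizationResult]],
    experiment_set: ExperimentSet,
    background_scope: str = "dataset_psm",
) -> list[LocalizationProfile]:
    """Build per-peak profiles for each experiment and pooled (``"(all)"``).

    ``background_scope`` selects the residue background: every localizable
    PSM in the entire data set (default, ``dataset_psm``), unique peptides
    thereof (``dataset_peptide``), or the peak's own localizable PSMs /
    unique peptides (``bin_psm`` / ``bin_peptide``).  Enrichment for residue
    ``a`` is (localized weight fraction on ``a``) / (background fraction of
    ``a``); residues absent from the background are omitted.
    """
    unique = background_scope.endswith("_peptide")
    dataset_bg: Counter | None = None
    if background_scope.startswith("dataset"):
        all_results = [r for rs in localizations.values() for r in rs]
        dataset_bg = _residue_counter(all_results, unique)

    profiles: list[LocalizationProfile] = []
    labels = list(experiment_set.experiments) + ["(all)"]
    for k, results in localizations.items():
        for label in labels:
            subset = (
                results
                if label == "(all)"
                else [r for r in results if r.psm.experiment == label]
            )
            loc = [r for r in subset if r.localizable]
            residue_counts: dict[str, float] = {}
            for r in loc:
                for pos, w in enumerate(r.site_weights):
                    if w > 0:
                        aa = r.psm.peptide[pos]
                        residue_counts[aa] = residue_counts.get(aa, 0.0) + float(w)
            bg = dataset_bg if dataset_bg is not None else _residue_counter(subset, unique)
            profile = LocalizationProfile(
                peak_index=k,
                experiment=label,
                n_attempted=len(subset),
                n_localizable=len(loc),
                nterm_rate=(
                    sum(r.nterm_flag for r in loc) / len(loc) if loc else 0.0
                ),
                residue_counts=residue_counts,
                background_counts=dict(bg),
            )
            total_rc = sum(residue_counts.values())
            total_bg = sum(bg.values())
            if total_rc > 0 and total_bg > 0:
                for aa, bg_count in bg.items():
                    if bg_count <= 0:
                        continue
                    rc = residue_counts.get(aa, 0.0)
                    profile.enrichment[aa] = (rc / total_rc) / (bg_count / total_bg)
            profiles.append(profile)
    return profiles
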