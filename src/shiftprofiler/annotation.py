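"""Mass-shift annotation: staged decomposition against a modification table.

Each peak mass is matched to a table of known shifts (a Unimod-style list
plus generated single-residue insertions/deletions, isotopic-error entries
and user-defined shifts), decomposing into at most two components:

* stage 1 ("single"): best single entry within the annotation tolerance;
* stage 2 ("user_combo"): best pair of a user-defined shift with any entry;
* stage 3 ("pair_combo"): best pair drawn from the pool of components used
  in earlier single annotations of this run plus earlier unannotated peak
  masses (peaks are processed in descending SNR order, so abundant shifts
  seed the pool for rarer composite ones);
* otherwise "unannotated", and the peak's own mass joins the pool.

With ``prioritize_user_mods`` set, any candidate containing a user entry
outranks any that does not; remaining ties break by smaller absolute
residual, then fewer components.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from .constants import RESIDUE_MASS
from .errors import RowParseError
from .model import ShepherdConfig
from .peaks import Peak, PeakSet

SOURCES = ("unimod", "residue_insertion", "residue_deletion", "isotope", "user", "peak")


@dataclass(frozen=True)
class ModificationEntry:
    name: str
    delta_mass: float
    source: str = "unimod"


# A compact roster of common Unimod shifts sufficient for open-search QC
# profiling: oxidation states, alkylation chemistry, labeling reagents,
# adducts, and frequent artifacts.  Exceptionally rare protocol labels
# (O18/N15 metabolic labeling) are deliberately excluded because they
# confound annotation of common shifts.
_DEFAULT_UNIMOD: list[tuple[str, float]] = [
    ("None", 0.0),
    ("Oxidation", 15.994915),
    ("Dioxidation", 31.989829),
    ("Trioxidation", 47.984744),
    ("Carbamidomethyl", 57.021464),
    ("Methyl", 14.015650),
    ("Dimethyl", 28.031300),
    ("Trimethyl", 42.046950),
    ("Formyl", 27.994915),
    ("Acetyl", 42.010565),
    ("Phospho", 79.966331),
    ("Deamidation", 0.984016),
    ("Amidation", -0.984016),
    ("Dehydration", -18.010565),
    ("Ammonia loss", -17.026549),
    ("Carbamyl", 43.005814),
    ("TMT10plex", 229.162932),
    ("HexNAc", 203.079373),
    ("Hex", 162.052824),
    ("Cation:Na", 21.981943),
    ("Cation:K", 37.955882),
    ("Methylol", 30.010565),
    ("Formaldehyde adduct", 12.000000),
    ("Cysteinylation", 119.004099),
    ("Glutathione", 305.068156),
    ("Succinic anhydride", 100.016044),
    ("Pyridylethyl", 105.057849),
    ("Propionamide", 71.037114),
    ("GG (ubiquitin remnant)", 114.042927),
    ("Carboxymethyl", 58.005479),
]


@dataclass
class PeakAnnotation:
    """Up to two modification components explaining a peak mass."""

    peak_index: int
    peak_mass: float
    components: tuple[ModificationEntry, ...]
    residual_error: float
    stage: str  # single | user_combo | pair_combo | unannotated

    @property
    def annotation(self) -> str:
        if not self.components:
            return "Unannotated"
        return " + ".join(c.name for c in self.components)


def build_entries(
    base: list[tuple[str, float]] | None = None,
    user_shifts: list[tuple[str, float]] = (),
    variable_mods: list[tuple[str, float]] = (),
    include_insertions: bool = True,
    include_deletions: bool = True,
    isotope_spacing: float = 1.00235,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> list[ModificationEntry]:
    """Assemble the annotation entry table.

    ``variable_mods`` are modifications that were searched as variable mods;
    for each, a signed counterpart (negative mass) is added so composite
    shifts caused by a misattributed variable modification (e.g. a Met
    oxidation assigned by the search engine but actually part of a larger
    shift) can enter two-component combinations.
    """
    entries: dict[tuple[str, str], ModificationEntry] = {}

    def add(name: str, mass: float, source: str) -> None:
        if name in exclude:
            return
        key = (name, source)
        if key not in entries:
            entries[key] = ModificationEntry(name, float(mass), source)

    for name, mass in (base if base is not None else _DEFAULT_UNIMOD):
        add(name, mass, "unimod")
    if include_insertions:
        for aa in sorted(RESIDUE_MASS):
            add(f"Addition of {aa}", RESIDUE_MASS[aa], "residue_insertion")
    if include_deletions:
        for aa in sorted(RESIDUE_MASS):
            add(f"Deletion of {aa}", -RESIDUE_MASS[aa], "residue_deletion")
    for k in (1, 2):
        add(f"+{k} isotopic error", k * isotope_spacing, "isotope")
        add(f"-{k} isotopic error", -k * isotope_spacing, "isotope")
    for name, mass in variable_mods:
        add(f"{name} (misattributed)", -mass, "unimod")
    for name, mass in user_shifts:
        add(name, mass, "user")
    return list(entries.values())


def default_entries(**kwargs) -> list[ModificationEntry]:
    """The built-in entry table (see :func:`build_entries` for options)."""
    return build_entries(**kwargs)


def load_modification_table(
    path: str | os.PathLike,
    user_shifts: list[tuple[str, float]] = (),
    **kwargs,
) -> list[ModificationEntry]:
    """Read a TSV modification table (name, monoisotopic mass[, source]) and
    extend it with generated insertion/deletion/isotope/user entries."""
    base: list[tuple[str, float]] = []
    extra: list[ModificationEntry] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if i == 0 and parts[0].lower() in ("name", "modification"):
                continue
            if len(parts) < 2:
                raise RowParseError(i, f"expected at least 2 columns, got {len(parts)}")
            try:
                mass = float(parts[1])
            except ValueError as exc:
                raise RowParseError(i, f"unparseable mass '{parts[1]}'") from exc
            source = parts[2] if len(parts) > 2 else "unimod"
            if source == "unimod":
                base.append((parts[0], mass))
            else:
                extra.append(ModificationEntry(parts[0], mass, source))
    out = build_entries(base=base, user_shifts=user_shifts, **kwargs)
    out.extend(extra)
    return out


def _rank_key(cand: tuple[tuple[ModificationEntry, ...], float], prioritize: bool):
    comps, residual = cand
    has_user = any(c.source == "user" for c in comps)
    return (
        0 if (prioritize and has_user) else 1,
        abs(residual),
        len(comps),
        tuple(c.name for c in comps),
    )


def _best(cands, prioritize):
    return min(cands, key=lambda c: _rank_key(c, prioritize)) if cands else None


def annotate_peaks(
    peakset: PeakSet | list[Peak],
    entries: list[ModificationEntry],
    config: ShepherdConfig,
) -> list[PeakAnnotation]:
    """Annotate peaks in order (descending SNR) by the staged procedure."""
    peaks = list(peakset.peaks) if isinstance(peakset, PeakSet) else list(peakset)
    tol = config.annotation_tol
    prioritize = config.prioritize_user_mods
    user_entries = [e for e in entries if e.source == "user"]

    used_singles: list[ModificationEntry] = []
    used_names: set[tuple[str, str]] = set()
    pool: list[ModificationEntry] = []  # stage-3 component pool, in SNR order
    out: list[PeakAnnotation] = []

    for k, peak in enumerate(peaks):
        mass = peak.reported_mass if peak.reported_mass == peak.reported_mass else peak.apex_mass
        # Stage 1: single entry.
        cands = [
            ((e,), mass - e.delta_mass)
            for e in entries
            if abs(mass - e.delta_mass) <= tol
        ]
        best = _best(cands, prioritize)
        if best is not None:
            comps, res = best
            out.append(PeakAnnotation(k, mass, comps, res, "single"))
            e = comps[0]
            if (e.name, e.source) not in used_names:
                used_names.add((e.name, e.source))
                used_singles.append(e)
            continue
        # Stage 2: user shift + any entry.
        cands = [
            ((u, e), mass - (u.delta_mass + e.delta_mass))
            for u in user_entries
            for e in entries
            if abs(mass - (u.delta_mass + e.delta_mass)) <= tol
        ]
        best = _best(cands, prioritize)
        if best is not None:
            comps, res = best
            out.append(PeakAnnotation(k, mass, comps, res, "user_combo"))
            continue
        # Stage 3: pairs from previously used singles + unannotated masses.
        stage3_pool = used_singles + pool
        cands = []
        for i, a in enumerate(stage3_pool):
            for b in stage3_pool[i:]:
                res = mass - (a.delta_mass + b.delta_mass)
                if abs(res) <= tol:
                    cands.append(((a, b), res))
        best = _best(cands, prioritize)
        if best is not None:
            comps, res = best
            out.append(PeakAnnotation(k, mass, comps, res, "pair_combo"))
            continue
        # Unannotated: the mass itself becomes a potential component.
        out.append(PeakAnnotation(k, mass, (), float("nan"), "unannotated"))
        pool.append(ModificationEntry(f"unannotated {mass:.4f}", mass, "peak"))
    return out
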