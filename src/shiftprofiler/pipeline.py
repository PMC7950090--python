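"""End-to-end orchestration of the profiling stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotation import ModificationEntry, PeakAnnotation, annotate_peaks, default_entries
from .histogram import MassShiftHistogram, build_histogram, smooth_histogram
from .localization import (
    LocalizationProfile,
    LocalizationResult,
    aggregate_localization_profiles,
    localize_peakset,
)
from .model import ExperimentSet, ShepherdConfig
from .peaks import PeakSet, assign_psms_to_peaks, pick_peaks, quantify_peaks
from .similarity import (
    ComparisonProfile,
    aggregate_comparison_profiles,
    build_unmodified_index,
    compare_peakset,
)


@dataclass
class PipelineResult:
    config: ShepherdConfig
    histogram: MassShiftHistogram
    smoothed: MassShiftHistogram
    peakset: PeakSet
    quantification: pd.DataFrame
    annotations: list[PeakAnnotation]
    localizations: dict[int, list[LocalizationResult]] = field(default_factory=dict)
    localization_profiles: list[LocalizationProfile] = field(default_factory=list)
    comparison_profiles: list[ComparisonProfile] = field(default_factory=list)


def run_pipeline(
    experiment_set: ExperimentSet,
    config: ShepherdConfig | None = None,
    entries: list[ModificationEntry] | None = None,
) -> PipelineResult:
    """Histogram -> peaks -> quantify -> annotate -> localize -> compare.

    Localization and similarity run only for PSMs whose spectra resolve in
    the experiment set's spectrum store; with an empty store the result
    carries histogram/peak/annotation stages only.
    """
    config = config or ShepherdConfig()
    entries = entries if entries is not None else default_entries()

    psms = experiment_set.all_psms()
    hist = build_histogram(psms, config)
    smoothed = smooth_histogram(
        hist, config.smoothing_bins, config.smoothing_mass_fraction
    )
    peakset = pick_peaks(smoothed, config)
    assign_psms_to_peaks(peakset, psms)
    quantification = quantify_peaks(peakset, experiment_set)
    annotations = annotate_peaks(peakset, entries, config)

    result = PipelineResult(
        config=config,
        histogram=hist,
        smoothed=smoothed,
        peakset=peakset,
        quantification=quantification,
        annotations=annotations,
    )
    if experiment_set.spectra:
        result.localizations = localize_peakset(peakset, experiment_set, config)
        result.localization_profiles = aggregate_localization_profiles(
            result.localizations, experiment_set, config.background_scope
        )
        index = build_unmodified_index(psms, config)
        comparisons = compare_peakset(peakset, experiment_set, config, index)
        result.comparison_profiles = aggregate_comparison_profiles(
            comparisons, peakset, experiment_set
        )
    return result
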