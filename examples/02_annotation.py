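"""Decompose composite mass shifts into modification components.

Two classic open-search puzzles: a -9.0368 Da shift in an underalkylated
sample (failed carbamidomethylation of Cys plus triple oxidation to cysteic
acid) and a +213.1680 Da shift in TMT-labeled data (an extra TMT tag on a
peptide whose reported Met oxidation belongs to the composite shift
instead).  Both need two components; neither matches a single table entry.
"""

from shiftprofiler import ShepherdConfig, annotate_peaks, default_entries
from shiftprofiler.peaks import Peak


def peak(mass):
    return Peak(0, mass, 1.0, 1.0, 1.0, mass - 0.005, mass + 0.005, reported_mass=mass)


config = ShepherdConfig(prioritize_user_mods=True)

# Underalkylation: the user declares the failed-alkylation shift.
entries = default_entries(user_shifts=[("failed alkylation", -57.0215)])
[ann] = annotate_peaks([peak(-9.0368)], entries, config)
print(f"-9.0368 Da  -> {ann.annotation}  (stage {ann.stage}, "
      f"residual {ann.residual_error:+.5f} Da)")

# TMT overlabeling combined with a misattributed variable modification.
entries = default_entries(
    user_shifts=[("TMT", 229.162932)],
    variable_mods=[("Oxidation", 15.994915)],
)
[ann] = annotate_peaks([peak(213.1680)], entries, config)
print(f"+213.1680 Da -> {ann.annotation}  (stage {ann.stage}, "
      f"residual {ann.residual_error:+.5f} Da)")

# Each line names the <= 2 components whose masses sum to the peak mass
# within the 0.01 Da annotation tolerance; the residual is the leftover.
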