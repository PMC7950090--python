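"""Localize mass shifts onto residues and separate in-source losses from
real modifications by retention-time shift.

Implants two populations: a water loss (-18.0106 Da) with zero RT offset
(an in-source loss happens after elution, so modified and unmodified forms
co-elute) and a pyro-Glu-like ammonia loss (-17.0265 Da on Gln) eluting
450 s later.  Localization rescoring places each shift on its residue;
the per-peak mean RT shift separates the two mechanisms.
"""

from shiftprofiler import ShepherdConfig, run_pipeline
from shiftprofiler.fixtures import FixtureSpec, ImplantedShift, generate_experiment_set

spec = FixtureSpec(
    n_experiments=1,
    n_psms_per_experiment=800,
    n_peptides_per_experiment=80,
    shifts=(
        ImplantedShift(-18.0106, "E", 0.12, 0.0),      # in-source loss
        ImplantedShift(-17.0265, "Q", 0.12, 450.0),    # pre-elution modification
    ),
    rng_seed=23,
)
es, _ = generate_experiment_set(spec)
result = run_pipeline(es, ShepherdConfig())

loc = {p.peak_index: p for p in result.localization_profiles if p.experiment == "(all)"}
cmp = {p.peak_index: p for p in result.comparison_profiles if p.experiment == "(all)"}

print(f"{'mass':>10} {'top residue':>12} {'loc. frac':>9} {'dRT (s)':>8} {'verdict'}")
for k, peak in enumerate(result.peakset):
    if abs(peak.reported_mass) < 0.01 or k not in cmp or cmp[k].n_compared == 0:
        continue
    top = loc[k].top_residues(1)
    top_txt = f"{top[0][0]} ({top[0][1]:.1f})" if top else "-"
    drt = cmp[k].mean_delta_rt
    verdict = "in-source loss" if abs(drt) < 30 else "pre-elution modification"
    print(f"{peak.reported_mass:>10.4f} {top_txt:>12} "
          f"{loc[k].localized_fraction:>9.2f} {drt:>8.0f} {verdict}")
# The -18.0106 row shows dRT ~ 0 (in-source), the -17.0265 row ~ +450 s with
# Gln as the top-enriched residue; enrichment is the residue's localized
# fraction divided by its background frequency in localizable peptides.
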