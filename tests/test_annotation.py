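import numpy as np
import pytest

from shiftprofiler import (
    ModificationEntry,
    ShepherdConfig,
    annotate_peaks,
    build_entries,
    default_entries,
    load_modification_table,
)
from shiftprofiler.peaks import Peak


def _peak(mass, snr=1.0):
    return Peak(
        apex_index=0,
        apex_mass=mass,
        apex_height=1.0,
        prominence=1.0,
        snr=snr,
        left_bound=mass - 0.005,
        right_bound=mass + 0.005,
        reported_mass=mass,
    )


class TestEntryTable:
    def test_user_shift_present(self):
        entries = build_entries(user_shifts=[("failed alkylation", -57.0215)])
        hit = [e for e in entries if e.name == "failed alkylation"]
        assert len(hit) == 1 and hit[0].source == "user"
        assert hit[0].delta_mass == pytest.approx(-57.0215)

    def test_glycine_deletion_mass(self):
        entries = build_entries()
        gly = [e for e in entries if e.name == "Deletion of G"][0]
        assert gly.delta_mass == pytest.approx(-57.02146, abs=1e-5)
        assert gly.source == "residue_deletion"

    def test_isotope_entries(self):
        masses = {
            e.name: e.delta_mass for e in build_entries() if e.source == "isotope"
        }
        for k in (1, 2):
            assert masses[f"+{k} isotopic error"] == pytest.approx(k * 1.00235)
            assert masses[f"-{k} isotopic error"] == pytest.approx(-k * 1.00235)

    def test_exclusion_list_applied(self):
        entries = build_entries(exclude={"Glutathione"})
        assert not any(e.name == "Glutathione" for e in entries)

    def test_table_file_loader(self, tmp_path):
        p = tmp_path / "mods.tsv"
        p.write_text("name\tmass\nMyMod\t123.4567\n")
        entries = load_modification_table(p, user_shifts=[("u1", -5.0)])
        assert any(e.name == "MyMod" and e.source == "unimod" for e in entries)
        assert any(e.name == "u1" and e.source == "user" for e in entries)


class TestStagedAnnotation:
    def test_failed_alkylation_decomposition(self):
        """-9.0368 Da = failed alkylation (-57.0215) + trioxidation (+47.9847)."""
        cfg = ShepherdConfig(prioritize_user_mods=True)
        entries = default_entries(user_shifts=[("failed alkylation", -57.0215)])
        [ann] = annotate_peaks([_peak(-9.0368)], entries, cfg)
        names = {c.name for c in ann.components}
        assert names == {"failed alkylation", "Trioxidation"}
        assert ann.stage == "user_combo"
        assert abs(ann.residual_error) <= 1e-4

    def test_zero_shift_is_none_single(self):
        cfg = ShepherdConfig()
        [ann] = annotate_peaks([_peak(0.0)], default_entries(), cfg)
        assert ann.annotation == "None"
        assert ann.stage == "single"

    def test_tmt_overlabeling_minus_misattributed_oxidation(self):
        """+213.1680 Da = TMT (+229.1629) with a -15.9949 counterpart."""
        cfg = ShepherdConfig(prioritize_user_mods=True)
        entries = default_entries(
            user_shifts=[("TMT", 229.162932)],
            variable_mods=[("Oxidation", 15.994915)],
        )
        [ann] = annotate_peaks([_peak(213.1680)], entries, cfg)
        names = {c.name for c in ann.components}
        assert names == {"TMT", "Oxidation (misattributed)"}
        assert abs(ann.residual_error) <= 1e-4

    def test_stage3_uses_previously_seen_components(self):
        # 15.9949 and 79.9663 annotate singly; 95.9612 has no single/user match
        # and must decompose from the already-used pool.
        cfg = ShepherdConfig()
        entries = [
            ModificationEntry("Oxidation", 15.994915),
            ModificationEntry("Phospho", 79.966331),
        ]
        peaks = [_peak(15.9949, snr=3.0), _peak(79.9663, snr=2.0), _peak(95.9612, snr=1.0)]
        anns = annotate_peaks(peaks, entries, cfg)
        assert [a.stage for a in anns] == ["single", "single", "pair_combo"]
        assert {c.name for c in anns[2].components} == {"Oxidation", "Phospho"}

    def test_unannotated_mass_joins_pool(self):
        cfg = ShepherdConfig()
        entries = [ModificationEntry("Oxidation", 15.994915)]
        peaks = [
            _peak(15.9949, snr=3.0),   # single: puts Oxidation in the pool
            _peak(123.4000, snr=2.0),  # unannotated: its mass joins the pool
            _peak(139.3949, snr=1.0),  # = 123.4000 + 15.9949
        ]
        anns = annotate_peaks(peaks, entries, cfg)
        assert [a.stage for a in anns] == ["single", "unannotated", "pair_combo"]
        masses = sorted(c.delta_mass for c in anns[2].components)
        assert masses == pytest.approx([15.994915, 123.4000], abs=1e-4)

    def test_residual_invariant_and_stage_monotonicity(self):
        cfg = ShepherdConfig()
        entries = default_entries(user_shifts=[("u", -57.0215)])
        rng = np.random.default_rng(5)
        chosen = rng.choice(len(entries), size=40)
        peaks = [
            _peak(entries[i].delta_mass + rng.uniform(-0.005, 0.005), snr=40 - k)
            for k, i in enumerate(chosen)
        ]
        anns = annotate_peaks(peaks, entries, cfg)
        for ann in anns:
            # every constructed peak is within tolerance of a single entry
            assert ann.stage == "single"
            assert abs(ann.residual_error) <= cfg.annotation_tol

    def test_enlarging_table_never_unannotates(self):
        cfg = ShepherdConfig()
        small = [ModificationEntry("Oxidation", 15.994915)]
        large = small + [ModificationEntry("Phospho", 79.966331)]
        peaks = [_peak(15.9949, snr=2.0), _peak(79.9663, snr=1.0)]
        small_ann = annotate_peaks(peaks, small, cfg)
        large_ann = annotate_peaks(peaks, large, cfg)
        for s, l in zip(small_ann, large_ann):
            if s.stage != "unannotated":
                assert l.stage != "unannotated"

    def test_known_sums_fixture_always_mass_consistent(self):
        """Peaks built as sums of two table entries always decompose to a
        mass-consistent pair (component identity may be degenerate)."""
        cfg = ShepherdConfig()
        entries = default_entries()
        rng = np.random.default_rng(11)
        idx = rng.integers(0, len(entries), size=(30, 2))
        sums = [entries[i].delta_mass + entries[j].delta_mass for i, j in idx]
        # seed the pool: annotate the singles first (higher snr), then sums
        singles = [
            _peak(entries[i].delta_mass, snr=1000 - k)
            for k, i in enumerate(np.unique(idx))
        ]
        pair_peaks = [_peak(s, snr=10 - 1e-3 * k) for k, s in enumerate(sums)]
        anns = annotate_peaks(singles + pair_peaks, entries, cfg)
        for ann in anns:
            assert ann.stage != "unannotated"
            total = sum(c.delta_mass for c in ann.components)
            assert abs(ann.peak_mass - total) <= cfg.annotation_tol
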