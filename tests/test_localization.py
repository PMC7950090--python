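import math

import numpy as np
import pytest

from oracles import oracle_hyperscore

from shiftprofiler import (
    ShepherdConfig,
    Spectrum,
    aggregate_localization_profiles,
    hyperscore,
    localize_psm,
    theoretical_fragments,
)
from shiftprofiler.fixtures import generate_peptide_spectrum
from shiftprofiler.localization import LocalizationResult
from shiftprofiler.model import ExperimentSet, PSMRecord


def _psm(peptide, exp="A", i=0, charge=2):
    return PSMRecord(f"{exp}.{i}", exp, peptide, 0.0, 100.0, charge)


class TestTheoreticalFragments:
    def test_gg_reference_values(self):
        frags = dict(theoretical_fragments("GG"))
        assert frags["b1"] == pytest.approx(58.0287, abs=1e-4)
        assert frags["y1"] == pytest.approx(76.0393, abs=1e-4)

    @pytest.mark.parametrize("peptide", ["GG", "PEPTIDEK", "ACDEFGHIK"])
    def test_ion_count(self, peptide):
        assert len(theoretical_fragments(peptide)) == 2 * (len(peptide) - 1)

    def test_shift_at_position_one(self):
        length = 5
        base = dict(theoretical_fragments("AAAAK"))
        shifted = dict(theoretical_fragments("AAAAK", shift_mass=10.0, shift_pos=1))
        for i in range(1, length):
            assert shifted[f"b{i}"] == pytest.approx(base[f"b{i}"] + 10.0)
        for j in range(1, length - 1):
            assert shifted[f"y{j}"] == pytest.approx(base[f"y{j}"])

    def test_applied_mods_always_included(self):
        base = dict(theoretical_fragments("AAAAK"))
        mod = dict(theoretical_fragments("AAAAK", applied_mods=[(2, 57.0215)]))
        assert mod["b1"] == pytest.approx(base["b1"])
        assert mod["b2"] == pytest.approx(base["b2"] + 57.0215)


class TestHyperscore:
    def test_no_matches_scores_zero(self):
        sp = Spectrum("s", np.array([5000.0]), np.array([10.0]))
        sm = hyperscore(sp, theoretical_fragments("PEPTIDEK"))
        assert sm.nb == sm.ny == 0
        assert sm.score == 0.0

    def test_closed_form(self):
        from shiftprofiler.localization import ScoredMatch

        sm = ScoredMatch(nb=2, ny=2, sum_ib=10.0, sum_iy=10.0)
        assert sm.score == pytest.approx(math.log10(400), rel=1e-12)

    def test_empty_spectrum(self):
        sm = hyperscore(Spectrum("s", np.array([]), np.array([])), theoretical_fragments("AAK"))
        assert sm.score == 0.0 and sm.matched == 0

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_matcher(self, seed):
        rng = np.random.default_rng(seed)
        cfg = ShepherdConfig(fragment_tol=0.3, fragment_tol_unit="da")
        n = int(rng.integers(1, 21))
        sp = Spectrum("s", np.sort(rng.uniform(100, 900, n)), rng.uniform(1, 100, n))
        frags = [
            (("b" if rng.random() < 0.5 else "y") + str(i), float(m))
            for i, m in enumerate(rng.uniform(100, 900, int(rng.integers(1, 15))))
        ]
        got = hyperscore(sp, frags, cfg)
        nb, ny, sib, siy, score = oracle_hyperscore(sp, frags, cfg)
        assert (got.nb, got.ny) == (nb, ny)
        assert got.sum_ib == pytest.approx(sib)
        assert got.sum_iy == pytest.approx(siy)
        assert got.score == pytest.approx(score, rel=1e-9)


class TestLocalizePsm:
    def test_recovers_true_site_without_noise(self):
        rng = np.random.default_rng(3)
        pep = "AAASAAKK"
        sp = generate_peptide_spectrum(pep, 79.9663, 4, 0, rng)
        res = localize_psm(_psm(pep), sp, 79.9663, ShepherdConfig())
        assert res.localizable
        np.testing.assert_allclose(res.site_weights[3], 1.0)

    def test_tied_sites_share_weight(self):
        # shift on residue 1 of "GG": b1 shifted, y1 not; placing at position
        # 2 instead shifts y1 only -> by symmetry of matching counts the two
        # placements tie when both shifted ions are present.
        rng = np.random.default_rng(4)
        pep = "AGGK"
        sp = generate_peptide_spectrum(pep, 100.0, 2, 0, rng)
        res = localize_psm(_psm(pep), sp, 100.0, ShepherdConfig())
        tied = np.flatnonzero(res.site_weights > 0)
        if tied.size > 1:
            np.testing.assert_allclose(
                res.site_weights[tied], 1.0 / tied.size
            )
        assert res.site_weights.sum() in (0.0, pytest.approx(1.0))

    def test_unlocalized_when_no_shifted_ions(self):
        rng = np.random.default_rng(5)
        pep = "AAASAAKK"
        sp = generate_peptide_spectrum(pep, 0.0, None, 0, rng)  # unshifted ladder
        res = localize_psm(_psm(pep), sp, 79.9663, ShepherdConfig())
        assert not res.localizable
        assert res.site_weights.sum() == 0.0

    def test_weight_conservation_on_fixture(self, small_result):
        for results in small_result.localizations.values():
            for r in results:
                assert r.site_weights.sum() == pytest.approx(1.0) or (
                    not r.localizable and r.site_weights.sum() == 0.0
                )


class TestProfiles:
    def _toy_profiles(self, scope):
        # Two localizable PSMs, shift always on S.
        es = ExperimentSet(experiments={"A": []})
        results = []
        for i, pep in enumerate(["ASAK", "SSAK"]):
            psm = _psm(pep, i=i)
            es.experiments["A"].append(psm)
            w = np.zeros(len(pep))
            w[pep.index("S")] = 1.0
            results.append(LocalizationResult(psm, True, w, 1.0, pep[0] == "S"))
        return aggregate_localization_profiles({0: results}, es, scope)

    @pytest.mark.parametrize(
        "scope", ["dataset_psm", "dataset_peptide", "bin_psm", "bin_peptide"]
    )
    def test_background_weighted_mean_enrichment_is_one(self, scope):
        for p in self._toy_profiles(scope):
            if not p.enrichment:
                continue
            total_bg = sum(p.background_counts.values())
            mean = sum(
                (bg / total_bg) * p.enrichment[aa]
                for aa, bg in p.background_counts.items()
                if aa in p.enrichment
            )
            assert mean == pytest.approx(1.0, abs=1e-12)

    def test_enrichment_definition(self):
        # localized fraction 0.5 on S against background fraction 0.25 -> 2.0
        es = ExperimentSet(experiments={"A": []})
        results = []
        for i, (pep, site) in enumerate([("SAAA", 1), ("ASAA", 3)]):
            # second weight on a non-S residue to make S fraction 0.5
            psm = _psm(pep, i=i)
            es.experiments["A"].append(psm)
            w = np.zeros(4)
            w[site - 1] = 1.0
            results.append(LocalizationResult(psm, True, w, 1.0, site == 1))
        [profile] = [
            p
            for p in aggregate_localization_profiles({0: results}, es, "dataset_psm")
            if p.experiment == "(all)"
        ]
        # residue counts: S=1, A=1; background: S=2, A=6
        assert profile.enrichment["S"] == pytest.approx((0.5) / (0.25))

    def test_designated_residue_top_enriched(self, full_result, full_fixture):
        spec, _, _ = full_fixture
        truth = {s.mass: s.residue for s in spec.shifts if s.residue}
        pooled = {
            p.peak_index: p
            for p in full_result.localization_profiles
            if p.experiment == "(all)" and p.enrichment
        }
        for k, peak in enumerate(full_result.peakset.peaks):
            match = [r for m, r in truth.items() if abs(m - peak.reported_mass) < 0.005]
            if not match or k not in pooled:
                continue
            top_aa = pooled[k].top_residues(1)[0][0]
            assert top_aa == match[0]

    def test_nterm_rate_range(self, full_result):
        for p in full_result.localization_profiles:
            assert 0.0 <= p.nterm_rate <= 1.0
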