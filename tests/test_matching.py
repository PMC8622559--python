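"""Spectral similarity, subformula enumeration, HRF, and ranking."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcmscreen.matching import (
    MatchConfig,
    annotate_fragments,
    enumerate_subformulas,
    hrf_score,
    pair_peaks,
    rank_candidates,
    si_score,
    total_score,
)
from fcmscreen.msdata import (
    ELECTRON_MASS,
    ISOTOPE_MASSES,
    ElementalFormula,
    Spectrum,
    monoisotopic_mass,
    parse_formula,
)


def cation_mz(text: str) -> float:
    return monoisotopic_mass(parse_formula(text), as_radical_cation=True)


# ---------------------------------------------------------------------------
# search-index similarity
# ---------------------------------------------------------------------------


class TestSiScore:
    def test_self_similarity_is_100(self):
        s = Spectrum([50.0, 100.0, 150.0], [10.0, 100.0, 30.0])
        assert si_score(s, s) == pytest.approx(100.0, abs=1e-9)

    def test_disjoint_spectra_score_zero(self):
        a = Spectrum([50.0, 100.0], [1.0, 1.0])
        b = Spectrum([60.0, 110.0], [1.0, 1.0])
        assert si_score(a, b) == 0.0

    def test_hand_computed_composite(self):
        """Two 3-peak spectra sharing two peaks, against an independent
        elementwise evaluation of the documented composite formula."""
        q = Spectrum([100.0, 150.0, 200.0], [1.0, 0.5, 0.8])
        lib = Spectrum([100.0, 150.0, 250.0], [1.0, 0.5, 0.3])
        wq = np.array([i**0.6 * m**3 for m, i in zip(q.mz, q.intensities)])
        wl = np.array([i**0.6 * m**3 for m, i in zip(lib.mz, lib.intensities)])
        dot = wq[0] * wl[0] + wq[1] * wl[1]  # only the two shared peaks pair
        f_dot = dot**2 / (np.sum(wq**2) * np.sum(wl**2))
        r = (0.5 / 1.0) * (1.0 / 0.5)  # consecutive paired-intensity ratio = 1
        f_ratio = min(r, 1.0 / r)
        expected = 100.0 * (3 * f_dot + 2 * f_ratio) / (3 + 2)
        assert si_score(q, lib) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("scale", [0.01, 3.0, 1e4])
    def test_invariant_under_uniform_intensity_scaling(self, scale):
        rng = np.random.default_rng(0)
        q = Spectrum(np.sort(rng.uniform(40, 500, 12)), rng.uniform(1, 100, 12))
        lib = Spectrum(q.mz + rng.uniform(-0.002, 0.002, 12), rng.uniform(1, 100, 12))
        scaled = Spectrum(q.mz, q.intensities * scale)
        assert si_score(scaled, lib) == pytest.approx(si_score(q, lib), rel=1e-9)

    def test_dot_term_matches_matchms_cosine(self):
        """matchms CosineGreedy with the same weighting is an independent
        oracle for the dot-product term (its score is the cosine, ours the
        squared cosine) on spectra with unambiguous pairing."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(1)
        mz = np.sort(rng.uniform(40, 500, 10))
        q = Spectrum(mz, rng.uniform(1, 100, 10))
        lib = Spectrum(mz, rng.uniform(1, 100, 10))
        wq, wl = q.intensities**0.6 * q.mz**3, lib.intensities**0.6 * lib.mz**3
        f_dot = (wq @ wl) ** 2 / ((wq @ wq) * (wl @ wl))
        ms_q = matchms.Spectrum(mz=q.mz, intensities=q.intensities, metadata_harmonization=False)
        ms_l = matchms.Spectrum(mz=lib.mz, intensities=lib.intensities, metadata_harmonization=False)
        res = CosineGreedy(tolerance=0.005, mz_power=3.0, intensity_power=0.6).pair(ms_q, ms_l)
        assert f_dot == pytest.approx(float(res["score"]) ** 2, rel=1e-6)

    def test_empty_spectrum_rejected(self):
        s = Spectrum([50.0], [1.0])
        with pytest.raises(Exception):
            si_score(s, Spectrum([50.0], [0.0]))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.data())
    def test_score_bounded_for_arbitrary_spectra(self, data):
        def spec(seed):
            rng = np.random.default_rng(seed)
            n = rng.integers(1, 15)
            return Spectrum(
                np.cumsum(rng.uniform(0.01, 50, n)) + 40, rng.uniform(0.1, 1000, n)
            )

        a = spec(data.draw(st.integers(0, 10_000)))
        b = spec(data.draw(st.integers(0, 10_000)))
        assert 0.0 <= si_score(a, b) <= 100.0 + 1e-9


class TestPairPeaks:
    def test_one_to_one_within_tolerance(self):
        q = Spectrum([100.000, 100.004, 200.0], [1, 1, 1])
        lib = Spectrum([100.002, 300.0], [1, 1])
        pairs = pair_peaks(q, lib, 0.005)
        assert len(pairs) == 1
        assert pairs[0][1] == 0


# ---------------------------------------------------------------------------
# subformula enumeration
# ---------------------------------------------------------------------------


def brute_force_subformulas(parent, target_mz, tol_ppm):
    """Exhaustive nested-loop oracle over every elementwise-bounded formula."""
    syms = sorted(parent.counts)
    hits = []
    for combo in itertools.product(*(range(parent.counts[s] + 1) for s in syms)):
        if not any(combo):
            continue
        mass = sum(ISOTOPE_MASSES[s] * k for s, k in zip(syms, combo)) - ELECTRON_MASS
        if abs(1e6 * (mass - target_mz) / target_mz) <= tol_ppm * (1 + 1e-12):
            hits.append({s: k for s, k in zip(syms, combo) if k})
    return hits


class TestEnumerateSubformulas:
    def test_parent_is_its_own_subformula(self):
        parent = parse_formula("C H4")
        hits = enumerate_subformulas(parent, cation_mz("C H4"), 2.0)
        assert [f.counts for f, _ in hits] == [{"C": 1, "H": 4}]

    def test_unreachable_target_is_empty(self):
        assert enumerate_subformulas(parse_formula("C H4"), 100.0, 2.0) == []

    def test_bht_contains_butyl_cation(self):
        hits = enumerate_subformulas(parse_formula("C15 H24 O"), cation_mz("C4 H9"), 2.0)
        assert {"C": 4, "H": 9} in [f.counts for f, _ in hits]

    def test_oversized_parent_rejected(self):
        with pytest.raises(ValueError, match="atoms"):
            enumerate_subformulas(parse_formula("C100 H102"), 100.0, 2.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_brute_force_oracle(self, seed):
        """Exhaustive agreement on random parents of up to 60 atoms."""
        rng = np.random.default_rng(seed)
        elements = list(rng.choice(["C", "H", "O", "N", "S", "Cl", "P", "F"], size=4, replace=False))
        counts = {}
        budget = 60
        for sym in elements:
            k = int(rng.integers(1, min(20, budget) + 1))
            counts[sym] = k
            budget -= k
            if budget <= 0:
                break
        parent = ElementalFormula(counts)
        target = float(rng.uniform(40, min(500, monoisotopic_mass(parent))))
        tol = float(rng.choice([2.0, 10.0, 50.0]))
        ours = sorted(tuple(sorted(f.counts.items())) for f, _ in enumerate_subformulas(parent, target, tol))
        oracle = sorted(tuple(sorted(h.items())) for h in brute_force_subformulas(parent, target, tol))
        assert ours == oracle


# ---------------------------------------------------------------------------
# high-resolution filtering
# ---------------------------------------------------------------------------


class TestHrfScore:
    def test_fully_explained_spectrum_scores_100(self):
        parent = parse_formula("C15 H24 O")
        mzs = [cation_mz("C4 H9"), cation_mz("C11 H15 O"), cation_mz("C15 H24 O")]
        s = Spectrum(mzs, [50.0, 100.0, 20.0])
        assert hrf_score(s, parent, 2.0) == pytest.approx(100.0)

    def test_unassignable_spectrum_scores_zero(self):
        s = Spectrum([41.5, 99.99, 250.77], [1.0, 1.0, 1.0])
        assert hrf_score(s, parse_formula("C H4"), 2.0) == 0.0

    def test_two_of_three_equal_peaks(self):
        parent = parse_formula("C2 H6")
        s = Spectrum([cation_mz("C H3"), cation_mz("C2 H6"), 100.0], [5.0, 5.0, 5.0])
        assert hrf_score(s, parent, 2.0) == pytest.approx(200.0 / 3.0, abs=0.05)

    def test_peaks_below_intensity_floor_ignored(self):
        parent = parse_formula("C2 H6")
        s = Spectrum([cation_mz("C2 H6"), 100.0], [1000.0, 0.5])
        assert hrf_score(s, parent, 2.0, intensity_floor_frac=0.001) == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_tolerance(self, seed):
        rng = np.random.default_rng(seed)
        parent = parse_formula("C10 H14 O2")
        s = Spectrum(np.sort(rng.uniform(40, 170, 8)), rng.uniform(1, 100, 8))
        scores = [hrf_score(s, parent, tol) for tol in (0.5, 2.0, 10.0, 100.0, 1000.0)]
        assert scores == sorted(scores)


class TestTotalScore:
    def test_perfect_scores(self):
        assert total_score(100.0, 100.0) == (100.0, False)

    def test_weighted_mean(self):
        score, si_only = total_score(96.0, 98.0, (0.5, 0.5))
        assert score == pytest.approx(97.0)
        assert not si_only

    def test_degenerates_to_si_without_hrf(self):
        assert total_score(90.0, None) == (90.0, True)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            total_score(50.0, 50.0, (0.7, 0.5))


# ---------------------------------------------------------------------------
# fragment annotation
# ---------------------------------------------------------------------------


class TestAnnotateFragments:
    def bht_spectrum(self, offset_ppm: float = 0.0) -> Spectrum:
        mzs = np.array(
            [
                cation_mz("C4 H9"),
                cation_mz("C14 H21 O"),  # loss of methyl
                cation_mz("C15 H23"),  # loss of OH
                cation_mz("C15 H24 O"),  # molecular ion, 220.182 region
            ]
        )
        return Spectrum(mzs * (1 + offset_ppm * 1e-6), [40.0, 100.0, 25.0, 60.0])

    def test_exact_mass_spectrum_fully_annotated(self):
        annotations, mol_ion = annotate_fragments(self.bht_spectrum(), parse_formula("C15 H24 O"))
        assert mol_ion
        within = [a for a in annotations if abs(a.delta_ppm) < 2.0]
        assert len(within) >= 3
        assert any(a.is_molecular_ion for a in annotations)
        assert all(abs(a.delta_ppm) < 1e-6 for a in annotations)

    def test_offset_spectrum_has_no_annotations(self):
        annotations, mol_ion = annotate_fragments(
            self.bht_spectrum(offset_ppm=10.0), parse_formula("C15 H24 O"), tol_ppm=2.0
        )
        assert annotations == []
        assert not mol_ion

    def test_best_assignment_has_lowest_ppm_and_reports_alternatives(self):
        # a loose tolerance forces multiple candidate subformulas per peak;
        # the winner must be the |ppm|-closest, ties broken to fewer heteroatoms
        parent = parse_formula("C10 H20 O2 N2")
        s = Spectrum([100.1], [1.0])
        annotations, _ = annotate_fragments(s, parent, tol_ppm=50_000.0)
        (a,) = annotations
        assert a.alternatives, "loose tolerance should yield alternatives"
        best_ppm = abs(a.delta_ppm)
        for alt in a.alternatives:
            alt_mz = monoisotopic_mass(alt) - ELECTRON_MASS
            assert abs(1e6 * (a.mz - alt_mz) / alt_mz) >= best_ppm - 1e-9


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


class TestRankCandidates:
    def test_identical_library_spectrum_ranks_first(self, small_study):
        rec = small_study.library[0]
        ranked = rank_candidates(rec.spectrum, small_study.library)
        assert ranked[0].record.name == rec.name
        assert ranked[0].total > 99.0

    def test_tie_order_is_deterministic(self):
        s = Spectrum([50.0, 60.0], [10.0, 20.0])
        from fcmscreen.msdata import LibraryRecord

        lib = [
            LibraryRecord(name="b-record", spectrum=s),
            LibraryRecord(name="a-record", spectrum=s),
        ]
        ranked = rank_candidates(s, lib)
        assert [m.record.name for m in ranked] == ["a-record", "b-record"]
        assert ranked[0].total == ranked[1].total

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            rank_candidates(Spectrum([50.0], [1.0]), [])

    def test_decoy_features_score_below_gate(self, small_study):
        decoys = [f for f in small_study.features if f.feature_id in small_study.decoy_ids]
        for feat in decoys[:4]:
            ranked = rank_candidates(feat, small_study.library)
            assert ranked[0].total < 90.0
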