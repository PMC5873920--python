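from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import make_matrix, random_matrix
from sweepscan.selection_stats import (
    HaplotypeSpectrum,
    h12,
    max_abs_nsl,
    nsl_scores,
    nucleotide_diversity,
    sfs_summary,
    tajima_constants,
    tajimas_d,
    wc_fst,
)


@st.composite
def state_arrays(draw, max_samples=5, max_sites=10, min_samples=2):
    n = 2 * draw(st.integers(min_samples, max_samples))
    s = draw(st.integers(1, max_sites))
    flat = draw(
        st.lists(st.integers(0, 1), min_size=n * s, max_size=n * s)
    )
    return np.array(flat, dtype=np.uint8).reshape(n, s)


class TestNucleotideDiversity:
    def test_identical_haplotypes(self):
        m = make_matrix(np.zeros((4, 3)), region_end=3)
        assert nucleotide_diversity(m) == (0.0, 0.0)

    def test_single_site_half_frequency(self):
        # 6 pairs, 4 of them differ -> 4/6
        m = make_matrix([[0], [0], [1], [1]], region_end=1)
        total, _ = nucleotide_diversity(m)
        assert total == pytest.approx(4 / 6)

    def test_per_site_normalisation(self):
        m = make_matrix([[0], [1]], region_end=100)
        total, per_site = nucleotide_diversity(m)
        assert total == 1.0
        assert per_site == pytest.approx(0.01)

    def test_zero_sites(self):
        m = make_matrix(np.zeros((4, 0)), region_end=50)
        assert nucleotide_diversity(m) == (0.0, 0.0)

    def test_single_haplotype_pair_warns_below_two(self):
        m = make_matrix(np.zeros((2, 1)), region_end=1).take_haplotypes([0, 1])
        # still two rows; the <2 case needs a custom degenerate object, so
        # just confirm two haplotypes are fine
        total, _ = nucleotide_diversity(m)
        assert total == 0.0

    @given(state_arrays())
    @settings(max_examples=60, deadline=None)
    def test_matches_pair_enumeration(self, states):
        m = make_matrix(states, region_end=states.shape[1])
        total, _ = nucleotide_diversity(m)
        assert total == pytest.approx(oracles.pi_oracle(states), abs=1e-12)

    @given(state_arrays())
    @settings(max_examples=60, deadline=None)
    def test_unbiased_heterozygosity_identity(self, states):
        # pi == sum_sites 2 p (1-p) n/(n-1)
        m = make_matrix(states, region_end=states.shape[1])
        n = states.shape[0]
        p = states.mean(axis=0)
        identity = float(np.sum(2 * p * (1 - p) * n / (n - 1)))
        assert nucleotide_diversity(m)[0] == pytest.approx(identity, abs=1e-10)


class TestTajimasD:
    def test_constants_match_series(self):
        for n in (4, 7, 10, 25):
            c = tajima_constants(n)
            assert c["a1"] == pytest.approx(sum(1 / i for i in range(1, n)))
            assert c["a2"] == pytest.approx(sum(1 / i**2 for i in range(1, n)))

    def test_singleton_excess_is_negative(self):
        # 10 haplotypes, 5 singleton sites carried by distinct haplotypes
        states = np.zeros((10, 5), dtype=np.uint8)
        for j in range(5):
            states[j, j] = 1
        m = make_matrix(states, region_end=5)
        d = tajimas_d(m)
        assert d < 0
        assert d == pytest.approx(oracles.tajimas_d_oracle(states), abs=1e-12)

    def test_monomorphic_is_nan(self):
        m = make_matrix(np.zeros((6, 0)), region_end=10)
        assert math.isnan(tajimas_d(m))

    def test_zero_when_pi_equals_watterson(self):
        # n=2: a1=1 so D's numerator is pi - S; one site with both alleles
        # at 50% gives pi = 1 = S -> numerator exactly 0... but n=2 < 4, so
        # construct the balanced case at n=4 numerically instead.
        states = np.array(
            [[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8
        )
        m = make_matrix(states, region_end=2)
        s = sfs_summary(m)
        expected = (s.pi_total - s.S / s.a1) / math.sqrt(
            s.e1 * s.S + s.e2 * s.S * (s.S - 1)
        )
        assert tajimas_d(m) == pytest.approx(expected)

    @given(state_arrays())
    @settings(max_examples=60, deadline=None)
    def test_matches_series_oracle(self, states):
        m = make_matrix(states, region_end=states.shape[1])
        got, want = tajimas_d(m), oracles.tajimas_d_oracle(states)
        if math.isnan(want):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)

    @given(state_arrays(), st.randoms(use_true_random=False))
    @settings(max_examples=40, deadline=None)
    def test_invariant_to_row_and_column_order(self, states, rnd):
        m = make_matrix(states, region_end=states.shape[1])
        rows = list(range(states.shape[0]))
        # permute sample pairs together to keep the diploid structure
        pairs = [(i, i + 1) for i in rows[::2]]
        rnd.shuffle(pairs)
        perm = [i for p in pairs for i in p]
        m2 = make_matrix(states[perm], region_end=states.shape[1])
        d1, d2 = tajimas_d(m), tajimas_d(m2)
        assert (math.isnan(d1) and math.isnan(d2)) or d1 == pytest.approx(d2)

    def test_polarity_flip_does_not_change_sfs_stats(self, rng):
        m = random_matrix(rng, n_haps=8, n_sites=6)
        flipped = make_matrix(1 - m.states, region_end=6)
        assert tajimas_d(m) == pytest.approx(tajimas_d(flipped))
        assert nucleotide_diversity(m)[0] == pytest.approx(
            nucleotide_diversity(flipped)[0]
        )


class TestWcFst:
    def test_fixed_differences_give_one(self):
        states = np.array(
            [[0, 0], [0, 0], [0, 0], [0, 0], [1, 1], [1, 1], [1, 1], [1, 1]],
            dtype=np.uint8,
        )
        pops = ["AFR"] * 4 + ["EUR"] * 4
        m = make_matrix(states, pops=pops, region_end=2)
        assert wc_fst(m)["global"].weighted == pytest.approx(1.0)

    def test_identical_populations_near_zero(self):
        base = np.array([[0, 1], [1, 0], [0, 0], [1, 1]], dtype=np.uint8)
        states = np.vstack([base, base])
        pops = ["AFR"] * 4 + ["EUR"] * 4
        m = make_matrix(states, pops=pops, region_end=2)
        res = wc_fst(m)["global"]
        want_w, want_m = oracles.wc_fst_oracle(states, ["AFR", "AFR", "EUR", "EUR"])
        assert res.weighted <= 0.0 + 1e-12
        assert res.weighted == pytest.approx(want_w, abs=1e-12)
        assert res.mean == pytest.approx(want_m, abs=1e-12)

    def test_monomorphic_sites_excluded_from_mean(self, rng):
        states = rng.integers(0, 2, size=(12, 2)).astype(np.uint8)
        states[:, 1] = 0  # second site monomorphic overall
        pops = ["AFR"] * 4 + ["EUR"] * 4 + ["EAS"] * 4
        m = make_matrix(states, pops=pops, region_end=2)
        res = wc_fst(m)["global"]
        # mean computed over the single polymorphic site only
        w1, m1 = oracles.wc_fst_oracle(states[:, :1], ["AFR", "AFR", "EUR", "EUR", "EAS", "EAS"])
        assert res.mean == pytest.approx(m1, abs=1e-12)
        assert res.weighted == pytest.approx(w1, abs=1e-12)

    def test_all_monomorphic_nan(self):
        m = make_matrix(
            np.zeros((8, 2)), pops=["AFR"] * 4 + ["EUR"] * 4, region_end=2
        )
        res = wc_fst(m)["global"]
        assert math.isnan(res.weighted) and math.isnan(res.mean)

    def test_single_population_errors(self):
        m = make_matrix(np.zeros((4, 1)), pops=["AFR"] * 4, region_end=1)
        with pytest.raises(Exception):
            wc_fst(m)

    def test_pairwise_mode_returns_all_pairs(self, rng):
        m = random_matrix(rng, n_haps=12, n_sites=5, pops=("AFR", "EUR", "EAS"))
        res = wc_fst(m, mode="pairwise")
        assert {"AFR-EUR", "AFR-EAS", "EUR-EAS"} <= set(res)

    def test_matches_component_oracle_on_random_fixtures(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 4))
            pops = ["AFR", "EUR", "EAS"][:k]
            n_per = [int(rng.integers(2, 6)) for _ in range(k)]
            labels = [p for p, n in zip(pops, n_per) for _ in range(2 * n)]
            states = rng.integers(
                0, 2, size=(len(labels), int(rng.integers(1, 6)))
            ).astype(np.uint8)
            m = make_matrix(states, pops=labels, region_end=states.shape[1])
            res = wc_fst(m)["global"]
            pop_of_ind = labels[::2]
            want_w, want_m = oracles.wc_fst_oracle(states, pop_of_ind)
            if math.isnan(want_w):
                assert math.isnan(res.weighted)
            else:
                assert res.weighted == pytest.approx(want_w, abs=1e-12)
                assert res.mean == pytest.approx(want_m, abs=1e-12)


class TestNsl:
    def test_spec_fixture_by_hand(self):
        # h1=(1,1,0) h2=(1,1,1) h3=(0,0,0) h4=(0,0,1); focal middle site:
        # both classes share {focal, left}, mismatch right -> SL_A = SL_D = 2
        states = np.array(
            [[1, 1, 0], [1, 1, 1], [0, 0, 0], [0, 0, 1]], dtype=np.uint8
        )
        m = make_matrix(states, region_end=3)
        scores = nsl_scores(m, maf_cutoff=0.0)
        focal = [s for s in scores if s.position == 2]
        assert len(focal) == 1
        assert focal[0].sl_ancestral == pytest.approx(2.0)
        assert focal[0].sl_derived == pytest.approx(2.0)
        assert focal[0].nsl == pytest.approx(0.0)

    def test_symmetric_classes_zero(self):
        states = np.array(
            [[0, 1, 0], [0, 1, 1], [1, 0, 0], [1, 0, 1]], dtype=np.uint8
        )
        m = make_matrix(states, region_end=3)
        for s in nsl_scores(m, maf_cutoff=0.0):
            assert s.nsl == pytest.approx(0.0)

    def test_maf_cutoff_filters(self):
        # derived frequency 1/200 = 0.005 < 0.01 -> no score at that site
        states = np.zeros((200, 2), dtype=np.uint8)
        states[0, 0] = 1
        states[:100, 1] = 1
        m = make_matrix(states, region_end=2)
        scores = nsl_scores(m, maf_cutoff=0.01)
        assert all(s.position != 1 for s in scores)

    def test_class_below_two_skipped(self):
        states = np.zeros((6, 2), dtype=np.uint8)
        states[0, 0] = 1  # one derived carrier only
        states[:3, 1] = 1
        m = make_matrix(states, region_end=2)
        assert all(s.position != 1 for s in nsl_scores(m, maf_cutoff=0.0))

    def test_fewer_than_two_sites_empty(self):
        m = make_matrix(np.array([[0], [1], [0], [1]]), region_end=1)
        assert nsl_scores(m, maf_cutoff=0.0) == []

    def test_polarity_unknown_sites_removed(self):
        states = np.array(
            [[0, 1, 0], [0, 1, 1], [1, 0, 0], [1, 0, 1]], dtype=np.uint8
        )
        m = make_matrix(states, polarity=[True, False, True], region_end=3)
        scores = nsl_scores(m, maf_cutoff=0.0)
        assert {s.position for s in scores} <= {1, 3}
        # tract lengths must ignore the unknown middle column
        m_dropped = make_matrix(states[:, [0, 2]], positions=[1, 3], region_end=3)
        want = nsl_scores(m_dropped, maf_cutoff=0.0)
        assert [(s.position, s.nsl) for s in scores] == [
            (s.position, s.nsl) for s in want
        ]

    def test_matches_pair_enumeration_on_random_fixtures(self, rng):
        for _ in range(60):
            n = 2 * int(rng.integers(2, 5))
            s = int(rng.integers(2, 11))
            states = rng.integers(0, 2, size=(n, s)).astype(np.uint8)
            m = make_matrix(states, region_end=s)
            cap = int(rng.integers(1, 12))
            scores = {sc.position: sc for sc in nsl_scores(m, maf_cutoff=0.0, cap=cap)}
            for focal in range(s):
                want = oracles.nsl_site_oracle(states, focal, cap)
                if want is None:
                    assert focal + 1 not in scores
                    continue
                got = scores[focal + 1]
                assert got.sl_ancestral == pytest.approx(want[0], abs=1e-12)
                assert got.sl_derived == pytest.approx(want[1], abs=1e-12)

    def test_max_abs(self):
        class FakeScore:
            def __init__(self, v):
                self.nsl = v

        assert max_abs_nsl([FakeScore(-2.1), FakeScore(0.3), FakeScore(1.7)]) == 2.1
        assert max_abs_nsl([FakeScore(0.0)]) == 0.0
        assert math.isnan(max_abs_nsl([]))


class TestH12:
    def test_all_identical(self):
        m = make_matrix(np.ones((6, 3)), region_end=3)
        spec = h12(m)
        assert spec.h12 == pytest.approx(1.0)
        assert spec.h1 == pytest.approx(1.0)

    def test_two_equal_classes(self):
        states = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], dtype=np.uint8)
        spec = h12(make_matrix(states, region_end=2))
        assert spec.h1 == pytest.approx(0.5)
        assert spec.h12 == pytest.approx(1.0)

    def test_four_class_spectrum(self):
        # frequencies 0.4/0.3/0.2/0.1 over 10 haplotypes
        rows = [[0, 0]] * 4 + [[0, 1]] * 3 + [[1, 0]] * 2 + [[1, 1]] * 1
        spec = h12(make_matrix(np.array(rows), region_end=2))
        assert spec.frequencies == pytest.approx((0.4, 0.3, 0.2, 0.1))
        assert spec.h12 == pytest.approx(0.7**2 + 0.04 + 0.01)

    def test_zero_sites_degenerate(self):
        with pytest.warns(UserWarning):
            spec = h12(make_matrix(np.zeros((4, 0)), region_end=10))
        assert spec.h12 == 1.0

    @given(state_arrays())
    @settings(max_examples=60, deadline=None)
    def test_matches_counter_oracle_and_invariants(self, states):
        spec = h12(make_matrix(states, region_end=states.shape[1]))
        h1, h12_val = oracles.h12_oracle(states)
        assert spec.h1 == pytest.approx(h1, abs=1e-12)
        assert spec.h12 == pytest.approx(h12_val, abs=1e-12)
        assert sum(spec.frequencies) == pytest.approx(1.0)
        assert spec.h1 - 1e-12 <= spec.h12 <= 1.0 + 1e-12
        f = spec.frequencies
        p1, p2 = f[0], f[1] if len(f) > 1 else 0.0
        assert spec.h12 - spec.h1 == pytest.approx(2 * p1 * p2, abs=1e-12)

    def test_polarity_flip_invariant(self, rng):
        m = random_matrix(rng, n_haps=10, n_sites=4)
        flipped = make_matrix(1 - m.states, region_end=4)
        assert h12(m).h12 == pytest.approx(h12(flipped).h12)
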