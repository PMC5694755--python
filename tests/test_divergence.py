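import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recold import (
    bootstrap_significance,
    contributing_sequences,
    jensen_shannon,
    pairwise_sample_jsd,
    position_frequency_matrix,
)
from recold.density import DensityGrid, Grid, estimate_pdf, make_grid
from recold.embedding import EmbeddedPoints

from oracles import jsd_direct_oracle

# the twenty length-11 consensus-motif variants observed on one side of a
# strongly diverged sample pair (shared ...YQLIWG suffix)
MOTIF_NEIGHBORHOOD = [
    "CAASAYQLIWG", "CAASCYQLIWG", "CAASRYQLIWG", "CAASTYQLIWG",
    "CAARNYQLIWG", "CAAGNYQLIWG", "CAAADYQLIWG", "CAANNYQLIWG",
    "CAASDYQLIWG", "CAASNYQLIWG", "CAATNYQLIWG", "CAARDYQLIWG",
    "CADSNYQLIWG", "CAGSNYQLIWG", "CAGGNYQLIWG", "CASSNYQLIWG",
    "CATSNYQLIWG", "CAVSNYQLIWG", "CGGSNYQLIWG", "CVGSNYQLIWG",
]


def density_from(probs, sample_id="p"):
    probs = np.asarray(probs, dtype=float)
    edges = tuple(
        np.arange(n + 1, dtype=float) for n in probs.shape
    )
    return DensityGrid(Grid(edges), probs, bandwidth=1.0, sample_id=sample_id)


class TestJensenShannon:
    def test_identity_gives_zero(self):
        p = density_from([0.25, 0.25, 0.5])
        res = jensen_shannon(p, p)
        assert res.global_jsd == 0.0
        assert np.all(res.local_map == 0.0)

    def test_disjoint_supports_give_ln2(self):
        p = density_from([1.0, 0.0])
        q = density_from([0.0, 1.0])
        assert jensen_shannon(p, q).global_jsd == pytest.approx(math.log(2), abs=1e-12)

    def test_two_bin_hand_case(self):
        # P=(1,0), Q=(0.5,0.5):
        # 1/2 ln(4/3) + 1/4 ln(2/3) + 1/4 ln 2 = 0.215762...
        p = density_from([1.0, 0.0])
        q = density_from([0.5, 0.5])
        expected = 0.5 * math.log(4 / 3) + 0.25 * math.log(2 / 3) + 0.25 * math.log(2)
        assert jensen_shannon(p, q).global_jsd == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.215762, abs=1e-6)

    def test_local_map_sums_to_global(self, rng):
        a = rng.random((20, 20))
        b = rng.random((20, 20))
        p, q = density_from(a / a.sum()), density_from(b / b.sum())
        res = jensen_shannon(p, q)
        assert res.local_map.sum() == pytest.approx(res.global_jsd, abs=1e-9)

    def test_symmetry_bounds_and_oracle(self, rng):
        for _ in range(20):
            a, b = rng.random(10), rng.random(10)
            # random sparsity patterns exercise the 0 log 0 convention
            a[rng.random(10) < 0.3] = 0
            b[rng.random(10) < 0.3] = 0
            if a.sum() == 0 or b.sum() == 0:
                continue
            p, q = density_from(a / a.sum()), density_from(b / b.sum())
            fwd = jensen_shannon(p, q).global_jsd
            rev = jensen_shannon(q, p).global_jsd
            assert fwd == pytest.approx(rev, abs=1e-15)
            assert -1e-15 <= fwd <= math.log(2) + 1e-12
            assert fwd == pytest.approx(jsd_direct_oracle(p.flat, q.flat), abs=1e-12)

    def test_bits_option(self):
        p = density_from([1.0, 0.0])
        q = density_from([0.0, 1.0])
        assert jensen_shannon(p, q, base="bits").global_jsd == pytest.approx(1.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        raw_p=st.lists(st.floats(0, 1, allow_nan=False), min_size=5, max_size=5),
        raw_q=st.lists(st.floats(0, 1, allow_nan=False), min_size=5, max_size=5),
    )
    def test_properties_hold_for_arbitrary_distributions(self, raw_p, raw_q):
        a, b = np.array(raw_p), np.array(raw_q)
        if a.sum() == 0 or b.sum() == 0:
            return
        p, q = density_from(a / a.sum()), density_from(b / b.sum())
        res = jensen_shannon(p, q)
        assert -1e-15 <= res.global_jsd <= math.log(2) + 1e-12
        assert np.all(res.local_map >= -1e-18)  # per-bin local JSD is non-negative
        assert res.global_jsd == pytest.approx(
            jensen_shannon(q, p).global_jsd, abs=1e-15
        )
        if np.allclose(p.flat, q.flat, atol=0):
            assert res.global_jsd == pytest.approx(0.0, abs=1e-15)

    def test_grid_mismatch_rejected(self):
        p = density_from([1.0, 0.0])
        q = density_from([0.25, 0.25, 0.5])
        with pytest.raises(ValueError, match="grid"):
            jensen_shannon(p, q)


class TestPairwiseJsd:
    def test_identical_pdfs_zero_matrix(self):
        p = density_from([0.5, 0.5], "a")
        q = density_from([0.5, 0.5], "b")
        mat = pairwise_sample_jsd([p, q])
        assert np.all(mat.to_numpy() == 0.0)

    def test_entries_consistent_with_pairwise_calls(self, rng):
        pdfs = []
        for i in range(3):
            a = rng.random(8)
            pdfs.append(density_from(a / a.sum(), f"s{i}"))
        mat = pairwise_sample_jsd(pdfs)
        for i in range(3):
            for j in range(3):
                expect = 0.0 if i == j else jensen_shannon(pdfs[i], pdfs[j]).global_jsd
                assert mat.iloc[i, j] == pytest.approx(expect, abs=1e-15)


class TestContributingSequences:
    def _points(self, seqs, coords):
        return EmbeddedPoints(tuple(seqs), np.asarray(coords, float), "mds")

    def test_identical_samples_empty_set(self):
        p = density_from(np.full((4, 4), 1 / 16), "a")
        res = jensen_shannon(p, p)
        pts = self._points(["CAAS"], [[0.5, 0.5]])
        cs = contributing_sequences(res, pts, pts)
        assert cs.selected_bins.size == 0
        assert all(len(v) == 0 for v in cs.members.values())

    def test_planted_exclusive_cluster_recovered(self, rng):
        # sample A has a tight exclusive cluster; its sequences must be in
        # the contributing set while B's shared-region points stay out
        shared = rng.normal(size=(30, 2)) * 0.1
        exclusive = rng.normal(size=(10, 2)) * 0.05 + np.array([3.0, 3.0])
        all_pts = np.vstack([shared, exclusive])
        grid = make_grid(all_pts, bins=60)
        a_pts = np.vstack([shared[:15], exclusive])
        b_pts = shared[15:]
        pa = estimate_pdf(a_pts, grid, 0.15, sample_id="A")
        pb = estimate_pdf(b_pts, grid, 0.15, sample_id="B")
        res = jensen_shannon(pa, pb)
        a_names = [f"a{i}" for i in range(15)] + [f"x{i}" for i in range(10)]
        b_names = [f"b{i}" for i in range(15)]
        cs = contributing_sequences(
            res,
            self._points(a_names, a_pts),
            self._points(b_names, b_pts),
            top_frac=0.01,
        )
        planted = {f"x{i}" for i in range(10)}
        assert planted <= set(cs.members["A"])

    def test_top_frac_one_returns_all_positive_bin_sequences(self, rng):
        pts = rng.normal(size=(20, 2))
        grid = make_grid(pts, bins=30)
        pa = estimate_pdf(pts[:10], grid, 0.3, sample_id="A")
        pb = estimate_pdf(pts[10:], grid, 0.3, sample_id="B")
        res = jensen_shannon(pa, pb)
        cs = contributing_sequences(
            res,
            self._points([f"a{i}" for i in range(10)], pts[:10]),
            self._points([f"b{i}" for i in range(10)], pts[10:]),
            top_frac=1.0,
        )
        # with every positive bin selected, every point in a positive bin
        # is returned; here all bins have positive local JSD
        assert len(cs.members["A"]) == 10
        assert len(cs.members["B"]) == 10

    def test_top_frac_validated(self):
        p = density_from([0.5, 0.5], "a")
        res = jensen_shannon(p, p)
        pts = self._points(["CAAS"], [[0.5]])
        with pytest.raises(ValueError):
            contributing_sequences(res, pts, pts, top_frac=0.0)


@pytest.fixture(scope="module")
def naive_pdf():
    rng = np.random.default_rng(11)
    pts = rng.normal(size=(60, 2))
    grid = make_grid(pts, bins=80)
    return estimate_pdf(pts, grid, 0.4, sample_id="s")


class TestBootstrap:
    def test_nonnegative_and_reproducible(self, naive_pdf):
        a = bootstrap_significance(naive_pdf, n_points=60, n_boot=30, seed=5)
        b = bootstrap_significance(naive_pdf, n_points=60, n_boot=30, seed=5)
        assert np.all(a.jsd_samples >= 0)
        assert a.threshold >= 0
        assert np.array_equal(a.jsd_samples, b.jsd_samples)
        assert a.threshold == b.threshold

    def test_larger_resample_shrinks_noise(self, naive_pdf):
        small = bootstrap_significance(naive_pdf, n_points=60, n_boot=30, seed=1)
        large = bootstrap_significance(naive_pdf, n_points=600, n_boot=30, seed=1)
        assert np.median(large.jsd_samples) < np.median(small.jsd_samples)

    def test_threshold_between_order_statistics(self, naive_pdf):
        res = bootstrap_significance(naive_pdf, n_points=60, n_boot=100, seed=2)
        s = np.sort(res.jsd_samples)
        assert s[98] <= res.threshold <= s[99]

    def test_jitter_path(self, naive_pdf):
        res = bootstrap_significance(
            naive_pdf, n_points=40, n_boot=5, seed=3, jitter=True
        )
        assert np.all(res.jsd_samples >= 0)

    def test_argument_validation(self, naive_pdf):
        with pytest.raises(ValueError):
            bootstrap_significance(naive_pdf, n_points=0, n_boot=10, seed=0)
        with pytest.raises(ValueError):
            bootstrap_significance(naive_pdf, n_points=10, n_boot=1, seed=0)


class TestPositionFrequencyMatrix:
    def test_identical_sequences(self):
        pfm = position_frequency_matrix(["CAAS", "CAAS"])
        assert pfm.loc[1, "C"] == 1.0
        assert pfm.loc[4, "S"] == 1.0
        assert np.allclose(pfm.sum(axis=1), 1.0)

    def test_even_split(self):
        pfm = position_frequency_matrix(["CA", "CT"])
        assert pfm.loc[2, "A"] == 0.5
        assert pfm.loc[2, "T"] == 0.5

    def test_consensus_suffix_of_motif_neighborhood(self):
        # the shared suffix of the twenty motif variants dominates
        # positions 6-11 completely (consensus YQLIWG)
        pfm = position_frequency_matrix(MOTIF_NEIGHBORHOOD)
        for pos, aa in zip(range(6, 12), "YQLIWG"):
            assert pfm.loc[pos, aa] == 1.0
        # the variable core positions are not single-residue
        assert pfm.loc[4].max() < 1.0

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            position_frequency_matrix(["CAAS", "CAASW"])
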