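"""Insulation scores, boundary calling, Li threshold, NFR correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse

from nucdomains import insulation as ins
from nucdomains import matrices as mx
from nucdomains import pairs as prs
from nucdomains import synthgen as sg
from nucdomains.presets import RemodelerPreset


def dense_to_matrix(D, resolution=80, contig="c"):
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    up = sparse.csr_matrix(np.triu(D))
    bins = pd.DataFrame({
        "chrom": contig,
        "start": np.arange(n) * resolution,
        "end": (np.arange(n) + 1) * resolution})
    return mx.ContactMatrix(bins, up, resolution, {contig: (0, n)})


def brute_force_insulation(D, w):
    """O(n * w^2) diamond means straight from the definition."""
    n = D.shape[0]
    out = np.full(n, np.nan)
    for i in range(w, n - w):
        cells = [D[a, b]
                 for a in range(i - w, i)
                 for b in range(i + 1, i + w + 1)]
        out[i] = np.mean(cells)
    return out


def brute_force_prominence(x, m):
    """Topographic prominence of minimum ``m`` by exhaustive walks."""
    v = x[m]
    left_max = -np.inf
    run = -np.inf
    for i in range(m - 1, -1, -1):
        if x[i] < v:
            break
        run = max(run, x[i])
    else:
        run = max(x[:m].max(initial=-np.inf), run)
    left_max = run if np.isfinite(run) else x[:m + 1].max()
    run = -np.inf
    for i in range(m + 1, len(x)):
        if x[i] < v:
            break
        run = max(run, x[i])
    else:
        run = max(x[m + 1:].max(initial=-np.inf), run)
    right_max = run if np.isfinite(run) else x[m:].max()
    return min(left_max, right_max) - v


class TestInsulationScore:
    def test_uniform_matrix_scores_zero(self):
        D = np.full((30, 30), 4.0)
        prof = ins.insulation_score(dense_to_matrix(D), 400)
        s = prof.scores["c"]
        finite = np.isfinite(s)
        assert finite.sum() == 30 - 2 * 5
        np.testing.assert_allclose(s[finite], 0.0, atol=1e-12)

    def test_attenuated_split_minimum_at_boundary_bin(self):
        """Distance decay with 10x attenuation across bin k: the diamond
        at k is the only one made purely of attenuated cells, so the
        score has its unique minimum there."""
        n, k = 30, 15
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        D = 1.0 / (1.0 + np.abs(i - j))
        D[(i < k) & (j >= k)] *= 0.1
        D[(j < k) & (i >= k)] *= 0.1
        prof = ins.insulation_score(dense_to_matrix(D), 400)
        s = prof.scores["c"]
        # the split falls between bins k-1 and k: those two diamonds are
        # the only ones made purely of attenuated cells and tie for the
        # global minimum; leftmost is reported
        assert np.nanargmin(s) in (k - 1, k)
        assert s[k - 1] == pytest.approx(s[k], abs=1e-9)
        assert s[k - 1] < s[k - 2] and s[k] < s[k + 1]
        calls = ins.call_boundaries(prof)
        deepest = min(calls, key=lambda c: c.score_at_minimum)
        assert deepest.position in ((k - 1) * 80 + 40, k * 80 + 40)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            n = 30
            D = rng.poisson(3, (n, n)).astype(float)
            D = np.triu(D) + np.triu(D, 1).T
            for w in (2, 4, 5):
                prof = ins.insulation_score(dense_to_matrix(D), w * 80,
                                            normalize=False)
                expected = brute_force_insulation(D, w)
                np.testing.assert_allclose(prof.scores["c"], expected,
                                           atol=1e-12)

    def test_normalization_is_log2_vs_mean(self):
        rng = np.random.default_rng(2)
        D = rng.poisson(5, (30, 30)).astype(float)
        D = np.triu(D) + np.triu(D, 1).T
        raw = ins.insulation_score(dense_to_matrix(D), 400, normalize=False)
        norm = ins.insulation_score(dense_to_matrix(D), 400)
        r = raw.scores["c"]
        expected = np.log2(r / np.nanmean(r))
        np.testing.assert_allclose(norm.scores["c"], expected, atol=1e-12)

    def test_window_too_large_raises(self):
        D = np.ones((8, 8))
        with pytest.raises(ValueError, match="too large"):
            ins.insulation_score(dense_to_matrix(D), 400)

    def test_window_not_multiple_of_resolution_raises(self):
        D = np.ones((30, 30))
        with pytest.raises(ValueError, match="multiple"):
            ins.insulation_score(dense_to_matrix(D), 410)


class TestBoundaries:
    def _profile(self, values, res=80):
        return ins.InsulationProfile({"c": np.asarray(values, float)},
                                     res, 800)

    def test_v_shape_prominence(self):
        calls = ins.call_boundaries(self._profile([0, -1, -2, -1, 0]))
        assert len(calls) == 1
        assert calls[0].prominence == pytest.approx(2.0)
        assert calls[0].position == 2 * 80 + 40

    def test_monotone_profile_has_no_boundaries(self):
        assert ins.call_boundaries(self._profile([0, 1, 2, 3, 4])) == []

    def test_plateau_reports_leftmost_bin(self):
        calls = ins.call_boundaries(self._profile([1, 0, 0, 0, 1]))
        assert len(calls) == 1
        assert calls[0].position == 1 * 80 + 40

    def test_all_nan_warns_empty(self):
        with pytest.warns(UserWarning, match="NaN"):
            calls = ins.call_boundaries(
                self._profile([np.nan] * 6))
        assert calls == []

    def test_matches_exhaustive_prominence_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            x = np.round(rng.normal(size=rng.integers(5, 50)), 3)
            calls = ins.call_boundaries(self._profile(x))
            # oracle: scan all interior leftmost-plateau minima
            expected = []
            for m in range(1, len(x) - 1):
                if x[m] < x[m - 1]:
                    j = m
                    while j + 1 < len(x) and x[j + 1] == x[m]:
                        j += 1
                    if j < len(x) - 1 and x[j + 1] > x[m]:
                        expected.append(m)
            assert [c.position for c in calls] == \
                [m * 80 + 40 for m in expected]
            for c, m in zip(calls, expected):
                assert c.prominence == pytest.approx(
                    brute_force_prominence(x, m), abs=1e-12)

    def test_boundary_set_invariant_under_constant_shift(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        a = ins.call_boundaries(self._profile(x))
        b = ins.call_boundaries(self._profile(x + 5.0))
        assert [c.position for c in a] == [c.position for c in b]
        np.testing.assert_allclose([c.prominence for c in a],
                                   [c.prominence for c in b])


class TestLiThreshold:
    def test_known_fixed_point(self):
        """{1,1,1,1,9,9}: one update lands on (1-9)/(ln1 - ln9) = 3.641."""
        t = ins.li_threshold([1, 1, 1, 1, 9, 9])
        assert t == pytest.approx(8 / np.log(9), abs=1e-3)
        assert t == pytest.approx(3.641, abs=1e-3)

    def test_bimodal_separation(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([rng.normal(1, 0.1, 100).clip(0.5),
                            rng.normal(10, 0.1, 100)])
        t = ins.li_threshold(v)
        assert 1.5 < t < 9.5

    def test_scale_homogeneity(self):
        v = np.array([0.5, 1.2, 3.0, 9.0, 9.5])
        t = ins.li_threshold(v)
        assert ins.li_threshold(10 * v) == pytest.approx(10 * t, rel=1e-4)

    def test_identical_values_raise(self):
        with pytest.raises(ValueError, match="distinct"):
            ins.li_threshold([2.0, 2.0, 2.0])

    def test_agrees_with_image_library(self):
        """Cross-check against the image-analysis implementation."""
        skimage = pytest.importorskip("skimage.filters")
        rng = np.random.default_rng(6)
        v = np.concatenate([rng.gamma(2, 0.5, 300), rng.gamma(20, 0.5, 60)])
        ours = ins.li_threshold(v)
        theirs = float(skimage.threshold_li(v))
        assert ours == pytest.approx(theirs, rel=0.05)

    def test_strong_count_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(7)
        proms = rng.gamma(2, 1, 50) + 0.01
        calls = [ins.BoundaryCall("c", i, p, -1.0)
                 for i, p in enumerate(proms)]
        counts = []
        for thr in np.linspace(proms.min(), proms.max(), 10):
            ins.mark_strong(calls, threshold=thr)
            counts.append(sum(c.strong for c in calls))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestAnchorComposites:
    def test_single_anchor_is_profile_slice(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=200)
        prof = ins.InsulationProfile({"c": s}, 80, 800)
        anchors = pd.DataFrame({"chrom": ["c"], "pos": [8000],
                                "strand": ["+"]})
        offs, comp, mn = ins.insulation_at_anchors(prof, anchors, 3000)
        b = 8000 // 80
        np.testing.assert_allclose(comp, s[b - 18: b + 19])

    def test_flat_zero_profile(self):
        prof = ins.InsulationProfile({"c": np.zeros(200)}, 80, 800)
        anchors = pd.DataFrame({"chrom": ["c"], "pos": [8000],
                                "strand": ["+"]})
        _, comp, mn = ins.insulation_at_anchors(prof, anchors, 3000)
        assert np.all(comp == 0) and mn == 0

    def test_no_interior_anchor_raises(self):
        prof = ins.InsulationProfile({"c": np.zeros(10)}, 80, 800)
        anchors = pd.DataFrame({"chrom": ["c"], "pos": [80],
                                "strand": ["+"]})
        with pytest.raises(ValueError, match="anchors"):
            ins.insulation_at_anchors(prof, anchors, 3000)

    def test_minima_deepen_with_nfr_width(self):
        """Wider planted NFRs insulate more: composite minima decrease
        strictly over widths 68 < 92 < 126 (same linker, same seed)."""
        minima = []
        for nfr in (68, 92, 126):
            p = RemodelerPreset("x", 41, nfr)
            cfg = sg.GeneratorConfig(
                contigs=[("c", 30_000, False)],
                tf_sites={"c": [5_000, 15_000, 25_000]},
                preset=p, n_pairs=200_000, seed=13)
            gt = sg.make_ground_truth(cfg)
            kept, _ = prs.process_pairs(sg.simulate_ligation_pairs(gt, cfg))
            m = mx.bin_pairs(kept, 80, {"c": 30_000})
            prof = ins.insulation_score(m, 800)
            _, _, mn = ins.insulation_at_anchors(prof, gt.tf_anchors())
            minima.append(mn)
        assert minima[0] > minima[1] > minima[2]


class TestBoundaryAnchorOverlap:
    def _calls(self, positions, contig="c"):
        return [ins.BoundaryCall(contig, p, 1.0, -1.0, strong=True)
                for p in positions]

    def test_exact_overlap(self):
        anchors = pd.DataFrame({"chrom": ["c"] * 3,
                                "pos": [1000, 2000, 3000]})
        out = ins.boundary_anchor_overlap(
            self._calls([1000, 2000, 3000]), anchors, {"c": 10_000})
        assert out["fraction_boundaries_near_anchor"] == 1.0
        assert out["fraction_anchors_near_boundary"] == 1.0

    def test_wrong_contig_no_overlap(self):
        anchors = pd.DataFrame({"chrom": ["other"], "pos": [1000]})
        out = ins.boundary_anchor_overlap(
            self._calls([1000]), anchors, {"c": 10_000})
        assert out["fraction_boundaries_near_anchor"] == 0.0

    def test_shuffled_boundaries_have_unit_enrichment(self):
        rng = np.random.default_rng(9)
        L = 200_000
        anchors = pd.DataFrame({
            "chrom": "c", "pos": rng.integers(0, L, 40)})
        random_calls = self._calls(rng.integers(0, L, 50))
        out = ins.boundary_anchor_overlap(
            random_calls, anchors, {"c": L}, n_permutations=400, seed=1)
        assert out["enrichment"] == pytest.approx(1.0, abs=0.75)


class TestNfrVsInsulation:
    def test_perfect_line(self):
        r, p = ins.nfr_vs_insulation([(68, -0.1), (92, -0.2), (116, -0.3)])
        assert r == pytest.approx(-1.0)

    def test_three_point_example(self):
        """Independent closed-form Pearson on (68,-.1),(92,-.2),(126,-.3)."""
        pts = [(68, -0.1), (92, -0.2), (126, -0.3)]
        w = np.array([p[0] for p in pts], float)
        m = np.array([p[1] for p in pts], float)
        cov = ((w - w.mean()) * (m - m.mean())).sum()
        expected = cov / np.sqrt(((w - w.mean()) ** 2).sum()
                                 * ((m - m.mean()) ** 2).sum())
        r, p = ins.nfr_vs_insulation(pts)
        assert r == pytest.approx(expected, abs=1e-12)
        assert r == pytest.approx(-0.9951, abs=1e-4)

    def test_constant_minima_raise(self):
        with pytest.raises(ValueError, match="variance"):
            ins.nfr_vs_insulation([(68, -0.1), (92, -0.1), (126, -0.1)])

    def test_too_few_conditions_raise(self):
        with pytest.raises(ValueError, match="3"):
            ins.nfr_vs_insulation([(68, -0.1), (92, -0.2)])


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.integers(-50, 50), min_size=5, max_size=50))
def test_boundary_calls_match_oracle_on_integer_profiles(values):
    """Property: minima and prominences agree with the exhaustive oracle
    on arbitrary (tie-rich) integer profiles."""
    x = np.asarray(values, dtype=float)
    prof = ins.InsulationProfile({"c": x}, 80, 800)
    calls = ins.call_boundaries(prof)
    for c in calls:
        m = (c.position - 40) // 80
        assert c.prominence == pytest.approx(
            brute_force_prominence(x, m), abs=1e-12)
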