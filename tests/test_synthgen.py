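"""Generator tests: planted structure, sampling laws, determinism."""

import numpy as np
import pandas as pd
import pytest

from nucdomains.presets import RemodelerPreset, get_preset
from nucdomains import synthgen as sg
from nucdomains import pairs as prs

from conftest import brute_force_lattice


class TestGroundTruth:
    def test_first_dyads_flank_the_nfr(self):
        """INO80 NFR of 126 bp at site 5000 puts dyads at 5000 ± 136."""
        p = RemodelerPreset("ino80", 41, 126, spacing_sd_bp=0.0)
        cfg = sg.GeneratorConfig(
            contigs=[("c", 12_000, False)], tf_sites={"c": [5_000]},
            preset=p, seed=0)
        gt = sg.make_ground_truth(cfg)
        d = gt.dyads["c"]
        assert 4864 in d and 5136 in d
        # next dyads one NRL (188 bp) further out
        assert 4864 - 188 in d and 5136 + 188 in d

    def test_spacing_within_arrays_equals_nrl(self, small_gt):
        """Consecutive dyads inside an array sit one NRL (188 bp) apart.

        Gaps at NFRs and at mid-domain seams where two arrays meet are
        excluded; with jitter off every within-array gap is exact.
        """
        d = small_gt.dyads["chrS"].astype(float)
        gaps = np.diff(d)
        arrays = gaps[gaps < 300]  # exclude NFR crossings
        assert np.median(arrays) == 188
        assert (arrays == 188).mean() > 0.8

    def test_lattice_matches_independent_construction(self, small_config,
                                                      small_gt):
        expected = brute_force_lattice([10_000, 20_000], 30_000,
                                       small_config.preset)
        np.testing.assert_array_equal(small_gt.dyads["chrS"], expected)

    def test_no_dyad_inside_nfr(self, ino80_noisy_config):
        gt = sg.make_ground_truth(ino80_noisy_config)
        d = gt.dyads["chrS"]
        for a, b in gt.nfr_intervals["chrS"]:
            assert not np.any((d >= a) & (d < b))

    def test_domain_ids_increment_at_each_nfr(self, small_gt):
        d = small_gt.dyads["chrS"]
        ids = small_gt.domain_ids["chrS"]
        assert set(ids) == {0, 1, 2}
        # ids are sorted along the contig and switch exactly at the sites
        assert np.all(np.diff(ids) >= 0)
        for site, lo, hi in [(10_000, 0, 1), (20_000, 1, 2)]:
            below = ids[d < site]
            above = ids[d > site]
            assert below.max() == lo and above.min() == hi

    def test_deterministic_per_seed(self, ino80_noisy_config):
        g1 = sg.make_ground_truth(ino80_noisy_config)
        g2 = sg.make_ground_truth(ino80_noisy_config)
        np.testing.assert_array_equal(g1.dyads["chrS"], g2.dyads["chrS"])

    def test_contig_too_short_raises(self):
        p = RemodelerPreset("ino80", 41, 126)
        cfg = dict(contigs=[("c", 900, False)], tf_sites={"c": [450]},
                   preset=p, seed=0)
        with pytest.raises(ValueError, match="too short"):
            sg.make_ground_truth(sg.GeneratorConfig(**cfg))

    def test_overlapping_nfrs_raise_with_site_names(self):
        p = RemodelerPreset("ino80", 41, 126)
        cfg = sg.GeneratorConfig(
            contigs=[("c", 30_000, False)], tf_sites={"c": [5000, 5100]},
            preset=p, seed=0)
        with pytest.raises(ValueError, match="5000"):
            sg.make_ground_truth(cfg)

    def test_unphased_arrays_keep_spacing(self):
        p = RemodelerPreset("x", 41, 126, spacing_sd_bp=0.0, phased=False)
        cfg = sg.GeneratorConfig(
            contigs=[("c", 30_000, False)], tf_sites={"c": [15_000]},
            preset=p, seed=1)
        gt = sg.make_ground_truth(cfg)
        gaps = np.diff(gt.dyads["c"].astype(float))
        assert np.all(gaps[gaps < 300] == 188)


class TestFragments:
    def test_deterministic(self, small_gt):
        f1 = sg.simulate_mnase_fragments(small_gt, 1000, seed=5)
        f2 = sg.simulate_mnase_fragments(small_gt, 1000, seed=5)
        pd.testing.assert_frame_equal(f1, f2)

    def test_zero_sd_gives_constant_length(self, small_gt):
        f = sg.simulate_mnase_fragments(small_gt, 500, frag_len_mean=160,
                                        frag_len_sd=0.0, seed=1)
        assert ((f["end"] - f["start"]) == 160).all()

    def test_zero_midpoint_sd_centers_on_dyads(self, small_gt):
        f = sg.simulate_mnase_fragments(small_gt, 500, frag_len_mean=160,
                                        frag_len_sd=0.0, seed=1,
                                        midpoint_sd=0.0)
        mids = (f["start"] + f["end"]) // 2
        assert np.isin(mids, small_gt.dyads["chrS"]).all()

    def test_lengths_truncated_to_100_260(self, small_gt):
        f = sg.simulate_mnase_fragments(small_gt, 5000, frag_len_mean=160,
                                        frag_len_sd=60.0, seed=1)
        lens = f["end"] - f["start"]
        assert lens.min() >= 100 and lens.max() <= 260

    def test_empty_dyads_raise(self, small_gt):
        empty = sg.GroundTruth({}, {}, {}, {}, {}, small_gt.preset)
        with pytest.raises(ValueError, match="no dyads"):
            sg.simulate_mnase_fragments(empty, 10, seed=0)


class TestLigationPairs:
    def test_deterministic(self, small_gt, small_config):
        p1 = sg.simulate_ligation_pairs(small_gt, small_config)
        p2 = sg.simulate_ligation_pairs(small_gt, small_config)
        pd.testing.assert_frame_equal(p1, p2)

    def test_orientation_mix_recovered(self, small_gt, small_config):
        """Class frequencies match the multinomial mix within 3 sd."""
        mix = (0.4, 0.3, 0.2, 0.1)
        cfg = sg.GeneratorConfig(
            contigs=small_config.contigs, tf_sites=small_config.tf_sites,
            preset=small_config.preset, n_pairs=40_000,
            orientation_mix=mix, seed=9)
        raw = sg.simulate_ligation_pairs(small_gt, cfg)
        kept, stats = prs.process_pairs(raw)
        frac = stats.orientation_fractions()
        n = stats.n_kept
        for cls, p in zip(
                ("inward", "outward", "tandem_entry", "tandem_exit"), mix):
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(frac[cls] - p) < 3 * sd + 0.01

    def test_beta_zero_is_a_hard_wall(self, small_gt, small_config):
        """With beta = 0 no pair crosses any planted NFR."""
        cfg = sg.GeneratorConfig(
            contigs=small_config.contigs, tf_sites=small_config.tf_sites,
            preset=small_config.preset, n_pairs=20_000,
            boundary_attenuation=lambda w: 0.0, seed=9)
        raw = sg.simulate_ligation_pairs(small_gt, cfg)
        kept, _ = prs.process_pairs(raw)
        lo = np.minimum(kept["pos1"], kept["pos2"])
        hi = np.maximum(kept["pos1"], kept["pos2"])
        for center in (10_000, 20_000):
            assert not np.any((lo < center) & (hi > center))

    def test_junctions_sit_80bp_outside_dyads(self, small_gt, small_config):
        """Dyad-shifting the emitted junctions recovers planted dyads."""
        raw = sg.simulate_ligation_pairs(small_gt, small_config)
        shifted = prs.shift_to_dyad(prs.classify_orientation(raw))
        d = small_gt.dyads["chrS"]
        assert np.isin(shifted["pos1"], d).all()
        assert np.isin(shifted["pos2"], d).all()

    def test_alpha_validation(self, small_config):
        with pytest.raises(ValueError, match="alpha"):
            sg.GeneratorConfig(
                contigs=small_config.contigs,
                tf_sites=small_config.tf_sites,
                preset=small_config.preset, decay_exponent=0.0)

    def test_beta_range_validation(self, small_gt, small_config):
        cfg = sg.GeneratorConfig(
            contigs=small_config.contigs, tf_sites=small_config.tf_sites,
            preset=small_config.preset,
            boundary_attenuation=lambda w: 1.5, seed=0)
        with pytest.raises(ValueError, match="beta"):
            sg.simulate_ligation_pairs(small_gt, cfg)

    def test_undigested_fraction_filtered_downstream(self, small_gt,
                                                     small_config):
        cfg = sg.GeneratorConfig(
            contigs=small_config.contigs, tf_sites=small_config.tf_sites,
            preset=small_config.preset, n_pairs=10_000,
            undigested_frac=0.2, seed=4)
        raw = sg.simulate_ligation_pairs(small_gt, cfg)
        kept, stats = prs.process_pairs(raw)
        assert stats.n_short > 0.15 * 10_000
        dist = np.abs(kept["pos2"] - kept["pos1"])
        assert dist.min() >= 147


class TestCutSites:
    def _config(self, f_cut, cuts=(3_000, 8_000), n_pairs=30_000, seed=2):
        p = RemodelerPreset("ino80", 41, 126, spacing_sd_bp=0.0)
        return sg.GeneratorConfig(
            contigs=[("p", 17_000, True)], tf_sites={"p": [5_500, 13_000]},
            preset=p, n_pairs=n_pairs, seed=seed,
            cut_sites={"p": list(cuts)}, f_cut=f_cut)

    def test_full_cut_severs_segments(self):
        """With two cuts, no sampled pair joins the two fragments."""
        cfg = self._config(1.0)
        gt = sg.make_ground_truth(cfg)
        raw = sg.simulate_ligation_pairs(gt, cfg)
        kept, _ = prs.process_pairs(raw)
        lo = np.minimum(kept["pos1"], kept["pos2"]).to_numpy()
        hi = np.maximum(kept["pos1"], kept["pos2"]).to_numpy()
        in_mid = lambda x: (x > 3_000) & (x < 8_000)  # noqa: E731
        assert not np.any(in_mid(lo) != in_mid(hi))

    def test_single_cut_depletes_short_arc_crossings(self):
        """One cut opens the circle: loci flanking the cut only stay in
        contact the long way round, so short-range crossings collapse."""
        def crossing(f_cut):
            cfg = self._config(f_cut, cuts=(8_000,), n_pairs=40_000)
            gt = sg.make_ground_truth(cfg)
            kept, _ = prs.process_pairs(sg.simulate_ligation_pairs(gt, cfg))
            lo = np.minimum(kept["pos1"], kept["pos2"]).to_numpy()
            hi = np.maximum(kept["pos1"], kept["pos2"]).to_numpy()
            return int(((lo < 8_000) & (hi > 8_000)
                        & ((hi - lo) < 2_000)).sum())
        assert crossing(1.0) < 0.1 * crossing(0.0)

    def test_zero_cut_fraction_is_identity(self):
        cfg0 = self._config(0.0)
        gt = sg.make_ground_truth(cfg0)
        with_cuts = sg.simulate_ligation_pairs(gt, cfg0)
        cfg_none = sg.GeneratorConfig(
            contigs=cfg0.contigs, tf_sites=cfg0.tf_sites,
            preset=cfg0.preset, n_pairs=cfg0.n_pairs, seed=cfg0.seed)
        without = sg.simulate_ligation_pairs(gt, cfg_none)
        pd.testing.assert_frame_equal(with_cuts, without)

    def test_half_cut_halves_cross_segment_pairs(self):
        """Binomial thinning: f_cut = 0.5 keeps ~half the pairs that
        join the two restriction fragments."""
        def cross_count(f_cut):
            cfg = self._config(f_cut, n_pairs=60_000)
            gt = sg.make_ground_truth(cfg)
            kept, _ = prs.process_pairs(sg.simulate_ligation_pairs(gt, cfg))
            lo = np.minimum(kept["pos1"], kept["pos2"]).to_numpy()
            hi = np.maximum(kept["pos1"], kept["pos2"]).to_numpy()
            in_mid = lambda x: (x > 3_000) & (x < 8_000)  # noqa: E731
            return int((in_mid(lo) != in_mid(hi)).sum())

        n_full = cross_count(0.0)
        n_half = cross_count(0.5)
        sd = np.sqrt(n_full * 0.5 * 0.5)
        assert abs(n_half - 0.5 * n_full) < 3 * sd

    def test_cut_outside_contig_raises(self):
        p = RemodelerPreset("ino80", 41, 126)
        with pytest.raises(ValueError, match="cut site"):
            sg.GeneratorConfig(
                contigs=[("p", 17_000, True)], tf_sites={"p": [4_000]},
                preset=p, cut_sites={"p": [20_000]})


def test_circular_arc_distance_symmetric_and_bounded():
    """Shorter-arc distances on a circle never exceed half the length."""
    p = RemodelerPreset("ino80", 41, 126, spacing_sd_bp=0.0)
    cfg = sg.GeneratorConfig(
        contigs=[("p", 10_000, True)], tf_sites={"p": [5_000]},
        preset=p, n_pairs=5_000, seed=6)
    gt = sg.make_ground_truth(cfg)
    d = gt.dyads["p"].astype(float)
    L = 10_000
    sep = np.abs(d[:, None] - d[None, :])
    arc = np.minimum(sep, L - sep)
    assert np.allclose(arc, arc.T)
    assert arc.max() <= L / 2
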