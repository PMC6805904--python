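"""Hi-C statistics versus brute-force per-pair oracles on toy matrices."""
import warnings

import numpy as np
import pytest

from helpers import (
    brute_cis_total,
    brute_insulation,
    brute_observed_over_expected,
    brute_ps,
)
from meioloop import (
    BarrierTrack,
    BinClassTrack,
    ContactMatrix,
    TSSAnnotation,
    average_feature_map,
    cis_total,
    classes_from_sites,
    compute_ps,
    insulation,
    make_chromosome_spec,
    mask_translocation_bins,
    observed_over_expected,
    ps_by_telomere_distance,
    site_pair_pileup,
    stratify_ps,
    synth_contact_map,
    synth_genome_contact_map,
    tss_orientation_profile,
)
from meioloop.hic import log_distance_edges
import pandas as pd


def powerlaw_matrix(spec, bin_bp=2000, seed=None, **kw):
    return synth_contact_map(spec, bin_bp=bin_bp, noise_seed=seed, **kw)


@pytest.fixture(scope="module")
def medium_spec():
    # 100 bins at 2 kb; centromere at bin 40
    return make_chromosome_spec("chrM", 200_000, 80_000)


class TestContactMatrix:
    def test_rejects_asymmetric_and_negative(self, toy_specs):
        m = ContactMatrix.zeros(toy_specs, 2000)
        bad = m.counts.copy()
        bad[0, 1] = 5
        with pytest.raises(ValueError):
            ContactMatrix(bad, 2000, toy_specs)
        with pytest.raises(ValueError):
            ContactMatrix(m.counts - 1, 2000, toy_specs)

    def test_arm_segmentation(self, toy_specs):
        m = ContactMatrix.zeros(toy_specs, 2000)
        ranges = list(m.arm_bin_ranges())
        assert len(ranges) == 4
        # chrA: 100 kb / 2 kb = 50 bins, cen at 40 kb -> split at bin 20
        assert ranges[0][2:] == (0, 20)
        assert ranges[1][2:] == (20, 50)


class TestTranslocationMask:
    def test_zero_trans_nothing_masked(self, toy_specs):
        m = synth_genome_contact_map(toy_specs, trans_level=0.0)
        mask = mask_translocation_bins(m)
        assert not mask.any()

    def test_single_trans_spike_masks_bin(self, toy_specs):
        m = synth_genome_contact_map(toy_specs, trans_level=0.0)
        spike_row = 5
        spike_col = m.chrom_slice(1).start + 3
        big = m.counts.max() * 10
        m.counts[spike_row, spike_col] = m.counts[spike_col, spike_row] = big
        mask = mask_translocation_bins(m)
        assert mask[spike_row] and mask[spike_col]
        assert mask.sum() == 2

    def test_uniform_matrix_masks_everything(self, uniform_matrix):
        mask = mask_translocation_bins(uniform_matrix)
        assert mask.all()

    def test_single_chromosome_noop_with_warning(self, medium_spec):
        m = powerlaw_matrix(medium_spec)
        with pytest.warns(UserWarning):
            mask = mask_translocation_bins(m)
        assert not mask.any()


class TestComputePs:
    def test_uniform_matrix_constant_one(self, uniform_matrix):
        ps = compute_ps(uniform_matrix)
        ok = np.isfinite(ps.value)
        assert np.allclose(ps.value[ok], 1.0)

    def test_inverse_distance_counts_halve_at_8kb(self, medium_spec):
        m = ContactMatrix.zeros([medium_spec], 2000)
        n = m.n_bins
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        m.counts[:] = np.where(d > 0, 1.0 / np.maximum(d, 1), 1.0)
        ps = compute_ps(m)
        idx8 = np.searchsorted(ps.edges_bp, 8000, side="right") - 1
        assert ps.value[idx8] == pytest.approx(0.5)

    def test_matches_bruteforce_exactly(self, medium_spec):
        m = powerlaw_matrix(medium_spec, seed=1)
        edges = log_distance_edges(60, 20)
        ps = compute_ps(m, edges_bins=edges)
        oracle, cnts = brute_ps(m, edges)
        anchor = oracle[int(np.searchsorted(edges * 2000, 4000, "right") - 1)]
        np.testing.assert_allclose(ps.value, oracle / anchor, equal_nan=True)
        np.testing.assert_array_equal(ps.n_pairs, cnts)

    def test_exclusion_zone_values_irrelevant(self, medium_spec):
        m1 = powerlaw_matrix(medium_spec, seed=2)
        m2 = ContactMatrix(m1.counts.copy(), 2000, (medium_spec,))
        # corrupt all pairs touching bins within 20 kb of the centromere
        near_cen = m2.dist_to_centromere < 20_000
        m2.counts[near_cen, :] += 999.0
        m2.counts[:, near_cen] += 999.0
        m2.counts[np.ix_(near_cen, near_cen)] = 5.0  # keep symmetric
        ps1, ps2 = compute_ps(m1), compute_ps(m2)
        np.testing.assert_allclose(ps1.value, ps2.value, equal_nan=True)

    def test_masked_bin_values_irrelevant(self, medium_spec):
        m1 = powerlaw_matrix(medium_spec, seed=3)
        m1.mask[33] = True
        m2 = ContactMatrix(m1.counts.copy(), 2000, (medium_spec,), m1.mask.copy())
        m2.counts[33, :] = 1e6
        m2.counts[:, 33] = 1e6
        np.testing.assert_allclose(
            compute_ps(m1).value, compute_ps(m2).value, equal_nan=True
        )


class TestStratifiedPs:
    def sites(self, spec, step_bp=24_000):
        pos = np.arange(24_000, spec.length_bp - 24_000, step_bp)
        pos = pos[np.abs(pos - spec.centromere_bp) > 4000]
        return BarrierTrack.from_arrays([spec.name] * len(pos), pos, [0.9] * len(pos))

    def test_all_non_equals_overall(self, medium_spec):
        m = powerlaw_matrix(medium_spec, seed=4)
        classes = BinClassTrack(np.zeros(m.n_bins, dtype=bool))
        with pytest.warns(UserWarning):
            strat = stratify_ps(m, classes)
        assert strat.rec8_rec8 is None and strat.rec8_non is None
        np.testing.assert_allclose(
            strat.non_non.value, compute_ps(m).value, equal_nan=True
        )

    def test_label_swap_swaps_pure_curves(self, medium_spec):
        m = powerlaw_matrix(medium_spec, seed=5)
        classes = classes_from_sites(m, self.sites(medium_spec))
        a = stratify_ps(m, classes)
        b = stratify_ps(m, BinClassTrack(~classes.is_site))
        np.testing.assert_allclose(
            a.rec8_rec8.mean_raw, b.non_non.mean_raw, equal_nan=True
        )
        np.testing.assert_allclose(
            a.rec8_non.mean_raw, b.rec8_non.mean_raw, equal_nan=True
        )

    def test_pair_weighted_recomposition(self, medium_spec):
        # class curves weighted by pair counts rebuild the overall P(s)
        m = powerlaw_matrix(medium_spec, seed=6)
        classes = classes_from_sites(m, self.sites(medium_spec))
        strat = stratify_ps(m, classes)
        overall = compute_ps(m)
        total = np.zeros(overall.n_dist_bins)
        npairs = np.zeros(overall.n_dist_bins)
        for c in strat.curves().values():
            contrib = np.where(c.n_pairs > 0, c.mean_raw * c.n_pairs, 0.0)
            total += contrib
            npairs += c.n_pairs
        with np.errstate(invalid="ignore"):
            recomposed = total / npairs
        np.testing.assert_allclose(recomposed, overall.mean_raw, equal_nan=True)

    def test_planted_pair_enrichment_lifts_site_curve(self, medium_spec):
        m0 = powerlaw_matrix(medium_spec)
        track = self.sites(medium_spec)
        bins = sorted({m0.bin_index("chrM", int(p)) for p in track.positions_for("chrM")})
        pairs = [(a, b) for a in bins for b in bins if a < b]
        m = synth_contact_map(medium_spec, peak_anchor_pairs=pairs, peak_fold=3.0)
        strat = stratify_ps(m, classes_from_sites(m, track))
        ok = (
            np.isfinite(strat.rec8_rec8.mean_raw)
            & np.isfinite(strat.non_non.mean_raw)
            & (strat.rec8_rec8.n_pairs > 2)
        )
        ratio = strat.rec8_rec8.mean_raw[ok] / strat.non_non.mean_raw[ok]
        assert np.median(ratio) > 1.5


class TestTelomereStratifiedPs:
    def test_uniform_all_strata_flat(self, medium_spec):
        m = ContactMatrix.zeros([medium_spec], 2000)
        m.counts[:] = 2.0
        out = ps_by_telomere_distance(m, [0, 60_000, 200_000])
        for _rng, curve in out:
            if curve is not None:
                ok = np.isfinite(curve.value)
                assert np.allclose(curve.value[ok], 1.0)

    def test_stratum_assignment_matches_bruteforce(self, medium_spec):
        m = powerlaw_matrix(medium_spec, seed=7)
        edges = [0.0, 50_000.0, 120_000.0, 400_000.0]
        out = ps_by_telomere_distance(m, edges)
        # brute force: classify every eligible pair, aggregate per stratum
        include = m.ps_include_mask(20_000) & (m.dist_to_telomere < m.dist_to_centromere)
        from helpers import bin_arm_bounds

        bounds = bin_arm_bounds(m)
        dist_edges = out[0][1].edges_bp / m.bin_bp if out[0][1] is not None else None
        for k, (rng, curve) in enumerate(out):
            if curve is None:
                continue
            de = curve.edges_bp / m.bin_bp
            sums = np.zeros(len(de) - 1)
            cnts = np.zeros(len(de) - 1)
            for i in range(m.n_bins):
                for j in range(i + 1, m.n_bins):
                    if not (include[i] and include[j]) or bounds[i] != bounds[j]:
                        continue
                    comb = m.dist_to_telomere[i] + m.dist_to_telomere[j]
                    if not (edges[k] <= comb < edges[k + 1]):
                        continue
                    d = j - i
                    if d < de[0] or d >= de[-1]:
                        continue
                    kk = int(np.searchsorted(de, d, side="right") - 1)
                    sums[kk] += m.counts[i, j]
                    cnts[kk] += 1
            with np.errstate(invalid="ignore"):
                oracle = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
            np.testing.assert_allclose(curve.mean_raw, oracle, equal_nan=True)

    def test_cen_proximal_pairs_excluded(self, medium_spec):
        m1 = powerlaw_matrix(medium_spec, seed=8)
        m2 = ContactMatrix(m1.counts.copy(), 2000, (medium_spec,))
        nearer_cen = m2.dist_to_centromere <= m2.dist_to_telomere
        m2.counts[np.ix_(nearer_cen, nearer_cen)] += 123.0
        for (r1, c1), (r2, c2) in zip(
            ps_by_telomere_distance(m1, [0, 80_000]),
            ps_by_telomere_distance(m2, [0, 80_000]),
        ):
            if c1 is not None:
                np.testing.assert_allclose(c1.mean_raw, c2.mean_raw, equal_nan=True)


class TestCisTotal:
    def test_zero_trans_gives_one(self, toy_specs):
        m = synth_genome_contact_map(toy_specs, trans_level=0.0)
        df = cis_total(m)
        r = df["cis_total"].to_numpy()
        assert np.allclose(r[np.isfinite(r)], 1.0)

    def test_matches_bruteforce_with_masking(self, toy_specs):
        m = synth_genome_contact_map(toy_specs, trans_level=0.5, noise_seed=9)
        m.mask[[3, 40]] = True
        df = cis_total(m)
        np.testing.assert_allclose(
            df["cis_total"].to_numpy(), brute_cis_total(m), equal_nan=True
        )

    def test_ratio_in_unit_interval_and_class_gap_recovered(self, toy_specs):
        m = synth_genome_contact_map(toy_specs, trans_level=1.0, noise_seed=10)
        # implant extra trans signal on a set of "non" bins
        weak = np.arange(5, 15)
        other = np.arange(m.chrom_slice(1).start, m.n_bins)
        m.counts[np.ix_(weak, other)] += 30.0
        m.counts[np.ix_(other, weak)] += 30.0
        labels = np.ones(m.n_bins, dtype=bool)
        labels[weak] = False
        df, means = cis_total(m, BinClassTrack(labels))
        r = df["cis_total"].to_numpy()
        assert np.all((r[np.isfinite(r)] >= 0) & (r[np.isfinite(r)] <= 1))
        assert means["rec8"] > means["non"]


class TestInsulation:
    def test_uniform_profile_zero(self, uniform_matrix):
        prof = insulation(uniform_matrix, half_window_bp=8000)
        ok = np.isfinite(prof.score)
        assert ok.any()
        assert np.allclose(prof.score[ok], 0.0, atol=1e-12)

    def test_matches_bruteforce(self, medium_spec):
        m = powerlaw_matrix(medium_spec, seed=11)
        m.mask[[10, 55]] = True
        prof = insulation(m, half_window_bp=10_000)
        _, oracle = brute_insulation(m, 10_000)
        np.testing.assert_allclose(prof.score, oracle, equal_nan=True)

    def test_two_masked_bins_undefine_window(self, medium_spec):
        m = powerlaw_matrix(medium_spec, seed=12)
        m.mask[[60, 62]] = True
        prof = insulation(m, half_window_bp=10_000)  # w = 5 bins
        assert np.isnan(prof.score[61])

    def test_block_boundary_is_minimum(self, medium_spec):
        m = ContactMatrix.zeros([medium_spec], 2000)
        # two dense blocks on the right arm (bins 40..70 and 70..100)
        m.counts[:] = 0.05
        m.counts[40:70, 40:70] = 1.0
        m.counts[70:100, 70:100] = 1.0
        prof = insulation(m, half_window_bp=10_000)
        right_arm = slice(40, 100)
        ok = np.isfinite(prof.score[right_arm])
        idx = np.nanargmin(prof.score[right_arm]) + 40
        assert idx in (69, 70)

    def test_window_must_be_whole_bins(self, uniform_matrix):
        with pytest.raises(ValueError):
            insulation(uniform_matrix, half_window_bp=2500)


class TestObservedOverExpected:
    def test_self_expectation_gives_ones(self, medium_spec):
        m = powerlaw_matrix(medium_spec)  # noise-free: counts == expectation model
        oe = observed_over_expected(m)
        # obs/exp of obs/exp is idempotent: re-dividing flat by flat stays 1
        spec2 = medium_spec
        m2 = ContactMatrix(np.nan_to_num(oe, nan=0.0), 2000, (spec2,))
        oe2 = observed_over_expected(m2)
        band = np.isfinite(oe2)
        assert np.allclose(oe2[band], 1.0, atol=1e-9)

    def test_matches_bruteforce(self, medium_spec):
        m = powerlaw_matrix(medium_spec, seed=13)
        m.mask[[7, 71]] = True
        np.testing.assert_allclose(
            observed_over_expected(m), brute_observed_over_expected(m), equal_nan=True
        )

    def test_planted_fourfold_peak(self, medium_spec):
        m = synth_contact_map(medium_spec, peak_anchor_pairs=[(50, 70)], peak_fold=4.0)
        oe = observed_over_expected(m)
        assert oe[50, 70] == pytest.approx(4.0, rel=0.05)


class TestAverageFeatureMap:
    def test_uniform_flat_patch(self, uniform_matrix):
        patch, n = average_feature_map(
            uniform_matrix, [("chrA", 30_000), ("chrB", 40_000)], "cis", flank_bp=6000
        )
        assert n == 2
        assert np.allclose(patch, 1.0)

    def test_edge_anchor_excluded(self, toy_specs):
        m = synth_genome_contact_map(toy_specs, trans_level=0.0)
        # one anchor too close to the chromosome start, one valid
        patch, n = average_feature_map(
            m, [("chrA", 2_000), ("chrA", 50_000)], "cis", flank_bp=10_000
        )
        assert n == 1
        with pytest.raises(ValueError):
            average_feature_map(m, [("chrA", 2_000)], "cis", flank_bp=10_000)

    def test_trans_telomere_enrichment_recovered(self, toy_specs):
        m = synth_genome_contact_map(toy_specs, trans_level=1.0)
        # implant tel-tel trans enrichment at right-arm ends
        aA = m.bin_index("chrA", 96_000)
        aB = m.bin_index("chrB", 76_000)
        m.counts[aA, aB] = m.counts[aB, aA] = 25.0
        patch, n = average_feature_map(
            m, [("chrA", 96_000), ("chrB", 76_000)], "trans", flank_bp=2000, within="arm"
        )
        assert n == 2
        f = patch.shape[0] // 2
        assert patch[f, f] > 2 * np.median(patch)


class TestSitePairPileup:
    def track(self, spec, positions):
        return BarrierTrack.from_arrays([spec.name] * len(positions), positions, [0.9] * len(positions))

    def test_no_enrichment_flat_zero(self, medium_spec):
        m = powerlaw_matrix(medium_spec)
        sites = self.track(medium_spec, np.arange(90_000, 190_000, 14_000))
        patch, n = site_pair_pileup(m, sites, separation_rank=1, flank_bp=6000)
        assert n > 0
        assert np.nanmax(np.abs(patch)) < 0.05

    def test_planted_adjacent_peaks_positive_centre(self, medium_spec):
        pos = np.arange(90_000, 190_000, 14_000)
        sites = self.track(medium_spec, pos)
        m0 = powerlaw_matrix(medium_spec)
        bins = [m0.bin_index("chrM", int(p)) for p in pos]
        pairs = [(bins[k], bins[k + 1]) for k in range(len(bins) - 1)]
        m = synth_contact_map(medium_spec, peak_anchor_pairs=pairs, peak_fold=3.0)
        patch, _ = site_pair_pileup(m, sites, separation_rank=1, flank_bp=6000)
        f = patch.shape[0] // 2
        # planted peaks share one bin distance and so inflate the expectation
        # there; the centre stays clearly positive and dominant
        assert np.log2(3.0) * 0.5 < patch[f, f] <= np.log2(3.0) + 0.05
        assert patch[f, f] > patch[0, 0] + 0.5

    def test_enrichment_decays_with_rank(self, medium_spec):
        pos = np.arange(90_000, 190_000, 10_000)
        sites = self.track(medium_spec, pos)
        m0 = powerlaw_matrix(medium_spec)
        bins = [m0.bin_index("chrM", int(p)) for p in pos]
        pairs, folds = [], {}
        for k in range(len(bins)):
            for r in (1, 2, 3):
                if k + r < len(bins):
                    pairs.append((bins[k], bins[k + r]))
                    folds[(bins[k], bins[k + r])] = 4.0 / r
        m = powerlaw_matrix(medium_spec)
        for (i, j), f in folds.items():
            m.counts[i, j] *= f
            m.counts[j, i] = m.counts[i, j]
        centres = []
        for r in (1, 2, 3):
            patch, _ = site_pair_pileup(m, sites, separation_rank=r, flank_bp=4000)
            centres.append(patch[patch.shape[0] // 2, patch.shape[1] // 2])
        assert centres[0] > centres[1] > centres[2]

    def test_shifted_sites_null_control(self, medium_spec):
        pos = np.arange(90_000, 190_000, 14_000)
        m0 = powerlaw_matrix(medium_spec)
        bins = [m0.bin_index("chrM", int(p)) for p in pos]
        pairs = [(bins[k], bins[k + 1]) for k in range(len(bins) - 1)]
        m = synth_contact_map(medium_spec, peak_anchor_pairs=pairs, peak_fold=3.0)
        shifted = self.track(medium_spec, (pos + 5_000))
        patch, _ = site_pair_pileup(m, shifted, separation_rank=1, flank_bp=2000)
        f = patch.shape[0] // 2
        on_target, _ = site_pair_pileup(m, self.track(medium_spec, pos), 1, flank_bp=2000)
        assert abs(patch[f, f]) < 0.3
        assert patch[f, f] < on_target[f, f] - 0.7

    def test_rank_zero_centres_single_sites(self, medium_spec):
        m = powerlaw_matrix(medium_spec)
        sites = self.track(medium_spec, np.arange(100_000, 180_000, 20_000))
        patch, n = site_pair_pileup(m, sites, separation_rank=0, flank_bp=6000)
        assert n == 4
        assert patch.shape == (7, 7)


class TestTssOrientationProfile:
    def test_single_tss_single_bin(self):
        tss = TSSAnnotation(
            pd.DataFrame({"chrom": ["c"], "pos": [10_250], "strand": ["+"]})
        )
        prof = tss_orientation_profile([("c", 10_000)], tss, flank_bp=2000)
        assert prof.plus.sum() == 1
        idx = np.searchsorted(prof.offsets_bp, 0, side="right") - 1
        assert prof.plus[idx] == 1  # offset +250 falls in bin [0, 500)
        assert prof.minus.sum() == 0

    def test_three_bin_smoothing(self):
        tss = TSSAnnotation(
            pd.DataFrame({"chrom": ["c"], "pos": [750], "strand": ["-"]})
        )
        prof = tss_orientation_profile([("c", 500)], tss, flank_bp=1500)
        # offset +250 lands in the [0, 500) bin, index 3 of 6
        np.testing.assert_allclose(prof.minus, [0, 0, 0, 1, 0, 0])
        np.testing.assert_allclose(prof.minus_smooth[2:5], [1 / 3, 1 / 3, 1 / 3])

    def test_convergent_bias_recovered(self, chr13_spec):
        from meioloop import sample_barrier_track, sample_tss_annotation

        barriers = sample_barrier_track(chr13_spec, 12_000, 0.95, seed=20)
        tss = sample_tss_annotation(
            chr13_spec, density_per_kb=0.3, convergent_bias_at=barriers, seed=21,
            bias_offset_bp=1000,
        )
        anchors = [("chr13", int(p)) for p in barriers.positions_for("chr13")]
        prof = tss_orientation_profile(anchors, tss, flank_bp=5000)
        mid = len(prof.offsets_bp) // 2
        # '+' enriched upstream of the anchor, '-' downstream
        assert prof.plus_smooth[:mid].sum() > 1.5 * prof.plus_smooth[mid:].sum()
        assert prof.minus_smooth[mid:].sum() > 1.5 * prof.minus_smooth[:mid].sum()

    def test_empty_anchors_rejected(self):
        with pytest.raises(ValueError):
            tss_orientation_profile([], TSSAnnotation.empty())
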