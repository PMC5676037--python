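import numpy as np
import pytest

from hupmap.chip_spatial import (
    ConfirmedPeak,
    ConfirmedPeakSet,
    annotate_peaks,
    confirm_peaks,
    density_profile,
    filter_by_enrichment,
    mean_interpeak_spacing,
    ori_ter_bias,
)
from hupmap.errors import ConfigurationError, InsufficientDataError, ValidationError
from hupmap.genome_io import Feature, GenomeContext

from conftest import make_peak


def set_from_midpoints(midpoints, width=100, L=None):
    """Build a ConfirmedPeakSet directly from midpoint coordinates."""
    peaks = []
    for i, m in enumerate(midpoints):
        s = int(m) - width // 2
        if L is not None:
            s = min(max(s, 0), L - width)
        peaks.append(ConfirmedPeak(f"p{i}", s, s + width, (), ()))
    return ConfirmedPeakSet(peaks)


# ---------------------------------------------------------------------------
# replicate confirmation
# ---------------------------------------------------------------------------

def confirm_oracle(rep1, rep2, control):
    """Independent fixed-point implementation: all-pairs intersections,
    order-independent merging, then control subtraction."""
    cands = []
    for p1 in rep1:
        for p2 in rep2:
            s, e = max(p1.start, p2.start), min(p1.end, p2.end)
            if s < e:
                cands.append((s, e))
    changed = True
    while changed:
        changed = False
        for i in range(len(cands)):
            for j in range(i + 1, len(cands)):
                (s1, e1), (s2, e2) = cands[i], cands[j]
                if s1 < e2 and s2 < e1:
                    cands[i] = (min(s1, s2), max(e1, e2))
                    cands.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(
        (s, e) for s, e in set(cands)
        if not any(s < c.end and c.start < e for c in control)
    )


class TestConfirmPeaks:
    def test_intersection_of_overlapping_replicates(self):
        out = confirm_peaks([make_peak(100, 200)], [make_peak(150, 250)], [])
        assert [(p.start, p.end) for p in out] == [(150, 200)]

    def test_control_overlap_removes_consensus(self):
        out = confirm_peaks(
            [make_peak(100, 200)], [make_peak(150, 250)], [make_peak(180, 300)]
        )
        assert out.n_confirmed == 0

    def test_no_replicate_overlap_gives_empty_set(self):
        out = confirm_peaks([make_peak(100, 200)], [make_peak(500, 600)], [])
        assert out.n_confirmed == 0

    def test_empty_replicate_warns_not_raises(self, caplog):
        out = confirm_peaks([], [make_peak(1, 2)], [])
        assert out.n_confirmed == 0

    def test_union_policy_widens_consensus(self):
        out = confirm_peaks(
            [make_peak(100, 200)], [make_peak(150, 250)], [], policy="union"
        )
        assert [(p.start, p.end) for p in out] == [(100, 250)]

    def test_provenance_records_contributing_intervals(self):
        a, b = make_peak(100, 200, 6.0, "rep1"), make_peak(150, 250, 5.2, "rep2")
        (p,) = confirm_peaks([a], [b], []).peaks
        assert p.rep1_intervals == (a,) and p.rep2_intervals == (b,)
        assert p.folds() == (6.0, 5.2)

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(200):
            def rand_set(n):
                out = []
                for _ in range(n):
                    s = int(rng.integers(0, 1900))
                    out.append(make_peak(s, s + int(rng.integers(10, 120))))
                return out
            rep1 = rand_set(int(rng.integers(0, 30)))
            rep2 = rand_set(int(rng.integers(0, 30)))
            ctrl = rand_set(int(rng.integers(0, 8)))
            got = [(p.start, p.end) for p in confirm_peaks(rep1, rep2, ctrl)]
            if not rep1 or not rep2:
                assert got == []
            else:
                assert sorted(got) == confirm_oracle(rep1, rep2, ctrl)


class TestFilterByEnrichment:
    def cps(self, f1, f2):
        a = make_peak(100, 200, f1, "rep1")
        b = make_peak(150, 250, f2, "rep2")
        return confirm_peaks([a], [b], [])

    def test_kept_when_both_clear_threshold(self):
        assert filter_by_enrichment(self.cps(6.0, 5.2), 5.0).n_confirmed == 1

    def test_dropped_when_one_replicate_below(self):
        assert filter_by_enrichment(self.cps(6.0, 4.9), 5.0, require_both=True).n_confirmed == 0

    def test_any_mode_keeps_single_passing_replicate(self):
        assert filter_by_enrichment(self.cps(6.0, 4.9), 5.0, require_both=False).n_confirmed == 1

    def test_zero_threshold_is_identity(self):
        assert filter_by_enrichment(self.cps(0.5, 0.1), 0.0).n_confirmed == 1

    def test_missing_fold_raises_configuration_error(self):
        cps = confirm_peaks([make_peak(100, 200)], [make_peak(150, 250)], [])
        with pytest.raises(ConfigurationError):
            filter_by_enrichment(cps, 5.0)


# ---------------------------------------------------------------------------
# spacing and density
# ---------------------------------------------------------------------------

class TestSpacing:
    def test_626_sites_on_7mb_circle_space_at_11kb(self, genome, rng):
        cps = set_from_midpoints(rng.uniform(0, 7e6, 626), L=genome.length_bp)
        spacing, gaps = mean_interpeak_spacing(cps, genome)
        assert spacing == pytest.approx(7_000_000 / 626)
        assert 10_500 < spacing < 11_500  # ~11,000-bp intervals
        assert gaps.sum() == pytest.approx(genome.length_bp)

    def test_single_peak_spans_whole_circle(self, genome):
        spacing, gaps = mean_interpeak_spacing(set_from_midpoints([1000]), genome)
        assert spacing == genome.length_bp
        assert list(gaps) == [genome.length_bp]

    def test_four_equally_spaced_peaks_have_equal_gaps(self, small_genome):
        ctx = GenomeContext("mini", 1000)
        cps = set_from_midpoints([125, 375, 625, 875], width=10, L=1000)
        _, gaps = mean_interpeak_spacing(cps, ctx)
        assert np.allclose(gaps, 250.0)

    def test_empty_set_rejected(self, genome):
        with pytest.raises(InsufficientDataError):
            mean_interpeak_spacing(ConfirmedPeakSet(), genome)

    def test_invariant_under_rotation(self, genome, rng):
        mids = rng.uniform(0, 7e6, 100)
        s1, _ = mean_interpeak_spacing(set_from_midpoints(mids, L=7_000_000), genome)
        rot = (mids + 1_234_567) % 7_000_000
        s2, _ = mean_interpeak_spacing(set_from_midpoints(rot, L=7_000_000), genome)
        assert s1 == pytest.approx(s2)


class TestDensityProfile:
    def test_inverse_gap_for_two_close_peaks(self, genome):
        cps = set_from_midpoints([10_000, 11_000])
        prof = density_profile(cps, genome)
        row = prof.per_peak.iloc[0]
        assert row.inv_gap == pytest.approx(1 / 1000)

    def test_peak_length_reported(self, genome):
        cps = ConfirmedPeakSet([ConfirmedPeak("p", 500, 1500, (), ())])
        prof = density_profile(cps, genome)
        assert prof.per_peak.length_bp.iloc[0] == 1000  # a "long" (>=1 kb) peak

    def test_uniform_grid_of_peaks_fills_bins_evenly(self):
        ctx = GenomeContext("c", 1_000_000)
        mids = np.arange(100) * 10_000 + 5_000
        prof = density_profile(set_from_midpoints(mids, L=ctx.length_bp), ctx, bin_bp=100_000)
        assert np.all(prof.bin_counts == 10)

    def test_bad_bin_size_rejected(self, genome):
        with pytest.raises(ValidationError):
            density_profile(set_from_midpoints([1]), genome, bin_bp=0)


# ---------------------------------------------------------------------------
# ori -> ter bias
# ---------------------------------------------------------------------------

class TestOriTerBias:
    def test_ori_proximal_clustering_detected(self, genome, rng):
        # all peaks in the oriC-proximal 10% of the circle
        mids = np.concatenate([
            rng.uniform(0, 0.05 * 7e6, 150),
            rng.uniform(0.95 * 7e6, 7e6, 150),
        ])
        res = ori_ter_bias(set_from_midpoints(mids, L=7_000_000), genome, seed=1)
        assert res.statistic < 0
        assert res.p_value < 0.05

    def test_uniform_peaks_give_null_statistic(self, genome, rng):
        mids = rng.uniform(0, 7e6, 500)
        res = ori_ter_bias(set_from_midpoints(mids, L=7_000_000), genome, seed=2)
        assert abs(res.statistic) < 0.3
        assert res.p_value > 0.01

    def test_mirror_image_flips_sign(self, genome, rng):
        mids = np.abs(rng.normal(0, 6e5, 300)) % 7e6
        cps = set_from_midpoints(mids, L=7_000_000)
        # reflect through the midpoint of the ori-ter axis: density now rises toward ter
        mirrored = (mids + 3_500_000) % 7_000_000
        cps_m = set_from_midpoints(mirrored, L=7_000_000)
        r1 = ori_ter_bias(cps, genome, seed=3)
        r2 = ori_ter_bias(cps_m, genome, seed=3)
        assert r1.statistic < 0 < r2.statistic

    def test_counts_sum_to_n_peaks(self, genome, rng):
        mids = rng.uniform(0, 7e6, 200)
        res = ori_ter_bias(set_from_midpoints(mids, L=7_000_000), genome, seed=4)
        assert res.bin_counts.sum() == 200
        assert -1 <= res.statistic <= 1 and 0 <= res.p_value <= 1

    def test_too_few_bins_rejected(self, genome):
        with pytest.raises(InsufficientDataError):
            ori_ter_bias(set_from_midpoints([5, 6]), genome, bin_bp=3_500_000, seed=0)

    def test_low_permutation_count_rejected(self, genome):
        with pytest.raises(ConfigurationError):
            ori_ter_bias(set_from_midpoints([5]), genome, n_perm=10, seed=0)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_oracle(peaks, features, L):
    """Base-pair-set enumeration of the promoter/gene-body predicates."""
    out = []
    for p in peaks:
        peak_bps = set(range(p.start, p.end))
        prom = False
        for f in features:
            if f.strand == "+":
                window = {(f.start - k) % L for k in range(1, 151)}
            else:
                window = {(f.end + k - 1) % L for k in range(1, 151)}
            if peak_bps & window:
                prom = True
                break
        body = any(f.start <= p.start and p.end <= f.end for f in features)
        if prom and body:
            out.append("mixed")
        elif prom:
            out.append("promoter")
        elif body:
            out.append("gene_body")
        else:
            out.append("intergenic")
    return out


class TestAnnotatePeaks:
    ctx = GenomeContext("mini", 10_000)

    def test_promoter_window_upstream_of_plus_strand_start(self):
        feats = [Feature("opA", 1000, 2000, "+")]
        anns, _ = annotate_peaks([make_peak(900, 940)], feats, self.ctx)
        assert anns[0].category == "promoter"
        assert anns[0].feature_id == "opA"

    def test_contained_peak_is_gene_body(self):
        feats = [Feature("opA", 1000, 2000, "+")]
        anns, _ = annotate_peaks([make_peak(1200, 1300)], feats, self.ctx)
        assert anns[0].category == "gene_body"

    def test_window_overlap_without_containment_is_promoter_not_mixed(self):
        feats = [Feature("opA", 1000, 2000, "+")]
        anns, _ = annotate_peaks([make_peak(900, 1300)], feats, self.ctx)
        assert anns[0].category == "promoter"

    def test_minus_strand_window_sits_downstream_of_end(self):
        feats = [Feature("opA", 1000, 2000, "-")]
        anns, _ = annotate_peaks([make_peak(2050, 2100)], feats, self.ctx)
        assert anns[0].category == "promoter"
        anns, _ = annotate_peaks([make_peak(900, 940)], feats, self.ctx)
        assert anns[0].category == "intergenic"

    def test_window_wraps_at_chromosome_edge(self):
        feats = [Feature("opA", 50, 600, "+")]  # window 9900..10000 + 0..50
        anns, _ = annotate_peaks([make_peak(9950, 9980)], feats, self.ctx)
        assert anns[0].category == "promoter"

    def test_tallies_are_fractions_summing_to_one(self):
        feats = [Feature("opA", 1000, 2000, "+")]
        peaks = [make_peak(900, 940), make_peak(1200, 1300), make_peak(5000, 5100)]
        anns, tallies = annotate_peaks(peaks, feats, self.ctx)
        assert sum(tallies.values()) == pytest.approx(1.0)
        assert len(anns) == 3

    def test_agrees_with_bp_set_oracle(self, rng):
        L = 10_000
        for _ in range(150):
            feats = []
            pos = int(rng.integers(0, 300))
            k = 0
            while pos < L - 600:
                k += 1
                length = int(rng.integers(200, 900))
                feats.append(
                    Feature(f"f{k}", pos, pos + length, "+" if rng.uniform() < 0.5 else "-")
                )
                pos += length + int(rng.integers(20, 300))
            peaks = []
            for _ in range(int(rng.integers(1, 30))):
                s = int(rng.integers(0, L - 200))
                peaks.append(make_peak(s, s + int(rng.integers(10, 200))))
            anns, _ = annotate_peaks(peaks, feats, self.ctx)
            assert [a.category for a in anns] == annotate_oracle(peaks, feats, L)

    def test_categories_exhaustive_and_exclusive(self, rng):
        feats = [Feature("opA", 1000, 2000, "+"), Feature("opB", 3000, 4500, "-")]
        peaks = [make_peak(int(s), int(s) + 50) for s in rng.integers(0, 9900, 200)]
        anns, tallies = annotate_peaks(peaks, feats, self.ctx)
        assert all(a.category in ("promoter", "gene_body", "intergenic", "mixed") for a in anns)
        assert sum(round(t * len(anns)) for t in tallies.values()) == len(anns)
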