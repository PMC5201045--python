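"""PWM scoring, scanning, presence, co-occurrence z-scores and spacing."""

import numpy as np
import pandas as pd
import pytest

from tfscape.intervals import GenomicInterval, IntervalSet
from tfscape.motifs import (
    BASES,
    MotifHit,
    PWM,
    cooccurrence_zscores,
    encode_sequence,
    filter_occupied,
    motif_presence_matrix,
    pwm_from_counts,
    read_jaspar,
    scan_sequence,
    spacing_distribution,
    write_jaspar,
)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq):
    return "".join(COMP[b] for b in reversed(seq))


def random_pwm(rng, length=None, name="M"):
    length = length or int(rng.integers(4, 9))
    counts = rng.integers(0, 20, size=(4, length)).astype(float)
    counts[rng.integers(0, 4), :] += 1  # avoid all-zero columns
    return PWM(name, counts)


def brute_scan(seq, pwm, threshold):
    """Exhaustive scoring of every window on both strands."""
    cut = threshold * pwm.max_score
    hits = []
    L = pwm.length
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for off in range(len(s) - L + 1):
            win = s[off:off + L]
            if "N" in win:
                continue
            score = sum(pwm.log_odds[BASES.index(b), j]
                        for j, b in enumerate(win))
            if score >= cut:
                start = off if strand == "+" else len(seq) - off - L
                hits.append((start, strand, round(score, 9)))
    return sorted(hits)


class TestPWM:
    def test_uniform_counts_uniform_background_zero_log_odds(self):
        pwm = pwm_from_counts("u", np.full((4, 5), 3.0))
        np.testing.assert_allclose(pwm.log_odds, 0.0, atol=1e-12)
        assert pwm.max_score == pytest.approx(0.0)

    def test_hand_arithmetic_single_column(self):
        counts = np.array([[8.0], [0.0], [0.0], [0.0]])
        pwm = pwm_from_counts("a", counts, pseudocount=1.0)
        # pA = 9/12 -> log2(0.75/0.25) = log2 3
        assert pwm.log_odds[0, 0] == pytest.approx(np.log2(3))

    def test_max_score_is_sum_of_column_maxima(self):
        rng = np.random.default_rng(0)
        pwm = random_pwm(rng)
        assert pwm.max_score == pytest.approx(pwm.log_odds.max(axis=0).sum())

    def test_zero_column_without_pseudocount_rejected(self):
        counts = np.zeros((4, 3))
        with pytest.raises(ValueError):
            pwm_from_counts("z", counts, pseudocount=0.0)

    def test_jaspar_round_trip(self, tmp_path, pwms):
        path = tmp_path / "m.jaspar"
        write_jaspar(pwms, path)
        back = read_jaspar(path)
        assert set(back) == set(pwms)
        for name in pwms:
            np.testing.assert_allclose(back[name].counts, pwms[name].counts)


class TestScanSequence:
    def test_unreachable_threshold_gives_no_hits(self):
        pwm = pwm_from_counts("a", np.array([[20, 20], [0, 0], [0, 0], [0, 0]]))
        assert scan_sequence("CCCCCCCC", pwm, threshold=1.0) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_window_scoring(self, seed):
        rng = np.random.default_rng(seed)
        pwm = random_pwm(rng)
        n = int(rng.integers(pwm.length, 1000))
        seq = "".join(rng.choice(list("ACGTN"), size=n,
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        threshold = float(rng.uniform(0.3, 0.95))
        if pwm.max_score <= 0:
            return
        hits = scan_sequence(seq, pwm, threshold=threshold)
        got = sorted((h.start, h.strand, round(h.score, 9)) for h in hits)
        assert got == brute_scan(seq, pwm, threshold)

    def test_reverse_complement_mirrors_hits(self):
        rng = np.random.default_rng(42)
        pwm = random_pwm(rng, length=5)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        fwd = scan_sequence(seq, pwm, threshold=0.6)
        rev = scan_sequence(revcomp(seq), pwm, threshold=0.6)
        mirrored = sorted(
            (len(seq) - h.end, {"+": "-", "-": "+"}[h.strand],
             round(h.score, 9))
            for h in fwd
        )
        assert mirrored == sorted(
            (h.start, h.strand, round(h.score, 9)) for h in rev)

    def test_windows_with_n_are_skipped(self):
        pwm = pwm_from_counts("a", np.array([[20, 20], [0, 0], [0, 0], [0, 0]]))
        assert scan_sequence("ANA", pwm, threshold=0.5) == []

    @pytest.mark.parametrize("threshold", [0.0, -0.5, 1.5])
    def test_invalid_threshold_rejected(self, threshold):
        pwm = pwm_from_counts("a", np.ones((4, 4)))
        with pytest.raises(ValueError):
            scan_sequence("ACGTACGT", pwm, threshold=threshold)


class TestPresenceMatrix:
    def test_no_hits_all_false(self):
        regions = IntervalSet([GenomicInterval("chr1", 0, 100)])
        mat = motif_presence_matrix(regions, {"m": []})
        assert not mat.to_numpy().any()

    def test_flush_hit_counts_as_contained(self):
        regions = IntervalSet([GenomicInterval("chr1", 10, 20)])
        flush = MotifHit("chr1", 14, 20, "m", "+", 1.0)
        hanging = MotifHit("chr1", 15, 21, "m2", "+", 1.0)
        mat = motif_presence_matrix(regions, {"m": [flush], "m2": [hanging]})
        assert bool(mat.at[0, "m"]) is True
        assert bool(mat.at[0, "m2"]) is False

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_containment(self, seed):
        rng = np.random.default_rng(seed)
        regions = IntervalSet(
            [GenomicInterval("chr1", int(s), int(s) + int(rng.integers(10, 60)))
             for s in rng.integers(0, 900, size=15)]
        )
        hits = {
            f"m{k}": [
                MotifHit("chr1", int(s), int(s) + 6, f"m{k}", "+", 1.0)
                for s in rng.integers(0, 950, size=20)
            ]
            for k in range(3)
        }
        mat = motif_presence_matrix(regions, hits)
        for i, iv in enumerate(regions):
            for name, hs in hits.items():
                expected = any(
                    h.start >= iv.start and h.end <= iv.end for h in hs)
                assert bool(mat.at[i, name]) is expected


def _regions_on_grid(n, start=0, width=60, step=200, chrom="chr1"):
    return IntervalSet(
        [GenomicInterval(chrom, start + i * step, start + i * step + width)
         for i in range(n)]
    )


class TestCooccurrence:
    def _planted_instance(self):
        """A pair planted in every fg footprint, absent from bg."""
        fg = _regions_on_grid(30)
        bg = _regions_on_grid(60, start=30 * 200 + 1000)
        hits = {"A": [], "B": [], "C": []}
        for iv in fg:
            hits["A"].append(MotifHit("chr1", iv.start + 5, iv.start + 11,
                                      "A", "+", 1.0))
            hits["B"].append(MotifHit("chr1", iv.start + 25, iv.start + 31,
                                      "B", "+", 1.0))
        rng = np.random.default_rng(0)
        for iv in bg:  # C occurs alone everywhere
            hits["C"].append(MotifHit("chr1", iv.start + 10, iv.start + 16,
                                      "C", "+", 1.0))
        return fg, bg, hits

    def test_planted_pair_scores_high(self):
        fg, bg, hits = self._planted_instance()
        res = cooccurrence_zscores(fg, bg, hits, window=50, n_subsamples=200,
                                   seed=1)
        assert res.pair("A", "B")["observed"] == 30
        z = res.z.at["A", "B"]
        assert not np.isfinite(z) or z > 5

    def test_matrix_is_symmetric(self, small_landscape, pwms):
        from tfscape.motifs import scan_genome

        ls = small_landscape
        hits = scan_genome(ls.sequences(), pwms, threshold=0.8)
        res = cooccurrence_zscores(ls.fg_footprints, ls.bg_regions, hits,
                                   n_subsamples=50, seed=2)
        for df in (res.observed, res.bg_mean, res.bg_sd):
            np.testing.assert_allclose(df.to_numpy(), df.to_numpy().T)

    def test_zero_sd_at_mean_is_zero_z(self):
        fg = _regions_on_grid(5)
        bg = _regions_on_grid(10, start=3000)
        # one motif never pairs: observed 0, every subsample 0 -> z = 0
        hits = {"A": [MotifHit("chr1", 5, 11, "A", "+", 1.0)],
                "B": [MotifHit("chr1", 3005, 3011, "B", "+", 1.0)]}
        res = cooccurrence_zscores(fg, bg, hits, n_subsamples=20, seed=3)
        assert res.z.at["A", "B"] == 0.0
        assert not res.flagged.at["A", "B"]

    def test_motif_label_permutation_permutes_result(self):
        fg, bg, hits = self._planted_instance()
        res1 = cooccurrence_zscores(fg, bg, hits, n_subsamples=100, seed=5)
        permuted = {"C": hits["C"], "A": hits["A"], "B": hits["B"]}
        res2 = cooccurrence_zscores(fg, bg, permuted, n_subsamples=100, seed=5)
        names = res1.z.index
        np.testing.assert_allclose(
            res1.z.loc[names, names].to_numpy(),
            res2.z.loc[names, names].to_numpy(),
        )

    def test_input_validation(self):
        fg = _regions_on_grid(5)
        bg = _regions_on_grid(3, start=3000)
        hits = {"A": []}
        with pytest.raises(ValueError, match="background"):
            cooccurrence_zscores(fg, bg, hits)
        with pytest.raises(ValueError, match="n_subsamples"):
            cooccurrence_zscores(fg, _regions_on_grid(10, start=3000), hits,
                                 n_subsamples=1)

    def test_seeded_draws_reproducible(self):
        fg, bg, hits = self._planted_instance()
        a = cooccurrence_zscores(fg, bg, hits, n_subsamples=50, seed=9)
        b = cooccurrence_zscores(fg, bg, hits, n_subsamples=50, seed=9)
        np.testing.assert_allclose(a.z.to_numpy(), b.z.to_numpy())


class TestSpacing:
    def test_worked_example_seven_bp_both_orientations(self):
        anchor_plus = MotifHit("chr1", 100, 106, "T", "+", 1.0)
        partner_plus = MotifHit("chr1", 113, 120, "A", "+", 1.0)
        res = spacing_distribution([anchor_plus], [partner_plus], max_dist=100)
        assert res.mode == 7
        # mirrored: - strand anchor, partner upstream on the genome
        anchor_minus = MotifHit("chr1", 200, 206, "T", "-", 1.0)
        partner_minus = MotifHit("chr1", 186, 193, "A", "-", 1.0)
        res = spacing_distribution([anchor_minus], [partner_minus],
                                   max_dist=100)
        assert res.mode == 7

    def test_start_to_start_convention(self):
        anchor = MotifHit("chr1", 100, 106, "T", "+", 1.0)
        partner = MotifHit("chr1", 113, 120, "A", "+", 1.0)
        res = spacing_distribution([anchor], [partner], max_dist=100,
                                   anchor_convention="start_to_start")
        assert res.mode == 13

    def test_empty_histogram_mode_is_undefined_not_zero(self):
        anchor = MotifHit("chr1", 100, 106, "T", "+", 1.0)
        res = spacing_distribution([anchor], [], max_dist=100)
        assert res.n_pairs == 0
        assert res.mode is None

    def test_mode_tie_breaks_to_smallest_absolute_distance(self):
        anchor = MotifHit("chr1", 100, 106, "T", "+", 1.0)
        partners = [MotifHit("chr1", 106 + d, 113 + d, "A", "+", 1.0)
                    for d in (-9, 3)]
        res = spacing_distribution([anchor], partners, max_dist=100)
        assert res.mode == 3

    def test_planted_spacing_recovered_over_noise(self):
        rng = np.random.default_rng(4)
        anchors, partners = [], []
        for i in range(300):
            s = 1000 * i
            strand = "+" if rng.random() < 0.5 else "-"
            anchors.append(MotifHit("chr1", s, s + 6, "T", strand, 1.0))
            if strand == "+":
                partners.append(MotifHit("chr1", s + 6 + 9, s + 6 + 16, "A",
                                         strand, 1.0))
            else:
                partners.append(MotifHit("chr1", s - 9 - 7, s - 9, "A",
                                         strand, 1.0))
            # uniform partner noise
            d = int(rng.integers(-80, 80))
            partners.append(MotifHit("chr1", s + d, s + d + 7, "A", "+", 1.0))
        res = spacing_distribution(anchors, partners, max_dist=100)
        assert res.mode == 9

    def test_invariant_under_global_shift(self):
        rng = np.random.default_rng(6)
        anchors = [MotifHit("chr1", int(s), int(s) + 6, "T",
                            "+" if rng.random() < 0.5 else "-", 1.0)
                   for s in rng.integers(1000, 50_000, size=50)]
        partners = [MotifHit("chr1", int(s), int(s) + 7, "A", "+", 1.0)
                    for s in rng.integers(1000, 50_000, size=80)]
        base = spacing_distribution(anchors, partners)
        shift = 1234
        a2 = [MotifHit(h.chrom, h.start + shift, h.end + shift, h.motif,
                       h.strand, h.score) for h in anchors]
        p2 = [MotifHit(h.chrom, h.start + shift, h.end + shift, h.motif,
                       h.strand, h.score) for h in partners]
        shifted = spacing_distribution(a2, p2)
        assert base.counts.tolist() == shifted.counts.tolist()

    def test_invariant_under_reverse_complementing_landscape(self):
        rng = np.random.default_rng(7)
        size = 100_000
        flip = {"+": "-", "-": "+"}
        anchors = [MotifHit("chr1", int(s), int(s) + 6, "T",
                            "+" if rng.random() < 0.5 else "-", 1.0)
                   for s in rng.integers(1000, 50_000, size=50)]
        partners = [MotifHit("chr1", int(s), int(s) + 7, "A",
                             "+" if rng.random() < 0.5 else "-", 1.0)
                    for s in rng.integers(1000, 50_000, size=80)]
        base = spacing_distribution(anchors, partners)

        def rc(h):
            return MotifHit(h.chrom, size - h.end, size - h.start, h.motif,
                            flip[h.strand], h.score)

        rced = spacing_distribution([rc(h) for h in anchors],
                                    [rc(h) for h in partners])
        assert base.counts.tolist() == rced.counts.tolist()


class TestFilterOccupied:
    def test_keeps_only_hits_overlapping_regions(self):
        regions = IntervalSet([GenomicInterval("chr1", 100, 150)])
        hits = {"m": [MotifHit("chr1", 95, 101, "m", "+", 1.0),
                      MotifHit("chr1", 200, 206, "m", "+", 1.0)]}
        out = filter_occupied(hits, regions)
        assert [h.start for h in out["m"]] == [95]
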