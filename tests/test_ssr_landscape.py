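import itertools
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pitanga.io_formats import GenomicInterval, PipelineConfig
from pitanga.ssr_landscape import (
    canonical_class, chi2_class_bias, classify_transcribed, density_per_mb,
    detect_ssrs, detect_ssrs_bruteforce, is_primitive, landscape_summary,
    merge_loci, reverse_complement,
)
from pitanga.synthetic_data import SimParams, simulate_genome

motif_st = st.text(alphabet="ACGT", min_size=1, max_size=6).filter(is_primitive)


class TestCanonicalClass:
    @pytest.mark.parametrize("motif, label", [
        ("GA", "AG/CT"),
        ("TTC", "AAG/CTT"),
        ("A", "A/T"),
        ("AT", "AT/AT"),
        ("AC", "AC/GT"),
    ])
    def test_known_labels(self, motif, label):
        assert canonical_class(motif) == label

    def test_exhaustive_class_counts(self):
        """4 dinucleotide and 10 trinucleotide classes exist."""
        def classes(k):
            return {canonical_class("".join(m))
                    for m in itertools.product("ACGT", repeat=k)
                    if is_primitive("".join(m))}
        assert classes(2) == {"AC/GT", "AG/CT", "AT/AT", "CG/CG"}
        assert len(classes(3)) == 10

    @given(motif_st, st.integers(0, 5))
    @settings(max_examples=200, derandomize=True)
    def test_rotation_and_revcomp_invariance(self, motif, shift):
        rotated = motif[shift % len(motif):] + motif[:shift % len(motif)]
        assert canonical_class(rotated) == canonical_class(motif)
        assert canonical_class(reverse_complement(motif)) == canonical_class(motif)

    @given(motif_st)
    @settings(max_examples=100, derandomize=True)
    def test_idempotent_under_recanonicalization(self, motif):
        x, y = canonical_class(motif).split("/")
        assert canonical_class(x) == f"{x}/{y}"

    def test_invalid_motifs_rejected(self):
        with pytest.raises(ValueError):
            canonical_class("ATAT")  # not primitive
        with pytest.raises(ValueError):
            canonical_class("AXT")


class TestDetect:
    def test_dinucleotide_at_threshold(self):
        recs = detect_ssrs("s", "ACACACACACAC")
        assert [(r.motif, r.n_repeats, r.interval.start, r.interval.end)
                for r in recs] == [("AC", 6, 0, 12)]

    def test_below_threshold_not_reported(self):
        assert detect_ssrs("s", "ACACACACAC") == []

    def test_primitive_motif_assignment(self):
        # AT x 8 must come out with motif AT, never ATAT or ATATAT
        recs = detect_ssrs("s", "G" * 5 + "AT" * 8 + "G" * 5)
        assert [(r.motif, r.n_repeats) for r in recs] == [("AT", 8)]

    def test_partial_trailing_unit_truncated(self):
        recs = detect_ssrs("s", "ACACACACACACA")  # AC x 6 + A
        (r,) = recs
        assert (r.interval.start, r.interval.end, r.n_repeats) == (0, 12, 6)

    def test_n_breaks_runs(self):
        assert detect_ssrs("s", "ACACACNACACAC") == []
        recs = detect_ssrs("s", "AC" * 6 + "N" + "AC" * 6)
        simple = [r for r in recs if not r.is_compound]
        assert len(simple) == 2

    def test_compound_within_interruption(self):
        seq = "AC" * 6 + "GTTGATCGGT" + "AG" * 6
        recs = detect_ssrs("s", seq)
        compound = [r for r in recs if r.is_compound]
        assert len(compound) == 1
        assert len(compound[0].members) == 2
        assert (compound[0].interval.start, compound[0].interval.end) == (0, 34)

    def test_no_compound_beyond_interruption(self):
        cfg = PipelineConfig()
        gap = "GTTGATCGGTTACGGATCGA" * 6  # 120 bp, no repeats
        seq = "AC" * 6 + gap + "AG" * 6
        recs = detect_ssrs("s", seq, cfg)
        assert not any(r.is_compound for r in recs)

    def test_empty_and_short_sequences(self):
        assert detect_ssrs("s", "") == []
        assert detect_ssrs("s", "ACGT") == []

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_on_random_sequence(self, seed):
        import numpy as np
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=8000)) + "AC" * 7 + "TTA" * 6
        fast = [(r.interval.start, r.interval.end, r.motif)
                for r in detect_ssrs("s", seq) if not r.is_compound]
        slow = [(r.interval.start, r.interval.end, r.motif)
                for r in detect_ssrs_bruteforce("s", seq)]
        assert fast == slow

    def test_strand_consistency_of_classes(self):
        import numpy as np
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=3000)) \
            + "AG" * 9 + "TTTTTTTTTTTT" + "CAT" * 7
        fwd = Counter(r.motif_class for r in detect_ssrs("s", seq)
                      if not r.is_compound)
        rev = Counter(r.motif_class
                      for r in detect_ssrs("s", reverse_complement(seq))
                      if not r.is_compound)
        assert fwd == rev

    def test_planted_truth_recovery(self, small_sim_params):
        entries, truth, _, _ = simulate_genome(small_sim_params, seed=5)
        detected = set()
        for name, seq in entries:
            for r in detect_ssrs(name, seq):
                if not r.is_compound:
                    detected.add((name, r.interval.start, r.motif, r.n_repeats))
        assert set(map(tuple, truth.planted_ssrs)) <= detected


def _rec(start, motif, reps, seq_id="chr1"):
    from pitanga.ssr_landscape import SSRRecord
    return SSRRecord(GenomicInterval(seq_id, start, start + len(motif) * reps),
                     motif, reps)


class TestMergeLoci:
    def test_same_motif_within_window_merges(self):
        loci = merge_loci([_rec(0, "AC", 6), _rec(62, "AC", 6)], 100)
        assert len(loci) == 1
        assert len(loci[0].members) == 2
        assert (loci[0].interval.start, loci[0].interval.end) == (0, 74)

    def test_beyond_window_stays_separate(self):
        assert len(merge_loci([_rec(0, "AC", 6), _rec(162, "AC", 6)], 100)) == 2

    def test_different_motifs_never_merge(self):
        assert len(merge_loci([_rec(0, "AC", 6), _rec(62, "AG", 6)], 100)) == 2

    def test_idempotent_and_order_independent(self):
        records = [_rec(0, "AC", 6), _rec(50, "AC", 7), _rec(300, "AC", 6),
                   _rec(20, "AG", 8, "chr2")]
        key = lambda l: (l.interval.seq_id, l.interval.start, l.motif)
        a = sorted(merge_loci(records, 100), key=key)
        b = sorted(merge_loci(records[::-1], 100), key=key)
        assert [(l.interval.start, l.interval.end, len(l.members)) for l in a] \
            == [(l.interval.start, l.interval.end, len(l.members)) for l in b]
        assert sum(len(l.members) for l in a) == len(records)


class TestClassifyTranscribed:
    def test_overlap_flags_transcribed(self):
        loci = merge_loci([_rec(100, "AC", 6)], 100)
        out = classify_transcribed(loci, [GenomicInterval("chr1", 0, 500)])
        assert out[0].transcribed

    def test_half_open_touching_is_no_overlap(self):
        loci = merge_loci([_rec(100, "AC", 6)], 100)
        out = classify_transcribed(loci, [GenomicInterval("chr1", 112, 500)])
        assert not out[0].transcribed

    def test_no_transcripts_all_false(self):
        loci = merge_loci([_rec(100, "AC", 6)], 100)
        assert not classify_transcribed(loci, [])[0].transcribed


class TestLandscapeSummary:
    def test_printed_table_arithmetic(self):
        per_class = {"Di": 38239, "Tri": 13243, "Tetra": 1533,
                     "Penta": 607, "Hexa": 465}
        compound = 932
        total = sum(per_class.values()) + compound
        assert total == 55019
        assert density_per_mb(total, 385104457) == 142.87

    def test_single_ssr_density(self):
        assert density_per_mb(1, 10**6) == 1.00

    def test_summary_matches_bruteforce_recount(self, small_sim_params):
        entries, _, _, _ = simulate_genome(small_sim_params, seed=2)
        records = [r for name, seq in entries for r in detect_ssrs(name, seq)]
        loci = merge_loci([r for r in records if not r.is_compound], 100)
        genome = sum(len(s) for _, s in entries)
        summary = landscape_summary(records, loci, genome)
        compounds = [r for r in records if r.is_compound]
        absorbed = {id(m) for c in compounds for m in c.members}
        free = [r for r in records if not r.is_compound
                and id(r) not in absorbed and len(r.motif) > 1]
        counted_compounds = [c for c in compounds
                             if any(len(m.motif) > 1 for m in c.members)]
        assert summary.total_ssrs == len(free) + len(counted_compounds)
        assert summary.n_compound == len(counted_compounds)
        for k in range(2, 7):
            assert summary.counts_by_motif_length[k] == \
                sum(1 for r in free if len(r.motif) == k)
        assert sum(summary.counts_by_motif_length.values()) \
            + summary.n_compound == summary.total_ssrs
        assert summary.density_per_mb == round(summary.total_ssrs / (genome / 1e6), 2)

    def test_monomers_excluded_by_default(self):
        records = [_rec(0, "A", 12), _rec(100, "AC", 6)]
        loci = merge_loci(records, 100)
        summary = landscape_summary(records, loci, 10**6)
        assert summary.total_ssrs == 1
        assert 1 not in summary.counts_by_motif_length
        incl = landscape_summary(records, loci, 10**6, include_monomers=True)
        assert incl.total_ssrs == 2

    def test_invalid_genome_size(self):
        with pytest.raises(ValueError):
            landscape_summary([], [], 0)


class TestChi2ClassBias:
    def test_identical_split_gives_zero_stat(self):
        counts = {"AC/GT": (20, 80), "AG/CT": (200, 800)}
        results = {r.motif_class: r for r in chi2_class_bias(counts)}
        assert results["AC/GT"].stat == pytest.approx(0.0)
        assert results["AC/GT"].p == pytest.approx(1.0)

    def test_matches_hand_computed_chisquare(self):
        # division totals: 250 transcribed / 850 untranscribed
        counts = {"AC/GT": (50, 50), "AG/CT": (200, 800)}
        div_frac = 250 / 1100
        expected_t, expected_u = 100 * div_frac, 100 * (1 - div_frac)
        stat = (50 - expected_t) ** 2 / expected_t \
            + (50 - expected_u) ** 2 / expected_u
        res = {r.motif_class: r for r in chi2_class_bias(counts)}
        assert res["AC/GT"].stat == pytest.approx(stat)
        assert res["AC/GT"].p == pytest.approx(float(stats.chi2.sf(stat, 1)))

    def test_low_representation_excluded(self):
        counts = {"AC/GT": (2, 2), "AG/CT": (300, 700)}  # 4/1004 = 0.4%
        res = {r.motif_class: r for r in chi2_class_bias(counts)}
        assert not res["AC/GT"].tested
        assert res["AG/CT"].tested

    def test_divisions_tested_separately(self):
        counts = {"AC/GT": (10, 90), "AAG/CTT": (90, 10)}
        res = chi2_class_bias(counts)
        # each class IS its whole division, so no deviation is possible
        assert all(r.stat == pytest.approx(0.0) for r in res if r.tested)
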