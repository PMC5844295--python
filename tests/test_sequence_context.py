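import math

import numpy as np
import pytest

from replicheck.io_formats import HET, HOM_ALT, GenomeSequence, VariantCall, revcomp
from replicheck.sequence_context import (
    ContextWindow,
    GenomeIndex,
    build_profile,
    cg_dinucleotide_content,
    deviation_profile,
    extract_windows,
    paralog_forensics,
    pct_change,
    revcomp_fold,
    sample_random_centers,
    transcript_mutation_stats,
    ungapped_scan,
)


def brute_force_scan(window, genome, max_mismatches):
    """Slide the query over every genome offset on both strands."""
    hits = []
    L = len(window.sequence)
    source_start0 = window.center_pos - 1 - window.flank
    for strand, qseq in (("+", window.sequence), ("-", revcomp(window.sequence))):
        q = np.frombuffer(qseq.encode(), dtype=np.uint8)
        for chrom, seq in genome.items():
            g = np.frombuffer(seq.encode(), dtype=np.uint8)
            if len(g) < L:
                continue
            from numpy.lib.stride_tricks import sliding_window_view

            wins = sliding_window_view(g, L)
            mism = (wins != q).sum(axis=1)
            has_n = (wins == ord("N")).any(axis=1)
            for start in np.nonzero((mism <= max_mismatches) & ~has_n)[0]:
                if (
                    strand == "+"
                    and chrom == window.chrom
                    and int(start) == source_start0
                ):
                    continue
                offs = np.nonzero(wins[start] != q)[0]
                if strand == "-":
                    offs = sorted(L - 1 - int(i) for i in offs)
                hits.append(
                    (chrom, int(start) + 1, strand, tuple(int(i) for i in offs))
                )
    return set(hits)


def _align_key(a):
    return (a.subject_chrom, a.subject_start, a.strand, a.mismatch_offsets)


class TestExtractWindows:
    def test_direct_slice_centered_on_position(self):
        genome = GenomeSequence({"c": "AAAGAAA"})
        windows, _ = extract_windows(genome, [("c", 4)], flank=2)
        (w,) = windows
        assert w.sequence == "AAGAA" and w.center_base == "G"

    def test_truncated_window_dropped(self):
        genome = GenomeSequence({"c": "ACGTACGTACGT"})
        windows, dropped = extract_windows(genome, [("c", 1)], flank=10)
        assert windows == [] and dropped["truncated"] == 1

    def test_n_window_and_off_contig_dropped(self):
        genome = GenomeSequence({"c": "AAANGAA"})
        windows, dropped = extract_windows(
            genome, [("c", 5), ("c", 99)], flank=2
        )
        assert windows == []
        assert dropped["contains_n"] == 1 and dropped["off_contig"] == 1


class TestRandomCenters:
    def test_error_when_base_absent(self):
        genome = GenomeSequence({"c": "AAAA"})
        with pytest.raises(ValueError):
            sample_random_centers(genome, "G", 1, seed=0)

    def test_n_equals_population_returns_all(self):
        genome = GenomeSequence({"c": "AGGA", "d": "GAAG"})
        got = sample_random_centers(genome, "G", 4, seed=0)
        assert sorted(got) == [("c", 2), ("c", 3), ("d", 1), ("d", 4)]

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(7)
        genome = GenomeSequence(
            {"c": "".join(rng.choice(list("ACGT"), size=2000))}
        )
        a = sample_random_centers(genome, "G", 50, seed=5)
        b = sample_random_centers(genome, "G", 50, seed=5)
        assert a == b

    def test_offset_frequencies_match_full_enumeration(self):
        """A large sample reproduces the genome-wide conditional base
        frequency one base downstream of G, computed by enumeration."""
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=100_000, p=[0.3, 0.2, 0.2, 0.3]))
        genome = GenomeSequence({"c": seq})
        # enumeration oracle: all G positions with a full window
        all_g = [
            ("c", i + 1)
            for i in range(len(seq))
            if seq[i] == "G" and 2 <= i <= len(seq) - 3
        ]
        def freq_c_at_plus1(positions):
            ws, _ = extract_windows(genome, positions, flank=2)
            prof = build_profile(ws)
            return prof.count(+1, "C") / prof.n_windows

        oracle = freq_c_at_plus1(all_g)
        sampled = sample_random_centers(genome, "G", 15_000, seed=2)
        assert freq_c_at_plus1(sampled) == pytest.approx(oracle, abs=0.02)


class TestProfiles:
    def _windows(self, seqs, base="G"):
        return [
            ContextWindow(chrom="c", center_pos=10 * i + 5, sequence=s)
            for i, s in enumerate(seqs)
        ]

    def test_rows_sum_to_n_windows(self):
        prof = build_profile(self._windows(["AAGCC", "CTGGA", "GGGTT"]))
        assert (prof.counts.sum(axis=1) == prof.n_windows).all()

    def test_self_deviation_identically_zero(self):
        prof = build_profile(self._windows(["AAGCC", "CTGGA"]))
        dev = deviation_profile(prof, prof)
        assert (dev.fillna(0).to_numpy() == 0).all()

    def test_unequal_sample_sizes_rejected(self):
        a = build_profile(self._windows(["AAGCC", "CTGGA"]))
        b = build_profile(self._windows(["AAGCC"]))
        with pytest.raises(ValueError):
            deviation_profile(a, b)

    def test_zero_random_count_is_nan(self):
        mut = build_profile(self._windows(["CAGCC"]))
        rand = build_profile(self._windows(["AAGCC"]))
        dev = deviation_profile(mut, rand)
        assert math.isnan(dev.loc[-2, "C"])

    def test_fold_maps_counts_to_complement_positions(self):
        prof = build_profile(self._windows(["CACTA"], base="C"))
        folded = revcomp_fold(prof)
        assert folded.center_base == "G"
        # count(-1, C) in the C profile equals count(+1, G) after folding
        assert prof.count(-1, "A") == folded.count(+1, "T")
        assert prof.count(-2, "C") == folded.count(+2, "G")

    def test_fold_is_involution(self):
        prof = build_profile(self._windows(["AAGCC", "CTGGA", "GGGTT"]))
        back = revcomp_fold(revcomp_fold(prof))
        assert back.center_base == prof.center_base
        assert (back.counts == prof.counts).all()

    def test_folded_c_profile_approximates_g_profile(self):
        """Under a strand-symmetric background the folded C-profile matches
        the G-profile within binomial error."""
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=60_000))
        genome = GenomeSequence({"c": seq})
        n = 4000
        g_pos = sample_random_centers(genome, "G", n, seed=1)
        c_pos = sample_random_centers(genome, "C", n, seed=2)
        g_prof = build_profile(extract_windows(genome, g_pos, 5)[0])
        c_prof = build_profile(extract_windows(genome, c_pos, 5)[0])
        folded = revcomp_fold(c_prof)
        # frequencies agree within ~5 sigma of binomial sampling error
        p = 0.25
        sigma = math.sqrt(p * (1 - p) / n)
        diff = np.abs(folded.counts / n - g_prof.counts / n)
        assert (diff < 5 * sigma + 0.01).all()


class TestPctChange:
    def test_population_scale_operands(self):
        assert round(pct_change(99_332, 127_287)) == 28
        assert round(pct_change(141_485, 186_396)) == 32
        assert round(pct_change(144_587, 106_292)) == -26
        assert round(pct_change(139_477, 192_222)) == 38

    def test_zero_reference_undefined(self):
        assert math.isnan(pct_change(0, 5))


class TestCgContent:
    def test_small_examples(self):
        assert cg_dinucleotide_content(["CGCG"]) == pytest.approx(2 / 3)
        assert cg_dinucleotide_content(["AAAA"]) == 0.0

    def test_matches_brute_force_on_toy_genome(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        expected = sum(
            1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"
        ) / (len(seq) - 1)
        assert cg_dinucleotide_content([seq]) == pytest.approx(expected)


def _plant(seq_arr, rng, src_start, dst_start, L, n_mismatch, central=None):
    """Copy a window and mutate n_mismatch offsets (central optionally)."""
    window = seq_arr[src_start : src_start + L].copy()
    offsets = set()
    if central is not None:
        offsets.add(central)
    while len(offsets) < n_mismatch:
        offsets.add(int(rng.integers(L)))
    for off in offsets:
        window[off] = (window[off] + 1 + rng.integers(3)) % 4
    seq_arr[dst_start : dst_start + L] = window


class TestUngappedScan:
    def _toy(self, size=20_000, seed=13):
        rng = np.random.default_rng(seed)
        return rng.integers(0, 4, size=size, dtype=np.uint8), rng

    def test_verbatim_copy_gives_perfect_alignment(self):
        arr, rng = self._toy()
        _plant(arr, rng, 1000, 5000, 51, 0)
        genome = GenomeSequence({"c": "".join("ACGT"[b] for b in arr)})
        w = ContextWindow("c", 1026, genome["c"][1000:1051])
        hits = ungapped_scan([w], genome, max_mismatches=3)
        perfect = [h for h in hits if h.n_mismatches == 0]
        assert any(h.subject_start == 5001 for h in perfect)

    def test_planted_central_mismatch_detected(self):
        arr, rng = self._toy(seed=14)
        _plant(arr, rng, 2000, 9000, 51, 1, central=25)
        genome = GenomeSequence({"c": "".join("ACGT"[b] for b in arr)})
        w = ContextWindow("c", 2026, genome["c"][2000:2051])
        hits = [
            h
            for h in ungapped_scan([w], genome, max_mismatches=3)
            if h.subject_start == 9001
        ]
        (h,) = hits
        assert h.central_mismatch and h.mismatch_offsets == (25,)

    def test_minus_strand_hit_reports_query_coordinates(self):
        arr, rng = self._toy(seed=15)
        genome_fwd = "".join("ACGT"[b] for b in arr)
        query = genome_fwd[3000:3051]
        planted = revcomp(query)
        seq = genome_fwd[:12_000] + planted + genome_fwd[12_000 + 51 :]
        genome = GenomeSequence({"c": seq})
        w = ContextWindow("c", 3026, seq[3000:3051])
        assert seq[3000:3051] == query  # planting far away kept the source
        hits = [
            h
            for h in ungapped_scan([w], genome, max_mismatches=1)
            if h.strand == "-"
        ]
        assert any(
            h.subject_start == 12_001 and h.n_mismatches == 0 for h in hits
        )

    def test_query_with_n_skipped(self):
        genome = GenomeSequence({"c": "ACGT" * 40})
        w = ContextWindow("c", 26, "N" * 51)
        assert ungapped_scan([w], genome, max_mismatches=3) == []

    def test_too_short_query_rejected(self):
        genome = GenomeSequence({"c": "ACGT" * 40})
        w = ContextWindow("c", 26, genome["c"][0:51])
        with pytest.raises(ValueError):
            ungapped_scan([w], genome, word_size=11, max_mismatches=4)

    def test_equals_brute_force_on_toy_genome(self):
        """Seed-and-verify returns exactly the exhaustive-slide result."""
        arr, rng = self._toy(size=30_000, seed=16)
        for i, (n_mm, central) in enumerate(
            [(0, None), (1, 25), (2, 25), (3, None), (2, None)]
        ):
            _plant(arr, rng, 500 + 600 * i, 15_000 + 200 * i, 51, n_mm, central)
        genome = GenomeSequence({"c": "".join("ACGT"[b] for b in arr)})
        index = GenomeIndex(genome, word_size=11)
        for i in range(5):
            start = 500 + 600 * i
            w = ContextWindow("c", start + 26, genome["c"][start : start + 51])
            got = {
                _align_key(a)[:4]
                for a in ungapped_scan([w], index, max_mismatches=3)
            }
            expected = brute_force_scan(w, genome, max_mismatches=3)
            assert got == expected


class TestParalogForensics:
    def test_position_with_no_alignment_is_all_zero(self):
        rng = np.random.default_rng(21)
        genome = GenomeSequence(
            {"c": "".join(rng.choice(list("ACGT"), size=2000))}
        )
        summaries, totals = paralog_forensics(
            [("c", 1000, "A")], genome, max_mismatches=1
        )
        (s,) = summaries
        assert s.n_global_alignments == 0 and not s.snp_allele_concordant
        assert totals["n_with_alignment"] == 0

    def test_planted_errors_more_concordant_than_random(self, small_sim):
        """Positions whose false calls come from a divergent paralog carry
        the called allele at the paralog's central base far more often
        than random positions do."""
        truth = small_sim.truth
        err_positions = [(e.chrom, e.pos, e.alt) for e in truth.errors]
        rng = np.random.default_rng(5)
        random_positions = [
            (chrom, pos, None)
            for chrom, pos in zip(
                rng.choice(small_sim.genome.names, size=len(err_positions)),
                rng.integers(100, 40_000, size=len(err_positions)),
            )
        ]
        index = GenomeIndex(small_sim.genome)
        _, err_tot = paralog_forensics(err_positions, index)
        _, rand_tot = paralog_forensics(random_positions, index)
        assert err_tot["n_central_mismatch_alignments"] > 0
        assert err_tot["allele_concordant_fraction"] > 0.9
        rand_frac = rand_tot["allele_concordant_fraction"]
        assert math.isnan(rand_frac) or rand_frac < err_tot[
            "allele_concordant_fraction"
        ]


class _Transcript:
    def __init__(self, tid, chrom, exons, g, c):
        self.transcript_id = tid
        self.gene_id = tid
        self.chrom = chrom
        self.strand = "+"
        self.exons = tuple(exons)
        self.spliced_length = sum(hi - lo + 1 for lo, hi in exons)
        self.g_count = g
        self.c_count = c

    @property
    def gc_fraction(self):
        return (self.g_count + self.c_count) / self.spliced_length


def _snp(chrom, pos):
    return VariantCall(
        "s", chrom, pos, "G", "A", 30.0, HOM_ALT, 8, (0, 0, 3, 3)
    )


class TestTranscriptStats:
    def test_exonic_snp_counted_intronic_not(self):
        t = _Transcript("t1", "c", [(10, 20), (40, 50)], 5, 5)
        df, _ = transcript_mutation_stats([_snp("c", 15), _snp("c", 30)], [t])
        assert df.loc[0, "n_snps"] == 1

    def test_gc_count_predicts_better_than_gc_fraction(self):
        """With mutations targeting G/C bases uniformly, counts track the
        G+C count, not the GC fraction."""
        rng = np.random.default_rng(8)
        transcripts, calls = [], []
        pos = 1
        for i in range(60):
            length = int(rng.integers(200, 4000))
            gc = int(length * rng.uniform(0.3, 0.7))
            t = _Transcript(f"t{i}", "c", [(pos, pos + length - 1)], gc // 2, gc - gc // 2)
            transcripts.append(t)
            lam = gc * 0.01
            for _ in range(rng.poisson(lam)):
                calls.append(_snp("c", int(rng.integers(pos, pos + length))))
            pos += length + 100
        df, r2 = transcript_mutation_stats(calls, transcripts)
        # closed-form least-squares oracle for one predictor
        x = df["gc_count"].to_numpy(float)
        y = df["n_snps"].to_numpy(float)
        ssxy = ((x - x.mean()) * (y - y.mean())).sum()
        r2_oracle = ssxy**2 / (((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r2["r2_gc_count"] == pytest.approx(r2_oracle)
        assert r2["r2_gc_count"] > 3 * r2["r2_gc_fraction"]

    def test_no_overlapping_snps_gives_zero_counts_nan_r2(self):
        t = _Transcript("t1", "c", [(10, 20)], 3, 3)
        df, r2 = transcript_mutation_stats([], [t])
        assert df["n_snps"].sum() == 0
        assert math.isnan(r2["r2_length"])
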