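"""Sequence-context diagnostics for mutated and error-prone positions.

Two analyses live here. The first profiles the 21-nt sequence context
of mutated G/C residues against equally sized random samples of G/C
positions, as percentage deviations per flanking position and base —
EMS-induced mutations are strongly shaped by their neighbors (CG-rich
context raises the mutation rate). The second is a forensic scan for
paralogs of 51-nt windows centered on error-prone positions: an
ungapped, end-to-end seed-and-verify aligner (exact 11-mer seeds,
explicit mismatch budget) finds every genome location where the window
aligns gap-free, and a mismatch at the central (SNP) offset whose
subject base equals the called alternate allele is the signature of a
divergent paralog driving the false calls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeSequence, VariantCall, revcomp
from .replicate_core import ErrorProneCatalog

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class ContextWindow:
    chrom: str
    center_pos: int  # 1-based
    sequence: str  # length 2*flank + 1

    @property
    def flank(self) -> int:
        return (len(self.sequence) - 1) // 2

    @property
    def center_base(self) -> str:
        return self.sequence[self.flank]


@dataclass(frozen=True)
class ContextProfile:
    """Base counts at each flanking position of a set of windows.

    counts has shape (2*flank, 4): rows are relative positions
    -flank..-1, +1..+flank (the center is excluded), columns A,C,G,T.
    Every row sums to n_windows.
    """

    center_base: str
    n_windows: int
    flank: int
    counts: np.ndarray

    @property
    def offsets(self) -> list[int]:
        return [o for o in range(-self.flank, self.flank + 1) if o != 0]

    def count(self, offset: int, base: str) -> int:
        return int(self.counts[self.offsets.index(offset), _BASE_INDEX[base]])


@dataclass(frozen=True)
class UngappedAlignment:
    query_id: str
    subject_chrom: str
    subject_start: int  # 1-based start of the aligned window
    strand: str  # '+' or '-'
    length: int
    mismatch_offsets: tuple[int, ...]  # 0-based, in query coordinates
    subject_central_base: str  # in query orientation

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_offsets)

    @property
    def central_mismatch(self) -> bool:
        return (self.length - 1) // 2 in self.mismatch_offsets


@dataclass(frozen=True)
class ParalogSummary:
    query_id: str
    n_global_alignments: int
    has_perfect_paralog: bool
    n_central_mismatch: int
    n_single_central_mismatch: int
    snp_allele_concordant: bool


def extract_windows(
    genome: GenomeSequence,
    positions: Iterable[tuple[str, int]],
    flank: int = 10,
) -> tuple[list[ContextWindow], dict[str, int]]:
    """Fixed-width windows centered on 1-based positions.

    Windows truncated by a contig end or containing N are dropped; the
    returned dict counts the drops by reason.
    """
    windows = []
    dropped = {"truncated": 0, "contains_n": 0, "off_contig": 0}
    for chrom, pos in positions:
        if chrom not in genome or not 1 <= pos <= len(genome[chrom]):
            dropped["off_contig"] += 1
            continue
        seq = genome.window(chrom, pos, flank)
        if seq is None:
            dropped["truncated"] += 1
            continue
        if "N" in seq:
            dropped["contains_n"] += 1
            continue
        windows.append(ContextWindow(chrom=chrom, center_pos=pos, sequence=seq))
    if any(dropped.values()):
        logger.info("dropped windows: %s", dropped)
    return windows, dropped


def sample_random_centers(
    genome: GenomeSequence,
    base: str,
    n: int,
    seed: int | np.random.Generator,
) -> list[tuple[str, int]]:
    """Uniform sample (without replacement) of positions with a given base."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    eligible: list[tuple[str, int]] = []
    for name, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        hits = np.nonzero(arr == ord(base))[0]
        eligible.extend((name, int(p) + 1) for p in hits)
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} {base} positions available, need {n}"
        )
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx)]


def build_profile(windows: Sequence[ContextWindow]) -> ContextProfile:
    """Tabulate base occurrences at each flanking position."""
    if not windows:
        raise ValueError("no windows to profile")
    flank = windows[0].flank
    center = windows[0].center_base
    if any(w.flank != flank for w in windows):
        raise ValueError("windows have mixed flank sizes")
    if any(w.center_base != center for w in windows):
        raise ValueError("windows have mixed center bases")
    mat = np.zeros((2 * flank + 1, 4), dtype=np.int64)
    for w in windows:
        codes = _CODE[np.frombuffer(w.sequence.encode(), dtype=np.uint8)]
        for pos in range(2 * flank + 1):
            mat[pos, codes[pos]] += 1
    counts = np.delete(mat, flank, axis=0)  # drop the invariant center row
    return ContextProfile(
        center_base=center, n_windows=len(windows), flank=flank, counts=counts
    )


def pct_change(count_rand: float, count_mut: float) -> float:
    """Percentage change from a random-background count to a mutant count."""
    if count_rand == 0:
        return math.nan
    return 100.0 * (count_mut - count_rand) / count_rand


def deviation_profile(
    mut_profile: ContextProfile, rand_profile: ContextProfile
) -> pd.DataFrame:
    """Per-position, per-base percentage deviation mutant vs random.

    Requires equal sample sizes and the same center base; cells with a
    zero random count are NaN.
    """
    if mut_profile.n_windows != rand_profile.n_windows:
        raise ValueError("profiles must have the same sample size")
    if mut_profile.center_base != rand_profile.center_base:
        raise ValueError("profiles must share a center base")
    if mut_profile.flank != rand_profile.flank:
        raise ValueError("profiles must share a flank size")
    mut = mut_profile.counts.astype(float)
    rand = rand_profile.counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = 100.0 * (mut - rand) / rand
    dev[rand == 0] = np.nan
    return pd.DataFrame(
        dev, index=mut_profile.offsets, columns=list(BASES)
    )


def revcomp_fold(profile: ContextProfile) -> ContextProfile:
    """Map a profile onto the opposite strand.

    The position axis is reversed and the base axis complemented, so a
    C-centered profile folds onto its G-centered equivalent. Folding
    twice is the identity.
    """
    comp_order = [3, 2, 1, 0]  # A<->T, C<->G
    folded = profile.counts[::-1][:, comp_order].copy()
    return ContextProfile(
        center_base={"A": "T", "C": "G", "G": "C", "T": "A"}[
            profile.center_base
        ],
        n_windows=profile.n_windows,
        flank=profile.flank,
        counts=folded,
    )


def cg_dinucleotide_content(sequences: Iterable[str]) -> float:
    """Fraction of overlapping dimers that are the CG dinucleotide."""
    n_cg = 0
    n_dimers = 0
    for seq in sequences:
        if len(seq) < 2:
            continue
        n_cg += seq.count("CG")
        n_dimers += len(seq) - 1
    if n_dimers == 0:
        return math.nan
    return n_cg / n_dimers


# ---------------------------------------------------------------------------
# Ungapped seed-and-verify scanner


class GenomeIndex:
    """Exact k-mer position index over a genome, for seed lookup."""

    def __init__(self, genome: GenomeSequence, word_size: int = 11):
        if word_size < 1 or word_size > 15:
            raise ValueError("word_size must be in 1..15")
        self.word_size = word_size
        self.genome = genome
        self._codes: dict[str, np.ndarray] = {}
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for name, seq in genome.items():
            codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            self._codes[name] = codes
            self._index[name] = self._build(codes)

    def _build(self, codes: np.ndarray):
        k = self.word_size
        n = len(codes) - k + 1
        if n <= 0:
            empty = np.array([], dtype=np.int64)
            return empty, empty, empty
        hashes = np.zeros(n, dtype=np.int64)
        valid = np.ones(n, dtype=bool)
        for j in range(k):
            window = codes[j : j + n]
            hashes = hashes * 4 + np.minimum(window, 3)
            valid &= window < 4  # any N invalidates the word
        hashes[~valid] = -1
        order = np.argsort(hashes, kind="stable")
        sorted_hashes = hashes[order]
        return sorted_hashes, order.astype(np.int64), hashes

    def codes(self, chrom: str) -> np.ndarray:
        return self._codes[chrom]

    def seed_positions(self, chrom: str, word_codes: np.ndarray) -> np.ndarray:
        """Genome offsets (0-based) where the exact word occurs."""
        if np.any(word_codes >= 4):
            return np.array([], dtype=np.int64)
        h = 0
        for c in word_codes:
            h = h * 4 + int(c)
        sorted_hashes, order, _ = self._index[chrom]
        lo = np.searchsorted(sorted_hashes, h, side="left")
        hi = np.searchsorted(sorted_hashes, h, side="right")
        return np.sort(order[lo:hi])


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def ungapped_scan(
    query_windows: Sequence[ContextWindow],
    genome: GenomeSequence | GenomeIndex,
    word_size: int = 11,
    max_mismatches: int = 3,
    exclude_self: bool = True,
) -> list[UngappedAlignment]:
    """Find all gap-free, end-to-end genome matches of each query window.

    Seeding partitions the query into max_mismatches+1 disjoint exact
    words of word_size; by pigeonhole, any alignment with at most
    max_mismatches mismatches contains at least one exact word, so the
    scan is exhaustive whenever (max_mismatches+1)*word_size <= query
    length. Both strands are scanned; minus-strand hits report their
    mismatch offsets in query coordinates and the subject central base
    complemented into query orientation. The query's own source locus
    (identical interval, plus strand) is excluded.
    """
    index = (
        genome
        if isinstance(genome, GenomeIndex)
        else GenomeIndex(genome, word_size)
    )
    if index.word_size != word_size:
        raise ValueError("index word_size differs from requested word_size")
    out: list[UngappedAlignment] = []
    for w in query_windows:
        if "N" in w.sequence:
            logger.info("skipping query at %s:%d (contains N)", w.chrom, w.center_pos)
            continue
        L = len(w.sequence)
        n_words = max_mismatches + 1
        if n_words * word_size > L:
            raise ValueError(
                f"query length {L} too short for {max_mismatches} mismatches "
                f"at word_size {word_size}: exhaustive seeding needs "
                f"(max_mismatches+1)*word_size <= length"
            )
        qid = f"{w.chrom}:{w.center_pos}"
        source_start0 = w.center_pos - 1 - w.flank
        for strand, qseq in (("+", w.sequence), ("-", revcomp(w.sequence))):
            qcodes = _encode(qseq)
            hits: set[int] = set()
            for chrom in index.genome.names:
                gcodes = index.codes(chrom)
                candidates: set[int] = set()
                for word_i in range(n_words):
                    off = word_i * word_size
                    seeds = index.seed_positions(
                        chrom, qcodes[off : off + word_size]
                    )
                    for s in seeds:
                        start = int(s) - off
                        if 0 <= start <= len(gcodes) - L:
                            candidates.add(start)
                for start in candidates:
                    window = gcodes[start : start + L]
                    mism = np.nonzero(window != qcodes)[0]
                    if mism.size > max_mismatches:
                        continue
                    if (
                        exclude_self
                        and strand == "+"
                        and chrom == w.chrom
                        and start == source_start0
                    ):
                        continue
                    if strand == "+":
                        offsets = tuple(int(i) for i in mism)
                    else:
                        offsets = tuple(sorted(L - 1 - int(i) for i in mism))
                    central = (L - 1) // 2
                    sub_base_code = int(window[central])
                    sub_base = (
                        "ACGTN"[sub_base_code]
                        if strand == "+"
                        else "TGCAN"[sub_base_code]
                    )
                    out.append(
                        UngappedAlignment(
                            query_id=qid,
                            subject_chrom=chrom,
                            subject_start=start + 1,
                            strand=strand,
                            length=L,
                            mismatch_offsets=offsets,
                            subject_central_base=sub_base,
                        )
                    )
    return out


def summarize_paralogs(
    alignments: Sequence[UngappedAlignment],
    query_id: str,
    called_alt: str | None,
) -> ParalogSummary:
    """Collapse one query's alignments into the forensic summary."""
    mine = [a for a in alignments if a.query_id == query_id]
    central = [a for a in mine if a.central_mismatch]
    return ParalogSummary(
        query_id=query_id,
        n_global_alignments=len(mine),
        has_perfect_paralog=any(a.n_mismatches == 0 for a in mine),
        n_central_mismatch=len(central),
        n_single_central_mismatch=sum(
            1 for a in central if a.n_mismatches == 1
        ),
        snp_allele_concordant=(
            called_alt is not None
            and any(a.subject_central_base == called_alt for a in central)
        ),
    )


def paralog_forensics(
    positions: Sequence[tuple[str, int, str | None]],
    genome: GenomeSequence | GenomeIndex,
    flank: int = 25,
    word_size: int = 11,
    max_mismatches: int = 3,
) -> tuple[list[ParalogSummary], dict[str, float]]:
    """Scan 51-nt contexts of positions and summarize paralog evidence.

    positions are (chrom, pos, called_alt); called_alt may be None for
    cohorts without a variant call (random genomic positions). Returns
    per-position summaries plus cohort totals: positions scanned/with
    alignments/with perfect paralogs, global and central-mismatch
    alignment counts, and the allele-concordant fraction among
    positions with at least one central-mismatch alignment.
    """
    gnm = genome.genome if isinstance(genome, GenomeIndex) else genome
    windows, _dropped = extract_windows(
        gnm, [(c, p) for c, p, _ in positions], flank=flank
    )
    by_pos = {(w.chrom, w.center_pos): w for w in windows}
    alignments = ungapped_scan(
        windows, genome, word_size=word_size, max_mismatches=max_mismatches
    )
    by_query: dict[str, list[UngappedAlignment]] = {}
    for a in alignments:
        by_query.setdefault(a.query_id, []).append(a)
    summaries = []
    for chrom, pos, alt in positions:
        w = by_pos.get((chrom, pos))
        if w is None:
            continue
        qid = f"{chrom}:{pos}"
        summaries.append(
            summarize_paralogs(by_query.get(qid, []), qid, alt)
        )
    n_central_pos = sum(1 for s in summaries if s.n_central_mismatch > 0)
    n_concordant = sum(1 for s in summaries if s.snp_allele_concordant)
    totals = {
        "n_positions": len(summaries),
        "n_with_alignment": sum(
            1 for s in summaries if s.n_global_alignments > 0
        ),
        "n_with_perfect": sum(1 for s in summaries if s.has_perfect_paralog),
        "n_global_alignments": sum(s.n_global_alignments for s in summaries),
        "n_central_mismatch_alignments": sum(
            s.n_central_mismatch for s in summaries
        ),
        "central_mismatch_pct": (
            100.0
            * sum(s.n_central_mismatch for s in summaries)
            / sum(s.n_global_alignments for s in summaries)
            if any(s.n_global_alignments for s in summaries)
            else math.nan
        ),
        "allele_concordant_fraction": (
            n_concordant / n_central_pos if n_central_pos else math.nan
        ),
    }
    return summaries, totals


def transcript_mutation_stats(
    calls: Sequence[VariantCall],
    transcripts: Sequence,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-transcript mutation counts and their linear predictors.

    SNPs are assigned to a transcript when they fall inside one of its
    exons. Returns the per-transcript table and r-squared of count vs
    spliced length, vs G+C count, and vs GC fraction.
    """
    by_chrom: dict[str, list[int]] = {}
    for c in calls:
        if c.is_snp:
            by_chrom.setdefault(c.chrom, []).append(c.pos)
    for chrom in by_chrom:
        by_chrom[chrom] = np.sort(np.array(by_chrom[chrom]))  # type: ignore[assignment]
    records = []
    for t in transcripts:
        positions = by_chrom.get(t.chrom)
        n = 0
        if positions is not None:
            arr = np.asarray(positions)
            for lo, hi in t.exons:
                n += int(
                    np.searchsorted(arr, hi, side="right")
                    - np.searchsorted(arr, lo, side="left")
                )
        records.append(
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "n_snps": n,
                "spliced_length": t.spliced_length,
                "gc_count": t.g_count + t.c_count,
                "gc_fraction": t.gc_fraction,
            }
        )
    df = pd.DataFrame.from_records(records)
    r2 = {}
    for key, col in (
        ("r2_length", "spliced_length"),
        ("r2_gc_count", "gc_count"),
        ("r2_gc_fraction", "gc_fraction"),
    ):
        x = df[col].to_numpy(float)
        y = df["n_snps"].to_numpy(float)
        if len(df) < 3 or np.std(x) == 0 or np.std(y) == 0:
            r2[key] = math.nan
        else:
            r2[key] = float(stats.linregress(x, y).rvalue ** 2)
    return df, r2


def export_windows_fasta(
    windows: Sequence[ContextWindow],
    dest,
    subsample: int | None = None,
    seed: int = 0,
) -> list[ContextWindow]:
    """Write windows as FASTA, optionally a seeded uniform subsample.

    Intended for handing the 21-nt contexts to external motif-discovery
    tools; returns the windows actually written.
    """
    chosen = list(windows)
    if subsample is not None and subsample < len(chosen):
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(chosen), size=subsample, replace=False))
        chosen = [chosen[i] for i in idx]

    def _write(fh) -> None:
        for w in chosen:
            fh.write(f">{w.chrom}:{w.center_pos}\n{w.sequence}\n")

    if hasattr(dest, "write"):
        _write(dest)
    else:
        with open(dest, "w") as fh:
            _write(fh)
    return chosen
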