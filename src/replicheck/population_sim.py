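"""Synthetic mutagenized-population generator with a truth log.

The generator emulates the statistical structure that the replication
method assumes in real data from an EMS-mutagenized diploid population
sequenced at low coverage:

* each line carries its own random set of induced mutations, nearly
  all G:C -> A:T transitions at G/C sites, with a minority of the
  known minor classes (A:T -> G:C the most common);
* a fixed set of error-prone positions fires recurrently across lines,
  always with the same artifact allele — each such position sits in a
  repeat-family segment whose divergent paralog copy differs at
  exactly that offset, the causal mechanism behind recurrent false
  calls from mismapped reads;
* occasional line pairs share a large fraction of mutations through
  pollen/seed contamination (shared pedigree).

Every draw is recorded in a machine-readable truth log so downstream
filters can be scored exactly. The generator emulates *calls at
detectable sites*: strand-resolved depths are drawn consistently with
zygosity at sites with enough coverage to be called, and QUAL is a
deterministic monotone function of the alternate-allele depth —
sufficient to exercise every threshold without claiming a genotype
likelihood model.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    HET,
    HOM_ALT,
    GenomeSequence,
    VariantCall,
    write_fasta,
    write_vcf,
)

_MUT = {"G": "A", "C": "T"}  # canonical EMS transitions
# Minor (non-G:C>A:T) classes and their relative weights among the
# ~2% non-canonical mutations: A:T>G:C dominates, then A:T>T:A.
_MINOR_CLASSES = (
    (("A", "G"), 0.35),
    (("T", "C"), 0.35),
    (("A", "T"), 0.125),
    (("T", "A"), 0.125),
    (("G", "T"), 0.0125),
    (("C", "A"), 0.0125),
    (("G", "C"), 0.0125),
    (("C", "G"), 0.0125),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic population.

    Defaults follow the population the method was developed on: ~7x
    mean coverage, ~500 induced mutations per line of which 98% are
    G:C -> A:T, 27% heterozygous, recurrent error-prone positions
    firing in about half the lines, and one contaminated line pair.
    """

    seed: int = 0
    genome_length: int = 2_000_000
    n_chroms: int = 2
    n_repeat_families: int = 10
    copies_per_family: int = 2
    repeat_length: int = 500
    paralog_divergence_rate: float = 0.02
    n_lines: int = 50
    mutations_per_line: int = 500
    ems_purity: float = 0.98
    het_fraction: float = 0.27
    n_error_positions: int = 100
    error_penetrance: float = 0.5
    n_contaminated_pairs: int = 1
    contaminated_shared_fraction: float = 0.8
    mean_depth: float = 7.0
    context_bias: float | None = None  # CG-dinucleotide weight multiplier

    def __post_init__(self) -> None:
        for name in (
            "paralog_divergence_rate",
            "ems_purity",
            "het_fraction",
            "error_penetrance",
            "contaminated_shared_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length < 200:
            raise ValueError("genome_length too small")


@dataclass(frozen=True)
class RepeatCopy:
    family: int
    chrom: str
    start: int  # 1-based
    length: int
    # (offset within copy, master base, copy base) for divergent sites
    divergent: tuple[tuple[int, str, str], ...]


@dataclass(frozen=True)
class RepeatAnnotation:
    masters: tuple[RepeatCopy, ...]
    copies: tuple[RepeatCopy, ...]


@dataclass(frozen=True)
class TrueMutation:
    line_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gt_class: str
    inherited_from: str | None = None  # contamination source line


@dataclass(frozen=True)
class PlantedError:
    chrom: str
    pos: int
    ref: str
    alt: str
    gt_class: str
    paralog_chrom: str
    paralog_pos: int


@dataclass(frozen=True)
class TruthSet:
    mutations: tuple[TrueMutation, ...]
    errors: tuple[PlantedError, ...]
    error_firings: tuple[tuple[str, str, int], ...]  # (line, chrom, pos)
    contaminated_pairs: tuple[tuple[str, str], ...]

    def mutations_of(self, line_id: str) -> list[TrueMutation]:
        return [m for m in self.mutations if m.line_id == line_id]


@dataclass(frozen=True)
class SimResult:
    config: SimConfig
    genome: GenomeSequence
    annotation: RepeatAnnotation
    calls: dict[str, list[VariantCall]]
    truth: TruthSet


def line_name(i: int) -> str:
    return f"line{i:03d}"


def make_genome(cfg: SimConfig) -> tuple[GenomeSequence, RepeatAnnotation]:
    """I.i.d. background sequence with planted divergent repeat families."""
    rng = np.random.default_rng(cfg.seed)
    per_chrom = cfg.genome_length // cfg.n_chroms
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    seqs = {
        name: rng.integers(0, 4, size=per_chrom, dtype=np.uint8)
        for name in chrom_names
    }
    n_segments = cfg.n_repeat_families * (1 + cfg.copies_per_family)
    if n_segments * cfg.repeat_length * 2 > cfg.genome_length:
        raise ValueError("repeat families too large for the genome")

    # non-overlapping slots for masters and copies
    used: dict[str, list[tuple[int, int]]] = {n: [] for n in chrom_names}

    def _pick_slot() -> tuple[str, int]:
        for _ in range(10_000):
            chrom = chrom_names[int(rng.integers(cfg.n_chroms))]
            start0 = int(rng.integers(0, per_chrom - cfg.repeat_length))
            if all(
                start0 + cfg.repeat_length <= lo or start0 >= hi
                for lo, hi in used[chrom]
            ):
                used[chrom].append((start0, start0 + cfg.repeat_length))
                return chrom, start0
        raise RuntimeError("could not place repeat segments without overlap")

    masters, copies = [], []
    for fam in range(cfg.n_repeat_families):
        m_chrom, m_start0 = _pick_slot()
        master_seq = seqs[m_chrom][m_start0 : m_start0 + cfg.repeat_length].copy()
        masters.append(
            RepeatCopy(
                family=fam,
                chrom=m_chrom,
                start=m_start0 + 1,
                length=cfg.repeat_length,
                divergent=(),
            )
        )
        for _copy in range(cfg.copies_per_family):
            c_chrom, c_start0 = _pick_slot()
            copy_seq = master_seq.copy()
            flips = np.nonzero(
                rng.random(cfg.repeat_length) < cfg.paralog_divergence_rate
            )[0]
            divergent = []
            for off in flips:
                new = (copy_seq[off] + 1 + rng.integers(3)) % 4
                divergent.append(
                    (
                        int(off),
                        "ACGT"[master_seq[off]],
                        "ACGT"[new],
                    )
                )
                copy_seq[off] = new
            seqs[c_chrom][c_start0 : c_start0 + cfg.repeat_length] = copy_seq
            copies.append(
                RepeatCopy(
                    family=fam,
                    chrom=c_chrom,
                    start=c_start0 + 1,
                    length=cfg.repeat_length,
                    divergent=tuple(divergent),
                )
            )
    genome = GenomeSequence(
        {
            name: "".join("ACGT"[b] for b in arr)
            for name, arr in seqs.items()
        }
    )
    return genome, RepeatAnnotation(
        masters=tuple(masters), copies=tuple(copies)
    )


def _eligible_sites(genome: GenomeSequence, bases: str) -> list[tuple[str, int]]:
    sites = []
    for name, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        mask = np.zeros(len(arr), dtype=bool)
        for b in bases:
            mask |= arr == ord(b)
        sites.extend((name, int(p) + 1) for p in np.nonzero(mask)[0])
    return sites


def _site_weights(
    genome: GenomeSequence,
    sites: Sequence[tuple[str, int]],
    context_bias: float | None,
) -> np.ndarray | None:
    """Optional CG-dinucleotide weighting of G/C mutation targets."""
    if context_bias is None:
        return None
    w = np.ones(len(sites))
    for i, (chrom, pos) in enumerate(sites):
        seq = genome[chrom]
        base = seq[pos - 1]
        in_cg = (base == "G" and pos >= 2 and seq[pos - 2] == "C") or (
            base == "C" and pos < len(seq) and seq[pos] == "G"
        )
        if in_cg:
            w[i] = context_bias
    return w / w.sum()


def _draw_dp4(
    rng: np.random.Generator, gt_class: str, mean_depth: float
) -> tuple[tuple[int, int, int, int], int]:
    """Strand-resolved depths consistent with zygosity.

    Homozygous-alt: no reference reads, alternate on both strands.
    Heterozygous: both alleles represented, alternate on both strands.
    """
    if gt_class == HOM_ALT:
        depth = max(2, int(rng.poisson(mean_depth)))
        alt_fwd = 1 + int(rng.binomial(depth - 2, 0.5))
        return (0, 0, alt_fwd, depth - alt_fwd), depth
    depth = max(3, int(rng.poisson(mean_depth)))
    alt_total = int(np.clip(rng.binomial(depth, 0.5), 2, depth - 1))
    alt_fwd = 1 + int(rng.binomial(alt_total - 2, 0.5))
    ref_total = depth - alt_total
    ref_fwd = int(rng.binomial(ref_total, 0.5))
    return (ref_fwd, ref_total - ref_fwd, alt_fwd, alt_total - alt_fwd), depth


def _qual_from_alt_depth(alt_depth: int) -> float:
    # deterministic, monotone in alternate-allele support
    return float(min(99, 10 * alt_depth))


def make_population(
    cfg: SimConfig,
    genome: GenomeSequence,
    annotation: RepeatAnnotation,
) -> tuple[dict[str, list[VariantCall]], TruthSet]:
    """Draw per-line calls and the truth log for a mutagenized population."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    lines = [line_name(i) for i in range(cfg.n_lines)]

    gc_sites = _eligible_sites(genome, "GC")
    gc_weights = _site_weights(genome, gc_sites, cfg.context_bias)
    by_ref: dict[str, list[tuple[str, int]]] = {
        b: _eligible_sites(genome, b) for b in "ACGT"
    }

    # --- planted error-prone positions at paralog-divergent offsets
    candidates: list[PlantedError] = []
    master_by_family = {m.family: m for m in annotation.masters}
    for copy in annotation.copies:
        master = master_by_family[copy.family]
        for off, master_base, copy_base in copy.divergent:
            candidates.append(
                PlantedError(
                    chrom=master.chrom,
                    pos=master.start + off,
                    ref=master_base,
                    alt=copy_base,
                    gt_class=HOM_ALT,  # reassigned below
                    paralog_chrom=copy.chrom,
                    paralog_pos=copy.start + off,
                )
            )
    if len(candidates) < cfg.n_error_positions:
        raise ValueError(
            f"only {len(candidates)} paralog-divergent offsets available "
            f"for {cfg.n_error_positions} error positions; increase "
            "n_repeat_families, repeat_length or paralog_divergence_rate"
        )
    # dedupe by position, keep deterministic order
    seen_pos: set[tuple[str, int]] = set()
    unique_candidates = []
    for c in sorted(candidates, key=lambda c: (c.chrom, c.pos)):
        if (c.chrom, c.pos) not in seen_pos:
            seen_pos.add((c.chrom, c.pos))
            unique_candidates.append(c)
    idx = rng.choice(
        len(unique_candidates), size=cfg.n_error_positions, replace=False
    )
    errors = []
    for i in sorted(idx):
        e = unique_candidates[i]
        gt = HOM_ALT if rng.random() < 0.5 else HET
        errors.append(replace(e, gt_class=gt))
    error_positions = {(e.chrom, e.pos) for e in errors}

    # --- true induced mutations per line
    def _draw_line_mutations(line_id: str) -> list[TrueMutation]:
        muts: list[TrueMutation] = []
        taken: set[tuple[str, int]] = set()
        while len(muts) < cfg.mutations_per_line:
            if rng.random() < cfg.ems_purity:
                if gc_weights is None:
                    chrom, pos = gc_sites[int(rng.integers(len(gc_sites)))]
                else:
                    chrom, pos = gc_sites[
                        int(rng.choice(len(gc_sites), p=gc_weights))
                    ]
                ref = genome.base(chrom, pos)
                alt = _MUT[ref]
            else:
                classes, weights = zip(*_MINOR_CLASSES)
                (ref, alt) = classes[
                    int(rng.choice(len(classes), p=np.array(weights) / sum(weights)))
                ]
                pool = by_ref[ref]
                chrom, pos = pool[int(rng.integers(len(pool)))]
            if (chrom, pos) in taken or (chrom, pos) in error_positions:
                continue
            taken.add((chrom, pos))
            gt = HET if rng.random() < cfg.het_fraction else HOM_ALT
            muts.append(
                TrueMutation(
                    line_id=line_id,
                    chrom=chrom,
                    pos=pos,
                    ref=genome.base(chrom, pos),
                    alt=alt,
                    gt_class=gt,
                )
            )
        return muts

    per_line_muts = {line: _draw_line_mutations(line) for line in lines}

    # --- contamination: line B inherits a share of line A's mutations
    pairs = []
    pool = list(lines)
    for _ in range(cfg.n_contaminated_pairs):
        if len(pool) < 2:
            break
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        a, b = pool[int(i)], pool[int(j)]
        pool = [l for l in pool if l not in (a, b)]
        pairs.append((a, b))
        n_shared = int(
            round(cfg.contaminated_shared_fraction * cfg.mutations_per_line)
        )
        shared_idx = rng.choice(
            cfg.mutations_per_line, size=n_shared, replace=False
        )
        shared = [per_line_muts[a][int(k)] for k in sorted(shared_idx)]
        own = [
            m
            for m in per_line_muts[b]
            if (m.chrom, m.pos) not in {(s.chrom, s.pos) for s in shared}
        ][: cfg.mutations_per_line - n_shared]
        per_line_muts[b] = [
            replace(m, line_id=b, inherited_from=a) for m in shared
        ] + own

    # --- materialize calls with depths and quality
    calls: dict[str, list[VariantCall]] = {}
    firings: list[tuple[str, str, int]] = []
    for line in lines:
        line_calls = []
        for m in per_line_muts[line]:
            dp4, depth = _draw_dp4(rng, m.gt_class, cfg.mean_depth)
            line_calls.append(
                VariantCall(
                    line_id=line,
                    chrom=m.chrom,
                    pos=m.pos,
                    ref=m.ref,
                    alt=m.alt,
                    qual=_qual_from_alt_depth(dp4[2] + dp4[3]),
                    gt_class=m.gt_class,
                    depth=depth,
                    dp4=dp4,
                )
            )
        for e in errors:
            if rng.random() < cfg.error_penetrance:
                dp4, depth = _draw_dp4(rng, e.gt_class, cfg.mean_depth)
                firings.append((line, e.chrom, e.pos))
                line_calls.append(
                    VariantCall(
                        line_id=line,
                        chrom=e.chrom,
                        pos=e.pos,
                        ref=e.ref,
                        alt=e.alt,
                        qual=_qual_from_alt_depth(dp4[2] + dp4[3]),
                        gt_class=e.gt_class,
                        depth=depth,
                        dp4=dp4,
                    )
                )
        calls[line] = sorted(line_calls, key=lambda c: (c.chrom, c.pos))

    truth = TruthSet(
        mutations=tuple(
            m for line in lines for m in per_line_muts[line]
        ),
        errors=tuple(errors),
        error_firings=tuple(firings),
        contaminated_pairs=tuple(pairs),
    )
    return calls, truth


def simulate_population(cfg: SimConfig) -> SimResult:
    genome, annotation = make_genome(cfg)
    calls, truth = make_population(cfg, genome, annotation)
    return SimResult(
        config=cfg, genome=genome, annotation=annotation, calls=calls, truth=truth
    )


def write_truth(truth: TruthSet, out_dir: str | os.PathLike) -> None:
    """Write the truth log as TSV tables under out_dir/truth/."""
    d = Path(out_dir) / "truth"
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([m.__dict__ for m in truth.mutations]).to_csv(
        d / "mutations.tsv", sep="\t", index=False
    )
    pd.DataFrame([e.__dict__ for e in truth.errors]).to_csv(
        d / "error_positions.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        truth.error_firings, columns=["line_id", "chrom", "pos"]
    ).to_csv(d / "error_firings.tsv", sep="\t", index=False)
    pd.DataFrame(
        truth.contaminated_pairs, columns=["line_a", "line_b"]
    ).to_csv(d / "contaminated_pairs.tsv", sep="\t", index=False)


def write_simulation(result: SimResult, out_dir: str | os.PathLike) -> None:
    """Write genome FASTA, per-line VCFs, repeat BED and truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(result.genome, out / "genome.fa")
    contigs = {name: len(result.genome[name]) for name in result.genome.names}
    for line, line_calls in result.calls.items():
        write_vcf(line_calls, out / f"{line}.vcf", sample=line, contigs=contigs)
    with open(out / "repeats.bed", "w") as fh:
        for seg in result.annotation.masters + result.annotation.copies:
            role = "master" if not seg.divergent and seg in result.annotation.masters else "copy"
            fh.write(
                f"{seg.chrom}\t{seg.start - 1}\t{seg.start - 1 + seg.length}\t"
                f"family{seg.family}_{role}\n"
            )
    write_truth(result.truth, out)
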