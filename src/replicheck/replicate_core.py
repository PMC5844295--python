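"""Cross-population replication analysis of variant calls.

Independently mutagenized lines should almost never carry an induced
mutation at the same genomic position: the per-pair coincidence
probability is ~m^2/G for m mutations per line over G mutable sites.
A position called variant in two or more lines is therefore almost
certainly a systematic artifact — in practice a divergent paralog that
attracts mismapped reads and produces the same false allele in every
line. This module tallies positions across lines, builds the
error-prone position catalogs, detects contaminated (sibling) line
pairs whose shared pedigree would otherwise poison the catalog, masks
catalog positions out of every line's call set, and recovers the small
class of low-replicate positions whose EMS-like spectrum marks them as
coincident true mutations rather than artifacts.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import HET, HOM_ALT, VariantCall
from .variant_filters import classify_substitution


@dataclass(frozen=True)
class PositionKey:
    chrom: str
    pos: int  # 1-based; for indels, the event start position
    gt_class: str | None  # None for the class-agnostic indel flow


@dataclass(frozen=True)
class PositionTally:
    key: PositionKey
    n_lines: int
    line_ids: tuple[str, ...]
    alt_alleles: tuple[str, ...]  # one per contributing line
    ref: str

    @property
    def n_calls(self) -> int:
        # one call per line per position per class
        return self.n_lines


@dataclass(frozen=True)
class CatalogEntry:
    ref: str
    consensus_alt: str
    n_lines: int
    allele_consistent: bool
    alts: tuple[str, ...]
    line_ids: tuple[str, ...]


@dataclass(frozen=True)
class ErrorProneCatalog:
    """Per-genotype-class map of probable error-prone positions."""

    gt_class: str | None
    entries: dict[tuple[str, int], CatalogEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.entries


@dataclass(frozen=True)
class OverlapRecord:
    line_a: str
    line_b: str
    shared: int
    overlap_fraction: float
    flagged_sibling: bool


@dataclass(frozen=True)
class SignalNoiseRow:
    n: int
    n_positions: int
    n_gcat: int

    @property
    def signal_pct(self) -> float:
        return 100.0 * self.n_gcat / self.n_positions


@dataclass(frozen=True)
class RecoveredCall:
    """A tentative false-negative call restored from the catalog."""

    line_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gt_class: str | None
    tentative: bool = True


def tally_positions(
    per_line_callsets: Mapping[str, Sequence[VariantCall]],
    gt_class: str | None,
    indels: bool = False,
) -> list[PositionTally]:
    """Tally each genomic position's appearances across lines.

    Only calls of the requested genotype class are counted (pass
    gt_class=None to tally regardless of class, as for indels). A line
    contributes at most once per position.
    """
    seen_lines = set()
    per_pos: dict[tuple[str, int], dict[str, str]] = defaultdict(dict)
    refs: dict[tuple[str, int], str] = {}
    for line_id, calls in per_line_callsets.items():
        if line_id in seen_lines:
            raise ValueError(f"duplicate line_id {line_id!r}")
        seen_lines.add(line_id)
        for c in calls:
            if c.is_indel != indels:
                continue
            if gt_class is not None and c.gt_class != gt_class:
                continue
            key = (c.chrom, c.pos)
            if line_id not in per_pos[key]:
                per_pos[key][line_id] = c.alt
                refs.setdefault(key, c.ref)
    out = []
    for (chrom, pos), line_alts in sorted(per_pos.items()):
        lines = tuple(sorted(line_alts))
        out.append(
            PositionTally(
                key=PositionKey(chrom, pos, gt_class),
                n_lines=len(lines),
                line_ids=lines,
                alt_alleles=tuple(line_alts[l] for l in lines),
                ref=refs[(chrom, pos)],
            )
        )
    return out


def _consensus(alts: Sequence[str]) -> str:
    counts = Counter(alts)
    top = max(counts.values())
    # modal allele; ties broken lexicographically for determinism
    return min(a for a, n in counts.items() if n == top)


def build_catalog(
    tallies: Iterable[PositionTally], min_replicates: int = 2
) -> ErrorProneCatalog:
    """Record positions tallied in >= min_replicates lines as error-prone."""
    if min_replicates < 2:
        raise ValueError("min_replicates < 2 would mask every call")
    tallies = list(tallies)
    gt_classes = {t.key.gt_class for t in tallies}
    if len(gt_classes) > 1:
        raise ValueError("tallies mix genotype classes")
    entries = {}
    for t in tallies:
        if t.n_lines < min_replicates:
            continue
        entries[(t.key.chrom, t.key.pos)] = CatalogEntry(
            ref=t.ref,
            consensus_alt=_consensus(t.alt_alleles),
            n_lines=t.n_lines,
            allele_consistent=len(set(t.alt_alleles)) == 1,
            alts=t.alt_alleles,
            line_ids=t.line_ids,
        )
    return ErrorProneCatalog(
        gt_class=next(iter(gt_classes)) if tallies else None, entries=entries
    )


def pairwise_overlap(
    per_line_callsets: Mapping[str, Sequence[VariantCall]],
    threshold: float = 0.68,
) -> list[OverlapRecord]:
    """Pairwise overlap of called positions, to expose shared pedigrees.

    overlap_fraction = |A ∩ B| / min(|A|, |B|) over (chrom, pos) sets;
    a pair exceeding the threshold is flagged as siblings (pollen/seed
    contamination). A line with zero calls has overlap 0 with everyone.
    """
    if len(per_line_callsets) < 2:
        raise ValueError("need at least two lines")
    pos_sets = {
        line: {(c.chrom, c.pos) for c in calls}
        for line, calls in per_line_callsets.items()
    }
    out = []
    for a, b in combinations(sorted(pos_sets), 2):
        sa, sb = pos_sets[a], pos_sets[b]
        denom = min(len(sa), len(sb))
        frac = len(sa & sb) / denom if denom else 0.0
        out.append(
            OverlapRecord(
                line_a=a,
                line_b=b,
                shared=len(sa & sb),
                overlap_fraction=frac,
                flagged_sibling=frac > threshold,
            )
        )
    return out


def select_mask_builders(
    lines: Iterable[str], overlap_records: Iterable[OverlapRecord]
) -> set[str]:
    """Lines eligible to build the catalog: everyone not in a flagged pair.

    Both members of every flagged pair are excluded so that mutations
    shared by pedigree are not mistaken for systematic errors; the
    catalog is still *applied* to the excluded lines.
    """
    excluded = set()
    for rec in overlap_records:
        if rec.flagged_sibling:
            excluded.update((rec.line_a, rec.line_b))
    return set(lines) - excluded


def mask_calls(
    callset: Sequence[VariantCall],
    catalog: ErrorProneCatalog,
    match_allele: bool = False,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Split a line's calls into (nonreplicate, removed) by the catalog.

    Matching is by chrom+pos within the catalog's genotype class; the
    allele is ignored by default (error-prone positions are nearly
    always allele-consistent anyway). Calls of the other genotype class
    pass through untouched.
    """
    kept, removed = [], []
    for c in callset:
        in_class = catalog.gt_class is None or c.gt_class == catalog.gt_class
        entry = catalog.entries.get((c.chrom, c.pos)) if in_class else None
        hit = entry is not None and (
            not match_allele or c.alt in entry.alts
        )
        (removed if hit else kept).append(c)
    return kept, removed


def signal_to_noise_table(catalog: ErrorProneCatalog) -> list[SignalNoiseRow]:
    """Group catalog positions by replicate count n.

    The signal is the percentage of positions whose consensus
    substitution is the canonical EMS class G:C>A:T; rows are sorted by
    ascending n. A sharp drop past n=2 marks the replicate count above
    which positions are almost all artifacts.
    """
    by_n: dict[int, list[CatalogEntry]] = defaultdict(list)
    for entry in catalog.entries.values():
        by_n[entry.n_lines].append(entry)
    rows = []
    for n in sorted(by_n):
        entries = by_n[n]
        n_gcat = sum(
            1
            for e in entries
            if len(e.ref) == 1
            and len(e.consensus_alt) == 1
            and classify_substitution(e.ref, e.consensus_alt).is_canonical_ems
        )
        rows.append(SignalNoiseRow(n=n, n_positions=len(entries), n_gcat=n_gcat))
    return rows


def recover_false_negatives(
    catalog: ErrorProneCatalog, max_n: int = 2
) -> list[RecoveredCall]:
    """Restore tentative coincident true mutations from the catalog.

    A catalog position qualifies when it was seen in 2..max_n lines,
    its consensus substitution is canonical EMS (G>A or C>T), and all
    contributing lines called the same allele. One recovered call is
    emitted per contributing line, labeled tentative.
    """
    if max_n < 2:
        return []
    out = []
    for (chrom, pos), e in sorted(catalog.entries.items()):
        if not 2 <= e.n_lines <= max_n:
            continue
        if not e.allele_consistent:
            continue
        if len(e.ref) != 1 or len(e.consensus_alt) != 1:
            continue
        if not classify_substitution(e.ref, e.consensus_alt).is_canonical_ems:
            continue
        for line_id in e.line_ids:
            out.append(
                RecoveredCall(
                    line_id=line_id,
                    chrom=chrom,
                    pos=pos,
                    ref=e.ref,
                    alt=e.consensus_alt,
                    gt_class=catalog.gt_class,
                )
            )
    return out


def mask_indels(
    per_line_indels: Mapping[str, Sequence[VariantCall]],
    builder_lines: Iterable[str],
) -> tuple[dict[str, list[VariantCall]], ErrorProneCatalog]:
    """Replicate-mask indels keyed by their start position alone.

    An indel's identity for cross-line comparison is (chrom, start):
    a deletion and an insertion starting at the same base in two lines
    both mark the position as error-prone, regardless of event length
    or genotype class. The catalog is built from builder lines only but
    applied to every line.
    """
    builder_lines = set(builder_lines)
    builder_sets = {
        l: calls for l, calls in per_line_indels.items() if l in builder_lines
    }
    tallies = tally_positions(builder_sets, gt_class=None, indels=True)
    catalog = build_catalog(tallies, min_replicates=2)
    kept = {}
    for line_id, calls in per_line_indels.items():
        indels = [c for c in calls if c.is_indel]
        kept[line_id], _removed = mask_calls(indels, catalog)
    return kept, catalog


def indel_length_stats(indels: Iterable[VariantCall]) -> dict[str, float]:
    """Signed-length histogram summary of an indel set."""
    lengths = np.array([c.indel_length for c in indels], dtype=float)
    if lengths.size == 0:
        return {"n": 0, "mean_abs_length": math.nan, "max_abs_length": math.nan}
    return {
        "n": int(lengths.size),
        "mean_abs_length": float(np.abs(lengths).mean()),
        "max_abs_length": float(np.abs(lengths).max()),
    }


def per_line_summary(
    hom_callsets: Mapping[str, Sequence[VariantCall]],
    het_callsets: Mapping[str, Sequence[VariantCall]],
    coverage_per_line: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-line counts and their correlation with mapping coverage.

    Returns a table with hom/het counts, the homozygosity fraction and
    the per-line EMS (G:C>A:T) fraction, plus Pearson correlations of
    the hom and het counts with coverage (NaN when undefined: fewer
    than 3 lines, missing coverage, or zero variance).
    """
    from .variant_filters import spectrum

    lines = sorted(set(hom_callsets) | set(het_callsets))
    records = []
    for line in lines:
        hom = list(hom_callsets.get(line, []))
        het = list(het_callsets.get(line, []))
        total = len(hom) + len(het)
        snps = [c for c in hom + het if c.is_snp]
        spec = spectrum(snps)
        records.append(
            {
                "line_id": line,
                "hom_count": len(hom),
                "het_count": len(het),
                "hom_fraction": len(hom) / total if total else math.nan,
                "ems_fraction": spec.ems_fraction,
                "coverage": (
                    coverage_per_line.get(line, math.nan)
                    if coverage_per_line
                    else math.nan
                ),
            }
        )
    df = pd.DataFrame.from_records(records)
    corr = {"r_hom_coverage": math.nan, "r_het_coverage": math.nan}
    if len(df) >= 3 and coverage_per_line:
        cov = df["coverage"].to_numpy(float)
        if np.isfinite(cov).all():
            for key, col in (
                ("r_hom_coverage", "hom_count"),
                ("r_het_coverage", "het_count"),
            ):
                x = df[col].to_numpy(float)
                if np.std(x) > 0 and np.std(cov) > 0:
                    corr[key] = float(np.corrcoef(x, cov)[0, 1])
    return df, corr
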