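"""The standard SNP/indel filter chain and the EMS substitution spectrum.

The chain mirrors the usual refinement of low-coverage bcftools-style
calls from a mutagenized line:

1. repeat filter — drop quality < 10, depth < 2 (too little support)
   and depth > 100 (likely collapsed repeats);
2. genotype-quality filter — keep QUAL >= 20 calls of the requested
   genotype class (homozygous-alternate or heterozygous);
3. strand filter — homozygous calls must show the alternate allele on
   both strands with no reference reads at all; heterozygous calls are
   only required to show the alternate allele on both strands.

Calls surviving all three are the "standard filtered" set. EMS
(ethyl methanesulfonate) alkylates O6-guanine, so induced mutations
are overwhelmingly G:C -> A:T transitions; classification into the 12
directed (and 6 strand-collapsed) substitution classes underpins both
the EMS-only subset and all spectrum diagnostics.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import HET, HOM_ALT, VariantCall

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Canonical directed substitutions whose strand-collapsed class is
#: G:C -> A:T, the EMS signature.
CANONICAL_EMS = {("G", "A"), ("C", "T")}

COLLAPSED_CLASSES = (
    "G:C>A:T",
    "A:T>G:C",
    "A:T>T:A",
    "G:C>T:A",
    "G:C>C:G",
    "A:T>C:G",
)


@dataclass(frozen=True)
class FilterConfig:
    min_keep_qual: float = 10.0
    min_depth: int = 2
    max_depth: int = 100
    min_genotype_qual: float = 20.0

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")
        if min(self.min_keep_qual, self.min_genotype_qual) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class SubstitutionClass:
    directed: str  # e.g. "G>A"
    collapsed: str  # e.g. "G:C>A:T"
    is_canonical_ems: bool


def classify_substitution(ref: str, alt: str) -> SubstitutionClass:
    """Classify a single-base substitution.

    The collapsed class is the strand-complement closure of the
    directed pair, written with the purine reference first (so G>A and
    C>T both collapse to "G:C>A:T").
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMP or alt not in _COMP:
        raise ValueError(f"non-ACGT substitution: {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    r, a = ref, alt
    if r in "CT":  # fold onto the purine-reference strand
        r, a = _COMP[r], _COMP[a]
    collapsed = f"{r}:{_COMP[r]}>{a}:{_COMP[a]}"
    return SubstitutionClass(
        directed=f"{ref}>{alt}",
        collapsed=collapsed,
        is_canonical_ems=(ref, alt) in CANONICAL_EMS,
    )


@dataclass(frozen=True)
class SubstitutionSpectrum:
    directed: dict[str, int]
    collapsed: dict[str, int]
    total: int

    @property
    def ems_fraction(self) -> float:
        """G:C>A:T share of all substitutions; NaN when total is 0."""
        if self.total == 0:
            return math.nan
        return self.collapsed.get("G:C>A:T", 0) / self.total


def spectrum(calls: Iterable[VariantCall]) -> SubstitutionSpectrum:
    """Tabulate the substitution spectrum of a set of SNP calls.

    Calls with N in ref or alt are skipped with a warning (their
    spectrum class is undefined); indels are rejected.
    """
    directed: Counter[str] = Counter()
    collapsed: Counter[str] = Counter()
    n_skipped = 0
    for c in calls:
        if c.is_indel:
            raise ValueError("spectrum() accepts SNP calls only")
        try:
            sub = classify_substitution(c.ref, c.alt)
        except ValueError:
            n_skipped += 1
            continue
        directed[sub.directed] += 1
        collapsed[sub.collapsed] += 1
    if n_skipped:
        logger.warning("skipped %d calls with non-ACGT alleles", n_skipped)
    return SubstitutionSpectrum(
        directed=dict(directed),
        collapsed=dict(collapsed),
        total=sum(directed.values()),
    )


def repeat_filter(
    calls: Iterable[VariantCall], cfg: FilterConfig = FilterConfig()
) -> list[VariantCall]:
    """Drop low-quality, low-coverage and repeat-depth calls.

    Removes qual < min_keep_qual, depth < min_depth, depth > max_depth
    (all strict, so the boundary values 10, 2 and 100 are retained).
    """
    return [
        c
        for c in calls
        if c.qual >= cfg.min_keep_qual
        and cfg.min_depth <= c.depth <= cfg.max_depth
    ]


def genotype_quality_filter(
    calls: Iterable[VariantCall],
    gt_class: str,
    cfg: FilterConfig = FilterConfig(),
) -> list[VariantCall]:
    """Keep calls of the requested genotype class with QUAL >= 20."""
    if gt_class not in (HOM_ALT, HET):
        raise ValueError(f"unknown gt_class {gt_class!r}")
    return [
        c
        for c in calls
        if c.gt_class == gt_class and c.qual >= cfg.min_genotype_qual
    ]


def strand_filter_hom(calls: Iterable[VariantCall]) -> list[VariantCall]:
    """Homozygous strand filter: no reference reads, alt on both strands.

    Keeps calls with DP4 = (0, 0, >0, >0).
    """
    return [
        c
        for c in calls
        if c.dp4[0] == 0 and c.dp4[1] == 0 and c.dp4[2] > 0 and c.dp4[3] > 0
    ]


def strand_filter_het(calls: Iterable[VariantCall]) -> list[VariantCall]:
    """Heterozygous strand filter: alt allele on both strands.

    Reference reads are allowed (and expected) for heterozygotes.
    """
    return [c for c in calls if c.dp4[2] > 0 and c.dp4[3] > 0]


def ems_only(calls: Iterable[VariantCall]) -> list[VariantCall]:
    """Subset of SNP calls whose substitution is G>A or C>T."""
    return [
        c for c in calls if c.is_snp and (c.ref, c.alt) in CANONICAL_EMS
    ]


def standard_filter_pipeline(
    calls: Sequence[VariantCall],
    gt_class: str,
    cfg: FilterConfig = FilterConfig(),
) -> list[VariantCall]:
    """Repeat -> genotype-quality -> strand filters, in that order.

    The strand predicate is chosen by gt_class. Indels pass through the
    repeat and genotype filters identically to SNPs and use the same
    strand predicates.
    """
    out = repeat_filter(calls, cfg)
    out = genotype_quality_filter(out, gt_class, cfg)
    if gt_class == HOM_ALT:
        out = strand_filter_hom(out)
    else:
        out = strand_filter_het(out)
    return out
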