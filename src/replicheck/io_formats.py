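"""Standard-format I/O and the shared variant data model.

Variant calls live in 1-based VCF coordinates throughout the library;
exported interval files (error-prone position catalogs) use 0-based
half-open BED coordinates, each format's native convention.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

HOM_ALT = "hom_alt"
HET = "het"
GT_CLASSES = (HOM_ALT, HET)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be parsed."""


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one sequenced line.

    ``dp4`` holds strand-resolved allele depths in the bcftools order:
    (ref_fwd, ref_rev, alt_fwd, alt_rev).
    """

    line_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    qual: float
    gt_class: str
    depth: int
    dp4: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.gt_class not in GT_CLASSES:
            raise ValueError(f"gt_class must be one of {GT_CLASSES}")
        if self.qual < 0:
            raise ValueError("qual must be non-negative")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if len(self.dp4) != 4 or any(x < 0 for x in self.dp4):
            raise ValueError("dp4 must be four non-negative integers")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def indel_length(self) -> int:
        """Signed event length: positive insertions, negative deletions."""
        return len(self.alt) - len(self.ref)


class GenomeSequence:
    """A reference genome held in memory as uppercase ACGTN strings."""

    def __init__(self, sequences: Mapping[str, str]):
        seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in seqs:
                raise ValueError(f"duplicate sequence name {name!r}")
            seqs[name] = seq.upper()
        self._seqs = seqs

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def items(self) -> Iterable[tuple[str, str]]:
        return self._seqs.items()

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self._seqs[chrom][pos - 1]

    def window(self, chrom: str, pos: int, flank: int) -> str | None:
        """2*flank+1 window centered on a 1-based position.

        Returns None when the window would run past a contig end.
        """
        seq = self._seqs[chrom]
        lo = pos - 1 - flank
        hi = pos + flank
        if lo < 0 or hi > len(seq):
            return None
        return seq[lo:hi]


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript with the base composition of its exons."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 1-based, closed intervals, sorted
    spliced_length: int
    g_count: int
    c_count: int

    @property
    def gc_fraction(self) -> float:
        return (self.g_count + self.c_count) / self.spliced_length

    def contains(self, chrom: str, pos: int) -> bool:
        if chrom != self.chrom:
            return False
        return any(lo <= pos <= hi for lo, hi in self.exons)


def _gt_class_of(gt: tuple[int | None, ...]) -> str | None:
    alleles = [a for a in gt if a is not None]
    if not alleles or all(a == 0 for a in alleles):
        return None
    nonref = {a for a in alleles if a != 0}
    if len(set(alleles)) == 1:
        return HOM_ALT
    return HET if nonref else None


def read_vcf(source: str | os.PathLike | IO[str], line_id: str) -> list[VariantCall]:
    """Read variant records into VariantCall objects.

    Multi-allelic records are split into one call per alternate allele,
    each inheriting QUAL, DP and DP4. Records without DP4 get a zero
    DP4 vector and a logged warning (such calls cannot pass any strand
    filter downstream).
    """
    if hasattr(source, "read"):
        with tempfile.NamedTemporaryFile(
            "w", suffix=".vcf", delete=False
        ) as tmp:
            tmp.write(source.read())
            path = tmp.name
        try:
            return _read_vcf_path(path, line_id)
        finally:
            os.unlink(path)
    return _read_vcf_path(os.fspath(source), line_id)


def _read_vcf_path(path: str, line_id: str) -> list[VariantCall]:
    calls: list[VariantCall] = []
    n_missing_dp4 = 0
    record_index = 0
    try:
        with pysam.VariantFile(path) as vf:
            for rec in vf:
                record_index += 1
                calls_for_rec, missing = _calls_from_record(rec, line_id)
                n_missing_dp4 += missing
                calls.extend(calls_for_rec)
    except (ValueError, OSError) as exc:
        raise VcfParseError(
            f"malformed VCF near record {record_index + 1} of {path}: {exc}"
        ) from exc
    if n_missing_dp4:
        logger.warning(
            "%d record(s) in %s lacked DP4; dp4 set to (0,0,0,0)",
            n_missing_dp4,
            path,
        )
    return calls


def _calls_from_record(
    rec: pysam.VariantRecord, line_id: str
) -> tuple[list[VariantCall], int]:
    if not rec.alts:
        return [], 0
    sample = rec.samples[0] if rec.samples else None
    gt = sample["GT"] if sample is not None and "GT" in sample else None
    gt_class = _gt_class_of(gt) if gt else None
    if gt_class is None:
        return [], 0
    qual = float(rec.qual) if rec.qual is not None else 0.0
    depth = int(rec.info.get("DP", 0) or 0)
    missing = 0
    if "DP4" in rec.info:
        dp4 = tuple(int(x) for x in rec.info["DP4"])
    else:
        dp4 = (0, 0, 0, 0)
        missing = 1
    out = []
    for alt in rec.alts:
        if alt is None or alt.startswith("<"):
            continue
        out.append(
            VariantCall(
                line_id=line_id,
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alt,
                qual=qual,
                gt_class=gt_class,
                depth=depth,
                dp4=dp4,  # type: ignore[arg-type]
            )
        )
    return out, missing


VCF_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">
##INFO=<ID=DP4,Number=4,Type=Integer,Description="Ref-forward, ref-reverse, alt-forward and alt-reverse bases">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    calls: Sequence[VariantCall],
    dest: str | os.PathLike | IO[str],
    sample: str,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write calls as minimal single-sample VCF text, sorted by position."""

    def _write(fh: IO[str]) -> None:
        fh.write(VCF_HEADER_TEMPLATE)
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample}\n"
        )
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt)):
            gt = "1/1" if c.gt_class == HOM_ALT else "0/1"
            dp4 = ",".join(str(x) for x in c.dp4)
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{c.qual:g}\t.\t"
                f"DP={c.depth};DP4={dp4}\tGT\t{gt}\n"
            )

    if hasattr(dest, "write"):
        _write(dest)
    else:
        with open(dest, "w") as fh:
            _write(fh)


def read_fasta(source: str | os.PathLike | IO[str]) -> GenomeSequence:
    """Read a FASTA file or handle into a GenomeSequence (uppercased)."""
    if hasattr(source, "read"):
        records = SeqIO.parse(source, "fasta")
        return _genome_from_records(records)
    with open(source) as fh:
        return _genome_from_records(SeqIO.parse(fh, "fasta"))


def _genome_from_records(records: Iterator) -> GenomeSequence:
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return GenomeSequence(seqs)


def write_fasta(
    genome: GenomeSequence, dest: str | os.PathLike | IO[str], width: int = 70
) -> None:
    def _write(fh: IO[str]) -> None:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")

    if hasattr(dest, "write"):
        _write(dest)
    else:
        with open(dest, "w") as fh:
            _write(fh)


def read_gff3_transcripts(
    source: str | os.PathLike, genome: GenomeSequence
) -> list[TranscriptModel]:
    """Load transcript models (mRNA + exon features) from GFF3.

    Exon base composition is taken from the reference genome, so the
    G/C counts refer to the plus-strand spliced sequence; GC fraction is
    strand-symmetric so the strand does not matter for the statistics
    computed downstream.
    """
    import gffutils

    db = gffutils.create_db(
        os.fspath(source),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    out: list[TranscriptModel] = []
    for feat in db.features_of_type(("mRNA", "transcript")):
        exons = sorted(
            (e.start, e.end) for e in db.children(feat, featuretype="exon")
        )
        if not exons:
            exons = [(feat.start, feat.end)]
        spliced = "".join(
            genome[feat.seqid][lo - 1 : hi] for lo, hi in exons
        )
        parents = list(db.parents(feat, featuretype="gene"))
        gene_id = parents[0].id if parents else feat.id
        out.append(
            TranscriptModel(
                transcript_id=feat.id,
                gene_id=gene_id,
                chrom=feat.seqid,
                strand=feat.strand,
                exons=tuple(exons),
                spliced_length=len(spliced),
                g_count=spliced.count("G"),
                c_count=spliced.count("C"),
            )
        )
    return out


def write_position_list(catalog, dest: str | os.PathLike | IO[str]) -> None:
    """Export an error-prone position catalog as BED (0-based, half-open).

    Columns: chrom, start, end, consensus_alt, n_lines, allele_consistent,
    ref, gt_class. Sorted by chrom then start.
    """

    def _write(fh: IO[str]) -> None:
        entries = sorted(catalog.entries.items())
        for (chrom, pos), entry in entries:
            fh.write(
                f"{chrom}\t{pos - 1}\t{pos}\t{entry.consensus_alt}\t"
                f"{entry.n_lines}\t{int(entry.allele_consistent)}\t"
                f"{entry.ref}\t{catalog.gt_class or '.'}\n"
            )

    if hasattr(dest, "write"):
        _write(dest)
    else:
        with open(dest, "w") as fh:
            _write(fh)


def read_position_list(source: str | os.PathLike | IO[str]):
    """Read a catalog BED written by :func:`write_position_list`."""
    from .replicate_core import CatalogEntry, ErrorProneCatalog

    def _read(fh: IO[str]) -> ErrorProneCatalog:
        entries: dict[tuple[str, int], CatalogEntry] = {}
        gt_class: str | None = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"bad catalog BED line {lineno}: {line!r}")
            chrom, start, _end, alt, n_lines, consistent, ref, gt = fields[:8]
            pos = int(start) + 1
            entries[(chrom, pos)] = CatalogEntry(
                ref=ref,
                consensus_alt=alt,
                n_lines=int(n_lines),
                allele_consistent=bool(int(consistent)),
                alts=(alt,),
                line_ids=(),
            )
            gt_class = None if gt == "." else gt
        return ErrorProneCatalog(gt_class=gt_class, entries=entries)

    if hasattr(source, "read"):
        return _read(source)
    with open(source) as fh:
        return _read(fh)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]
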