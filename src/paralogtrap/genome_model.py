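"""Core genomic data types and flat-file input/output.

Conventions
-----------
* User-facing coordinates are 1-based inclusive, the genome-browser style in
  which a 141 bp segment reads ``chr9:80537082-80537222``.  Internal
  arithmetic uses 0-based offsets and converts at the boundary.
* Sequences are uppercase strings over ``A C G T N``.  ``N`` is accepted in
  input but is never treated as matching anything during alignment.
* Contig names are compared with the ``chr`` prefix stripped, so ``chr9`` and
  ``9`` refer to the same contig.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CatalogueError, CoordinateError, FastaFormatError

NUCLEOTIDES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CATALOGUE_COLUMNS = (
    "rsid",
    "contig",
    "position",
    "ref",
    "alt",
    "allele_count",
    "total_alleles",
)


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an ``ACGTN`` string (``N`` maps to ``N``)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def normalize_contig(contig: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix so contig spellings compare equal."""
    lowered = contig.lower()
    return contig[3:] if lowered.startswith("chr") else contig


def same_contig(a: str, b: str) -> bool:
    return normalize_contig(a) == normalize_contig(b)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive interval on a contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise CoordinateError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise CoordinateError(
                f"interval end ({self.end}) precedes start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.contig}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Locus:
    """A named reference segment with its genomic placement and sequence.

    ``sequence`` is the segment as stored, i.e. already reverse-complemented
    for a ``-`` strand locus; ``genomic_position`` maps stored offsets back to
    forward-strand coordinates accordingly.
    """

    name: str
    interval: GenomicInterval
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise CoordinateError(f"strand must be '+' or '-', got {self.strand!r}")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) != self.interval.length:
            raise CoordinateError(
                f"sequence length {len(seq)} does not match interval "
                f"length {self.interval.length} for locus {self.name!r}"
            )
        bad = set(seq) - NUCLEOTIDES
        if bad:
            raise FastaFormatError(
                f"locus {self.name!r} contains disallowed characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def contig(self) -> str:
        return self.interval.contig

    def genomic_position(self, offset: int) -> int:
        """Forward-strand 1-based position of 0-based stored offset."""
        if not 0 <= offset < len(self.sequence):
            raise CoordinateError(f"offset {offset} outside locus {self.name!r}")
        if self.strand == "+":
            return self.interval.start + offset
        return self.interval.end - offset

    def offset_of(self, position: int) -> int:
        """0-based stored offset of a forward-strand 1-based position."""
        if not self.interval.contains(position):
            raise CoordinateError(
                f"position {position} outside {self.interval} of locus {self.name!r}"
            )
        if self.strand == "+":
            return position - self.interval.start
        return self.interval.end - position

    def base_at(self, position: int) -> str:
        """Forward-strand base at a genomic position."""
        base = self.sequence[self.offset_of(position)]
        return base if self.strand == "+" else base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class SNPRecord:
    """A catalogued population polymorphism with its allele counts."""

    rsid: str
    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    allele_count: int
    total_alleles: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise CatalogueError(f"{self.rsid}: position must be >= 1")
        for allele in (self.ref_allele, self.alt_allele):
            if len(allele) != 1 or allele not in NUCLEOTIDES:
                raise CatalogueError(
                    f"{self.rsid}: alleles must be single nucleotides, got {allele!r}"
                )
        if self.ref_allele == self.alt_allele:
            raise CatalogueError(f"{self.rsid}: ref and alt alleles are identical")
        if self.allele_count < 0:
            raise CatalogueError(f"{self.rsid}: negative allele count")
        if self.total_alleles <= 0:
            raise CatalogueError(f"{self.rsid}: total alleles must be positive")
        if self.allele_count > self.total_alleles:
            raise CatalogueError(
                f"{self.rsid}: allele count {self.allele_count} exceeds "
                f"total {self.total_alleles}"
            )

    @property
    def maf(self) -> float:
        """Minor-allele frequency as a percentage rounded to two decimals."""
        return compute_maf(self.allele_count, self.total_alleles)


@dataclass(frozen=True)
class VariantCall:
    """An observed candidate single-nucleotide variant with depth support."""

    contig: str
    position: int
    ref: str
    alt: str
    alt_depth: int = 0
    total_depth: int = 0
    annotation: Optional[SNPRecord] = None
    label: Optional[str] = None  # free text, e.g. an amino-acid tag

    def __post_init__(self) -> None:
        if self.position < 1:
            raise CoordinateError("variant position must be >= 1")
        for allele in (self.ref, self.alt):
            if len(allele) != 1 or allele not in NUCLEOTIDES:
                raise CoordinateError(
                    f"variant alleles must be single nucleotides, got {allele!r}"
                )
        if not 0 <= self.alt_depth <= max(self.total_depth, 0):
            raise CoordinateError(
                f"invalid depths {self.alt_depth}/{self.total_depth} at "
                f"{self.contig}:{self.position}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Site identity used for matching: normalized contig, pos, ref, alt."""
        return (normalize_contig(self.contig), self.position, self.ref, self.alt)

    def with_annotation(self, record: Optional[SNPRecord]) -> "VariantCall":
        return replace(self, annotation=record)


def compute_maf(allele_count: int, total_alleles: int) -> float:
    """Minor-allele frequency as a percentage, rounded half-up to 2 decimals.

    ``compute_maf(1386, 117782)`` returns ``1.18``, the convention in which
    allele counts from population databases are quoted.
    """
    if total_alleles <= 0:
        raise CatalogueError("total_alleles must be positive")
    if not 0 <= allele_count <= total_alleles:
        raise CatalogueError(
            f"allele_count {allele_count} outside [0, {total_alleles}]"
        )
    pct = Decimal(100 * allele_count) / Decimal(total_alleles)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(name, uppercase_sequence), ...]``.

    The header token (text up to the first whitespace) names each record.
    An empty file yields an empty list; non-FASTA content or sequences with
    characters outside ``ACGTN`` raise :class:`FastaFormatError`.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return []
    if not text.lstrip().startswith(">"):
        raise FastaFormatError(f"{path}: no FASTA header line found")
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - NUCLEOTIDES
        if bad:
            raise FastaFormatError(
                f"{path}: record {rec.id!r} contains disallowed "
                f"characters {sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str] | Locus], path: str | Path) -> None:
    """Write ``(name, sequence)`` pairs or :class:`Locus` objects as FASTA."""
    seq_records = []
    for rec in records:
        if isinstance(rec, Locus):
            name, seq = rec.name, rec.sequence
        else:
            name, seq = rec
        seq_records.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(seq_records, str(path), "fasta")


def extract_locus(
    genome_record: tuple[str, str],
    interval: GenomicInterval,
    strand: str = "+",
) -> Locus:
    """Cut a :class:`Locus` out of a full-contig record.

    ``interval`` is 1-based inclusive on the record; a ``-`` strand request
    returns the reverse complement and records the strand.
    """
    name, sequence = genome_record
    sequence = sequence.upper()
    if interval.end > len(sequence):
        raise CoordinateError(
            f"{interval} extends past the end of record {name!r} "
            f"(length {len(sequence)})"
        )
    sub = sequence[interval.start - 1 : interval.end]
    if strand == "-":
        sub = reverse_complement(sub)
    return Locus(name=name, interval=interval, strand=strand, sequence=sub)


# ---------------------------------------------------------------------------
# SNP catalogue
# ---------------------------------------------------------------------------

def load_snp_catalogue(path: str | Path) -> list[SNPRecord]:
    """Load a SNP catalogue from a headered TSV or a VCF.

    TSV columns: ``rsid contig position ref alt allele_count total_alleles``.
    VCF input takes the rsID from the ID column and allele counts from the
    ``AC``/``AN`` INFO fields.  Duplicate (contig, position, alt) entries are
    rejected.
    """
    path = Path(path)
    if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        records = _catalogue_from_vcf(path)
    else:
        records = _catalogue_from_tsv(path)
    seen: set[tuple[str, int, str]] = set()
    for rec in records:
        key = (normalize_contig(rec.contig), rec.position, rec.alt_allele)
        if key in seen:
            raise CatalogueError(
                f"duplicate catalogue entry at {rec.contig}:{rec.position} "
                f"alt {rec.alt_allele}"
            )
        seen.add(key)
    return records


def _catalogue_from_tsv(path: Path) -> list[SNPRecord]:
    if path.stat().st_size == 0:
        return []
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(CATALOGUE_COLUMNS) - set(frame.columns)
    if missing:
        raise CatalogueError(f"{path}: missing catalogue columns {sorted(missing)}")
    if frame.empty:
        return []
    return [
        SNPRecord(
            rsid=row.rsid,
            contig=row.contig,
            position=int(row.position),
            ref_allele=row.ref.upper(),
            alt_allele=row.alt.upper(),
            allele_count=int(row.allele_count),
            total_alleles=int(row.total_alleles),
        )
        for row in frame.itertuples(index=False)
    ]


def _catalogue_from_vcf(path: Path) -> list[SNPRecord]:
    from cyvcf2 import VCF

    records = []
    for v in VCF(str(path)):
        ac = v.INFO.get("AC")
        an = v.INFO.get("AN")
        if ac is None or an is None:
            raise CatalogueError(
                f"{path}: VCF catalogue requires AC and AN INFO fields"
            )
        if isinstance(ac, tuple):
            ac = ac[0]
        for alt in v.ALT:
            records.append(
                SNPRecord(
                    rsid=v.ID or f"{v.CHROM}:{v.POS}",
                    contig=v.CHROM,
                    position=v.POS,
                    ref_allele=v.REF.upper(),
                    alt_allele=alt.upper(),
                    allele_count=int(ac),
                    total_alleles=int(an),
                )
            )
    return records


def write_snp_catalogue(records: Sequence[SNPRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            (r.rsid, r.contig, r.position, r.ref_allele, r.alt_allele,
             r.allele_count, r.total_alleles)
            for r in records
        ],
        columns=list(CATALOGUE_COLUMNS),
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant-call tables
# ---------------------------------------------------------------------------

def load_variant_calls(path: str | Path) -> list[VariantCall]:
    """Read candidate calls from a TSV with columns
    ``contig position ref alt alt_depth total_depth``."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"contig", "position", "ref", "alt"}
    missing = required - set(frame.columns)
    if missing:
        raise CatalogueError(f"{path}: missing variant columns {sorted(missing)}")
    calls = []
    for row in frame.itertuples(index=False):
        calls.append(
            VariantCall(
                contig=row.contig,
                position=int(row.position),
                ref=row.ref.upper(),
                alt=row.alt.upper(),
                alt_depth=int(getattr(row, "alt_depth", 0) or 0),
                total_depth=int(getattr(row, "total_depth", 0) or 0),
            )
        )
    return calls


def write_variant_calls(calls: Sequence[VariantCall], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            (c.contig, c.position, c.ref, c.alt, c.alt_depth, c.total_depth,
             c.annotation.rsid if c.annotation else ".",
             c.annotation.maf if c.annotation else math.nan)
            for c in calls
        ],
        columns=["contig", "position", "ref", "alt", "alt_depth",
                 "total_depth", "rsid", "maf_pct"],
    )
    frame.to_csv(path, sep="\t", index=False)


def write_vcf(calls: Sequence[VariantCall], path: str | Path,
              contig_lengths: Optional[dict[str, int]] = None) -> None:
    """Write calls as a minimal VCF; rsIDs of annotated calls go in ID."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("source", "paralogtrap")
    contigs = contig_lengths or {}
    for call in calls:
        contigs.setdefault(call.contig, call.position + 1_000_000)
    for contig, length in contigs.items():
        header.contigs.add(contig, length=length)
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.info.add("DP", "1", "Integer", "Total depth")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in calls:
            rec = out.new_record(
                contig=call.contig,
                start=call.position - 1,
                stop=call.position,
                alleles=(call.ref, call.alt),
                id=call.annotation.rsid if call.annotation else None,
            )
            rec.info["DP"] = call.total_depth
            out.write(rec)
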