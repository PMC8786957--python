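"""Align reads against a small set of candidate loci and classify ambiguity.

Every read is aligned exhaustively (exact Smith-Waterman, both read
orientations) against every candidate locus.  The best alignment per locus
is kept; the overall best is the primary, mirroring the seed-and-extend
convention in which the highest-scoring alignment wins.  A read whose best
and second-best locus scores differ by at most ``tie_margin`` is classified
``ambiguous`` — under the default scheme one extra mismatch swings the score
by ``match - mismatch = 5``, so the default margin of 5 makes a read that
differs from two loci by one mismatch count non-unique, which is precisely
the situation that turns paralog reads into false somatic calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .errors import AlignmentError
from .genome_model import Locus, VariantCall, reverse_complement
from .pairwise_align import (
    DEFAULT_SCHEME,
    AlignmentResult,
    ScoringScheme,
    smith_waterman,
)
from .read_sim import SimulatedRead

DEFAULT_TIE_MARGIN = 5

UNIQUE = "unique"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class LocusAlignment:
    """The best local alignment of one read against one locus."""

    locus: Locus
    alignment: AlignmentResult
    reversed: bool  # True when the aligned query is the read's reverse complement

    @property
    def score(self) -> int:
        return self.alignment.score

    def genomic_position(self, target_offset: int) -> int:
        return self.locus.genomic_position(target_offset)

    @property
    def target_span(self) -> tuple[int, int]:
        """1-based inclusive genomic span covered on the locus."""
        a = self.locus.genomic_position(self.alignment.target_start)
        b = self.locus.genomic_position(self.alignment.target_end - 1)
        return (min(a, b), max(a, b))


@dataclass(frozen=True)
class MappingReport:
    """Ranked per-locus alignments of one read plus the ambiguity verdict."""

    read_id: str
    alignments: tuple[LocusAlignment, ...]  # sorted: score desc, locus name asc
    tie_margin: int = DEFAULT_TIE_MARGIN

    @property
    def best(self) -> LocusAlignment:
        return self.alignments[0]

    @property
    def best_locus(self) -> str:
        return self.best.locus.name

    def by_locus(self, name: str) -> LocusAlignment:
        for la in self.alignments:
            if la.locus.name == name:
                return la
        raise KeyError(name)

    @property
    def score_gap(self) -> float:
        if len(self.alignments) < 2:
            return math.inf
        return float(self.alignments[0].score - self.alignments[1].score)

    @property
    def mapping_class(self) -> str:
        return classify_mapping(self, self.tie_margin)


def align_read(
    read: Union[str, SimulatedRead],
    loci: Sequence[Locus],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    tie_margin: int = DEFAULT_TIE_MARGIN,
    read_id: Optional[str] = None,
) -> MappingReport:
    """Best alignment of the read against every locus, ranked and classified."""
    if not loci:
        raise AlignmentError("need at least one candidate locus")
    if isinstance(read, SimulatedRead):
        sequence = read.sequence
        read_id = read_id or read.id
    else:
        sequence = read
        read_id = read_id or "read"
    if not sequence:
        raise AlignmentError("cannot align an empty read")
    rc = reverse_complement(sequence)
    per_locus: list[LocusAlignment] = []
    for locus in loci:
        fwd = smith_waterman(sequence, locus.sequence, scheme)
        rev = smith_waterman(rc, locus.sequence, scheme)
        if rev.score > fwd.score:
            per_locus.append(LocusAlignment(locus, rev, True))
        else:
            per_locus.append(LocusAlignment(locus, fwd, False))
    per_locus.sort(key=lambda la: (-la.score, la.locus.name))
    return MappingReport(read_id=read_id, alignments=tuple(per_locus),
                         tie_margin=tie_margin)


def classify_mapping(report: MappingReport,
                     tie_margin: int = DEFAULT_TIE_MARGIN) -> str:
    """``ambiguous`` iff best-minus-second-best score <= tie_margin.

    Reports with a single candidate locus are unique by definition.
    """
    if not report.alignments:
        raise AlignmentError("report carries no alignments")
    return AMBIGUOUS if report.score_gap <= tie_margin else UNIQUE


def call_variants(locus_alignment: LocusAlignment) -> list[VariantCall]:
    """One SNV per mismatch column of an alignment, in genomic coordinates.

    Gap columns never yield SNVs.  Alleles are reported on the forward
    strand of the locus's contig.
    """
    locus = locus_alignment.locus
    aln = locus_alignment.alignment
    calls = []
    for col in aln.columns():
        if col.op != "X":
            continue
        position = locus.genomic_position(col.target_offset)
        ref, alt = col.target_base, col.query_base
        if locus.strand == "-":
            ref = reverse_complement(ref)
            alt = reverse_complement(alt)
        calls.append(
            VariantCall(contig=locus.contig, position=position,
                        ref=ref, alt=alt, alt_depth=1, total_depth=1)
        )
    calls.sort(key=lambda c: c.position)
    return calls


def pileup_variants(
    reports: Sequence[MappingReport],
    locus: Locus,
    min_alt_depth: int = 1,
) -> list[VariantCall]:
    """Aggregate per-read mismatch calls of primary alignments into a pileup.

    Only reads whose *primary* alignment is on ``locus`` contribute; depth at
    a position counts primary reads with an aligned (non-gap) column there.
    """
    alt_counts: dict[tuple[str, int, str, str], int] = {}
    depth: dict[int, int] = {}
    for report in reports:
        best = report.best
        if best.locus.name != locus.name:
            continue
        for col in best.alignment.columns():
            if col.target_offset is None:
                continue
            pos = locus.genomic_position(col.target_offset)
            depth[pos] = depth.get(pos, 0) + 1
        for call in call_variants(best):
            key = (call.contig, call.position, call.ref, call.alt)
            alt_counts[key] = alt_counts.get(key, 0) + 1
    calls = [
        VariantCall(contig=contig, position=pos, ref=ref, alt=alt,
                    alt_depth=count, total_depth=depth[pos])
        for (contig, pos, ref, alt), count in alt_counts.items()
        if count >= min_alt_depth
    ]
    calls.sort(key=lambda c: (c.position, c.alt))
    return calls


def reports_to_table(reports: Sequence[MappingReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for rank, la in enumerate(rep.alignments):
            rows.append(
                {
                    "read_id": rep.read_id,
                    "rank": rank,
                    "locus": la.locus.name,
                    "score": la.score,
                    "n_mismatch": la.alignment.n_mismatch,
                    "n_gap_bases": la.alignment.n_gap_bases,
                    "reversed": la.reversed,
                    "score_gap": rep.score_gap if rank == 0 else float("nan"),
                    "mapping_class": rep.mapping_class if rank == 0 else "",
                }
            )
    return pd.DataFrame(rows)


def export_sam(reports: Sequence[MappingReport], loci: Sequence[Locus],
               path: str | Path) -> None:
    """Write mapping reports as SAM: primary line per read plus secondary
    lines for the other loci, with AS (score) and NM (edit distance) tags.

    Reference names are locus names and positions are locus-local (1-based),
    which keeps the file self-contained with the emitted FASTA.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": locus.name, "LN": len(locus)} for locus in loci],
    }
    ref_ids = {locus.name: idx for idx, locus in enumerate(loci)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rep in reports:
            for rank, la in enumerate(rep.alignments):
                aln = la.alignment
                seg = pysam.AlignedSegment()
                seg.query_name = rep.read_id
                seg.query_sequence = aln.query
                seg.flag = (0x100 if rank > 0 else 0) | (0x10 if la.reversed else 0)
                seg.reference_id = ref_ids[la.locus.name]
                seg.reference_start = aln.target_start
                seg.mapping_quality = 60 if rep.mapping_class == UNIQUE else 0
                cigar = []
                if aln.query_start:
                    cigar.append((4, aln.query_start))  # soft clip
                op_codes = {"=": 7, "X": 8, "I": 1, "D": 2}
                cigar.extend((op_codes[op], length) for op, length in aln.path)
                tail = len(aln.query) - aln.query_end
                if tail:
                    cigar.append((4, tail))
                seg.cigartuples = cigar
                seg.set_tag("AS", aln.score)
                seg.set_tag("NM", aln.n_mismatch + aln.n_gap_bases)
                out.write(seg)
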