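"""Smith-Waterman local alignment with affine gaps, and the homology envelope.

The aligner is an exact O(mn) Gotoh dynamic program (no banding, no seeding):
candidate loci here are at most a few kilobases, and exactness is part of the
contract — mismatch accounting downstream must be provably correct, not
heuristic.  The inner loops are vectorised with numpy row by row; the
horizontal gap state is closed in O(n) per row with a running-maximum
identity, which is exact whenever ``gap_open < 0``.

Scoring follows the BWA-MEM convention: a gap of length ``k`` costs
``gap_open + k * gap_extend``, matches earn ``match``, mismatches cost
``mismatch``.  ``N`` never matches anything.

The homology envelope is the maximal locally aligned interval pair between
two loci (e.g. a gene and its pseudogene), stored with the full alignment
path so positions can be projected from one locus to the other through it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .errors import AlignmentError, CoordinateError
from .genome_model import GenomicInterval, Locus, reverse_complement

_NEG = np.int64(-(10**15))
_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
MATCH, MISMATCH, INSERTION, DELETION = "=", "X", "I", "D"


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring parameters.

    Defaults mirror BWA-MEM's (match +1, mismatch -4, gap open -6,
    gap extend -1) so that synthetic mismatch accounting uses the same
    trade-offs a short-read aligner would.
    """

    match: int = 1
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise AlignmentError("match reward must be positive")
        if self.mismatch >= 0:
            raise AlignmentError("mismatch penalty must be negative")
        if not self.gap_open <= self.gap_extend <= 0:
            raise AlignmentError("require gap_open <= gap_extend <= 0")

    def score_path(self, path: tuple[tuple[str, int], ...]) -> int:
        """Score of an operation path under this scheme (gap = open + k*extend)."""
        total = 0
        for op, length in path:
            if op == MATCH:
                total += self.match * length
            elif op == MISMATCH:
                total += self.mismatch * length
            elif op in (INSERTION, DELETION):
                total += self.gap_open + self.gap_extend * length
            else:  # pragma: no cover - defensive
                raise AlignmentError(f"unknown path operation {op!r}")
        return total


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class AlignmentColumn:
    op: str
    query_offset: Optional[int]
    target_offset: Optional[int]
    query_base: Optional[str]
    target_base: Optional[str]


@dataclass(frozen=True)
class AlignmentResult:
    """A scored local alignment with explicit mismatch/gap accounting.

    Offsets are 0-based half-open on the input sequences; genomic rendering
    is the caller's job (via a :class:`~paralogtrap.genome_model.Locus`).
    ``I`` consumes query only, ``D`` consumes target only.
    """

    query: str
    target: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    path: tuple[tuple[str, int], ...]
    score: int

    @property
    def n_columns(self) -> int:
        return sum(length for _, length in self.path)

    @property
    def n_match(self) -> int:
        return sum(l for op, l in self.path if op == MATCH)

    @property
    def n_mismatch(self) -> int:
        return sum(l for op, l in self.path if op == MISMATCH)

    @property
    def n_gap_bases(self) -> int:
        return sum(l for op, l in self.path if op in (INSERTION, DELETION))

    @property
    def identity(self) -> float:
        return self.n_match / self.n_columns if self.n_columns else 0.0

    @property
    def mismatch_positions(self) -> tuple[int, ...]:
        """0-based target offsets of mismatch columns."""
        return tuple(
            col.target_offset
            for col in self.columns()
            if col.op == MISMATCH and col.target_offset is not None
        )

    def columns(self) -> Iterator[AlignmentColumn]:
        q, t = self.query_start, self.target_start
        for op, length in self.path:
            for _ in range(length):
                if op in (MATCH, MISMATCH):
                    yield AlignmentColumn(op, q, t, self.query[q], self.target[t])
                    q += 1
                    t += 1
                elif op == INSERTION:
                    yield AlignmentColumn(op, q, None, self.query[q], None)
                    q += 1
                else:  # DELETION
                    yield AlignmentColumn(op, None, t, None, self.target[t])
                    t += 1

    def query_base_at_target(self, target_offset: int) -> Optional[str]:
        """Query base aligned to a target offset, or None if gapped/uncovered."""
        for col in self.columns():
            if col.target_offset == target_offset:
                return col.query_base
        return None

    def cigar(self) -> str:
        return "".join(f"{length}{op}" for op, length in self.path)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_CODES[b] for b in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:  # pragma: no cover - validated upstream normally
        raise AlignmentError(f"non-nucleotide character {exc} in sequence") from exc


def smith_waterman(
    seq_a: str,
    seq_b: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> AlignmentResult:
    """Maximum-scoring local alignment of ``seq_a`` (query) vs ``seq_b`` (target).

    Traceback tie-breaks are fixed — diagonal over vertical (query gap
    closes) over horizontal — and the start cell is the first maximum in
    row-major order, so the reported alignment is deterministic.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if not seq_a or not seq_b:
        raise AlignmentError("cannot align an empty sequence")
    a, b = _encode(seq_a), _encode(seq_b)
    m, n = len(a), len(b)
    oe = scheme.gap_open + scheme.gap_extend
    ext = scheme.gap_extend

    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), _NEG, dtype=np.int64)  # horizontal: gap in query
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int64)  # vertical: gap in target
    ext_j = ext * np.arange(n + 1, dtype=np.int64)
    open_plus_ext_j = scheme.gap_open + ext_j
    # substitution score of every target column against each possible query code
    sub_rows = np.where(
        (b[None, :] == np.arange(4, dtype=np.int8)[:, None]),
        scheme.match,
        scheme.mismatch,
    ).astype(np.int64)
    sub_rows[:, b == 4] = scheme.mismatch
    sub_rows = np.vstack([sub_rows, np.full(n, scheme.mismatch, dtype=np.int64)])
    t = np.empty(n + 1, dtype=np.int64)
    tmp = np.empty(n, dtype=np.int64)

    for i in range(1, m + 1):
        hp = H[i - 1]
        np.add(hp[1:], oe, out=tmp)
        frow = F[i]
        np.add(F[i - 1, 1:], ext, out=frow[1:])
        np.maximum(frow[1:], tmp, out=frow[1:])
        np.add(hp[:-1], sub_rows[a[i - 1]], out=tmp)  # diagonal move
        h0 = np.maximum(tmp, frow[1:])
        np.maximum(h0, 0, out=h0)
        # close the horizontal gap state in one pass:
        # E[i,j] = gap_open + ext*j + max_{k<j}(h[k] - ext*k), exact for gap_open<0
        t[0] = 0
        np.subtract(h0, ext_j[1:], out=t[1:])
        np.maximum.accumulate(t, out=t)
        erow = E[i]
        np.add(open_plus_ext_j[1:], t[:-1], out=erow[1:])
        np.maximum(h0, erow[1:], out=H[i, 1:])

    flat = int(np.argmax(H))
    i, j = divmod(flat, n + 1)
    score = int(H[i, j])
    if score == 0:
        return AlignmentResult(seq_a, seq_b, 0, 0, 0, 0, (), 0)
    q_end, t_end = i, j

    ops: list[str] = []
    state = "H"
    while True:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            moved = False
            if i > 0 and j > 0:
                match_here = a[i - 1] == b[j - 1] and a[i - 1] != 4 and b[j - 1] != 4
                sub = scheme.match if match_here else scheme.mismatch
                if h == H[i - 1, j - 1] + sub:
                    ops.append(MATCH if match_here else MISMATCH)
                    i -= 1
                    j -= 1
                    moved = True
            if not moved and i > 0 and h == F[i, j]:
                state = "F"
                moved = True
            if not moved and j > 0 and h == E[i, j]:
                state = "E"
                moved = True
            if not moved:  # pragma: no cover - defensive
                raise AlignmentError("traceback failed: inconsistent DP matrices")
        elif state == "F":
            ops.append(INSERTION)
            if H[i - 1, j] + oe == F[i, j]:
                state = "H"
            i -= 1
        else:  # state == "E"
            ops.append(DELETION)
            if H[i, j - 1] + oe == E[i, j]:
                state = "H"
            j -= 1

    ops.reverse()
    path: list[tuple[str, int]] = []
    for op in ops:
        if path and path[-1][0] == op:
            path[-1] = (op, path[-1][1] + 1)
        else:
            path.append((op, 1))
    return AlignmentResult(
        query=seq_a,
        target=seq_b,
        query_start=i,
        query_end=q_end,
        target_start=j,
        target_end=t_end,
        path=tuple(path),
        score=score,
    )


# ---------------------------------------------------------------------------
# Homology envelope
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomologyEnvelope:
    """Paired intervals on two loci plus the alignment path between them.

    ``path`` aligns locus_a's footprint (ascending genomic order) against
    locus_b's footprint in the stored ``orientation``; for ``inverted``
    envelopes, walking the path moves *down* locus_b's coordinates and
    projected alleles must be complemented by the caller (see
    ``complement_alleles``).
    """

    locus_a: Locus
    locus_b: Locus
    interval_a: GenomicInterval
    interval_b: GenomicInterval
    orientation: str  # {"same", "inverted"}
    path: tuple[tuple[str, int], ...]
    score: int = 0
    identity: float = 0.0

    @property
    def complement_alleles(self) -> bool:
        return self.orientation == "inverted"

    @property
    def length_a(self) -> int:
        return self.interval_a.length

    @property
    def n_mismatch_columns(self) -> int:
        return sum(l for op, l in self.path if op == MISMATCH)

    def project(self, position_on_a: int) -> Optional[int]:
        return project_position(self, position_on_a)

    def project_to_a(self, position_on_b: int) -> Optional[int]:
        """Inverse projection (locus_b position -> locus_a position)."""
        if not self.interval_b.contains(position_on_b):
            raise CoordinateError(
                f"position {position_on_b} outside envelope interval {self.interval_b}"
            )
        if self.orientation == "same":
            d = position_on_b - self.interval_b.start
        else:
            d = self.interval_b.end - position_on_b
        a_off, b_off = 0, 0
        for op, length in self.path:
            if op in (MATCH, MISMATCH):
                if b_off <= d < b_off + length:
                    return self.interval_a.start + a_off + (d - b_off)
                a_off += length
                b_off += length
            elif op == INSERTION:  # consumes a only
                a_off += length
            else:  # DELETION consumes b only
                if b_off <= d < b_off + length:
                    return None
                b_off += length
        raise CoordinateError("projection walk exhausted the envelope path")

    def to_record(self) -> dict:
        """BED-like serialisable record (two blocks + CIGAR-style path)."""
        return {
            "contig_a": self.interval_a.contig,
            "start_a": self.interval_a.start,
            "end_a": self.interval_a.end,
            "contig_b": self.interval_b.contig,
            "start_b": self.interval_b.start,
            "end_b": self.interval_b.end,
            "orientation": self.orientation,
            "path": "".join(f"{l}{op}" for op, l in self.path),
            "score": self.score,
            "identity": round(self.identity, 4),
        }


def project_position(envelope: HomologyEnvelope, position_on_a: int) -> Optional[int]:
    """Project a locus_a position through the envelope onto locus_b.

    Returns the aligned 1-based position on locus_b, or ``None`` when the
    position falls in a gap column ("gapped").  Positions outside the
    envelope raise :class:`CoordinateError`.  For inverted envelopes the
    returned position is on the opposite strand; allele comparisons must
    complement (``envelope.complement_alleles``).
    """
    if not envelope.interval_a.contains(position_on_a):
        raise CoordinateError(
            f"position {position_on_a} outside envelope interval {envelope.interval_a}"
        )
    d = position_on_a - envelope.interval_a.start
    a_off, b_off = 0, 0
    for op, length in envelope.path:
        if op in (MATCH, MISMATCH):
            if a_off <= d < a_off + length:
                b_here = b_off + (d - a_off)
                if envelope.orientation == "same":
                    return envelope.interval_b.start + b_here
                return envelope.interval_b.end - b_here
            a_off += length
            b_off += length
        elif op == INSERTION:  # consumes a only: a column aligned to a gap in b
            if a_off <= d < a_off + length:
                return None
            a_off += length
        else:  # DELETION consumes b only
            b_off += length
    raise CoordinateError("projection walk exhausted the envelope path")


def derive_envelope(
    locus_a: Locus,
    locus_b: Locus,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_identity: float = 0.8,
    min_length: int = 50,
) -> Optional[HomologyEnvelope]:
    """Locate the homologous interval pair between two loci.

    Aligns locus_b in both orientations, keeps the higher-scoring local
    alignment, and returns ``None`` ("no homology") when the fraction of
    matching columns falls below ``min_identity`` or the alignment spans
    fewer than ``min_length`` columns (unrelated sequences always contain
    short perfect matches by chance; a homology envelope must be long
    enough to trap a read).
    """
    if not 0 < min_identity <= 1:
        raise AlignmentError("min_identity must be in (0, 1]")
    fwd = smith_waterman(locus_a.sequence, locus_b.sequence, scheme)
    rev = smith_waterman(
        locus_a.sequence, reverse_complement(locus_b.sequence), scheme
    )
    if fwd.score >= rev.score:
        best, orientation = fwd, "same"
    else:
        best, orientation = rev, "inverted"
    if best.n_columns < max(min_length, 1) or best.identity < min_identity:
        return None

    pos_a = sorted(
        (locus_a.genomic_position(best.query_start),
         locus_a.genomic_position(best.query_end - 1))
    )
    interval_a = GenomicInterval(locus_a.contig, pos_a[0], pos_a[1])
    L = len(locus_b.sequence)
    if orientation == "same":
        offs = (best.target_start, best.target_end - 1)
    else:
        # offsets are on the reverse complement; map back to stored coordinates
        offs = (L - best.target_end, L - 1 - best.target_start)
    pos_b = sorted(
        (locus_b.genomic_position(offs[0]), locus_b.genomic_position(offs[1]))
    )
    interval_b = GenomicInterval(locus_b.contig, pos_b[0], pos_b[1])
    return HomologyEnvelope(
        locus_a=locus_a,
        locus_b=locus_b,
        interval_a=interval_a,
        interval_b=interval_b,
        orientation=orientation,
        path=best.path,
        score=best.score,
        identity=best.identity,
    )
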