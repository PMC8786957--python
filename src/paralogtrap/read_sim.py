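"""Error-free read simulation with configurable read-length models.

The two stock models emulate the library types whose read-length contrast
drives the leak-through phenomenon: fragmented FFPE tumor DNA (truncated
normal, mean 90 bp, capped at 100 bp) versus fresh whole-blood germline DNA
(fixed 125 bp).  Reads are single-end and error-free by default — the
misalignment argument is about where perfect reads go, not about sequencing
noise — with an optional uniform substitution-error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import SimulationError
from .genome_model import Locus, VariantCall, reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReadLengthModel:
    """Distribution of read lengths in bases.

    ``fixed`` always emits ``mean``; ``truncated-normal`` draws from a normal
    with the given mean/sd truncated to ``[min_length, max_length]`` and
    rounds to integers.
    """

    kind: str  # {"fixed", "truncated-normal"}
    mean: float
    sd: float = 0.0
    min_length: int = 20
    max_length: int = 500

    def __post_init__(self) -> None:
        if self.kind not in {"fixed", "truncated-normal"}:
            raise SimulationError(f"unknown length-model kind {self.kind!r}")
        if self.min_length < 20:
            raise SimulationError("minimum read length must be >= 20")
        if self.max_length < self.min_length:
            raise SimulationError(
                f"max_length {self.max_length} < min_length {self.min_length}"
            )
        if self.kind == "fixed":
            if not self.min_length <= self.mean <= self.max_length:
                raise SimulationError("fixed length outside [min, max]")
        elif self.sd <= 0:
            raise SimulationError("truncated-normal model needs sd > 0")

    @classmethod
    def fixed(cls, length: int) -> "ReadLengthModel":
        return cls(kind="fixed", mean=length, min_length=min(length, 500),
                   max_length=max(length, 20))

    @classmethod
    def truncated_normal(cls, mean: float, sd: float,
                         min_length: int, max_length: int) -> "ReadLengthModel":
        return cls(kind="truncated-normal", mean=mean, sd=sd,
                   min_length=min_length, max_length=max_length)

    def truncated_mean(self) -> float:
        """Analytic mean of the model (before integer rounding)."""
        if self.kind == "fixed":
            return float(self.mean)
        a = (self.min_length - self.mean) / self.sd
        b = (self.max_length - self.mean) / self.sd
        return float(truncnorm.mean(a, b, loc=self.mean, scale=self.sd))


#: Fragmented FFPE tumor libraries: short reads, never above ~100 bp.
FFPE_MODEL = ReadLengthModel.truncated_normal(mean=90, sd=10,
                                              min_length=50, max_length=100)
#: Whole-blood germline libraries: fixed 125 bp reads.
BLOOD_MODEL = ReadLengthModel.fixed(125)


def sample_lengths(model: ReadLengthModel, n: int, seed: int = 0) -> list[int]:
    """Draw ``n`` integer read lengths from the model, deterministic under seed."""
    if n < 1:
        raise SimulationError("n must be >= 1")
    if model.kind == "fixed":
        return [int(model.mean)] * n
    a = (model.min_length - model.mean) / model.sd
    b = (model.max_length - model.mean) / model.sd
    rng = np.random.default_rng(seed)
    draws = truncnorm.rvs(a, b, loc=model.mean, scale=model.sd,
                          size=n, random_state=rng)
    lengths = np.clip(np.rint(draws).astype(int),
                      model.min_length, model.max_length)
    return lengths.tolist()


@dataclass(frozen=True)
class SimulatedRead:
    """A simulated read with its ground-truth provenance.

    ``truth_start`` is the 1-based genomic position of the leftmost covered
    base on the source locus; ``truth_strand`` is ``-`` when the emitted
    sequence is the reverse complement of the source subsequence.
    """

    id: str
    sequence: str
    truth_locus: str
    truth_start: int
    truth_strand: str = "+"
    carried_variants: tuple[VariantCall, ...] = ()

    def __len__(self) -> int:
        return len(self.sequence)


def inject_variants(locus: Locus, variants: Sequence[VariantCall]) -> str:
    """Return the locus sequence with the variant alt alleles substituted.

    Each variant's ref allele must match the locus at its position (this
    guards against coordinate bookkeeping bugs); the input locus is not
    modified.  Alleles are interpreted on the forward strand and stored in
    the locus's own orientation.
    """
    seq = list(locus.sequence)
    for v in variants:
        if not locus.interval.contains(v.position):
            raise SimulationError(
                f"variant {v.contig}:{v.position} outside locus {locus.name!r}"
            )
        observed = locus.base_at(v.position)
        if observed != v.ref:
            raise SimulationError(
                f"ref-allele mismatch at {v.contig}:{v.position}: variant says "
                f"{v.ref!r} but locus {locus.name!r} has {observed!r}"
            )
        off = locus.offset_of(v.position)
        alt = v.alt if locus.strand == "+" else reverse_complement(v.alt)
        seq[off] = alt
    return "".join(seq)


def simulate_reads(
    locus: Locus,
    variants: Sequence[VariantCall],
    length_model: ReadLengthModel,
    n_reads: int,
    seed: int = 0,
    *,
    start: Optional[int] = None,
    start_window: Optional[tuple[int, int]] = None,
    rc_prob: float = 0.0,
    error_rate: float = 0.0,
    id_prefix: Optional[str] = None,
) -> list[SimulatedRead]:
    """Simulate error-free reads from a locus carrying injected variants.

    Start positions are uniform over all starts that keep the read inside
    the locus (optionally restricted to ``start_window``, a 1-based genomic
    interval of allowed leftmost positions), or pinned with ``start``.
    Reads are reverse-complemented with probability ``rc_prob``.
    Deterministic under ``seed``.
    """
    if n_reads < 1:
        raise SimulationError("n_reads must be >= 1")
    if not 0 <= rc_prob <= 1:
        raise SimulationError("rc_prob must be in [0, 1]")
    if len(locus) < length_model.max_length:
        raise SimulationError(
            f"locus {locus.name!r} ({len(locus)} bp) shorter than the length "
            f"model maximum ({length_model.max_length} bp)"
        )
    mutated = inject_variants(locus, variants)
    rng = np.random.default_rng(seed)
    lengths = sample_lengths(length_model, n_reads,
                             seed=int(rng.integers(2**31)))
    prefix = id_prefix or locus.name
    reads: list[SimulatedRead] = []
    for i, length in enumerate(lengths):
        max_off = len(locus) - length
        lo, hi = 0, max_off
        if start_window is not None:
            lo = max(lo, locus.offset_of(max(start_window[0], locus.interval.start)))
            hi = min(hi, locus.offset_of(min(start_window[1], locus.interval.end)))
            if lo > hi:
                raise SimulationError("start_window admits no valid read start")
        if start is not None:
            off = locus.offset_of(start)
            if off > max_off:
                raise SimulationError("fixed start leaves no room for the read")
        else:
            off = int(rng.integers(lo, hi + 1))
        seq = mutated[off : off + length]
        if error_rate > 0:
            seq = _apply_errors(seq, error_rate, rng)
        strand = "+"
        if rc_prob > 0 and rng.random() < rc_prob:
            seq = reverse_complement(seq)
            strand = "-"
        carried = tuple(
            v for v in variants
            if off <= locus.offset_of(v.position) < off + length
        )
        # leftmost genomic position of the covered span
        span_positions = (locus.genomic_position(off),
                          locus.genomic_position(off + length - 1))
        reads.append(
            SimulatedRead(
                id=f"{prefix}_r{i:05d}",
                sequence=seq,
                truth_locus=locus.name,
                truth_start=min(span_positions),
                truth_strand=strand,
                carried_variants=carried,
            )
        )
    return reads


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for pos in hits:
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[int(rng.integers(3))]
    return "".join(arr)


def read_fastq(path: str | Path) -> list[SimulatedRead]:
    """Load reads written by :func:`write_fastq`, restoring truth labels."""
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        fields = dict(
            token.split("=", 1)
            for token in rec.description.split()[1:]
            if "=" in token
        )
        reads.append(
            SimulatedRead(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                truth_locus=fields.get("locus", "?"),
                truth_start=int(fields.get("start", 1)),
                truth_strand=fields.get("strand", "+"),
            )
        )
    return reads


def write_fastq(reads: Sequence[SimulatedRead], path: str | Path,
                quality_char: str = "I") -> None:
    """Write reads as FASTQ with constant quality and truth labels in headers."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(
                f"@{read.id} locus={read.truth_locus} start={read.truth_start} "
                f"strand={read.truth_strand}\n{read.sequence}\n+\n"
                f"{quality_char * len(read.sequence)}\n"
            )


def truth_table(reads: Sequence[SimulatedRead]) -> pd.DataFrame:
    """Tabulate truth labels: one row per read."""
    rows = []
    for read in reads:
        rows.append(
            {
                "read_id": read.id,
                "truth_locus": read.truth_locus,
                "truth_start": read.truth_start,
                "truth_strand": read.truth_strand,
                "length": len(read),
                "carried_variants": ";".join(
                    f"{v.contig}:{v.position}{v.ref}>{v.alt}"
                    for v in read.carried_variants
                ) or ".",
            }
        )
    return pd.DataFrame(rows)
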