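"""The decision layer: validation criteria, leak-through risk, verdicts.

Two per-alignment criteria decide whether a candidate somatic variant at the
gene locus is genuine:

1. *encodes* — the read alignment must actually carry the target variant
   allele(s) at the target position(s);
2. *errorless extension* — the alignment must continue past the homology
   envelope boundary into gene-unique flank for at least ``min_flank``
   columns with zero mismatches and zero gaps in every such extension.

A variant with at least one supporting read satisfying both is
``confirmed``; if no supporting read escapes the envelope and the
cross-locus SNP pattern is complete it is an ``artefact_suspect``;
everything else is ``indeterminate``.

The leak-through model quantifies why matched tumor/normal designs fail to
subtract such artefacts: for a read length L and an envelope of length E,
the probability that a read covering the variant lies wholly inside the
envelope (and is therefore assignable to either locus) is computed by exact
enumeration of start positions.  Short FFPE tumor reads have a higher
trapped probability than long blood normal reads, so the artefact appears in
the tumor but not the normal and survives somatic subtraction.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .errors import ParalogTrapError
from .genome_model import (
    GenomicInterval,
    Locus,
    SNPRecord,
    VariantCall,
    normalize_contig,
)
from .multi_locus_aligner import (
    DEFAULT_TIE_MARGIN,
    LocusAlignment,
    MappingReport,
    align_read,
    pileup_variants,
)
from .pairwise_align import DEFAULT_SCHEME, HomologyEnvelope, ScoringScheme
from .read_sim import ReadLengthModel, SimulatedRead, sample_lengths
from .variant_projection import ArtefactPattern, annotate_calls, match_artefact_pattern

CONFIRMED = "confirmed"
ARTEFACT_SUSPECT = "artefact_suspect"
INDETERMINATE = "indeterminate"

DEFAULT_MIN_FLANK = 10
DEFAULT_COMMON_MAF_PCT = 0.1


# ---------------------------------------------------------------------------
# Per-alignment criteria
# ---------------------------------------------------------------------------

def criterion_encodes(
    gene_alignment: LocusAlignment,
    target_variants: Sequence[VariantCall],
) -> bool:
    """Does the alignment carry every target variant's alt allele?

    True iff each target position is covered by an aligned (non-gap) column
    whose read base equals the variant's alt allele (forward strand).
    """
    locus = gene_alignment.locus
    aln = gene_alignment.alignment
    wanted = {}
    for v in target_variants:
        if not locus.interval.contains(v.position):
            return False
        wanted[locus.offset_of(v.position)] = (
            v.alt if locus.strand == "+" else _complement(v.alt)
        )
    found = 0
    for col in aln.columns():
        if col.target_offset in wanted:
            if col.query_base != wanted[col.target_offset]:
                return False
            found += 1
    return found == len(wanted)


def _complement(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[base]


def criterion_errorless_extension(
    gene_alignment: LocusAlignment,
    envelope: HomologyEnvelope,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> bool:
    """Does the alignment extend errorless beyond the homology envelope?

    True iff the alignment has >= ``min_flank`` aligned columns past at
    least one envelope boundary and *every* extension region (left and
    right of the envelope) is free of mismatches and gap columns.
    """
    locus = gene_alignment.locus
    interval = envelope.interval_a
    left_cols = right_cols = 0
    left_clean = right_clean = True
    current_pos = None
    for col in gene_alignment.alignment.columns():
        if col.target_offset is not None:
            current_pos = locus.genomic_position(col.target_offset)
        if current_pos is None:
            continue  # leading insertion before any aligned target base
        if current_pos < interval.start:
            region = "left" if locus.strand == "+" else "right"
        elif current_pos > interval.end:
            region = "right" if locus.strand == "+" else "left"
        else:
            continue
        clean = col.op == "="
        if region == "left":
            left_cols += 1
            left_clean &= clean
        else:
            right_cols += 1
            right_clean &= clean
    if not (left_clean and right_clean):
        return False
    return (left_cols >= min_flank and left_cols > 0) or (
        right_cols >= min_flank and right_cols > 0
    )


# ---------------------------------------------------------------------------
# Leak-through probability model
# ---------------------------------------------------------------------------

def ambiguity_probability(
    read_length: int,
    envelope_interval: GenomicInterval,
    variant_position: int,
) -> float:
    """P(read covering the variant lies wholly inside the envelope).

    Start positions are assumed uniform among all starts that cover the
    variant; the locus flanks are assumed longer than the read, so the
    denominator is exactly ``read_length``.  Computed by exact enumeration
    of start positions.
    """
    if read_length < 1:
        raise ParalogTrapError("read_length must be >= 1")
    v = variant_position
    inside = 0
    for start in range(v - read_length + 1, v + 1):
        end = start + read_length - 1
        if start >= envelope_interval.start and end <= envelope_interval.end:
            inside += 1
    return inside / read_length


@dataclass(frozen=True)
class LeakThroughReport:
    """Tumor-vs-normal ambiguity contrast at one variant site."""

    envelope_length: int
    variant_offset: int  # 1-based offset of the variant within the envelope
    tumor_ambiguity: float
    normal_ambiguity: float
    risk_flag: bool

    @property
    def differential(self) -> float:
        return self.tumor_ambiguity - self.normal_ambiguity


def _model_ambiguity(
    model: ReadLengthModel,
    interval: GenomicInterval,
    variant_position: int,
    n_samples: int,
    seed: int,
) -> float:
    if model.kind == "fixed":
        return ambiguity_probability(int(model.mean), interval, variant_position)
    lengths = Counter(sample_lengths(model, n_samples, seed))
    total = sum(lengths.values())
    return sum(
        count * ambiguity_probability(length, interval, variant_position)
        for length, count in lengths.items()
    ) / total


def leak_through_assessment(
    tumor_model: ReadLengthModel,
    normal_model: ReadLengthModel,
    envelope_interval: GenomicInterval,
    variant_position: int,
    n_samples: int = 10_000,
    seed: int = 0,
) -> LeakThroughReport:
    """Compare trapped-read probabilities between tumor and normal libraries.

    Exact for fixed-length models; Monte-Carlo averaged over the length
    distribution (deterministic under ``seed``) otherwise.  ``risk_flag`` is
    raised when the tumor probability is positive and exceeds the normal's —
    the configuration in which an artefact can appear somatic.
    """
    tumor_p = _model_ambiguity(tumor_model, envelope_interval,
                               variant_position, n_samples, seed)
    normal_p = _model_ambiguity(normal_model, envelope_interval,
                                variant_position, n_samples, seed + 1)
    return LeakThroughReport(
        envelope_length=envelope_interval.length,
        variant_offset=variant_position - envelope_interval.start + 1,
        tumor_ambiguity=tumor_p,
        normal_ambiguity=normal_p,
        risk_flag=tumor_p > normal_p and tumor_p > 0,
    )


# ---------------------------------------------------------------------------
# Verdicts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArtefactVerdict:
    variant: VariantCall
    criterion_1_encodes: bool
    criterion_2_errorless_extension: bool
    pattern_complete: bool
    maf_flag: bool
    verdict: str  # {confirmed, artefact_suspect, indeterminate}
    n_supporting: int = 0


def classify_variant(
    variant: VariantCall,
    supporting_alignments: Sequence[LocusAlignment],
    envelope: HomologyEnvelope,
    pattern: Optional[ArtefactPattern],
    *,
    target_variants: Optional[Sequence[VariantCall]] = None,
    min_flank: int = DEFAULT_MIN_FLANK,
    maf_threshold_pct: float = DEFAULT_COMMON_MAF_PCT,
) -> ArtefactVerdict:
    """Final verdict for one candidate variant over its supporting reads.

    ``confirmed`` iff at least one supporting read satisfies both criteria
    simultaneously (the criteria are per-alignment statements, so a single
    read that both encodes the target variants and extends errorless past
    the envelope is decisive).  ``artefact_suspect`` iff no supporting read
    extends past the envelope *and* the cross-locus SNP pattern is complete.
    Anything else is ``indeterminate``.  The stored criterion booleans are
    any-read aggregates and can both be true without the variant being
    confirmed when no single read satisfies the conjunction.

    ``maf_flag`` marks variants annotated as catalogued SNPs at or above the
    common-MAF threshold (percent) — "too common to be a driver".
    """
    targets = list(target_variants) if target_variants else [variant]
    if not supporting_alignments:
        warnings.warn(
            f"variant {variant.contig}:{variant.position}{variant.ref}>"
            f"{variant.alt} has no supporting reads", stacklevel=2,
        )
        c1_any = c2_any = confirmed = False
    else:
        c1 = [criterion_encodes(a, targets) for a in supporting_alignments]
        c2 = [
            criterion_errorless_extension(a, envelope, min_flank)
            for a in supporting_alignments
        ]
        c1_any, c2_any = any(c1), any(c2)
        confirmed = any(x and y for x, y in zip(c1, c2))
    pattern_complete = bool(pattern and pattern.complete)
    if confirmed:
        verdict = CONFIRMED
    elif supporting_alignments and not c2_any and pattern_complete:
        verdict = ARTEFACT_SUSPECT
    else:
        verdict = INDETERMINATE
    maf_flag = (
        variant.annotation is not None
        and variant.annotation.maf >= maf_threshold_pct
    )
    return ArtefactVerdict(
        variant=variant,
        criterion_1_encodes=c1_any,
        criterion_2_errorless_extension=c2_any,
        pattern_complete=pattern_complete,
        maf_flag=maf_flag,
        verdict=verdict,
        n_supporting=len(supporting_alignments),
    )


# ---------------------------------------------------------------------------
# Cohort screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningResult:
    verdicts: tuple[ArtefactVerdict, ...]
    candidates: tuple[VariantCall, ...]       # tumor calls surviving subtraction
    subtracted: tuple[VariantCall, ...]       # tumor calls also seen in normal
    tumor_reports: tuple[MappingReport, ...]
    normal_reports: tuple[MappingReport, ...]

    def table(self) -> pd.DataFrame:
        rows = []
        for v in self.verdicts:
            rows.append(
                {
                    "contig": v.variant.contig,
                    "position": v.variant.position,
                    "ref": v.variant.ref,
                    "alt": v.variant.alt,
                    "alt_depth": v.variant.alt_depth,
                    "total_depth": v.variant.total_depth,
                    "rsid": v.variant.annotation.rsid if v.variant.annotation else ".",
                    "n_supporting": v.n_supporting,
                    "encodes": v.criterion_1_encodes,
                    "errorless_extension": v.criterion_2_errorless_extension,
                    "pattern_complete": v.pattern_complete,
                    "maf_flag": v.maf_flag,
                    "verdict": v.verdict,
                }
            )
        return pd.DataFrame(rows)


def screen_cohort(
    gene: Locus,
    paralog: Locus,
    envelope: HomologyEnvelope,
    catalogue: Sequence[SNPRecord],
    tumor_reads: Sequence[SimulatedRead],
    normal_reads: Sequence[SimulatedRead] = (),
    *,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    tie_margin: int = DEFAULT_TIE_MARGIN,
    min_flank: int = DEFAULT_MIN_FLANK,
    min_alt_depth: int = 2,
    maf_threshold_pct: float = DEFAULT_COMMON_MAF_PCT,
) -> ScreeningResult:
    """Run the full per-variant decision procedure on a tumor/normal cohort.

    Pipeline: align every read to {gene, paralog}; pile up mismatches of
    gene-primary reads into candidate calls; subtract candidates whose alt
    allele also appears in the normal pileup (the germline filter); then for
    each surviving candidate evaluate both criteria over its supporting
    reads and the cross-locus SNP pattern via the supporting read's paralog
    alignment.
    """
    loci = [gene, paralog]
    tumor_reports = [align_read(r, loci, scheme, tie_margin) for r in tumor_reads]
    normal_reports = [align_read(r, loci, scheme, tie_margin) for r in normal_reads]

    tumor_calls = pileup_variants(tumor_reports, gene, min_alt_depth)
    normal_keys = {c.key for c in pileup_variants(normal_reports, gene)}
    candidates, subtracted = [], []
    for call in tumor_calls:
        (subtracted if call.key in normal_keys else candidates).append(call)
    candidates = annotate_calls(candidates, catalogue)

    verdicts = []
    for call in candidates:
        supporting = _supporting_alignments(tumor_reports, gene, call)
        pattern = _best_pattern(call, supporting, tumor_reports, paralog,
                                envelope, catalogue)
        verdicts.append(
            classify_variant(
                call,
                [s.by_locus(gene.name) for s in supporting],
                envelope,
                pattern,
                min_flank=min_flank,
                maf_threshold_pct=maf_threshold_pct,
            )
        )
    return ScreeningResult(
        verdicts=tuple(verdicts),
        candidates=tuple(candidates),
        subtracted=tuple(subtracted),
        tumor_reports=tuple(tumor_reports),
        normal_reports=tuple(normal_reports),
    )


def _supporting_alignments(
    reports: Sequence[MappingReport], gene: Locus, call: VariantCall
) -> list[MappingReport]:
    """Reports whose primary gene alignment shows this call's mismatch."""
    out = []
    for rep in reports:
        if rep.best.locus.name != gene.name:
            continue
        off = gene.offset_of(call.position)
        base = rep.best.alignment.query_base_at_target(off)
        want = call.alt if gene.strand == "+" else _complement(call.alt)
        if base == want:
            out.append(rep)
    return out


def _best_pattern(
    call: VariantCall,
    supporting: Sequence[MappingReport],
    reports: Sequence[MappingReport],
    paralog: Locus,
    envelope: HomologyEnvelope,
    catalogue: Sequence[SNPRecord],
) -> Optional[ArtefactPattern]:
    """Pattern from the supporting read with the best paralog alignment."""
    best_rep = None
    best_score = -1
    for rep in supporting:
        try:
            pa = rep.by_locus(paralog.name)
        except KeyError:  # pragma: no cover - paralog always aligned here
            continue
        if pa.score > best_score:
            best_rep, best_score = rep, pa.score
    if best_rep is None:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return match_artefact_pattern(
            [call], envelope, catalogue, best_rep.by_locus(paralog.name)
        )
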