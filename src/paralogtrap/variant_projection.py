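"""Annotate candidate calls against the SNP catalogue and test the
cross-locus artefact pattern.

The artefact signature this module looks for: candidate "somatic" calls at a
gene locus whose supporting reads, when aligned to the homologous paralog
(pseudogene), mismatch the paralog *only* at catalogued common-SNP sites —
i.e. the read is better explained as a paralog molecule carrying a known SNP
haplotype than as a mutant gene molecule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .genome_model import SNPRecord, VariantCall, normalize_contig
from .multi_locus_aligner import LocusAlignment, call_variants
from .pairwise_align import HomologyEnvelope


def _catalogue_index(
    catalogue: Sequence[SNPRecord],
) -> dict[tuple[str, int, str, str], SNPRecord]:
    return {
        (normalize_contig(rec.contig), rec.position, rec.ref_allele,
         rec.alt_allele): rec
        for rec in catalogue
    }


def annotate_calls(
    calls: Sequence[VariantCall], catalogue: Sequence[SNPRecord]
) -> list[VariantCall]:
    """Attach catalogue records to calls matching on (contig, pos, ref, alt).

    Non-matching calls come back with ``annotation=None`` (uncatalogued).
    The operation is idempotent and never mutates its inputs.
    """
    index = _catalogue_index(catalogue)
    return [call.with_annotation(index.get(call.key)) for call in calls]


@dataclass(frozen=True)
class ProjectedSite:
    """One mismatch site of the paralog alignment, looked up in the catalogue."""

    position_b: int  # genomic position on the paralog contig
    read_allele: str
    paralog_ref: str
    catalogued: bool
    record: Optional[SNPRecord] = None


@dataclass(frozen=True)
class ArtefactPattern:
    """Outcome of the cross-locus pattern test for a set of gene calls.

    ``complete`` means the paralog alignment of the supporting read has at
    least one mismatch and *every* non-gapped mismatch is a catalogued
    common SNP — the full artefact signature.
    """

    gene_calls: tuple[VariantCall, ...]
    projected_sites: tuple[ProjectedSite, ...]
    n_catalogued: int
    complete: bool
    excluded_calls: tuple[VariantCall, ...] = ()


def match_artefact_pattern(
    gene_calls: Sequence[VariantCall],
    envelope: HomologyEnvelope,
    catalogue: Sequence[SNPRecord],
    paralog_alignment: LocusAlignment,
) -> ArtefactPattern:
    """Test whether gene calls project onto a catalogued paralog SNP haplotype.

    The mismatch columns of ``paralog_alignment`` (the supporting read
    aligned to the paralog locus) are looked up in the catalogue on
    (contig, position, ref, alt); allele orientation is handled by
    ``call_variants``, which always reports forward-strand alleles, so an
    inverted envelope needs no special casing here.  Gene calls outside the
    envelope are excluded with a warning rather than failing.
    """
    inside, excluded = [], []
    for call in gene_calls:
        if envelope.interval_a.contains(call.position):
            inside.append(call)
        else:
            excluded.append(call)
    if excluded:
        warnings.warn(
            f"{len(excluded)} gene call(s) fall outside the homology envelope "
            f"{envelope.interval_a} and were excluded from the pattern test",
            stacklevel=2,
        )

    index = _catalogue_index(catalogue)
    sites = []
    for mismatch in call_variants(paralog_alignment):
        record = index.get(mismatch.key)
        sites.append(
            ProjectedSite(
                position_b=mismatch.position,
                read_allele=mismatch.alt,
                paralog_ref=mismatch.ref,
                catalogued=record is not None,
                record=record,
            )
        )
    n_catalogued = sum(site.catalogued for site in sites)
    complete = bool(sites) and n_catalogued == len(sites)
    return ArtefactPattern(
        gene_calls=tuple(inside),
        projected_sites=tuple(sites),
        n_catalogued=n_catalogued,
        complete=complete,
        excluded_calls=tuple(excluded),
    )
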