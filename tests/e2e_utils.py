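"""Shared driver for end-to-end truth-vs-verdict checks on synthetic cohorts.

Study conditions: FFPE-like tumor reads (truncated normal, <=100 bp) against
long germline reads (fixed 150 bp, i.e. longer than the 141 bp homology
core, so germline reads always escape the envelope), 20% of locus reads
carrying the pseudogene SNP haplotype, and one true somatic variant at core
offset 50 supported by envelope-crossing reads.
"""

from __future__ import annotations

import paralogtrap as pt

SOMATIC_CORE_OFFSET = 50


def run_dataset(seed: int) -> tuple[pt.LocusPair, pt.VariantCall, object]:
    pair = pt.generate_locus_pair(pt.LocusPairSpec(seed=seed, flank_length=200))
    somatic = pair.gene_variant(SOMATIC_CORE_OFFSET, label="true_somatic")
    cohort = pt.generate_cohort(
        pair,
        pt.CohortSpec(
            seed=100_000 + seed,
            somatic_variants=(somatic,),
            normal_model=pt.ReadLengthModel.fixed(150),
        ),
    )
    result = pt.screen_cohort(
        pair.gene, pair.pseudogene, pair.envelope, pair.catalogue,
        cohort.tumor_reads, cohort.normal_reads,
    )
    return pair, somatic, result


def contradictions(pair: pt.LocusPair, somatic: pt.VariantCall,
                   result) -> list[str]:
    """Disagreements between ground-truth labels and pipeline verdicts."""
    verdict_by_key = {v.variant.key: v.verdict for v in result.verdicts}
    problems = []
    for truth_variant in pair.artefact_variants:
        got = verdict_by_key.get(truth_variant.key)
        if got != pt.ARTEFACT_SUSPECT:
            problems.append(
                f"paralog-haplotype variant at {truth_variant.position}: "
                f"expected artefact_suspect, got {got}"
            )
    got = verdict_by_key.get(somatic.key)
    if got != pt.CONFIRMED:
        problems.append(
            f"true somatic at {somatic.position}: expected confirmed, got {got}"
        )
    truth_keys = {v.key for v in pair.artefact_variants} | {somatic.key}
    for verdict in result.verdicts:
        if verdict.variant.key not in truth_keys and verdict.verdict in (
            pt.CONFIRMED, pt.ARTEFACT_SUSPECT,
        ):
            problems.append(
                f"spurious {verdict.verdict} at {verdict.variant.position}"
            )
    return problems
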