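"""Shared fixtures: a small gene/pseudogene pair and derived objects.

Everything is generated in memory by the synthetic_data module; no files
are shipped.  The default pair uses short (200 bp) flanks to keep alignment
matrices small while still leaving room for reads to escape the envelope.
"""

import pytest

import paralogtrap as pt


@pytest.fixture(scope="session")
def pair() -> pt.LocusPair:
    return pt.generate_locus_pair(pt.LocusPairSpec(seed=1, flank_length=200))


@pytest.fixture(scope="session")
def doubly_mutant_read(pair: pt.LocusPair) -> str:
    """A 100 bp gene read carrying both planted 'somatic' variants.

    It starts at the first core base, so it covers all three SNP-triplet
    sites (core offsets 14, 31 and 75) and lies wholly inside the envelope —
    byte-identical to a pseudogene read carrying the full SNP haplotype.
    """
    mutated = pt.inject_variants(pair.gene, pair.artefact_variants)
    core_offset = pair.core_interval.start - pair.gene.interval.start
    return mutated[core_offset : core_offset + 100]


@pytest.fixture(scope="session")
def fig_report(pair, doubly_mutant_read) -> pt.MappingReport:
    """The doubly-mutant read aligned against both loci."""
    return pt.align_read(doubly_mutant_read, [pair.gene, pair.pseudogene])
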