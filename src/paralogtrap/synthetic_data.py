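"""Generate gene/pseudogene fixtures with ground truth for every stage.

The generator reproduces the geometry of a gene caught in a pseudogene
misalignment trap:

* a *core* of (default) 141 bp shared between gene and pseudogene — the
  homology envelope — surrounded by unique random flanks;
* a triplet of catalogued pseudogene SNPs inside the core, of two kinds:

  - **call sites** (default core offsets 14 and 31, the offsets of the two
    reported hotspot variants from the start of the printed homology
    interval): gene and pseudogene agree on the reference base, and the SNP
    alt is a third allele.  A pseudogene read carrying these alts mismatches
    the gene exactly there — these become the false "somatic" calls;
  - **mimic sites** (default offset 75): the pseudogene reference base
    *differs* from the gene, and the SNP alt equals the gene base, hiding
    the divergence.  These are the divergent sites: the pseudogene differs
    from the gene at exactly the mimic sites.

  A pseudogene read carrying the full SNP haplotype therefore aligns to the
  gene with 2 mismatches but to its true pseudogene origin with 3 — the
  aligner prefers the wrong locus by one mismatch (a 5-point swing under
  the default scoring), and a read simulated from the gene with the two
  "somatic" variants injected is the *same sequence*;

* tumor/normal read cohorts with distinct length models (short fragmented
  FFPE tumor vs long blood normal) in which a stated fraction of reads at
  the locus originate from the pseudogene SNP haplotype, plus optional true
  somatic variants at the gene.

All randomness flows from a single recorded seed per dataset, and every
output carries truth labels so pipeline verdicts can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SimulationError
from .genome_model import (
    GenomicInterval,
    Locus,
    SNPRecord,
    VariantCall,
    reverse_complement,
    write_fasta,
    write_snp_catalogue,
)
from .ld_stats import HaplotypePanel
from .pairwise_align import HomologyEnvelope
from .read_sim import (
    BLOOD_MODEL,
    FFPE_MODEL,
    ReadLengthModel,
    SimulatedRead,
    simulate_reads,
    truth_table,
)

_BASES = "ACGT"


@dataclass(frozen=True)
class LocusPairSpec:
    """Recipe for a gene/pseudogene pair with planted SNP structure.

    Offsets are 1-based within the shared core.  ``call_offsets`` are the
    sites that will surface as false somatic calls at the gene;
    ``mimic_offsets`` are the divergent sites whose SNP alt allele equals
    the gene base.  Allele counts give every catalogue SNP a population
    frequency (default 1386/117782, i.e. a 1.18% MAF).
    """

    core_length: int = 141
    call_offsets: tuple[int, ...] = (14, 31)
    mimic_offsets: tuple[int, ...] = (75,)
    flank_length: int = 500
    orientation: str = "same"  # relative orientation of the pseudogene
    gene_name: str = "GENE1"
    pseudogene_name: str = "GENE1P"
    gene_contig: str = "chrG"
    pseudogene_contig: str = "chrP"
    locus_start: int = 10_001
    allele_count: int = 1386
    total_alleles: int = 117_782
    seed: int = 0

    def __post_init__(self) -> None:
        offsets = self.call_offsets + self.mimic_offsets
        if len(set(offsets)) != len(offsets):
            raise SimulationError("SNP site offsets must be distinct")
        for off in offsets:
            if not 1 <= off <= self.core_length:
                raise SimulationError(
                    f"SNP offset {off} outside core of length {self.core_length}"
                )
        if self.orientation not in {"same", "inverted"}:
            raise SimulationError("orientation must be 'same' or 'inverted'")
        if self.flank_length < 0:
            raise SimulationError("flank_length must be >= 0")


@dataclass(frozen=True)
class LocusPair:
    """A generated pair with its truth envelope, catalogue and variant truth."""

    gene: Locus
    pseudogene: Locus
    envelope: HomologyEnvelope
    catalogue: tuple[SNPRecord, ...]
    artefact_variants: tuple[VariantCall, ...]   # expected false calls (gene coords)
    haplotype_variants: tuple[VariantCall, ...]  # SNP alts (pseudogene coords)
    spec: LocusPairSpec

    @property
    def core_interval(self) -> GenomicInterval:
        return self.envelope.interval_a

    def gene_variant(self, core_offset: int, alt: Optional[str] = None,
                     label: Optional[str] = None) -> VariantCall:
        """Convenience: a gene-coordinate variant at a 1-based core offset."""
        position = self.core_interval.start + core_offset - 1
        ref = self.gene.base_at(position)
        if alt is None:
            alt = _BASES[(_BASES.index(ref) + 1) % 4]
        return VariantCall(contig=self.gene.contig, position=position,
                           ref=ref, alt=alt, label=label)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=length)])


def _other_base(rng: np.random.Generator, *exclude: str) -> str:
    choices = [b for b in _BASES if b not in exclude]
    return choices[int(rng.integers(len(choices)))]


def generate_locus_pair(spec: LocusPairSpec) -> LocusPair:
    """Build the gene/pseudogene pair, truth envelope and SNP catalogue."""
    rng = np.random.default_rng(spec.seed)
    core = list(_random_seq(rng, spec.core_length))
    flanks = [_random_seq(rng, spec.flank_length) for _ in range(4)]

    psg_core = core.copy()
    site_info = []  # (offset, psg_ref_fwd, alt_fwd)
    for off in sorted(spec.call_offsets + spec.mimic_offsets):
        idx = off - 1
        gene_base = core[idx]
        if off in spec.call_offsets:
            alt = _other_base(rng, gene_base)          # third allele, psg == gene
            site_info.append((off, gene_base, alt))
        else:
            psg_base = _other_base(rng, gene_base)     # divergent site
            psg_core[idx] = psg_base
            site_info.append((off, psg_base, gene_base))  # alt mimics the gene

    total = spec.flank_length * 2 + spec.core_length
    gene_seq = flanks[0] + "".join(core) + flanks[1]
    gene = Locus(
        name=spec.gene_name,
        interval=GenomicInterval(spec.gene_contig, spec.locus_start,
                                 spec.locus_start + total - 1),
        strand="+",
        sequence=gene_seq,
    )
    psg_forward = flanks[2] + "".join(psg_core) + flanks[3]
    psg_seq = psg_forward if spec.orientation == "same" else reverse_complement(
        psg_forward
    )
    pseudogene = Locus(
        name=spec.pseudogene_name,
        interval=GenomicInterval(spec.pseudogene_contig, spec.locus_start,
                                 spec.locus_start + total - 1),
        strand="+",
        sequence=psg_seq,
    )

    core_start_a = spec.locus_start + spec.flank_length
    interval_a = GenomicInterval(spec.gene_contig, core_start_a,
                                 core_start_a + spec.core_length - 1)
    # flanks are equal length, so the core occupies the same stored offsets
    # in both orientations
    interval_b = GenomicInterval(spec.pseudogene_contig, core_start_a,
                                 core_start_a + spec.core_length - 1)
    path = _truth_path(spec)
    n_div = len(spec.mimic_offsets)
    envelope = HomologyEnvelope(
        locus_a=gene,
        locus_b=pseudogene,
        interval_a=interval_a,
        interval_b=interval_b,
        orientation=spec.orientation,
        path=path,
        score=0,
        identity=(spec.core_length - n_div) / spec.core_length,
    )

    catalogue, haplotype_variants, artefact_variants = [], [], []
    for off, psg_ref_fwd, alt_fwd in site_info:
        # position/alleles on the pseudogene contig's forward strand
        if spec.orientation == "same":
            pos_b = interval_b.start + off - 1
            ref_b, alt_b = psg_ref_fwd, alt_fwd
        else:
            pos_b = interval_b.end - (off - 1)
            ref_b = reverse_complement(psg_ref_fwd)
            alt_b = reverse_complement(alt_fwd)
        record = SNPRecord(
            rsid=f"rsyn{off:04d}",
            contig=spec.pseudogene_contig,
            position=pos_b,
            ref_allele=ref_b,
            alt_allele=alt_b,
            allele_count=spec.allele_count,
            total_alleles=spec.total_alleles,
        )
        catalogue.append(record)
        haplotype_variants.append(
            VariantCall(contig=spec.pseudogene_contig, position=pos_b,
                        ref=ref_b, alt=alt_b)
        )
        if off in spec.call_offsets:
            artefact_variants.append(
                VariantCall(contig=spec.gene_contig,
                            position=interval_a.start + off - 1,
                            ref=psg_ref_fwd, alt=alt_fwd)
            )
    return LocusPair(
        gene=gene,
        pseudogene=pseudogene,
        envelope=envelope,
        catalogue=tuple(catalogue),
        artefact_variants=tuple(artefact_variants),
        haplotype_variants=tuple(haplotype_variants),
        spec=spec,
    )


def _truth_path(spec: LocusPairSpec) -> tuple[tuple[str, int], ...]:
    """Match/mismatch path of the core alignment: X at the divergent sites."""
    divergent = set(spec.mimic_offsets)
    path: list[tuple[str, int]] = []
    for off in range(1, spec.core_length + 1):
        op = "X" if off in divergent else "="
        if path and path[-1][0] == op:
            path[-1] = (op, path[-1][1] + 1)
        else:
            path.append((op, 1))
    return tuple(path)


# ---------------------------------------------------------------------------
# Haplotype panels
# ---------------------------------------------------------------------------

def generate_panel(
    catalogue: Sequence[SNPRecord],
    cooccurrence: str = "perfect",
    n_haplotypes: int = 100,
    alt_freq: float = 0.1,
    freqs: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> HaplotypePanel:
    """Phased haplotype panel over the catalogue sites.

    ``perfect``: the alt alleles appear only jointly, on a
    ``round(alt_freq * n)`` subset of haplotypes — the co-occurring triplet.
    ``independent``: each site drawn independently at ``alt_freq``.
    ``custom``: independent draws at per-site ``freqs``.
    """
    if n_haplotypes < 2:
        raise SimulationError("panel needs at least 2 haplotypes")
    if not catalogue:
        raise SimulationError("catalogue is empty")
    site_freqs = [alt_freq] * len(catalogue) if freqs is None else list(freqs)
    if len(site_freqs) != len(catalogue):
        raise SimulationError("freqs length must match the catalogue")
    for f in site_freqs:
        if not 0 < f < 1:
            raise SimulationError(f"allele frequency {f} outside (0, 1)")
    rng = np.random.default_rng(seed)
    n_sites = len(catalogue)
    if cooccurrence == "perfect":
        k = max(1, round(alt_freq * n_haplotypes))
        if k >= n_haplotypes:
            raise SimulationError("perfect-mode alt frequency leaves no ref rows")
        matrix = np.zeros((n_haplotypes, n_sites), dtype=np.int8)
        carriers = rng.choice(n_haplotypes, size=k, replace=False)
        matrix[carriers, :] = 1
    elif cooccurrence in {"independent", "custom"}:
        matrix = (
            rng.random((n_haplotypes, n_sites)) < np.asarray(site_freqs)
        ).astype(np.int8)
    else:
        raise SimulationError(f"unknown cooccurrence mode {cooccurrence!r}")
    return HaplotypePanel(tuple(rec.rsid for rec in catalogue), matrix)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Tumor/normal read-cohort recipe.

    ``haplotype_fraction`` of tumor reads at the locus derive from the
    pseudogene carrying the full SNP haplotype (the germline carrier state;
    normals use ``normal_haplotype_fraction``, defaulting to the same).
    The remaining background splits evenly between wild-type gene and
    wild-type pseudogene molecules; ``somatic_fraction`` of the gene-origin
    tumor reads additionally carry ``somatic_variants``.  ``read_window``
    "core" restricts read starts to positions overlapping the homologous
    core (a locus-targeted pileup); "locus" draws starts uniformly over the
    whole locus.
    """

    n_tumor: int = 800
    n_normal: int = 300
    tumor_model: ReadLengthModel = FFPE_MODEL
    normal_model: ReadLengthModel = BLOOD_MODEL
    haplotype_fraction: float = 0.2
    normal_haplotype_fraction: Optional[float] = None
    somatic_variants: tuple[VariantCall, ...] = ()
    somatic_fraction: float = 0.3
    read_window: str = "core"
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.haplotype_fraction, self.somatic_fraction):
            if not 0 <= frac <= 1:
                raise SimulationError(f"fraction {frac} outside [0, 1]")
        if self.normal_haplotype_fraction is not None and not (
            0 <= self.normal_haplotype_fraction <= 1
        ):
            raise SimulationError("normal_haplotype_fraction outside [0, 1]")
        if self.read_window not in {"core", "locus"}:
            raise SimulationError("read_window must be 'core' or 'locus'")


@dataclass(frozen=True)
class Cohort:
    tumor_reads: tuple[SimulatedRead, ...]
    normal_reads: tuple[SimulatedRead, ...]
    truth: pd.DataFrame
    spec: CohortSpec


def _window(pair: LocusPair, locus: Locus, model: ReadLengthModel,
            which: str) -> Optional[tuple[int, int]]:
    if which == "locus":
        return None
    # starts whose read can overlap the homologous core
    core = pair.core_interval
    lo = max(locus.interval.start, core.start - model.max_length + 1)
    return (lo, min(core.end, locus.interval.end - model.max_length + 1))


def _simulate_group(
    locus: Locus,
    variants: Sequence[VariantCall],
    model: ReadLengthModel,
    n: int,
    window: Optional[tuple[int, int]],
    prefix: str,
    seed: int,
) -> list[SimulatedRead]:
    if n <= 0:
        return []
    return simulate_reads(
        locus, variants, model, n, seed=seed,
        start_window=window, id_prefix=prefix,
    )


def generate_cohort(pair: LocusPair, cohort_spec: CohortSpec) -> Cohort:
    """Simulate the tumor and normal read sets with full truth labels."""
    spec = cohort_spec
    rng = np.random.default_rng(spec.seed)

    def seeds() -> int:
        return int(rng.integers(2**31))

    groups: list[tuple[str, list[SimulatedRead]]] = []

    def build(sample: str, n_total: int, hap_frac: float,
              model: ReadLengthModel, somatic: bool) -> list[SimulatedRead]:
        n_hap = round(n_total * hap_frac)
        n_rest = n_total - n_hap
        n_gene = n_rest // 2
        n_psg = n_rest - n_gene
        n_som = round(n_gene * spec.somatic_fraction) if (
            somatic and spec.somatic_variants
        ) else 0
        n_gene_wt = n_gene - n_som
        win_g = _window(pair, pair.gene, model, spec.read_window)
        win_p = _window(pair, pair.pseudogene, model, spec.read_window)
        reads: list[SimulatedRead] = []
        reads += _simulate_group(pair.pseudogene, pair.haplotype_variants,
                                 model, n_hap, win_p, f"{sample}_hap", seeds())
        reads += _simulate_group(pair.gene, spec.somatic_variants, model,
                                 n_som, win_g, f"{sample}_som", seeds())
        reads += _simulate_group(pair.gene, [], model, n_gene_wt, win_g,
                                 f"{sample}_gene", seeds())
        reads += _simulate_group(pair.pseudogene, [], model, n_psg, win_p,
                                 f"{sample}_psg", seeds())
        return reads

    tumor = build("tumor", spec.n_tumor, spec.haplotype_fraction,
                  spec.tumor_model, somatic=True)
    normal_frac = (
        spec.haplotype_fraction
        if spec.normal_haplotype_fraction is None
        else spec.normal_haplotype_fraction
    )
    normal = build("normal", spec.n_normal, normal_frac,
                   spec.normal_model, somatic=False)

    truth = pd.concat(
        [
            truth_table(tumor).assign(sample="tumor"),
            truth_table(normal).assign(sample="normal"),
        ],
        ignore_index=True,
    )
    truth["origin"] = truth["read_id"].str.extract(r"^(?:tumor|normal)_(\w+?)_r")
    return Cohort(tuple(tumor), tuple(normal), truth, spec)


# ---------------------------------------------------------------------------
# Dataset export
# ---------------------------------------------------------------------------

def write_dataset(pair: LocusPair, panel: HaplotypePanel, cohort: Cohort,
                  outdir: str | Path) -> None:
    """Write a dataset in the flat-text formats the pipeline consumes."""
    from .read_sim import write_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([pair.gene, pair.pseudogene], outdir / "loci.fasta")
    write_snp_catalogue(pair.catalogue, outdir / "snp_catalogue.tsv")
    panel.to_tsv(outdir / "haplotype_panel.tsv")
    write_fastq(cohort.tumor_reads, outdir / "tumor.fastq")
    write_fastq(cohort.normal_reads, outdir / "normal.fastq")
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    pd.DataFrame([pair.envelope.to_record()]).to_csv(
        outdir / "envelope.tsv", sep="\t", index=False
    )
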