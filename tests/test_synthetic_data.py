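"""The synthetic generator: locus pairs, panels, cohorts, determinism."""

import numpy as np
import pytest

import paralogtrap as pt
from paralogtrap.errors import SimulationError


def core_sequences(p: pt.LocusPair) -> tuple[str, str]:
    f = p.spec.flank_length
    c = p.spec.core_length
    return p.gene.sequence[f : f + c], p.pseudogene.sequence[f : f + c]


class TestGenerateLocusPair:
    def test_divergent_sites_differ_and_only_they_differ(self):
        spec = pt.LocusPairSpec(seed=2, call_offsets=(),
                                mimic_offsets=(14, 35, 75))
        p = pt.generate_locus_pair(spec)
        gene_core, psg_core = core_sequences(p)
        diffs = [i + 1 for i, (a, b) in enumerate(zip(gene_core, psg_core))
                 if a != b]
        assert diffs == [14, 35, 75]

    def test_zero_divergent_sites_give_identical_cores(self):
        spec = pt.LocusPairSpec(seed=2, call_offsets=(14, 31), mimic_offsets=())
        p = pt.generate_locus_pair(spec)
        gene_core, psg_core = core_sequences(p)
        assert gene_core == psg_core
        assert len(p.catalogue) == 2

    def test_same_seed_is_byte_identical(self):
        a = pt.generate_locus_pair(pt.LocusPairSpec(seed=33))
        b = pt.generate_locus_pair(pt.LocusPairSpec(seed=33))
        assert a.gene.sequence == b.gene.sequence
        assert a.pseudogene.sequence == b.pseudogene.sequence
        assert a.catalogue == b.catalogue
        c = pt.generate_locus_pair(pt.LocusPairSpec(seed=34))
        assert a.gene.sequence != c.gene.sequence

    def test_snp_triplet_structure(self, pair):
        # call sites: pseudogene ref equals the gene base, alt is a third
        # allele; mimic sites: pseudogene ref differs, alt IS the gene base
        gene_core, psg_core = core_sequences(pair)
        by_offset = {
            rec.position - pair.envelope.interval_b.start + 1: rec
            for rec in pair.catalogue
        }
        for off in pair.spec.call_offsets:
            rec = by_offset[off]
            assert rec.ref_allele == gene_core[off - 1] == psg_core[off - 1]
            assert rec.alt_allele not in (rec.ref_allele,)
        for off in pair.spec.mimic_offsets:
            rec = by_offset[off]
            assert rec.ref_allele == psg_core[off - 1] != gene_core[off - 1]
            assert rec.alt_allele == gene_core[off - 1]

    def test_haplotype_read_equals_doubly_mutant_gene_read(
        self, pair, doubly_mutant_read
    ):
        hap = pt.inject_variants(pair.pseudogene, pair.haplotype_variants)
        core0 = pair.core_interval.start - pair.pseudogene.interval.start
        assert hap[core0 : core0 + 100] == doubly_mutant_read

    def test_out_of_range_offset_rejected(self):
        with pytest.raises(SimulationError):
            pt.LocusPairSpec(call_offsets=(14, 200))

    def test_truth_envelope_agrees_with_derived_envelope_identity(self, pair):
        derived = pt.derive_envelope(pair.gene, pair.pseudogene)
        assert derived is not None
        assert derived.orientation == "same"
        assert derived.interval_a.start <= pair.core_interval.start
        assert derived.interval_a.end >= pair.core_interval.end


class TestGeneratePanel:
    def test_perfect_mode_forces_joint_occurrence(self, pair):
        panel = pt.generate_panel(pair.catalogue, "perfect", 100, 0.1, seed=1)
        assert panel.matrix.sum(axis=0).tolist() == [10, 10, 10]
        row_sums = panel.matrix.sum(axis=1)
        assert set(row_sums.tolist()) <= {0, 3}
        verdict = pt.triplet_cooccurrence(panel)
        assert verdict.cooccur

    def test_independent_mode_has_small_d(self, pair):
        n = 10_000
        panel = pt.generate_panel(pair.catalogue, "independent", n, 0.3, seed=2)
        se = np.sqrt(0.3 * 0.7 * 0.3 * 0.7 / n)
        for res in pt.all_pairs_ld(panel):
            assert abs(res.d) < 3 * se

    def test_single_haplotype_rejected(self, pair):
        with pytest.raises(SimulationError):
            pt.generate_panel(pair.catalogue, "perfect", 1)

    def test_bad_frequency_rejected(self, pair):
        with pytest.raises(SimulationError):
            pt.generate_panel(pair.catalogue, "independent", 10, alt_freq=1.5)

    def test_seed_determinism(self, pair):
        a = pt.generate_panel(pair.catalogue, "independent", 50, 0.2, seed=7)
        b = pt.generate_panel(pair.catalogue, "independent", 50, 0.2, seed=7)
        assert (a.matrix == b.matrix).all()


class TestGenerateCohort:
    def test_composition_and_truth_labels(self, pair):
        spec = pt.CohortSpec(n_tumor=100, n_normal=40, seed=5,
                             somatic_variants=(pair.gene_variant(50),))
        cohort = pt.generate_cohort(pair, spec)
        assert len(cohort.tumor_reads) == 100
        assert len(cohort.normal_reads) == 40
        truth = cohort.truth
        tumor = truth[truth["sample"] == "tumor"]
        assert (tumor["origin"] == "hap").sum() == 20  # fraction 0.2
        assert set(truth["origin"]) <= {"hap", "som", "gene", "psg"}
        # haplotype reads originate from the pseudogene
        assert (
            truth.loc[truth["origin"] == "hap", "truth_locus"]
            == pair.pseudogene.name
        ).all()

    def test_tumor_reads_respect_ffpe_cap(self, pair):
        cohort = pt.generate_cohort(pair, pt.CohortSpec(n_tumor=50, n_normal=10,
                                                        seed=6))
        assert max(len(r) for r in cohort.tumor_reads) <= 100
        assert all(len(r) == 125 for r in cohort.normal_reads)

    def test_core_window_restricts_read_starts(self, pair):
        """Starts stay inside the core-targeted window (positions from
        which a maximum-length read overlaps the homologous core)."""
        spec = pt.CohortSpec(n_tumor=60, n_normal=10, seed=7)
        cohort = pt.generate_cohort(pair, spec)
        core = pair.core_interval
        max_len = spec.tumor_model.max_length
        for read in cohort.tumor_reads:
            assert core.start - max_len + 1 <= read.truth_start <= core.end

    def test_seed_determinism(self, pair):
        a = pt.generate_cohort(pair, pt.CohortSpec(n_tumor=30, n_normal=10,
                                                   seed=9))
        b = pt.generate_cohort(pair, pt.CohortSpec(n_tumor=30, n_normal=10,
                                                   seed=9))
        assert a.tumor_reads == b.tumor_reads
        assert a.normal_reads == b.normal_reads


class TestWriteDataset:
    def test_dataset_files_round_trip(self, pair, tmp_path):
        panel = pt.generate_panel(pair.catalogue, "perfect", 20, 0.2, seed=3)
        cohort = pt.generate_cohort(pair, pt.CohortSpec(n_tumor=20, n_normal=5,
                                                        seed=3))
        pt.write_dataset(pair, panel, cohort, tmp_path)
        loci = pt.read_fasta(tmp_path / "loci.fasta")
        assert [name for name, _ in loci] == [pair.gene.name,
                                              pair.pseudogene.name]
        assert loci[0][1] == pair.gene.sequence
        catalogue = pt.load_snp_catalogue(tmp_path / "snp_catalogue.tsv")
        assert tuple(catalogue) == pair.catalogue
        assert (tmp_path / "tumor.fastq").exists()
        assert (tmp_path / "truth.tsv").exists()
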