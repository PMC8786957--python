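#!/usr/bin/env python
"""Generate the synthetic study dataset.

Builds the gene/pseudogene locus pair (141 bp homologous core, SNP triplet
at core offsets 14/31/75, unique 500 bp flanks), a perfectly co-occurring
haplotype panel, and a tumor/normal read cohort: short FFPE-like tumor
reads, long (150 bp) blood-like normal reads, 20% of locus reads carrying
the pseudogene SNP haplotype, and one true somatic variant at core offset
50.  Everything is written under results/data/ in the flat-text formats the
rest of the pipeline consumes.
"""

import json
from pathlib import Path

import paralogtrap as pt

RESULTS = Path(__file__).resolve().parents[1] / "results"
DATA = RESULTS / "data"
SEED = 2024


def main() -> None:
    pair = pt.generate_locus_pair(pt.LocusPairSpec(seed=SEED))
    somatic = pair.gene_variant(50, label="true_somatic")
    panel = pt.generate_panel(pair.catalogue, "perfect",
                              n_haplotypes=100, alt_freq=0.1, seed=SEED)
    cohort = pt.generate_cohort(
        pair,
        pt.CohortSpec(seed=SEED, somatic_variants=(somatic,),
                      normal_model=pt.ReadLengthModel.fixed(150)),
    )
    pt.write_dataset(pair, panel, cohort, DATA)
    from paralogtrap.genome_model import write_variant_calls
    write_variant_calls(list(pair.artefact_variants) + [somatic],
                        DATA / "truth_variants.tsv")
    meta = {
        "seed": SEED,
        "gene": pair.gene.name,
        "pseudogene": pair.pseudogene.name,
        "core": str(pair.core_interval),
        "n_tumor_reads": len(cohort.tumor_reads),
        "n_normal_reads": len(cohort.normal_reads),
        "true_somatic": f"{somatic.contig}:{somatic.position}"
                        f"{somatic.ref}>{somatic.alt}",
    }
    (DATA / "metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    print(f"wrote dataset to {DATA}")
    for key, value in meta.items():
        print(f"  {key}: {value}")


if __name__ == "__main__":
    main()
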