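"""Generate the synthetic study datasets.

Builds a two-chromosome yeast-like genome fixture (134 origins with ±10
positioned nucleosomes each; 400 genes with a +1..+6 nucleosome array
downstream of an NFR), then simulates, for four genotypes, strand-resolved
eSPAN fragment libraries for the parental (H3K4me3-like) and new
(H3K56ac-like) histone marks, an MNase-seq library, and the phenotype
count tables. Fragment BEDs go to scratch/simdata/ (they are large and
fully reproducible from the seeds); a small summary lands in results/.

Run from the repository root:  python analysis/01_simulate.py [seed]
"""

import sys
from pathlib import Path

import pandas as pd

from espantools import synthetic
from espantools.io import write_fragments_bed

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "simdata"
RESULTS = ROOT / "results"

#: phenotype ground truths per genotype — illustrative values on the scales
#: the assays operate at (rates per cell, frequencies per viable cell)
PHENOTYPE_TRUTH = synthetic.PhenotypeTruth(
    silencing_loss_rate={"WT": 0.004, "dpb3": 0.012, "mcm2-3A": 0.010,
                         "dpb3_mcm2-3A": 0.006},
    hr_frequency={"WT": 1e-4, "dpb3": 5e-5, "mcm2-3A": 6e-5,
                  "dpb3_mcm2-3A": 3e-5},
    foci_probability={"WT": 0.02, "dpb3": 0.05, "mcm2-3A": 0.045,
                      "dpb3_mcm2-3A": 0.06},
    soluble_ratio={"WT": 1.0, "dpb3": 1.8, "mcm2-3A": 1.6,
                   "dpb3_mcm2-3A": 2.4, "rad53": 3.0},
)


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    fixture = synthetic.make_genome(n_origins=134, n_genes=400, seed=SEED)
    fixture.write_bed(SCRATCH)
    print(f"genome: {len(fixture.origins)} origins, {len(fixture.tss)} genes, "
          f"{len(fixture.nuc_map)} positioned nucleosomes")

    rows = []
    for gi, (geno_name, p) in enumerate(synthetic.GENOTYPE_PRESETS.items()):
        for mi, mark in enumerate(("parental", "new")):
            geno = synthetic.GenotypeParams(
                geno_name, p_lagging=p, depth=373,
                seed=SEED + 10 * gi + mi + 1,
            )
            frags = synthetic.simulate_espan(fixture, geno, mark=mark)
            path = SCRATCH / f"espan_{geno_name}_{mark}.bed"
            write_fragments_bed(frags, path)
            rows.append({"genotype": geno_name, "assay": f"eSPAN_{mark}",
                         "p_lagging": p, "fragments": len(frags)})
        mn = synthetic.simulate_mnase(fixture, positioning_sd=20.0, depth=42,
                                      background=0.05, seed=SEED + 100 + gi,
                                      kind="all")
        write_fragments_bed(mn, SCRATCH / f"mnase_{geno_name}.bed")
        rows.append({"genotype": geno_name, "assay": "MNase", "p_lagging": p,
                     "fragments": len(mn)})

    tabs = synthetic.simulate_phenotypes(PHENOTYPE_TRUTH, seed=SEED + 500)
    for key, tab in tabs.items():
        tab.to_csv(SCRATCH / f"pheno_{key}.tsv", sep="\t", index=False)
        rows.append({"genotype": "all", "assay": f"pheno_{key}",
                     "p_lagging": float("nan"), "fragments": len(tab)})

    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "simulation_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nfragment BEDs and phenotype tables under {SCRATCH}")


if __name__ == "__main__":
    main()
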