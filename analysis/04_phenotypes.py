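"""Phenotype statistics over the simulated assay tables.

Computes, per genotype: the CRASH silencing-loss rate (RFP+GFP+ over all
RFP+ events) with mean ± SEM over colonies; the median HR frequency per
viable cell and its value relative to WT; the Rad52-focus-positive cell
percentage with a one-way ANOVA against WT; and the soluble-histone /
PGK1 blot ratio normalized to WT. Compares each estimate with the ground
truth used by the simulator.
"""

import sys
from pathlib import Path

import pandas as pd

from espantools import phenotypes as ph

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "simdata"
RESULTS = ROOT / "results"


def main() -> None:
    if not (SCRATCH / "pheno_crash.tsv").exists():
        sys.exit("no simulated data found — run analysis/01_simulate.py first")
    RESULTS.mkdir(exist_ok=True)
    crash = pd.read_csv(SCRATCH / "pheno_crash.tsv", sep="\t")
    _, crash_summary = ph.silencing_loss_rate(crash)
    crash_summary.to_csv(RESULTS / "crash_rates.tsv", sep="\t", index=False)
    print("CRASH silencing-loss rates (truth: WT 0.004, dpb3 0.012, "
          "mcm2-3A 0.010, double 0.006):")
    print(crash_summary.round(5).to_string(index=False))

    hr = pd.read_csv(SCRATCH / "pheno_hr.tsv", sep="\t")
    hr_rel = ph.relative_hr(hr, reference="WT")
    hr_rel.to_csv(RESULTS / "hr_frequencies.tsv", sep="\t", index=False)
    print("\nHR median frequencies per viable cell, relative to WT "
          "(truth ratios: dpb3 0.5, mcm2-3A 0.6, double 0.3):")
    print(hr_rel.round(6).to_string(index=False))

    foci = pd.read_csv(SCRATCH / "pheno_foci.tsv", sep="\t")
    per, foci_summary = ph.foci_fraction(foci)
    tests = ph.pairwise_anova_vs_reference(per, "percent", "WT")
    foci_out = foci_summary.merge(tests, on="strain", how="left")
    foci_out.to_csv(RESULTS / "foci_fractions.tsv", sep="\t", index=False)
    print("\nRad52-focus-positive percentages with ANOVA vs WT "
          "(truth: 2, 5, 4.5, 6 %):")
    print(foci_out.round(4).to_string(index=False))

    blot = pd.read_csv(SCRATCH / "pheno_blot.tsv", sep="\t")
    _, blot_summary = ph.soluble_histone_ratio(blot, reference="WT")
    blot_summary.to_csv(RESULTS / "soluble_histone.tsv", sep="\t", index=False)
    print("\nsoluble H3 / PGK1 relative to WT (truth: 1, 1.8, 1.6, 2.4; "
          "rad53 control 3.0):")
    print(blot_summary.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
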