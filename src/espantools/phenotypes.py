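"""Phenotype statistics for replication-coupled chromatin assays.

Covers four assay read-outs:

* CRASH flow cytometry — apparent silencing-loss rate per colony:
  RFP+GFP+ / (RFP+GFP+ + RFP+GFP-); "other" events never enter the
  denominator because only RFP+ cells can still lose silencing.
* Homologous-recombination frequency — per-replicate selective/viable
  colony ratio summarized as the median over replicates, per viable cell.
* Rad52-focus fractions — percentage of focus-positive cells per imaging
  field, strain mean ± SEM, compared by one-way ANOVA.
* Soluble-histone western blots — histone signal normalized to soluble
  PGK1 and expressed relative to a reference strain.

SEM throughout is sample sd / sqrt(n).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan
    return mean, sem


def silencing_loss_rate(events: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-colony silencing-loss rate and per-strain mean/SEM.

    ``events`` columns: strain, colony, rfp_gfp_pos, rfp_gfp_neg, other.
    Colonies with an empty RFP+ pool (zero denominator) are flagged NaN
    and excluded from the strain summary.
    """
    ev = events.copy()
    denom = ev["rfp_gfp_pos"] + ev["rfp_gfp_neg"]
    ev["rate"] = np.where(denom > 0, ev["rfp_gfp_pos"] / denom.replace(0, np.nan), np.nan)
    rows = []
    for strain, grp in ev.groupby("strain", sort=False):
        rates = grp["rate"].dropna().to_numpy()
        if rates.size:
            mean, sem = _mean_sem(rates)
        else:
            mean, sem = np.nan, np.nan
        rows.append({"strain": strain, "mean_rate": mean, "sem": sem, "n": rates.size})
    return ev, pd.DataFrame(rows)


def hr_frequency(counts: pd.DataFrame, dilution: float = 1.0) -> pd.DataFrame:
    """Median recombination frequency per viable cell, per strain.

    ``counts`` columns: strain, replicate, selective, viable; ``viable``
    is the viable-plate colony count, multiplied by ``dilution`` to give
    viable cells. Per-replicate frequency = selective / (viable *
    dilution); strain statistic = median over replicates (even n: mean of
    the central pair).
    """
    if (counts["viable"] <= 0).any():
        bad = counts.loc[counts["viable"] <= 0]
        rep = bad.iloc[0]
        raise ValueError(
            f"non-positive viable count for strain {rep['strain']!r} "
            f"replicate {rep['replicate']}"
        )
    freq = counts["selective"] / (counts["viable"] * dilution)
    per_rep = counts.assign(frequency=freq)
    med = (
        per_rep.groupby("strain", sort=False)["frequency"]
        .agg(["median", "count"])
        .reset_index()
        .rename(columns={"median": "median_frequency", "count": "n"})
    )
    return med


def relative_hr(counts: pd.DataFrame, reference: str, dilution: float = 1.0) -> pd.DataFrame:
    """Mutant median HR frequency divided by the reference strain's."""
    med = hr_frequency(counts, dilution)
    ref = med.loc[med["strain"] == reference, "median_frequency"]
    if ref.empty:
        raise ValueError(f"reference strain {reference!r} absent")
    med = med.copy()
    med["relative"] = med["median_frequency"] / float(ref.iloc[0])
    return med


def foci_fraction(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage of focus-positive cells per field plus strain mean/SEM.

    ``table`` columns: strain, replicate, counted, positive.
    """
    if (table["counted"] <= 0).any():
        raise ValueError("counted must be > 0")
    if (table["positive"] > table["counted"]).any():
        raise ValueError("positive exceeds counted")
    per = table.assign(percent=100.0 * table["positive"] / table["counted"])
    rows = []
    for strain, grp in per.groupby("strain", sort=False):
        mean, sem = _mean_sem(grp["percent"].to_numpy())
        rows.append(
            {"strain": strain, "mean_percent": mean, "sem": sem, "n": len(grp)}
        )
    return per, pd.DataFrame(rows)


def one_way_anova(*groups: np.ndarray) -> tuple[float, float]:
    """Standard one-way ANOVA F and p over >=2 groups of observations.

    Degenerate input (every observation identical, zero total variance)
    has no defined F and returns (nan, nan).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs n >= 2")
    allvals = np.concatenate(arrs)
    if np.ptp(allvals) == 0:
        return float("nan"), float("nan")
    res = stats.f_oneway(*arrs)
    return float(res.statistic), float(res.pvalue)


def pairwise_anova_vs_reference(
    table: pd.DataFrame, value: str, reference: str, bonferroni: bool = False
) -> pd.DataFrame:
    """Per-strain one-way ANOVA of each strain against the reference.

    Mirrors reporting per-comparison significance without multiplicity
    correction by default; ``bonferroni=True`` multiplies p-values by the
    number of comparisons (capped at 1).
    """
    ref_vals = table.loc[table["strain"] == reference, value].to_numpy()
    strains = [s for s in table["strain"].unique() if s != reference]
    rows = []
    for s in strains:
        f, p = one_way_anova(ref_vals, table.loc[table["strain"] == s, value].to_numpy())
        rows.append({"strain": s, "F": f, "p": p})
    out = pd.DataFrame(rows)
    if bonferroni and len(out):
        out["p"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def soluble_histone_ratio(blot: pd.DataFrame, reference: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histone/PGK1 blot ratio per replicate, relative to the reference
    strain's mean ratio (reference = 1.0); strain mean/SEM.

    ``blot`` columns: strain, replicate, histone, pgk1 (positive signals).
    """
    if (blot["histone"] <= 0).any() or (blot["pgk1"] <= 0).any():
        raise ValueError("blot signals must be positive")
    per = blot.assign(ratio=blot["histone"] / blot["pgk1"])
    ref = per.loc[per["strain"] == reference, "ratio"]
    if ref.empty:
        raise ValueError(f"reference strain {reference!r} absent")
    per["relative"] = per["ratio"] / ref.mean()
    rows = []
    for strain, grp in per.groupby("strain", sort=False):
        mean, sem = _mean_sem(grp["relative"].to_numpy())
        rows.append({"strain": strain, "mean_relative": mean, "sem": sem, "n": len(grp)})
    return per, pd.DataFrame(rows)
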