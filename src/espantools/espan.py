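"""eSPAN strand-bias statistic around replication origins.

The pipeline: keep mononucleosome-sized fragments, assign each fragment to
the unique origin-flanking nucleosome interval containing its midpoint,
count Watson (+) and Crick (-) fragments per (origin, nucleosome position)
cell, and form the per-origin log2(Watson/Crick) bias matrix and its
position-averaged profile. Positions run -10..-1, +1..+10 relative to the
origin midpoint (no position 0: the origin sits in a nucleosome-free
region). Under bidirectional fork geometry, lagging-strand-biased
deposition appears as positive bias left of the origin and negative bias
right of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ORIGIN_POSITIONS
from .synthetic import NUC_HALF, GenomeFixture

STRANDS = ["+", "-"]  # Watson, Crick


@dataclass
class OriginAnnotation:
    """Nucleosome intervals flanking one origin.

    ``intervals`` maps signed position index (-10..-1, +1..+10) to a
    half-open (start, end) interval on ``chrom``. Negative indices lie
    entirely left of the midpoint, positive entirely right; intervals must
    not overlap and must be ordered with the index.
    """

    name: str
    chrom: str
    mid: int
    intervals: dict[int, tuple[int, int]]

    def __post_init__(self) -> None:
        prev_end = None
        for idx in sorted(self.intervals):
            s, e = self.intervals[idx]
            if s >= e:
                raise ValueError(f"{self.name} position {idx}: empty interval")
            if idx < 0 and e > self.mid:
                raise ValueError(f"{self.name} position {idx}: not left of midpoint")
            if idx > 0 and s < self.mid:
                raise ValueError(f"{self.name} position {idx}: not right of midpoint")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.name}: overlapping intervals at {idx}")
            prev_end = e


def origins_from_fixture(
    fixture: GenomeFixture, half: int = NUC_HALF
) -> list[OriginAnnotation]:
    """Build origin annotations from a fixture's dyad map (dyad ± half)."""
    return origins_from_nucmap(fixture.origin_dyads(), fixture.origins, half)


def origins_from_nucmap(nucmap: pd.DataFrame, origins: pd.DataFrame, half: int = NUC_HALF) -> list[OriginAnnotation]:
    """Same, from plain tables (anchor/index/chrom/dyad + chrom/mid/name)."""
    out = []
    for r in origins.itertuples(index=False):
        sub = nucmap[nucmap["anchor"] == r.name]
        intervals = {
            int(i): (int(d) - half, int(d) + half + 1)
            for i, d in zip(sub["index"], sub["dyad"])
        }
        out.append(OriginAnnotation(r.name, r.chrom, int(r.mid), intervals))
    return out


@dataclass
class CountsTensor:
    """Integer fragment counts indexed by (origin, position, strand).

    ``counts`` has shape (n_origins, 20, 2); strand axis order is Watson
    then Crick. Origins are kept in genomic-coordinate order.
    """

    origins: list[str]
    positions: list[int]
    counts: np.ndarray

    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product(
            [self.origins, self.positions, STRANDS],
            names=["origin", "position", "strand"],
        )
        return pd.DataFrame(
            {"count": self.counts.reshape(-1)}, index=idx
        ).reset_index()


def filter_fragments(
    frags: pd.DataFrame, min_len: int = 120, max_len: int = 170
) -> pd.DataFrame:
    """Keep fragments with min_len <= end-start <= max_len (inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    lengths = frags["end"] - frags["start"]
    return frags[(lengths >= min_len) & (lengths <= max_len)].reset_index(drop=True)


def dedup_fragments(frags: pd.DataFrame) -> pd.DataFrame:
    """Drop exact duplicate (chrom,start,end,strand) fragments."""
    return frags.drop_duplicates(
        subset=["chrom", "start", "end", "strand"]
    ).reset_index(drop=True)


def count_by_nucleosome(
    frags: pd.DataFrame, origins: list[OriginAnnotation]
) -> CountsTensor:
    """Count fragments into origin-flanking nucleosome bins by strand.

    A fragment belongs to the unique interval containing its midpoint
    (floor((start+end)/2)); midpoints outside every interval are ignored.
    Overlapping intervals across origins raise (ambiguous assignment).
    """
    origins = sorted(origins, key=lambda o: (o.chrom, o.mid))
    positions = ORIGIN_POSITIONS
    pos_index = {p: i for i, p in enumerate(positions)}

    # flatten intervals per chromosome, check global disjointness
    per_chrom: dict[str, list[tuple[int, int, int, int]]] = {}
    for oi, o in enumerate(origins):
        for idx, (s, e) in o.intervals.items():
            if idx not in pos_index:
                raise ValueError(f"{o.name}: unexpected position index {idx}")
            per_chrom.setdefault(o.chrom, []).append((s, e, oi, pos_index[idx]))
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        for (s1, e1, *_), (s2, _, o2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping nucleosome intervals on {chrom} near "
                    f"{s2} (origin {origins[o2].name})"
                )

    counts = np.zeros((len(origins), len(positions), 2), dtype=np.int64)
    for chrom, ivs in per_chrom.items():
        sub = frags[frags["chrom"] == chrom]
        if sub.empty:
            continue
        mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(
            np.int64
        )
        is_watson = (sub["strand"] == "+").to_numpy()
        starts = np.array([iv[0] for iv in ivs])
        ends = np.array([iv[1] for iv in ivs])
        oidx = np.array([iv[2] for iv in ivs])
        pidx = np.array([iv[3] for iv in ivs])
        j = np.searchsorted(starts, mids, side="right") - 1
        ok = (j >= 0) & (mids < ends[np.clip(j, 0, None)])
        j = j[ok]
        np.add.at(counts, (oidx[j], pidx[j], np.where(is_watson[ok], 0, 1)), 1)
    return CountsTensor([o.name for o in origins], list(positions), counts)


def bias_matrix(
    counts: CountsTensor,
    pseudocount: float = 1.0,
    min_origin_reads: int = 0,
) -> pd.DataFrame:
    """Per-origin log2((W+pc)/(C+pc)) bias matrix.

    With pseudocount 0, cells where either strand count is 0 are missing
    (NaN): a zero numerator or denominator has no finite log ratio.
    Origins with fewer than ``min_origin_reads`` total fragments are
    dropped.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    w = counts.counts[:, :, 0].astype(float)
    c = counts.counts[:, :, 1].astype(float)
    # log2(W+pc) - log2(C+pc): algebraically log2((W+pc)/(C+pc)), but
    # exactly antisymmetric under the W<->C swap in floating point
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.log2(w + pseudocount) - np.log2(c + pseudocount)
    vals[~np.isfinite(vals)] = np.nan
    if pseudocount == 0:
        vals[(w == 0) | (c == 0)] = np.nan
    mat = pd.DataFrame(vals, index=counts.origins, columns=counts.positions)
    if min_origin_reads > 0:
        keep = counts.counts.sum(axis=(1, 2)) >= min_origin_reads
        mat = mat.loc[np.asarray(keep)]
    return mat


def average_bias_profile(matrix: pd.DataFrame) -> pd.DataFrame:
    """Position-averaged bias profile: mean, SEM and n over origins.

    Missing cells are excluded positionwise; a position with zero usable
    origins has NaN mean/SEM and n = 0. SEM is sample sd / sqrt(n).
    """
    if matrix.shape[0] < 1:
        raise ValueError("need at least one origin")
    vals = matrix.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    n = finite.sum(axis=0)
    filled = np.where(finite, vals, 0.0)
    mean = np.where(n > 0, filled.sum(axis=0) / np.maximum(n, 1), np.nan)
    sd = np.full(vals.shape[1], np.nan)
    for j in range(vals.shape[1]):
        col = vals[finite[:, j], j]
        if col.size >= 2:
            sd[j] = np.std(col, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return pd.DataFrame(
        {
            "position": list(matrix.columns),
            "mean": mean,
            "sem": sem,
            "n": n.astype(int),
        }
    )


def fold_leading_lagging(profile: pd.DataFrame) -> pd.DataFrame:
    """Fold a bias profile across the origin.

    Right-side values are sign-flipped and averaged with the matching
    left-side value by |index|, so positive folded bias = lagging-strand
    enrichment under the Watson-left convention. SEMs combine in
    quadrature over the pair mean; n sums.
    """
    prof = profile.set_index("position")
    left_idx = sorted(p for p in prof.index if p < 0)
    right_idx = sorted(p for p in prof.index if p > 0)
    if not left_idx or not right_idx:
        raise ValueError("profile must cover both sides of the origin")
    rows = []
    for k in sorted({abs(p) for p in prof.index}):
        parts, sems, n = [], [], 0
        if -k in prof.index and np.isfinite(prof.loc[-k, "mean"]):
            parts.append(prof.loc[-k, "mean"])
            sems.append(prof.loc[-k, "sem"])
            n += int(prof.loc[-k, "n"])
        if k in prof.index and np.isfinite(prof.loc[k, "mean"]):
            parts.append(-prof.loc[k, "mean"])
            sems.append(prof.loc[k, "sem"])
            n += int(prof.loc[k, "n"])
        if parts:
            mean = float(np.mean(parts))
            sem = float(np.sqrt(np.nansum(np.square(sems))) / len(parts))
        else:
            mean, sem = np.nan, np.nan
        rows.append({"position": k, "mean": mean, "sem": sem, "n": n})
    return pd.DataFrame(rows)
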