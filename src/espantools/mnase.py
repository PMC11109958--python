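"""MNase-seq nucleosome-occupancy metaprofiles and digestion-gel ratios.

Occupancy is full-span per-base fragment coverage. Around each anchor
(TSS or origin midpoint) the coverage window is standardized to mean 0
and unit variance (population convention) before averaging across
anchors, so every region contributes on the same scale regardless of its
sequencing depth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def coverage(frags: pd.DataFrame, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base coverage: each base of a fragment's [start, end) adds 1."""
    tracks = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    for chrom, sub in frags.groupby("chrom"):
        if chrom not in tracks:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
        track = tracks[chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (starts < 0).any() or (ends > track.size).any():
            raise ValueError(f"fragment outside {chrom} bounds")
        # difference-array trick: O(bases + fragments)
        diff = np.zeros(track.size + 1, dtype=np.int64)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
        track += np.cumsum(diff[:-1])
    return tracks


def standardize_region(
    track: np.ndarray, anchor: int, strand: str, half_width: int
) -> np.ndarray | None:
    """(x - mean)/sd over the window anchor±half_width, population sd.

    Minus-strand anchors are reversed so +x is always downstream. The
    window must lie fully inside the chromosome; a constant window has no
    scale and returns None (excluded from averaging).
    """
    lo, hi = anchor - half_width, anchor + half_width + 1
    if lo < 0 or hi > track.size:
        raise ValueError("window extends beyond chromosome")
    win = track[lo:hi].astype(float)
    sd = win.std()  # population (ddof=0)
    if sd == 0:
        return None
    z = (win - win.mean()) / sd
    return z[::-1] if strand == "-" else z


def metaprofile(
    track_by_chrom: dict[str, np.ndarray],
    anchors: pd.DataFrame,
    half_width: int = 500,
) -> pd.DataFrame:
    """Positionwise mean of standardized windows over usable anchors.

    ``anchors`` needs columns chrom, pos, strand. Anchors whose window is
    constant or leaves the chromosome are skipped; at least one must
    remain. Returns position (-half_width..+half_width), mean, n.
    """
    acc = np.zeros(2 * half_width + 1)
    n = 0
    for chrom, pos, strand in zip(anchors["chrom"], anchors["pos"], anchors["strand"]):
        track = track_by_chrom.get(chrom)
        if track is None:
            continue
        lo, hi = pos - half_width, pos + half_width + 1
        if lo < 0 or hi > track.size:
            continue
        z = standardize_region(track, int(pos), strand, half_width)
        if z is None:
            continue
        acc += z
        n += 1
    if n == 0:
        raise ValueError("no usable anchors")
    return pd.DataFrame(
        {
            "position": np.arange(-half_width, half_width + 1),
            "mean": acc / n,
            "n": n,
        }
    )


def profile_peaks(
    profile: pd.DataFrame,
    min_prominence: float = 0.1,
    min_distance: int = 80,
    refine_half: int = 40,
) -> np.ndarray:
    """Local maxima positions of a metaprofile.

    ``min_distance`` (bp) suppresses sub-nucleosomal wiggles: nucleosome
    repeats are ~165 bp so two genuine peaks are never closer than ~half
    of that. Each detected maximum is refined by a parabolic fit over
    ±``refine_half`` bp, which localizes the broad nucleosomal peaks well
    below the 1 bp grid noise; set ``refine_half=0`` for raw grid maxima.
    """
    from scipy.signal import find_peaks

    y = profile["mean"].to_numpy()
    pos = profile["position"].to_numpy()
    idx, _ = find_peaks(y, prominence=min_prominence, distance=min_distance)
    if refine_half <= 0:
        return pos[idx].astype(float)
    out = []
    for i in idx:
        lo, hi = max(0, i - refine_half), min(y.size, i + refine_half + 1)
        a, b, _ = np.polyfit(np.arange(lo, hi), y[lo:hi], 2)
        out.append(float(pos[0] + (-b / (2 * a))) if a < 0 else float(pos[i]))
    return np.asarray(out)


def mono_undigested_ratio(
    bands: pd.DataFrame, reference: str
) -> pd.DataFrame:
    """Mono/undigested band-intensity ratio per strain, relative to a
    reference strain (reference = 1.0).

    ``bands`` needs columns strain, mono, undigested (positive
    intensities, e.g. gel densitometry values).
    """
    req = {"strain", "mono", "undigested"}
    if not req.issubset(bands.columns):
        raise ValueError(f"band table needs columns {sorted(req)}")
    if (bands["mono"] <= 0).any() or (bands["undigested"] <= 0).any():
        raise ValueError("band intensities must be positive")
    out = bands.copy()
    out["ratio"] = out["mono"] / out["undigested"]
    ref = out.loc[out["strain"] == reference, "ratio"]
    if ref.empty:
        raise ValueError(f"reference strain {reference!r} not in table")
    out["relative"] = out["ratio"] / ref.mean()
    return out[["strain", "ratio", "relative"]]
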