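"""Readers, writers and run configuration.

Fragments are carried as a pandas DataFrame with columns
``chrom, start, end, strand, mark`` — 0-based half-open coordinates
throughout (BED-native), strand in ``{+, -, .}``, mark an arbitrary label
(``.`` when absent). All readers and writers round-trip.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam
import yaml

FRAGMENT_COLUMNS = ["chrom", "start", "end", "strand", "mark"]

#: nucleosome positions flanking an origin: -10..-1 then +1..+10 (no 0 — the
#: origin itself sits in a nucleosome-free region)
ORIGIN_POSITIONS = [i for i in range(-10, 11) if i != 0]


class FragmentParseError(ValueError):
    """Malformed fragment input; message names the offending line."""


@dataclass
class RunConfig:
    """Tunable parameters of the pipeline.

    Fragment-size windows are inclusive bp bounds per assay; the eSPAN
    window follows the methods' 120-170 bp selection, the MNase-seq window
    the 149-170 bp selection used for occupancy profiles.
    """

    espan_min_len: int = 120
    espan_max_len: int = 170
    mnase_min_len: int = 149
    mnase_max_len: int = 170
    pseudocount: float = 1.0
    half_width: int = 500
    min_origin_reads: int = 0
    dedup: bool = False
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.espan_min_len > self.espan_max_len:
            raise ValueError("eSPAN fragment window: min > max")
        if self.mnase_min_len > self.mnase_max_len:
            raise ValueError("MNase fragment window: min > max")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)


def empty_fragments() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "mark": pd.Series(dtype=str),
        }
    )


def _fragments_from_records(records: list[tuple]) -> pd.DataFrame:
    if not records:
        return empty_fragments()
    df = pd.DataFrame(records, columns=FRAGMENT_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def read_fragments(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read fragments from a BED-like table or a SAM/BAM alignment.

    ``format`` is ``"bed"`` or ``"sam"``; when omitted it is inferred from
    the file suffix. Alignment input keeps only proper pairs and derives the
    fragment strand from the orientation of the first-in-pair read (eSPAN
    libraries are strand-preserving, so insert orientation is meaningful).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in {".sam", ".bam", ".cram"}:
            format = "sam"
        elif suffix in {".bed", ".tsv", ".txt"}:
            format = "bed"
        else:
            raise ValueError(f"cannot infer fragment format from {path.name!r}")
    if format == "bed":
        return _read_fragments_bed(path)
    if format == "sam":
        return _read_fragments_sam(path)
    raise ValueError(f"unknown fragment format {format!r}")


def _read_fragments_bed(path: Path) -> pd.DataFrame:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FragmentParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FragmentParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise FragmentParseError(
                    f"{path}:{lineno}: requires 0 <= start < end, "
                    f"got {start}..{end}"
                )
            mark = fields[3] if len(fields) > 3 and fields[3] else "."
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in {"+", "-", "."}:
                raise FragmentParseError(
                    f"{path}:{lineno}: bad strand {strand!r}"
                )
            records.append((chrom, start, end, strand, mark))
    return _fragments_from_records(records)


def _read_fragments_sam(path: Path) -> pd.DataFrame:
    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af:
            if (
                not read.is_proper_pair
                or not read.is_read1
                or read.is_unmapped
                or read.mate_is_unmapped
                or read.is_secondary
                or read.is_supplementary
            ):
                continue
            tlen = read.template_length
            if tlen == 0:
                continue
            if tlen > 0:
                start = read.reference_start
                end = start + tlen
            else:
                # read1 is the rightmost mate; the insert spans |tlen| back
                # from its reference end
                end = read.reference_end
                start = end + tlen
            strand = "-" if read.is_reverse else "+"
            mark = read.get_tag("XM") if read.has_tag("XM") else "."
            records.append(
                (read.reference_name, int(start), int(end), strand, str(mark))
            )
    return _fragments_from_records(records)


def write_fragments_bed(frags: pd.DataFrame, path: str | Path) -> None:
    """BED6: name column carries the mark label, score is 0."""
    with open(path, "w") as fh:
        for row in frags.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.mark}\t0\t{row.strand}\n"
            )


# ---------------------------------------------------------------------------
# bias matrices / profiles


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Serialize a per-origin bias matrix (or any origin x position table).

    Header row: ``origin`` then nucleosome positions -10..-1,+1..+10.
    Rows keep the input (genomic) order. Missing cells are ``NA``.
    Round-trips losslessly via :func:`read_matrix`.
    """
    cols = list(matrix.columns)
    with open(path, "w") as fh:
        fh.write("origin\t" + "\t".join(str(c) for c in cols) + "\n")
        for origin, row in matrix.iterrows():
            vals = [
                "NA" if not np.isfinite(v) else repr(float(v)) for v in row.to_numpy()
            ]
            fh.write(str(origin) + "\t" + "\t".join(vals) + "\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"],
        float_precision="round_trip",
    )
    df.columns = [int(c) for c in df.columns]
    df.index.name = None
    return df


def write_profile(profile: pd.DataFrame, path: str | Path) -> None:
    profile.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_profile(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=["NA"], float_precision="round_trip"
    )


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(
    coverage: dict[str, np.ndarray], path: str | Path
) -> None:
    """Write per-base coverage as bedGraph, merging equal-value runs.

    Zero-valued runs are written too so the file reproduces every base of
    each chromosome on re-expansion.
    """
    with open(path, "w") as fh:
        for chrom in coverage:
            vals = np.asarray(coverage[chrom], dtype=float)
            if vals.size == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vals.size]))
            for s, e in zip(starts, ends):
                v = vals[s]
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(
    path: str | Path, chrom_sizes: dict[str, int] | None = None
) -> dict[str, np.ndarray]:
    """Expand a bedGraph back to per-base arrays."""
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FragmentParseError(
                    f"{path}:{lineno}: bedGraph needs 4 fields"
                )
            chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            intervals.setdefault(chrom, []).append((s, e, v))
    out = {}
    for chrom, ivs in intervals.items():
        size = (
            chrom_sizes[chrom]
            if chrom_sizes is not None
            else max(e for _, e, _ in ivs)
        )
        arr = np.zeros(size, dtype=float)
        for s, e, v in ivs:
            arr[s:e] = v
        out[chrom] = arr
    return out


# ---------------------------------------------------------------------------
# simple anchored BED (origins / TSS)


def read_anchors_bed(path: str | Path) -> pd.DataFrame:
    """Read origin midpoints or TSS as BED; returns chrom, pos, strand, name.

    ``pos`` is the interval start (anchors are written as 1-bp intervals).
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FragmentParseError(f"{path}:{lineno}: expected >=3 fields")
            name = fields[3] if len(fields) > 3 else f"anchor{lineno}"
            strand = fields[5] if len(fields) > 5 else "+"
            records.append((fields[0], int(fields[1]), strand, name))
    return pd.DataFrame(records, columns=["chrom", "pos", "strand", "name"])
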