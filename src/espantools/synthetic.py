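"""Synthetic data with known ground truth.

Emulates the inputs of a strand-resolved replication-epigenomics study in
budding yeast:

* eSPAN-like fragment collections in which parental-histone-mark fragments
  derive from the lagging strand with a per-genotype probability
  ``p_lagging`` (new-mark fragments are complementary), producing the
  positive-left / negative-right log2(Watson/Crick) pattern around
  bidirectional origins;
* MNase-seq-like mononucleosome fragments around positioned dyads with
  tunable positioning strength;
* phenotype count tables (flow-cytometry silencing-loss events,
  recombination colony counts, focus-positive cell counts, blot
  intensities) drawn from the Bernoulli/Poisson models the downstream
  statistics assume.

Strand convention: Watson = reference forward strand. A rightward fork's
continuous (leading) nascent strand is Watson, so lagging-biased parental
marks enrich Watson LEFT of the origin and Crick RIGHT of it.

Every generator takes an explicit seed and owns its RNG stream; fixed seed
implies byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import empty_fragments, write_fragments_bed

NUC_HALF = 73  # bp from dyad to nucleosome edge; core particle = 147 bp
DEFAULT_SPACING = 165  # typical yeast nucleosome repeat length, bp
DEFAULT_NFR = 140  # nucleosome-free region width, bp

ORIGIN_SIDE_POSITIONS = list(range(1, 11))  # |index| 1..10 per side
GENE_POSITIONS = list(range(1, 7))  # +1..+6 downstream of the TSS


@dataclass
class GenomeFixture:
    """A small synthetic genome with annotated origins and genes.

    ``origins``: chrom, mid, name. ``tss``: chrom, pos, strand, name.
    ``nuc_map``: one row per dyad — anchor name, anchor kind
    (origin/gene), signed nucleosome index, chrom, dyad (bp).
    """

    chrom_sizes: dict[str, int]
    origins: pd.DataFrame
    tss: pd.DataFrame
    nuc_map: pd.DataFrame
    spacing: int = DEFAULT_SPACING
    nfr_width: int = DEFAULT_NFR

    def origin_dyads(self) -> pd.DataFrame:
        return self.nuc_map[self.nuc_map["kind"] == "origin"]

    def gene_dyads(self) -> pd.DataFrame:
        return self.nuc_map[self.nuc_map["kind"] == "gene"]

    def write_bed(self, outdir: str | Path) -> dict[str, Path]:
        """Emit origins.bed, tss.bed and nuc_map.tsv; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "origins": outdir / "origins.bed",
            "tss": outdir / "tss.bed",
            "nuc_map": outdir / "nuc_map.tsv",
        }
        with open(paths["origins"], "w") as fh:
            for r in self.origins.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.mid}\t{r.mid + 1}\t{r.name}\t0\t+\n")
        with open(paths["tss"], "w") as fh:
            for r in self.tss.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.name}\t0\t{r.strand}\n")
        self.nuc_map.to_csv(paths["nuc_map"], sep="\t", index=False)
        return paths


@dataclass
class GenotypeParams:
    """Simulation parameters for one genotype.

    ``p_lagging`` is the probability that a parental-mark fragment derives
    from the lagging nascent strand at any origin-flanking nucleosome; it
    must lie strictly inside (0, 1) because the bias statistic is a log
    ratio. ``depth`` is fragments per origin side.
    """

    name: str
    p_lagging: float
    depth: int = 500
    frag_len_mean: float = 148.0
    frag_len_sd: float = 8.0
    background: float = 0.05
    jitter_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_lagging < 1.0:
            raise ValueError(
                f"p_lagging must be strictly in (0,1), got {self.p_lagging}"
            )
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.background < 1.0:
            raise ValueError("background fraction must be in [0,1)")


#: Illustrative per-genotype lagging-strand transfer probabilities.  WT has
#: a slight lagging bias; dpb3Δ loses leading-strand routing (strong lagging
#: bias); mcm2-3A loses lagging-strand routing (leading bias); the double
#: mutant is balanced like WT.  These are design values for the simulator,
#: not measurements.
GENOTYPE_PRESETS: dict[str, float] = {
    "WT": 0.55,
    "dpb3": 0.80,
    "mcm2-3A": 0.20,
    "dpb3_mcm2-3A": 0.55,
}


@dataclass
class PhenotypeTruth:
    """Ground-truth per-genotype phenotype probabilities."""

    silencing_loss_rate: dict[str, float] = field(default_factory=dict)
    hr_frequency: dict[str, float] = field(default_factory=dict)
    foci_probability: dict[str, float] = field(default_factory=dict)
    soluble_ratio: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for attr in ("silencing_loss_rate", "hr_frequency", "foci_probability"):
            for strain, p in getattr(self, attr).items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{attr}[{strain!r}] = {p} outside [0,1]")


# ---------------------------------------------------------------------------
# genome


def make_genome(
    n_origins: int = 134,
    n_genes: int = 100,
    chrom_length: int = 2_000_000,
    spacing: int = DEFAULT_SPACING,
    nfr_width: int = DEFAULT_NFR,
    seed: int = 0,
) -> GenomeFixture:
    """Lay out origins on chrI and genes on chrII, each with positioned
    nucleosomes.

    Each origin midpoint sits in an NFR and carries 10 dyads per side at
    indices -10..-1, +1..+10; each TSS carries dyads +1..+6 downstream of
    an upstream NFR.  Anchors are evenly spaced with a small seeded jitter.
    Raises if the per-anchor footprint (21 nucleosomes around an origin)
    does not fit the chromosome.
    """
    rng = np.random.default_rng(seed)
    half_span = nfr_width // 2 + NUC_HALF + (len(ORIGIN_SIDE_POSITIONS) - 1) * spacing + NUC_HALF
    footprint = 2 * half_span + 1
    if n_origins * footprint > chrom_length:
        raise ValueError(
            f"{n_origins} origins with {footprint} bp windows do not fit a "
            f"{chrom_length} bp chromosome"
        )
    gene_span = nfr_width + NUC_HALF + (len(GENE_POSITIONS) - 1) * spacing + NUC_HALF
    if n_genes * (gene_span + 1) > chrom_length:
        raise ValueError(
            f"{n_genes} genes with {gene_span} bp windows do not fit a "
            f"{chrom_length} bp chromosome"
        )

    def _anchor_positions(n: int, margin: int) -> np.ndarray:
        usable = chrom_length - 2 * margin
        base = margin + (np.arange(n) + 0.5) / n * usable
        slack = usable / n - 2 * margin if n else 0
        jitter_amp = max(0, min(spacing, int(slack // 4)))
        jitter = rng.integers(-jitter_amp, jitter_amp + 1, size=n) if jitter_amp else 0
        return base.astype(np.int64) + jitter

    origin_mids = _anchor_positions(n_origins, half_span + 1)
    origin_rows, nuc_rows = [], []
    for i, mid in enumerate(origin_mids):
        name = f"ori{i + 1:03d}"
        origin_rows.append(("chrI", int(mid), name))
        for idx in ORIGIN_SIDE_POSITIONS:
            offset = nfr_width // 2 + NUC_HALF + (idx - 1) * spacing
            nuc_rows.append((name, "origin", idx, "chrI", int(mid) + offset))
            nuc_rows.append((name, "origin", -idx, "chrI", int(mid) - offset))

    tss_rows = []
    if n_genes:
        gene_anchors = _anchor_positions(n_genes, gene_span + 1)
        strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
        for i, (pos, strand) in enumerate(zip(gene_anchors, strands)):
            name = f"gene{i + 1:03d}"
            tss_rows.append(("chrII", int(pos), strand, name))
            sign = 1 if strand == "+" else -1
            for idx in GENE_POSITIONS:
                offset = NUC_HALF + (idx - 1) * spacing
                nuc_rows.append(
                    (name, "gene", idx, "chrII", int(pos) + sign * offset)
                )

    nuc_map = pd.DataFrame(
        nuc_rows, columns=["anchor", "kind", "index", "chrom", "dyad"]
    ).sort_values(["chrom", "dyad"], kind="stable", ignore_index=True)
    fixture = GenomeFixture(
        chrom_sizes={"chrI": chrom_length, "chrII": chrom_length},
        origins=pd.DataFrame(origin_rows, columns=["chrom", "mid", "name"]),
        tss=pd.DataFrame(tss_rows, columns=["chrom", "pos", "strand", "name"]),
        nuc_map=nuc_map,
        spacing=spacing,
        nfr_width=nfr_width,
    )
    _check_fixture(fixture)
    return fixture


def _check_fixture(fx: GenomeFixture) -> None:
    for chrom, grp in fx.nuc_map.groupby("chrom"):
        size = fx.chrom_sizes[chrom]
        dyads = grp["dyad"].to_numpy()
        if (dyads - NUC_HALF < 0).any() or (dyads + NUC_HALF >= size).any():
            raise ValueError(f"dyads outside {chrom} bounds")
    for (anchor,), grp in fx.nuc_map.groupby(["anchor"]):
        if grp["index"].duplicated().any():
            raise ValueError(f"duplicate nucleosome index at {anchor}")


# ---------------------------------------------------------------------------
# eSPAN fragments


def _draw_lengths(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: int, hi: int
) -> np.ndarray:
    lengths = np.rint(rng.normal(mean, sd, size=n)).astype(np.int64)
    return np.clip(lengths, lo, hi)


def simulate_espan(
    fixture: GenomeFixture,
    geno: GenotypeParams,
    mark: str = "parental",
) -> pd.DataFrame:
    """Simulate strand-resolved eSPAN fragments around origins.

    Per origin side, ``geno.depth`` fragments are placed on dyads chosen
    uniformly among that side's 10 nucleosomes, midpoint-jittered by
    ``jitter_sd``.  Watson probability at a nucleosome LEFT of the origin
    is ``p_lagging`` for the parental mark (Crick-complemented on the
    right); for ``mark="new"`` the probabilities are complemented.
    A background fraction of the emitted total is placed uniformly over
    chrI with fair strand choice.
    """
    if mark not in {"parental", "new"}:
        raise ValueError(f"mark must be 'parental' or 'new', got {mark!r}")
    dyads = fixture.origin_dyads()
    if dyads.empty:
        raise ValueError("fixture has no origin nucleosomes")
    rng = np.random.default_rng(geno.seed)

    p_watson_left = geno.p_lagging if mark == "parental" else 1.0 - geno.p_lagging
    n_origins = len(fixture.origins)
    n_signal = geno.depth * 2 * n_origins

    # choose (origin, side, nucleosome) uniformly: exactly depth per side
    left = dyads[dyads["index"] < 0]
    right = dyads[dyads["index"] > 0]
    per_side = {}
    for side_name, side in (("left", left), ("right", right)):
        pool = side["dyad"].to_numpy()
        # depth fragments per origin side, dyad chosen uniformly within side
        choice = np.concatenate(
            [
                rng.choice(
                    grp["dyad"].to_numpy(), size=geno.depth, replace=True
                )
                for _, grp in side.groupby("anchor", sort=True)
            ]
        )
        del pool
        per_side[side_name] = choice

    mids_left = per_side["left"] + np.rint(
        rng.normal(0.0, geno.jitter_sd, size=per_side["left"].size)
    ).astype(np.int64)
    mids_right = per_side["right"] + np.rint(
        rng.normal(0.0, geno.jitter_sd, size=per_side["right"].size)
    ).astype(np.int64)

    watson_left = rng.random(mids_left.size) < p_watson_left
    watson_right = rng.random(mids_right.size) < (1.0 - p_watson_left)

    mids = np.concatenate([mids_left, mids_right])
    watson = np.concatenate([watson_left, watson_right])

    n_bg = int(round(n_signal * geno.background / (1.0 - geno.background)))
    chrom_len = fixture.chrom_sizes["chrI"]
    if n_bg:
        bg_mids = rng.integers(NUC_HALF + 1, chrom_len - NUC_HALF - 1, size=n_bg)
        bg_watson = rng.random(n_bg) < 0.5
        mids = np.concatenate([mids, bg_mids])
        watson = np.concatenate([watson, bg_watson])

    lengths = _draw_lengths(
        rng, mids.size, geno.frag_len_mean, geno.frag_len_sd, 120, 170
    )
    starts = mids - lengths // 2
    ends = starts + lengths
    starts = np.clip(starts, 0, chrom_len - 1)
    ends = np.clip(ends, starts + 1, chrom_len)

    return pd.DataFrame(
        {
            "chrom": "chrI",
            "start": starts.astype(np.int64),
            "end": ends.astype(np.int64),
            "strand": np.where(watson, "+", "-"),
            "mark": mark,
        }
    )


# ---------------------------------------------------------------------------
# MNase fragments


def simulate_mnase(
    fixture: GenomeFixture,
    positioning_sd: float = 20.0,
    depth: int = 200,
    background: float = 0.05,
    seed: int = 0,
    kind: str = "gene",
) -> pd.DataFrame:
    """Simulate strandless mononucleosome fragments around positioned dyads.

    ``depth`` fragments per dyad with midpoints ~ Normal(dyad,
    positioning_sd); lengths clipped to 149-170 bp; a ``background``
    fraction of the total is placed uniformly.  ``kind`` selects gene,
    origin, or all dyads.
    """
    if positioning_sd < 0:
        raise ValueError("positioning_sd must be >= 0")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= background <= 1.0:
        raise ValueError("background must be in [0,1]")
    if kind == "gene":
        dyads = fixture.gene_dyads()
    elif kind == "origin":
        dyads = fixture.origin_dyads()
    elif kind == "all":
        dyads = fixture.nuc_map
    else:
        raise ValueError(f"unknown dyad kind {kind!r}")
    if dyads.empty:
        raise ValueError(f"fixture has no {kind} nucleosomes")

    rng = np.random.default_rng(seed)
    dyad_pos = np.repeat(dyads["dyad"].to_numpy(), depth)
    chroms = np.repeat(dyads["chrom"].to_numpy(), depth)
    n_total = dyad_pos.size
    n_bg = int(round(n_total * background))
    n_pos = n_total - n_bg

    keep = rng.permutation(n_total)[:n_pos]
    keep.sort()
    mids_pos = dyad_pos[keep] + np.rint(
        rng.normal(0.0, positioning_sd, size=n_pos)
    ).astype(np.int64)
    chroms_pos = chroms[keep]

    chrom_names = list(fixture.chrom_sizes)
    bg_chrom_idx = rng.integers(0, len(chrom_names), size=n_bg)
    bg_chroms = np.array(chrom_names, dtype=object)[bg_chrom_idx]
    bg_sizes = np.array([fixture.chrom_sizes[c] for c in bg_chroms], dtype=np.int64) if n_bg else np.array([], dtype=np.int64)
    bg_mids = (
        (rng.random(n_bg) * (bg_sizes - 2 * NUC_HALF) + NUC_HALF).astype(np.int64)
        if n_bg
        else np.array([], dtype=np.int64)
    )

    mids = np.concatenate([mids_pos, bg_mids])
    all_chroms = np.concatenate([chroms_pos, bg_chroms]) if n_bg else chroms_pos
    lengths = _draw_lengths(rng, mids.size, 158.0, 8.0, 149, 170)
    starts = mids - lengths // 2
    ends = starts + lengths
    sizes = np.array([fixture.chrom_sizes[c] for c in all_chroms], dtype=np.int64)
    starts = np.clip(starts, 0, sizes - 1)
    ends = np.clip(ends, starts + 1, sizes)
    strands = np.where(rng.random(mids.size) < 0.5, "+", "-")

    df = pd.DataFrame(
        {
            "chrom": all_chroms.astype(str),
            "start": starts.astype(np.int64),
            "end": ends.astype(np.int64),
            "strand": strands,
            "mark": "mnase",
        }
    )
    return df


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    truth: PhenotypeTruth,
    n_events: int = 50_000,
    n_colonies: int = 10,
    n_replicates: int = 6,
    n_cells_plated: int = 1_000_000,
    n_cells_field: int = 500,
    n_fields: int = 3,
    p_rfp: float = 0.9,
    n_blot_reps: int = 4,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Draw phenotype count tables from the truth probabilities.

    Returns a dict with keys ``crash`` (per-colony flow events, multinomial
    over RFP+GFP+/RFP+GFP-/other with ``p_rfp`` the RFP+ fraction), ``hr``
    (per-replicate selective and viable colony counts), ``foci`` (per-field
    counted/positive cells), and, when soluble-ratio truths are given,
    ``blot`` (per-replicate histone and PGK1 intensities).
    """
    rng = np.random.default_rng(seed)
    crash_rows, hr_rows, foci_rows, blot_rows = [], [], [], []

    for strain, rate in truth.silencing_loss_rate.items():
        probs = [p_rfp * rate, p_rfp * (1.0 - rate), 1.0 - p_rfp]
        draws = rng.multinomial(n_events, probs, size=n_colonies)
        for colony, (gg, gn, other) in enumerate(draws, start=1):
            crash_rows.append((strain, colony, int(gg), int(gn), int(other)))

    for strain, freq in truth.hr_frequency.items():
        sel = rng.binomial(n_cells_plated, freq, size=n_replicates)
        for rep in range(1, n_replicates + 1):
            hr_rows.append((strain, rep, int(sel[rep - 1]), int(n_cells_plated)))

    for strain, p in truth.foci_probability.items():
        pos = rng.binomial(n_cells_field, p, size=n_fields)
        for rep in range(1, n_fields + 1):
            foci_rows.append((strain, rep, int(n_cells_field), int(pos[rep - 1])))

    for strain, ratio in truth.soluble_ratio.items():
        # multiplicative measurement noise around a shared loading level
        pgk1 = rng.lognormal(mean=np.log(1000.0), sigma=0.15, size=n_blot_reps)
        hist = ratio * pgk1 * rng.lognormal(mean=0.0, sigma=0.10, size=n_blot_reps)
        for rep in range(1, n_blot_reps + 1):
            blot_rows.append((strain, rep, float(hist[rep - 1]), float(pgk1[rep - 1])))

    out = {
        "crash": pd.DataFrame(
            crash_rows,
            columns=["strain", "colony", "rfp_gfp_pos", "rfp_gfp_neg", "other"],
        ),
        "hr": pd.DataFrame(
            hr_rows, columns=["strain", "replicate", "selective", "viable"]
        ),
        "foci": pd.DataFrame(
            foci_rows, columns=["strain", "replicate", "counted", "positive"]
        ),
    }
    if blot_rows:
        out["blot"] = pd.DataFrame(
            blot_rows, columns=["strain", "replicate", "histone", "pgk1"]
        )
    return out
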