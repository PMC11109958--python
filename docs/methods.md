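# Methods

## Strand-bias model

eSPAN reads are strand-resolved nascent-chromatin fragments. The package
takes aligned fragments (it does not align reads) and assumes they are
already nascent-strand-resolved; the BrdU double-IP that achieves this is
wet-lab scope and is represented in the simulator, not re-modeled
analytically.

Conventions, fixed once and tested:

* Coordinates are 0-based half-open everywhere internally (BED-native).
* Watson = reference forward strand. A rightward-moving fork synthesizes
  its leading strand on Watson; by bidirectional fork geometry a
  lagging-biased parental mark therefore enriches Watson at nucleosomes
  left of the origin midpoint and Crick at nucleosomes right of it.
* Fragment strand from alignment input is the strand of the first-in-pair
  read: eSPAN libraries are single-strand-preserving, so insert
  orientation carries the signal.
* Nucleosome positions are indexed −10..−1, +1..+10 around each origin;
  there is no position 0 because origins sit in a nucleosome-free region.

Pipeline: fragments are filtered to mononucleosome size (120–170 bp
inclusive for eSPAN), each fragment is assigned to the unique nucleosome
interval containing its midpoint `floor((start+end)/2)` (midpoint
containment is unambiguous with half-open intervals; fragments landing in
no interval are ignored; overlapping intervals across origins are an
error), and Watson/Crick counts per (origin, position) cell give

    bias(o, k) = log2(W + pc) − log2(C + pc),

computed as a difference of logs so that swapping the strand labels
negates every cell exactly in floating point. With `pc = 0` a cell with
either strand count zero is marked missing rather than ±∞. The default
pseudocount is 1, which keeps all 20 positions defined at low depth; the
plain log-ratio (`pc = 0`) is the statistic itself and is what the
validation suite uses at full depth, because a unit pseudocount shrinks
the ratio noticeably when per-cell counts are a few tens.

The profile is the per-position mean over origins with sample-sd/√n SEM
and explicit n (missing cells excluded positionwise). Folding sign-flips
the right arm and averages it with the left by |index|, so the folded
plateau estimates `log2(p/(1−p))` for lagging-transfer probability `p`.
Heatmap rows are ordered by origin genomic coordinate.

## MNase occupancy

Occupancy is full-span per-base fragment coverage (each base in
`[start, end)` increments by 1), computed with a difference array. MNase
fragments are filtered to 149–170 bp; eSPAN occupancy uses 120–170 bp —
the two windows are deliberately different defaults, both configurable.
Around each anchor (TSS with strand, or origin midpoint) the ±500 bp
coverage window is standardized to mean 0 and unit variance using the
population (ddof=0) convention — the window is the entire population of
positions — then minus-strand windows are reversed so +x is downstream,
and usable windows are averaged with equal weight per anchor. Constant
windows (sd = 0) carry no shape information and are excluded. Peak
calling on a metaprofile uses `scipy.signal.find_peaks` with a minimum
peak spacing of 80 bp (half a nucleosome repeat) followed by a parabolic
fit over ±40 bp; raw 1-bp-grid maxima wander by up to ~15 bp under
coverage noise correlated at the fragment-length scale, while refined
maxima localize within a few bp.

The mono/undigested chromatin ratio consumes a numeric band-intensity
table (gel densitometry happens upstream) and reports mono/undigested per
strain relative to a designated reference strain.

## Phenotype statistics

* CRASH: per-colony rate = RFP+GFP+ / (RFP+GFP+ + RFP+GFP−); events that
  are not RFP+ never enter the denominator because only RFP+ cells retain
  the potential to lose silencing. Zero-denominator colonies are flagged
  missing. Strain summary is mean ± SEM over colonies.
* HR frequency: per-replicate frequency = selective count / (viable count
  × dilution); the strain statistic is the median over replicates, with
  an even count summarized by the mean of the central pair. Relative HR
  divides the mutant median by the reference median (medians-ratio rather
  than mean of per-replicate ratios — the median is the assay's statistic,
  so the ratio of the two reported statistics is the natural relative
  measure).
* Foci: percentage of focus-positive cells per imaging field; strain
  mean ± SEM; strains compared to the reference by one-way ANOVA
  (scipy's F test), reported per comparison without multiplicity
  correction by default, with an optional Bonferroni flag. Degenerate
  input with zero total variance has no defined F and is flagged NaN.
* Soluble histones: per-replicate histone/PGK1 ratio, divided by the
  reference strain's mean ratio so the reference is 1.0; invariant to any
  common rescaling of the blot signals.

SEM is sample sd/√n throughout.

## Synthetic data

The generator produces the statistical structure the analysis assumes,
with ground truth for recovery tests:

* **Genome**: origins on chrI, genes on chrII (default 2 Mb each),
  anchors evenly spaced with a small seeded jitter. Each origin has a
  140 bp NFR and 10 dyads per side at a 165 bp repeat (typical yeast
  spacing); each gene has an upstream NFR and dyads +1..+6 downstream of
  the TSS, mirrored for minus-strand genes. Layouts that cannot fit the
  chromosome raise rather than spill over.
* **eSPAN**: per origin side, `depth` fragments choose a dyad uniformly,
  jitter their midpoints (sd 10 bp default), and draw lengths from
  Normal(148, 8) clipped to [120, 170]. P(Watson | left side) =
  `p_lagging` for the parental mark, complemented on the right side and
  complemented again for the new mark. A background fraction (default
  0.05) is uniform with fair strand choice. Genotype presets — WT 0.55,
  dpb3 0.80, mcm2-3A 0.20, double mutant 0.55 — are illustrative design
  values encoding "slight lagging bias; strong lagging; strong leading;
  rebalanced", not measurements. `p_lagging` is restricted to the open
  interval (0,1) because the log-ratio diverges at the endpoints.
* **MNase**: fragment midpoints ~ Normal(dyad, positioning_sd), lengths
  clipped to [149, 170], strandless; `background=1` is allowed and gives
  the fully unpositioned null.
* **Phenotypes**: CRASH events are multinomial over
  {RFP+GFP+, RFP+GFP−, other} with an RFP+ fraction of 0.9 by default;
  selective HR colonies are Binomial(cells plated, frequency) per
  replicate with the viable count taken as the plated number; foci are
  Binomial(cells per field, focus probability); blot intensities are
  log-normal measurement noise around a shared loading level times the
  true soluble ratio.

Each generator owns one explicitly seeded RNG stream; fixed seed gives
byte-identical output files.

What the simulator does **not** emulate: replication-timing variation
between origins, fork-direction heterogeneity and termination zones,
mappability and GC biases, PCR duplicates, chromatin-state covariates of
nucleosome positioning, and fluctuation-test (jackpot) dynamics in the HR
assay. Passing recovery tests therefore demonstrates the estimators are
correct under the assumed sampling models at realistic scales, not that
real libraries are free of these confounders.

## Validation scales and numerical choices

Validation simulations use 134 origins with ~10⁵ eSPAN fragments per
library (per-side depth 373), where the folded plateau recovers
log2(p/(1−p)) within ~0.05–0.1 including small-count log-ratio (Jensen)
bias, and 2000 gene anchors with ~10⁵ MNase fragments, where the
flat-null metaprofile range stays well below 0.2 (the null range is set
by the anchor count alone, since standardization fixes each window's
variance). Standardization residuals are held to 1e-9. TSV writers emit
shortest round-tripping float representations and readers parse with
round-trip precision, so write→read is exact; missing values are "NA".
Duplicate-fragment removal is off by default and exposed as a flag.

## Known limitations

Fragment counting assumes disjoint nucleosome intervals across origins
(closely spaced origins sharing flanking nucleosomes would need an
assignment rule the data cannot disambiguate). The bias statistic is
undefined at `p ∈ {0, 1}` and increasingly shrunk by the pseudocount at
low depth. Metaprofile peak refinement assumes locally quadratic peaks,
appropriate for nucleosomal scales but not for sub-10 bp features.
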