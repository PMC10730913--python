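# Methods

This note records the models behind each stage, the defaults and why they
were chosen, the numerical conventions, and what the simulation-based tests
do and do not establish about real data.

## Codebook model

Features are encoded as constant-weight binary codewords over an
`n_cycles × n_channels` grid (default 15 × 4 = 60 bits), weight 4, minimum
pairwise Hamming distance 4. Commercial panels do not disclose their code
design; a constant-weight, distance-4 scheme is the standard published
construction for combinatorial FISH barcoding (it detects any single bit
error and corrects none, leaving error control to the likelihood margin and
the downstream quality calibration), so it is adopted here with weight and
distance exposed as parameters. Codes are generated by seeded randomized
greedy search: draw uniform weight-w codes, accept those at distance ≥ d
from all accepted codes, fail with an explicit "infeasible" error after a
bounded number of rejections per slot. Generation is bitwise reproducible
given the seed.

Three control classes share the gene codes' weight/distance constraints:
negative-control *probes* (physical probes against non-biological targets —
they report assay-level non-specific binding), negative-control *codewords*
(codebook entries with no probe — every call to one is a decoder error,
the anchor for quality calibration), and *unassigned* codewords. Bit order
is row-major cycle-then-channel, 0-based.

## Optical and noise model

Each transcript's punctum emits, per bit, a log-normally distributed
intensity: log-intensity ~ N(μ_on, σ_on²) for on-bits and N(μ_off, σ_off²)
for off-bits (defaults μ_on = 4.0, μ_off = 2.0, σ = 0.3 — an e²≈7×
on/off contrast typical of well-quenched chemistry). Before intensities are
drawn, each on-bit drops out with probability `p_dropout` (default 0.05)
and each off-bit fires spuriously with `p_spurious` (default 0.005).
Dropout is the dominant error mode in practice (incomplete hybridization,
photobleaching), which is why the defaults are asymmetric.

The decoder assumes the same functional form: independent per-bit Gaussians
on log-intensity with known state parameters. Parameters come either from
the generating configuration or from a two-component moment-matching split
of observed log-intensities (`NoiseModel.estimate`), which is scale-free
and therefore also works on window-integrated detection intensities.
Position does not enter the likelihood; decoding is single-pass with a
uniform prior over all codebook entries (no FOV-level iterative
re-estimation).

`raw_q = min(40, −10·log₁₀(1 − p_best))` with `p_best` the softmax
posterior of the argmax codeword. The cap of 40 is the conventional Phred
ceiling; posterior-based scaling puts raw quality on the same scale as the
calibrated score. Intensities are floored at 1e−6 before taking logs. Ties
in the argmax resolve to the lowest code index.

## Quality calibration

Raw qualities are binned into 20 equal-width bins over [0, 40]; in each bin

    per-codeword false-call rate = (n_ncc + 1) / N_ncc_codes
    FDR̂  = min(1, rate × N_gene_codes / max(1, n_gene_calls))
    qv    = min(40, −10·log₁₀(FDR̂))

The +1 pseudocount keeps empty bins finite and conservative (rule-of-three
style); scaling by the gene/control codeword ratio converts a
per-control-codeword rate into an expected count of false gene calls.
Weighted pool-adjacent-violators then enforces that `qv` is non-decreasing
in raw quality, and each transcript inherits its bin's `qv`.

Bins with fewer than 50 calls are unreliable; each *maximal run of
consecutive sparse bins* is pooled into one estimation block, while
populated bins always stand alone. The direction of this merge matters:
attaching sparse bins to a populated neighbor contaminates the saturated
top bin (where most calls concentrate) with low-quality strays and can
collapse the whole calibration at small n, whereas pooling sparse runs
among themselves leaves high-quality bins pure and pushes the uncertainty
into blocks that were uninformative anyway.

The default analysis filter is `qv ≥ 20` (nominal 1% error). At high noise
(e.g. 10% dropout) the calibrator can conclude that *no* bin supports a 1%
error rate and pass nothing — that is the intended conservative behavior,
not a failure mode: with 60-bit codes at distance 4, a dropout plus a
spurious bit occasionally produces a confidently wrong call that no margin
can flag, and the control-codeword rate is what detects this regime.

## Segmentation and assignment

Nucleus masks are an input (a 2D integer label raster); producing them from
morphology images is out of scope. Expansion measures Euclidean distance
from each background pixel to the nearest *nucleus pixel* (not the
centroid — "expanding outwards" semantics), claims pixels within 15 µm,
and stops where another nucleus is closer, which yields non-overlapping
territories in a single rule. It is implemented as a per-label distance
transform restricted to each nucleus's padded bounding box with a
strict-improvement update, so the documented tie-break (lower label id
wins) is exact rather than dependent on library internals.

Raster convention: pixel (0,0) covers [0, px) × [0, px) µm, x rightward
(columns), y downward (rows); transcripts map to the pixel containing
their centroid; out-of-bounds and background pixels give cell id 0. The
default raster resolution is 0.2 µm/pixel, the imaging resolution of the
instrument class being modeled; at this resolution the raster assignment
differs from exact vector geometry only in a sub-pixel band along
territory boundaries (measured at ≈0.3% of uniformly random points, all on
boundaries).

The cell × feature matrix counts quality-filtered, assigned transcripts;
control features remain as flagged columns for QC and are dropped by
`gene_matrix()` for analysis. Export is a MatrixMarket triplet in the 10x
dialect (features as rows; features.tsv columns id/name/type) plus a
transcripts CSV; readers also accept the deposited-platform column dialect
(`feature_name`, `x_location`, …) and gzip streams.

## Label transfer

The query is restricted to genes shared with the reference, each cell
size-normalized to the *reference* median total, log1p-transformed,
z-scored per gene with reference statistics, and projected onto the
reference's top 50 principal components. Each query cell takes the modal
label among its 30 nearest reference cells (Euclidean) iff that label
holds ≥ ⌈0.5·30⌉ = 15 neighbors; a tie between two labels at the winning
count yields "unlabeled". Normalization details (size-factor target, log
base, z-scoring with reference statistics) are common single-cell practice
and parameterized; the tie rule is a deliberate resolution of an ambiguity
in the "at least 50%" criterion, chosen so that an exactly split vote never
asserts a type.

## Spot interpolation and registration

Spot grids are hexagonal lattices with 100 µm pitch and 55 µm spot
diameter (the standard spot-array geometry); rows are spaced pitch·√3/2
with alternate rows offset by pitch/2, so all nearest-neighbor distances
equal the pitch. Items (transcripts or weighted cell centroids) join their
nearest spot center, with exact distance ties to the lower spot index;
with no radius cap the binning conserves per-feature totals exactly, which
is the property downstream deconvolution tools rely on.

Registration fits rigid/similarity/affine/homography models to paired
landmarks via RANSAC (minimal-sample fits, consensus at a 5 µm residual
tolerance, least-squares refit on the best consensus), seeded and
deterministic. An all-outlier input raises rather than returning a
spurious fit. Spot-composition deconvolution itself is delegated to
existing tools; this package produces the spot × feature pseudobulk they
consume.

## QC metrics

Median gene sensitivity = median over genes of per-gene mean counts per
cell (median, not mean, because a few high expressors dominate the mean).
Complexity = smallest k such that the k largest per-gene totals reach 50%
of counts. Percentiles use linear interpolation between order statistics.
Control rates are fractions of quality-passing counts per control
category. Downsampling is binomial thinning with a single global retention
probability (the package has no read-level data, so read-depth matching
collapses to count thinning — a documented divergence). Replicate
concordance is r² of per-gene log₁₀(total+1) pseudobulk between sections;
the log scale is a choice (the raw-vs-log convention is not standardized)
and is exposed as a parameter.

## What the simulator does and does not emulate

Emulated: combinatorial codeword signals with realistic error modes,
background puncta with *random* bit patterns (so some decode to
negative-control codewords — without this the calibration would be
untestable), non-overlapping cells with nucleus/cytoplasm structure,
negative-binomial expression with well-separated type profiles, Gaussian
PSF image formation with optional shot noise, landmark sets with exact
outlier counts.

Not emulated: 3D z-stacks (simulation is single-plane; z is carried but
zero — the decoding and assignment math is dimension-agnostic), optical
crosstalk between channels, cell-shape irregularity, autofluorescence and
tissue-dependent background structure, FOV tiling and stitching artifacts,
segmentation errors in the input nucleus masks, and continuous or
overlapping cell-type manifolds. Passing tests therefore demonstrate
correctness of the algorithms under their stated noise model, not
performance on real tissue; in particular real label-transfer accuracy
will be lower than the simulated ≥95% because real cell types are not
disjoint marker blocks.

## Problem sizes and numerical conventions

The standard test conditions are a 313-gene panel (plus 20 negative-control
probes, 40 negative-control codewords, 20 unassigned codes), ~60 cells at
166 mean transcripts per cell (negative binomial, dispersion 10) in a
300 × 300 µm field — about 10⁴ puncta per section — with background at
5 false puncta per 100 × 100 µm. These sizes make every stage's
ground-truth comparison exact and fast while keeping per-gene counts high
enough for stable calibration; replicate-concordance r² at this depth
(~0.83) is limited by counting noise on ~30-count pseudobulk totals and
rises toward 1 with depth. Detection tests render smaller fields
(≤120 × 120 µm) because image rendering is the only stage whose cost
scales with area rather than transcript count.

Other conventions: decode ties break to the lowest code index; the
calibration table's last bin is right-closed so capped raw qualities land
in it; PAVA output is clipped to [0, 40] defensively; distances are µm
everywhere; all generators are NumPy `default_rng` seeded from explicit
configuration, with no hidden entropy.

## Known limitations

- The likelihood treats bits independently; correlated failures (a bad
  cycle, channel-wide crosstalk) are neither simulated nor modeled.
- Calibration is per-bin global, not per-gene; genes with atypical optical
  behavior would share their bin's qv.
- The greedy codebook search is not guaranteed to find maximal codebooks
  near the packing bound; it fails loudly rather than degrading.
- `NoiseModel.estimate` assumes a clearly bimodal log-intensity mixture;
  at extreme dropout the on-component can be underpopulated.
- Spot interpolation models capture by proximity only (no spot-diameter
  masking unless `max_radius` is set), matching the pseudobulk convention
  rather than physical capture.
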