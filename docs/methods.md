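# Methods

## Descriptor

The basic LBP operator at P = 8, R = 1 on the square grid (no interpolation)
codes each interior pixel by thresholding its eight neighbors against the
center level: code = Σ_p s(n_p − c)·2^p with s(x) = 1 for x ≥ 0 (a neighbor
equal to the center sets its bit, the standard convention). Neighbor p = 0 is
East and the order proceeds counter-clockwise; any fixed order yields the
same histograms up to a bin permutation, so one is fixed to make results
bit-exact. The one-pixel border is excluded rather than padded — padding
would fabricate levels — so an H×W plane yields (H−2)·(W−2) codes.

EOCLBP applies this operator to every ordered component pair (Ck, Ck′) of a
three-component image, center from Ck and neighbors from Ck′, producing nine
256-bin histograms per color space in the fixed order (C1,C1), (C2,C2),
(C3,C3), (C1,C2), (C2,C1), (C1,C3), (C3,C1), (C2,C3), (C3,C2). Histograms
are unit-normalized before any concatenation or distance: datasets mix image
sizes, and raw counts would not be comparable. Column provenance
(space, pair, bin) is carried with every feature matrix and its
space-major/pair-minor/bin-minor order is normative.

## Color spaces and quantization

The nine spaces are RGB; chromaticity rgb; full-range BT.601 YCbCr;
(wb, rg, by) with wb = (R+G+B)/3, rg = (R−G)/2, by = (2B−R−G)/4; Ohta's
I1I2I3 with I1 = (R+G+B)/3, I2 = (R−B)/2, I3 = (2G−R−B)/4; hexcone HSV;
double-hexcone HLS; HSI with I = (R+G+B)/3 and the arccos hue; and Hanbury's
improved HLS (HSV hue, Rec.709 luminance, saturation max−min). These are the
canonical textbook definitions of the named spaces.

Every derived component is mapped affinely onto 0..255 and rounded
half-away-from-zero (stable across platforms) with clamping. Signed
chrominance components use the symmetric range [−127.5, 127.5] so zero maps
to level 128. Hue is quantized by H·255/360 and treated as a linear level
thereafter; its circularity is a known limitation (codes at hue 0 and hue
255 are maximally distant although perceptually adjacent), accepted because
LBP needs a scalar order. Undefined hue (zero saturation) is set to 0, as is
the saturation of a black pixel; a black pixel's chromaticity is the neutral
1/3 per channel.

## Similarity matrix and relevance scores

The soft similarity matrix is a property of the training samples, computed
once from the full concatenated descriptor and reused by every candidate.
Each sample's L2-normalized descriptor x_i is reconstructed from the matrix
A_i of its same-class peers by min_w (1/2)‖x_i − A_i w‖² + λ‖w‖₁ subject to
w ≥ 0 (coordinate descent, tolerance 1e−6, at most 1000 iterations; λ
defaults to 0.1, scale-free because descriptors are L2-normalized). Row i of
S holds w rescaled by its maximum (all-zero if the fit is null), so values
lie in [0, 1]; the matrix is then symmetrized with the elementwise maximum.
Cross-class entries are exactly zero by construction, the diagonal is zero,
and a class with a single training sample yields a zero row plus a logged
warning. The solver is deterministic at these settings.

The histogram score divides the S-weighted sum of squared Jeffrey distances
by the between-class sum of squared Jeffrey distances; the bin score divides
the squared residual of the row-stochastic reconstruction by the feature's
variance. Both are ranked ascending; degenerate candidates (no between-class
separation, zero variance) score +inf and rank last, with ties broken by the
original candidate index so rankings are stable and reproducible. Both
scores implement the plain shape `(candidates, labels, S) -> scores`, so
alternative published scores (ICS, ASL, Fisher-type bin criteria) can be
plugged in without touching the selection code.

The Jeffrey distance uses the 0·ln(·) = 0 convention, bins empty in both
histograms contribute nothing, and for unit-normalized inputs the distance
is bounded by 2·ln 2 (each term h·ln(2h/(h+k)) ≤ h·ln 2).

## Selection

MCSHS ranks the 81 candidate histograms and evaluates at most 81 prefixes at
histogram granularity (blocks of 256 columns). MCSBS ranks all 20,736 bins
of the concatenated vector and evaluates bin prefixes. MCSHBS ranks
histograms with the histogram score, ranks bins within each histogram
independently with the bin score — scored once on the training data, not
re-scored after histogram ranking — and interleaves: group q of the final
ranking holds every histogram's q-th best bin, histograms visited in ranked
order. The interleaved output is a permutation of all bins that preserves
each histogram's internal bin order.

Prefix accuracies (1-NN, L1, validation subset) are computed incrementally:
appending a ranked unit adds its columns' absolute-difference contribution
to the running validation×training distance matrix, processed in blocks with
a cumulative sum, which is exactly equal to recomputing each prefix from
scratch. The selected dimension is the argmax of the curve; ties resolve to
the smallest prefix, preferring the most compact subspace consistent with
the dimensionality-reduction goal. A configurable evaluation stride
(default 1 = exact) subsamples the prefixes for fast exploratory runs; the
final full prefix is always evaluated, so the selected accuracy can never
fall below the no-selection accuracy on the validation subset at any stride.

## Evaluation protocol

Accuracy is the rate of well-classified test images under 1-NN/L1, with
distance ties resolved to the lowest training index. Benchmark texture
suites provide only train/test splits, so the conventional protocol reuses
the test subset as the validation subset for the embedded dimension choice;
this package reproduces that mode as the default behind an explicit flag and
logs a warning, because the selected dimension is then tuned on the data it
is evaluated on and the reported accuracy is optimistically biased. The
proper-split mode uses a disjoint validation subset and is the recommended
setting when a three-way split exists.

## Synthetic textures

The generator produces each class as an oriented binary grating — orientation
k·180°/n_classes, period 6 px, duty cycle 0.5, levels 64/192 — injected into
a configurable subset of the R, G, B channels with additive clamped Gaussian
noise (σ defaults to 8); non-signal channels are i.i.d. uniform noise.
Gratings rather than Markov random fields: they mirror the oriented
micro-texture of bark while keeping the LBP structure analytically
predictable and generation cheap. The grating phase is randomized per image;
LBP histograms are translation-invariant, so phase carries no class
information and within-class variation comes from noise alone. Per-image
seeds derive deterministically from the master seed, so datasets regenerate
byte-identically. Default sizes (64×64, 4 classes, 5 images per class per
subset) keep a full 20-seed study under a minute.

What passing on this generator shows — and does not. The generator
guarantees channel-confined, orientation-coded, stationary signal with
homogeneous noise; real bark adds illumination drift, scale variation,
non-stationary structure and inter-class color overlap. Recovery and
improvement results on the generator validate the machinery (the scores find
the signal-bearing channel, the embedded choice never selects a subspace
that validates worse than the full set); they do not predict benchmark
accuracy on photographic datasets.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the study
conditions (40 images of 64×64, 20,736 candidate bins, 20 seeds), which
completes in roughly half a minute on one CPU; the incremental curve makes
the 20,736-prefix MCSBS/MCSHBS evaluation linear in the number of candidate
bins.

## Known limitations

Hue circularity is ignored after quantization. Only the basic P = 8, R = 1
neighborhood is implemented (the histogram count 2^P makes larger P
expensive and the method's contribution is selection, not the operator).
The SpASL and supervised-sparsity formulas follow the published property
descriptions (soft similarity, Jeffrey distance, ascending ranking) in the
exact form stated above; other published variants can be substituted through
the score interface. The 1-NN/L1 classifier is deliberate and fixed — the
package isolates the contribution of feature selection, not classifier
engineering.
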