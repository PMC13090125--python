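# Methods

This note records the models and procedures the package implements, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic generators do and do not emulate.

## Quality control

**Instrument accuracy (XIC dispersion).** The estimator builds extracted ion
chromatograms in two rounds. Round one seeds XICs from MS1 base-peak m/z
values at a 0.5 Da absolute tolerance; an XIC is the per-scan closest peak
within tolerance, collected over scans in order. Seeds are deduplicated
greedily (a sorted seed is kept only if more than one tolerance from the
last kept seed) so that jittered copies of one ion species produce one XIC.
XICs with at least 5 points contribute their median m/z as a second-round
seed; round two repeats at 0.01 Da, and the estimate is the median of the
per-XIC m/z standard deviations (population standard deviation, ddof = 0).
When no second-round XIC reaches 5 points the accuracy is undefined and is
represented as a missing value, never as 0. The estimator is exactly
reproduced by an independent brute-force implementation in the test suite
and is monotone in the jitter injected by the run generator.

**Spectrum type.** Spectra with fewer than 5 peaks are centroided by fiat.
Otherwise the half-maximum window S around the base peak is the maximal
contiguous index run containing the base peak with intensity strictly above
half the base intensity. The literal set-builder definition of S is
vacuously true for all indices left of the base peak (its quantifier range
is empty there); the contiguous-run reading matches the evident intent (an
FWHM window) and reproduces the worked examples, so it is what we implement.
A narrow window (index span < 3) or a wide one (m/z width above the total
span divided by 1,000) indicates sticks (centroid); otherwise zeros
distinguish profile from thresholded data.

**Tier presets.** The numeric thresholds behind "low number of peaks" and
"low intensity amplitudes" are free parameters; the shipped presets are
this package's defaults, chosen so that tier outputs
nest (A ⊆ B ⊆ C): A requires ≥ 5 peaks, amplitude ≥ 10, known single
charge, estimated accuracy ≤ 10⁻³ Da ("about four decimal places"); B
relaxes the accuracy to 10⁻² Da and admits unknown charge; C requires only
≥ 3 peaks, amplitude ≥ 2, and drops the charge and accuracy checks. All
spectra must be positive-mode, centroided, with precursor m/z ≤ 1,000 Da.
An undefined accuracy estimate never fails the accuracy check on its own,
since there is nothing to compare.

## LSH

Binned vectors use half-open equal-width bins; the upper range boundary is
excluded. The hash bit is 1 when the hyperplane dot product is ≥ 0 (zero
counts as 1, per the defining ≥ condition). Vectors are not normalized before
hashing — the sign of a dot product is scale-free. Presets: `gems-dedup`
(64 hyperplanes, used for deduplication) and `gems-subset` (30 hyperplanes,
used for subset construction); both use 1 Da bins over [0, 1000) Da.
Cluster capping samples uniformly without replacement under the invocation
seed. Clustering quality metrics (mean intra-cluster modified cosine via
matchms, mean per-cluster precursor m/z standard deviation, cluster-count
fraction) are computed on demand.

## Murcko histograms

Rings are the SSSR rings of the Murcko scaffold with more than 3 atoms; a
fused system counts per constituent ring. For each ring, r accumulates half
the shared-atom count with every other ring and is floored once at the end —
so ortho-fused neighbors contribute 1, spiro junctions contribute ½ and a
lone spiro neighbor floors to 0. A literal set intersection of ring
atoms with linker atoms when computing l is always empty (linkers are
non-ring by definition); we instead count linker atoms *adjacent* to the ring, per
the stated meaning ("the number of adjacent linkers") and the worked
diphenylmethane example. The subhistogram relation uses the k = 4, m = 5 defaults.

The initial fold assignment before relocation is an open choice; ours groups molecules by
identical histogram, assigns groups to validation in seeded random order
until the target fraction is reached, then runs the relocation pass
group-wise until a fixed point. This makes the relation check linear in the
number of distinct histograms and guarantees zero related cross-fold pairs.

## Encoder

The frequency grid has a low block of reciprocals of the integers
m_max … 1 and a high block of reciprocals of multiples of m_min. The high block is designed to
end at 1/m_min while holding 5,000 entries at m_min = 10⁻⁴ — a unit-stride
enumeration of the multiples would give 10,000 — so we enumerate multiples k = 1, 1 + s, 1 + 2s, …
with stride s = 2 by default, which satisfies both. The summation prefix of the
attention-bias term (how many feature components enter the sum) defaults
to all 2B components and the prefix is configurable. The bias is an
unlearned sum shared across heads, computed once per input.

FFN widths are free parameters: the Fourier branch uses 4 layers with hidden
width 2·d_m (deeper than two layers helps; the width is ours), the raw
pair branch one hidden layer of width d_p. Transformer blocks are pre-norm,
bias-free, ReLU, 8 heads × 7 layers at full scale; layer norms carry a gain
only. With the full default configuration the parameter count lands at
~1.5 × 10⁸ — on the order of the hundred-million-parameter regime this
architecture targets at full scale. Attention masks exclude
padded columns as keys; padded positions are excluded from every loss.
Desk-scale tests use a d = 64, 2-layer configuration with a coarser grid
(m_min = 0.01) — problem sizes chosen so the whole stack, including three
seeded 500-step training runs, executes in minutes on one CPU.

The network runs on a tape-based reverse-mode autodiff engine over numpy
written for this package (the surrounding ecosystem here is
framework-free); every op is validated against central finite differences.
Optimization is Adam with default moments; desk-scale defaults are learning
rate 3 × 10⁻⁴, batch 16–64 pairs, constant schedule — all configurable.

## Pretraining

Masking draws round(0.3·n) peaks per spectrum by successive
intensity-proportional draws with renormalization; the precursor token is
never a candidate; masked m/z entries become −1.0 and flow through the
Fourier features as-is. Mass labels are half-open equal-width bins over
(0, 1000) Da. The masked-modeling loss sums cross-entropy over the masked peaks of
a spectrum and averages over the two spectra of a pair; batches reduce by
the mean over pairs. Because the summed form scales with the masked-peak
count, the loss trace also records the per-masked-peak cross-entropy, which
is the quantity commensurate with the uniform baseline ln c (the two
coincide when exactly one peak is masked per spectrum). Retention-order
labels are 1 when the second spectrum of the pair elutes later; pairs are
drawn uniformly within one run.

Linear probing trains one linear layer + sigmoid with BCE on frozen
embeddings by full-batch gradient descent and reports the best validation
recall within the epoch budget with its matching precision; bits without
positive validation examples are excluded from the averages. In the
synthetic setting the probing targets are the generator's ground-truth
fragment-membership bits — the full fragment set of the generating
molecule, including fragments not observed in that particular replicate.
This is deliberate: each replicate observes a random subset of its
molecule's fragments, so an untrained encoder (a random feature map of the
observed peaks) cannot linearly reach the unobserved bits, while
masked-peak training teaches exactly the co-occurrence structure needed to
complete them. The corpus uses 300 molecules so that molecule diversity
exceeds the random-feature capacity of the tiny embedding; with few
molecules a linear probe on random features already saturates and the
comparison measures nothing.

## Fine-tuning

A triplet hinge written as max{cos(z, z⁺) − cos(z, z⁻) + Δ, 0} would
penalize closeness to the positive — the opposite of the contrastive
intent — so we implement the intent-consistent form
max{cos(z, z⁻) − cos(z, z⁺) + Δ, 0}. The fingerprint objective is stated as a similarity; we minimize 1 − cos
so that lower is better. Cosines use an ε = 10⁻⁸
denominator clamp. The 11-property panel is configurable; the default panel is
QED, heavy-atom count, Bertz complexity, molecular weight, logP, TPSA,
H-bond donors/acceptors, rotatable bonds, ring count, and fraction sp³
carbons — synthetic accessibility is omitted because its reference
implementation is not importable from the packaged RDKit, and heavy-atom
count is used instead. Property scaling statistics
come from the training fold only; a constant property raises an error
naming it. Early stopping halts when the validation loss has not improved
for a configurable patience (3 epochs by default) and restores the
best-validation weights. Fold pairs are checked for Murcko-histogram
relatedness before training and leakage aborts.

## Atlas

Neighbor search is exact (scikit-learn, cosine metric, brute algorithm),
which trivially meets the brute-force-agreement contract at the scales this
package targets; approximate search is an optimization, not part of the
method's semantics. Collapsing iterates nodes by descending degree with
index tie-breaks; a BFS candidate joins only if both the traversed edge
similarity and its similarity to the start node reach the threshold
(0.9 by default). Rebuilding after collapse uses the representatives' own
embeddings, not centroids. Blank-run exclusion matches the marker
substrings (blank, no_inj, noinj, empty, solvent, wash) case-insensitively.
Path statistics report BFS hop counts on the undirected view and, among
shortest paths, the best bottleneck (maximum over paths of the minimum edge
similarity), via a layered search that keeps the best bottleneck per node
and hop count.

## Synthetic data

The run generator emulates: interleaved MS1/MS2 acquisition with strictly
increasing retention times; MS1 base peaks at a fixed species mass with
Gaussian m/z jitter (driving the accuracy estimator); MS2 spectra from a
fragment grammar — each molecule is a fixed subset of a 50-mass vocabulary,
each replicate observes a random sub-subset (≥ 4 fragments, keep
probability 0.65) with deterministic per-molecule intensity profiles, one
water neutral-loss peak, and uniform noise peaks at intensities below the
10th percentile of signal; precursor masses shared across isobar groups so
the precursor token alone never identifies a molecule; and stick, profile,
or thresholded peak rendering whose shapes are constructed to be classified
correctly by the type estimator (a dominant base peak keeps the
half-maximum window inside a single rendered shape). The library generator
emits real molecules (scaffold families decorated with structural-isomer
substituent pairs, so every molecule has a 0 Da-difference decoy), with
replicate spectra derived deterministically from Morgan fingerprint bits,
RDKit-computed property panels, and an exactly allocated fluorinated
fraction.

What the generators do **not** emulate: physical CID fragmentation,
isotope patterns, adduct chemistry beyond a constant shift, chimeric
spectra, detector saturation, or realistic intensity noise. Tests passing
on this data demonstrate that the algorithms implement their definitions
and that the learning signal the objectives target is recoverable when it
is present — not that a full-scale model reproduces benchmark numbers on real
repositories, which require licensed spectral libraries and GPU-scale
training and are out of scope here.

## Numerical notes

Spectrum matrices break top-n intensity ties toward lower m/z and order
retained peaks by ascending m/z after the precursor column (the encoder is
permutation-equivariant; the ordering only pins down reproducibility).
The tensor store round-trips finite values bit-exactly (float64
throughout). Undefined metadata is NaN in storage and `None` in memory.
Probabilities inside BCE-style losses are clamped at machine epsilon. All
stochastic components take explicit seeds or `numpy.random.Generator`
instances; the CLI funnels one seed per invocation and logs it in the run
manifest.
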