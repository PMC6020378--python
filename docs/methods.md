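# Methods

## Representation

A guide window is 23 nt: protospacer positions 1–20 (5′→3′) and the NGG
PAM at 21–23. The window is encoded as a 23×8 matrix with a fixed
channel order — A, C, G, T (one-hot), then CTCF, DNase, H3K4me3 (binary
per-position peak overlap) and RRBS (methylation beta in [0, 1],
continuous, 0 where uncovered). Coordinates are 0-based half-open;
minus-strand guides store the protospacer-strand sequence 5′→3′ and
their epigenetic vectors are reported in protospacer orientation.
Per-position (rather than per-window) epigenetic values keep the
"image" framing of the encoding; since real peaks are much wider than
23 nt the two coincide in practice. Ambiguity codes are rejected, not
imputed, and RRBS betas are kept continuous rather than binarized.

## Label construction

Classification labels binarize the measured log-fold-change knockout
efficacy at a cutoff of 1, boundary inclusive. Regression labels are
integrated across experiments with

    y_norm = y_ij − (m_row + m_column + m_all) / 3,

all three means over observed entries only (rows and columns with no
observation are rejected by name), followed by rank normalization
`(rank − 0.5)/n` with average ranks for ties. Equal weights (1/3) are
used for the three means. Note the subtraction removes only a third of
each additive row/column effect per entry, so the normalization is a
shrinkage step, not an exact two-way centering; with missing data,
very large experiment offsets would partially leak into guide-level
summaries.

Augmentation exploits the tolerance of cleavage efficacy to mismatches
at the two PAM-distal positions: each seed emits the 3×3 = 9 variants
with exactly one substitution at position 1 and one at position 2,
inheriting labels and epigenetic profile. An `include_singles` option
adds the 6 single-substitution variants. Output is deduplicated on
(sequence, cell type), first occurrence wins. All split schemes operate
on seed families and purge any residual train/test sequence overlap, so
augmented siblings of a held-out seed can never leak into training.

## Off-target candidate space

Candidate loci carry a canonical GG at PAM positions 22–23 on the
protospacer strand (no NAG); mismatch distance is counted over
protospacer positions 1–20 only, with the PAM's variable nucleotide
free; the budget is ≤6 mismatches. The scan is a vectorized naive pass
over both strands (plus strand: G at i+21, i+22; minus strand: C at i,
i+1, sequence reported as the reverse complement); windows overlapping
an N are skipped and counted. The implementation is held equal to a
character-by-character brute-force oracle in the test suite, for every
mismatch budget 0–6, on a seeded 100-kb genome. DNA/RNA bulges are out
of scope.

## Models

All models are built from one convolutional encoder family over the
23×8 input: three same-padded conv blocks (kernel 3; channels
32→64→64; strides 1, 2, 2; batch normalization + ReLU), giving a 6×64
latent map. The networks run on an in-package deterministic NumPy core
with full backpropagation, including gradients with respect to the
input (needed for activation maximization); given (config, seed),
training is bit-reproducible.

**Pretraining.** A denoising autoencoder corrupts each input (each
position's nucleotide one-hot replaced by a uniformly random one-hot
with probability 0.05 by default; Gaussian noise σ=0.1 on epigenetic
channels, clipped to [0, 1]) and reconstructs the clean input under MSE
through a mirrored upsampling decoder. The trained encoder — the
*parent network* — initializes every supervised model and fine-tunes at
`lr_parent` = 1e-4, ten-fold below the head's 1e-3 (or stays frozen for
ablations). Note that denoising can beat the corruption it sees only on
structured input: the synthetic unlabeled corpus therefore carries
position-specific base-composition biases (Dirichlet-distributed
per-position frequencies), emulating the strong compositional structure
of genome-wide guide populations; on uniform random sequence the
identity map is already the optimal denoiser.

**On-target head.** Two conv blocks, then a flattened (position-aware)
readout into a dense output — softmax for classification, identity for
regression. A global-average-pooling readout is available
(`readout="global_avg"`) but is not the default: a translation-invariant
pool cannot represent the position-specific determinants (positional
saliency, substitution zones) this framework exists to recover. The
model also carries a linear shortcut from the flattened input to the
output: position-specific nucleotide and chromatin effects are largely
additive, and the explicit low-capacity linear path generalizes from
small, noisily labeled sets far better than the conv path alone.
Training uses mixup (α=1) and label smoothing 0.1 — with ~2k
Bernoulli-noisy labels an unregularized net memorizes to training AUC
1.0 while held-out AUC stalls ~0.08 below the generating rule's
ceiling — plus decoupled weight decay 0.05, and averages a 3-member
ensemble trained from distinct initialization seeds.

**Off-target pair model.** The guide and the candidate site are encoded
independently as two 23×8 parts; two parent copies (fine-tuned
separately, hence diverging into distinct branch encoders) embed the
parts, the latent maps are concatenated channel-wise, and a conv head
scores the pair. The pair model's linear shortcut reads the
*elementwise product* of the two parts: for one-hot channels the
product marks per-position guide/site agreement, so the mismatch
indicator basis — the dominant determinant of cleavage at unintended
loci — is linearly readable. Mixup is off for pairs (convex mixing
destroys the exact-equality structure the label depends on).

Training is staged (`warmup_frac` = 0.75): the shortcut and a
zero-initialized output layer first learn with branch encoders and conv
head frozen; then everything fine-tunes jointly with convolutional
parameters at `lr_parent`. The staging addresses a failure mode
specific to bootstrap-balanced training with very few unique positives:
replicated into every balanced batch, they are memorized by an
unconstrained high-capacity pathway within an epoch, the loss
saturates, and the general mismatch rule is never learned.

**Imbalance.** Detected off-target sites are ~1 per 250 candidate loci.
Every training batch is bootstrap-balanced: the majority class is
shuffled and partitioned across an epoch (one epoch = one pass over the
majority; a trailing chunk smaller than half a batch is dropped so
every batch is exactly half-and-half), the minority class resampled
with replacement. With equal class counts both classes are partitioned
and each sample appears exactly once per epoch.

## Interpretation

**Saliency.** Activation maximization optimizes a synthetic input g
(nucleotide blocks on the probability simplex, epigenetic channels in
[0, 1]) by projected gradient ascent on `S_c(g) − λ‖g‖²` (uniform
initialization, 500 iterations, step 0.1, λ=1e-3, Euclidean simplex
projection, backtracking so the penalized objective never decreases).
For a two-class softmax the class score is the logit margin: only the
margin is identifiable, and evidence encoded by lowering the opposing
logit would be invisible to a single-logit gradient.

**Substitution maps.** For background pairs, position p and site base
Y, the effect is `score(site with Y at p) − score(matched site with the
guide's base at p)`, binned by guide base X into a 20 × (4×4) grid with
identity cells fixed at 0; the averaged map takes the per-position mean
over the 12 mismatch cells. Cells are filtered by a two-sided Fisher
exact test on (substitution present/absent) × (detected/not) counts,
α=0.05, no multiplicity correction by default (a Benjamini–Hochberg
option exists); non-significant cells render as hyphens. The rX:dY
duplex notation keeps the guide base as RNA and names the Watson–Crick
complement of the substituted site base (G→C ↔ rG:dG, G→T ↔ rG:dA).

**Zones.** The averaged map partitions positions 1–20 into contiguous
preference (> τ), undetermined, and avoiding (< −τ) ranges; τ defaults
to half the map's standard deviation.

## Profile summaries and metrics

The anti-OT score is `S = ln(1 + e^(−Σ OT_i))/ln 2` over all candidate
probabilities: S ∈ (0, 1], equals 1 exactly when ΣOT_i = 0, and is
strictly decreasing in every entry, so higher means lower genome-wide
off-target propensity. (The variant with a positive exponent is ≥ 1 and
increasing — inconsistent with both the stated range and ordering; it
remains available behind `literal=True` for comparison.) Severity bands
default to thresholds (1/3, 2/3) with green/yellow/red colors, exported
in coordinate order for circular-track display. Metrics: ROC-AUC
(midrank ties), step-integrated PR-AUC, Spearman, and a weighted
Spearman (weighted Pearson on midranks with weights proportional to the
rank of the measured cleavage frequency, summing to 1 — errors on the
strongest true off-targets cost the most; with equal weights it reduces
exactly to Spearman).

## Synthetic studies: what they do and do not show

Planted rules are linear-logistic. On-target: a rule favoring one base
at each of 6 random protospacer positions (favored +3.0, alternatives
−1.0, zero per-position mean), epigenetic channel weights ±0.5,
Bernoulli labels through the logistic link with 2% label flips; rule
scores are mean-centered so classes balance. These defaults make the
rule recoverable with headroom (its Bayes ROC-AUC ≈ 0.90–0.93): a
recovery fixture must plant a recoverable signal. Off-target: mismatch
positions drawn per pair (0–6 mismatches, weighted toward high counts
as in real candidate sets), detection probability
`sigmoid(c + Σ effects)` with planted effects +2.0 at positions 1–3, 0
at 4–15, −5.0 at 16–20 and c bisection-calibrated to the target
detection rate. The strong effects mirror the empirical regime:
detected off-target sites are highly separable from background by
mismatch position and count alone. Efficacy matrices are additive
(guide effect + experiment offset + noise) with a missingness mask that
always leaves each row and column one observation.

Study sizes used by the acceptance checks: 2k train / 500 held-out
guides (on-target), 20k pairs at 1:250 (off-target discrimination), 5k
pairs × 5 seeds (balancing ablation), 200 labels × 5 seeds with a
3k-window pretraining corpus (pretraining gain), 2k guides × 5 seeds
(saliency recovery), and 10k pairs at a 1:50 detection rate × 5 seeds
for zone recovery — at 1:250 a 10k-pair study holds only ~40 positives
and per-position effect estimates are noisier than any threshold rule
can tolerate, and the zone question is about positional structure, not
imbalance handling.

Passing these checks shows the pipeline recovers planted additive
structure under realistic imbalance and noise at desk scale. It does
not show performance on real screens: the generators omit chromatin
biology, assay-specific detection sensitivities, sequence-context
effects beyond single positions, and the scale of genome-wide
pretraining corpora. Qualitative observations reported for models
trained on real data — cytosine favored at the PAM's variable
nucleotide, thymine disfavored PAM-proximally, cytosine preference at
position 18, open-chromatin preference, methylation avoidance — are
properties of such models, not assertions tested here.

## Numerical and design notes

* Everything runs in float64; training, corruption, batching and
  generators derive all randomness from explicit integer seeds.
* Checkpoints (.npz) store architecture config, seed and a data-schema
  hash of the channel contract; loading under a different schema is
  refused rather than silently mis-scoring.
* Degenerate inputs are rejected early with the offender named:
  non-ACGT bases (with position), empty matrix rows/columns (by label),
  single-class training sets, invalid thresholds, truncated
  checkpoints.
* Stratified splitting takes whole seed families until the per-stratum
  test quota is met, so realized fractions are exact only up to family
  granularity; ties in rank normalization take average ranks.
* Known limitations: the naive scan is quadratic-ish in genome size ×
  guides (fine at desk scale, no FM-index); the NumPy core is
  single-threaded; bigWig tracks are not read (BED/bedGraph only); no
  NAG PAMs; no bulges.
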