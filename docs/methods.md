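# Methods

## Problem

Candidate detectors for pulmonary nodules on chest CT produce many spurious
hits: vessels seen end-on, pleural thickening and other smooth-margined
densities mimic the bright quasi-spherical appearance of a true nodule.
This package implements the *false-positive reduction* step: given a CT
volume and a list of candidate world coordinates, classify each candidate
as nodule vs non-nodule and report detection quality as a free-response ROC
(FROC) curve over per-scan false-positive rates.  True nodules differ from
their mimics mainly at the margin — coronal radiation and needle-like
protrusions (spiculation) against smooth boundaries — which is a local,
multi-scale shape cue, hence the design below.

## Model

Three fixed volumetric CNNs operate on co-centred cubes of one candidate:

| network | input | layers (rows incl. input and GAP) |
|---------|-------|------------------------------------|
| CNN-1   | 32^3  | conv 5^3 (20) -> pool -> conv 5^3 (50) -> GAP (5 rows) |
| CNN-2   | 64^3  | conv 5^3 (20) -> pool -> conv 5^3 (50) -> pool -> conv 4^3 (100) -> GAP (7 rows) |
| CNN-3   | 96^3  | conv 5^3 (20) -> pool -> conv 5^3 (50) -> pool -> conv 5^3 (100) -> pool -> conv 5^3 (100) -> GAP (9 rows) |

All convolutions are valid (no padding), stride 1; all poolings are 2^3
max-pool with stride 2 in *ceil mode*, so a trailing odd window is pooled
rather than dropped (this is forced by the 17 -> 9 pooling in CNN-3; even
edges are unaffected).  The published layer table prints CNN-1's first
convolution output as 32^3, which is impossible for a valid 5^3 kernel on a
32^3 input and contradicts the next row (pool output 14 requires input 28);
we use 28 and treat the printed value as a typo.  The table ends at global
average pooling with no classifier; we append the minimal two-class head —
a single linear unit on the pooled channel means followed by a sigmoid.
(Whether the original head was a 2-way softmax or a 1-unit sigmoid is not
determinable; the two are equivalent up to parametrization.)

**RT-ReLU.**  Every convolution is followed by a randomly translated ReLU:
during training `y_i = max(x_i + a_i, 0)` with fresh `a_i ~ N(0, sigma^2)`
drawn per activation element per forward pass; at test time `a_i = 0`,
reducing to the plain ReLU.  The jitter decentralizes the pre-activation
distribution and acts as a regularizer.  `sigma` defaults to 0.05 on
normalized activations (the original value is not published); per-element
sampling is the strongest reading of the construction and is what we
implement.

**Training.**  Weighted binary cross-entropy minimized by plain SGD
(momentum 0): each sample's loss term is multiplied by its boosting weight,
and minibatch gradients are scaled by `m/|B|` so uniform weights `1/m`
reduce to the ordinary batch mean.  Full-profile defaults follow the
published recipe: learning rate 0.001, weight decay 0.0005, 30 epochs.

**Boosting.**  The three networks are fused by sequential AdaBoost with one
round per network, in the order CNN-1 (32) -> CNN-2 (64) -> CNN-3 (96):

1. initialize `w_i = 1/m`;
2. train member k on its scale under the current distribution; compute its
   weighted training error `e_k` from *test-mode* predictions,
   `alpha_k = 1/2 ln((1-e_k)/e_k)`;
3. reweight `w_i <- w_i exp(-alpha_k y_i G_k(x_i)) / Z_k` and continue.

Weights enter the CNN loss multiplicatively (not by resampling): this is
deterministic and matches "training on the reweighted set" without
committing to a sampler; weighted-bootstrap resampling would be an easy
alternative but is not needed.  `e_k` is clipped to `[1e-10, 1-1e-10]` to
keep `alpha` finite when a member is perfect; a member with `e_k >= 0.5` is
kept with its non-positive `alpha` and a warning.  The fused hard decision
is `sign(sum_k alpha_k G_k(x))` with the exact tie mapped to +1.  Because
FROC needs a continuous score and the hard vote provides only a sign, we
also expose the normalized soft margin
`s(x) = sum_k alpha_k (2 p_k(x) - 1) / sum_k |alpha_k|` in [-1, 1].  Note
the two are *not* interchangeable: the score weights members by margin
magnitude, the hard vote does not, and a high-coefficient member with a
slim margin can flip one but not the other.  They provably agree when the
member votes are unanimous, which is what the tests assert; the FROC
analysis uses the soft score throughout.

## Preprocessing

Per scan: intensities are clipped to [-1000, 400] HU (air to dense soft
tissue) and mapped to [0, 1]; each axial slice is then sharpened with an
unsharp mask `y = x + lambda * z`, where `z` is the 4-neighbour Laplacian
high-pass `z(n,m) = 4x(n,m) - x(n-1,m) - x(n+1,m) - x(n,m-1) - x(n,m+1)`
with replicate borders (so constant slices are exact fixed points).
`lambda` defaults to 1.0, the conventional unit gain; the original scaling
factor is unpublished, and the published ablation is itself ambiguous (the
sharpened input scored *lower* on average sensitivity than the original in
the source's own table while the text calls it beneficial), so nothing
downstream depends on its value.  The order normalize -> enhance -> crop is
fixed so that the enhancement operates on resolution-independent
intensities.

Each candidate yields a 96^3 crop centred on its rounded voxel index
(rounding half away from zero, for deterministic hit tests); regions
outside the volume are filled with 0, the normalized air level.  The crop
is downsampled to 64^3 and 32^3 by trilinear interpolation over the *same
field of view* — reading "down-sampled" literally, rather than centre
cropping — so the three scales see the same anatomy at decreasing
resolution.  Optional augmentation adds the three axial-plane rotations
(90/180/270 degrees about z, the chest-CT convention; the rotation axis is
not stated in the source).  Annotated nodules are filtered to the closed
diameter interval [5, 30] mm.

## Evaluation

A candidate hits an annotation when its world distance to the centre is at
most one nodule radius (the LUNA16 convention; the matching rule is
otherwise unpublished).  Each annotation is claimed once by its
highest-scoring matching candidate; additional candidates inside a claimed
annotation are ignored — neither TP nor FP.  Sweeping the decision-score
threshold over all candidate scores yields the FROC curve; sensitivities
are read at 0.125, 0.25, 0.5, 1, 2, 4, 8 FPs/scan by the step-function
convention (best sensitivity achieved at or below the operating point,
zero if none qualifies — deterministic and conservative, no interpolation)
and averaged over the seven points (the CPM-style mean; this is the only
reading under which the published seven operating sensitivities reproduce
the published average of 0.876).

## Synthetic phantoms

The generator emulates the statistical structure the classifier exploits,
not anatomy.  Per scan (defaults in parentheses): a lung-level background
of -900 HU plus a smooth low-frequency tissue field (Gaussian-filtered
noise, sigma 8 voxels, 50 HU SD) and i.i.d. Gaussian noise (20 HU SD);
2-5 nodules with diameters uniform on the inclusion range [5, 30] mm,
rendered as mildly anisotropic ellipsoids of tissue intensity (-100 to
+50 HU) whose boundaries are roughened by needle-like radial lobes
`max(0, d.u_j)^8` scaled by the spiculation parameter (0.6) — boundary
roughness, measured as surface area over volume^(2/3), increases
monotonically with it; and matched-brightness confounders: smooth spheres
(5-20 mm) and vessel-like tubes (radius 1.5-3.5 mm).  Volumes are 64 x 128
x 128 voxels at (1.25, 0.9, 0.9) mm spacing — slice thickness under the
2.5 mm inclusion limit, small enough for CPU-scale experiments.  Candidate
lists contain one positive per nodule, jittered uniformly within half the
nodule radius, and exactly 11 negatives per scan (confounder centres plus
random background points, rejected within one radius of any nodule).
Scans — never candidates — are split 70/10/20 into train/validation/test;
the slightly larger test share (the published split is roughly 82/9/9)
stabilizes the per-scan FROC read-outs at 40-scan scale.

What the phantoms do **not** model: airway/vessel trees and lobar anatomy,
partial-volume and reconstruction-kernel effects, scanner noise spectra,
ground-glass and subsolid textures, pleural attachment.  Passing tests on
phantoms therefore demonstrate that the pipeline's mechanics (enhancement,
multi-scale extraction, boosting, FROC) behave as specified and that the
networks can exploit margin/size/shape contrast; they do not certify
clinical-scale sensitivity.

## Desk-scale ("tiny") profile

Training the published architectures is a GPU-scale job (the first
convolution of CNN-3 alone is ~0.5 G multiply-accumulates per sample).  For
CPU-scale runs the package provides a tiny profile that keeps the
conv-pool alternation and the three input scales but uses 3^3 kernels,
first-convolution strides of 1/2/3 for CNN-1/2/3, and channel widths
(5, 12, 25) — about 10 M multiply-accumulates per sample per network.  The
desk-scale learning rate default is 0.05 (the full-scale 0.001 is tuned to
~300k samples and 30 epochs; with ~400 samples and 3 epochs the step size
must be larger to move at all).  Architecture-shape guarantees are asserted
against the full profile only; the tiny profile is for end-to-end behaviour,
not shape fidelity.  Networks, backprop and SGD are implemented directly on
NumPy (im2col lowering to BLAS matrix products), which is entirely adequate
at these sizes.

End-to-end experiments (the acceptance script and the ensemble-vs-members
test) use 40 phantom scans (~580 candidates), the tiny profile, 3 epochs,
batch size 8.  At this scale CNN-1 — whose 32^3 cube covers an ~86 mm field
of view at ~2.7 mm/voxel — cannot resolve spiculation and typically falls
back on size/brightness cues; the boosting sequence then concentrates
weight on its mistakes, and the high-resolution CNN-3 dominates the fused
coefficient.  The fused score is expected to match or exceed the best
single member's sensitivity at 1 FP/scan.

## Numerical choices

- Engine tensors are float32; boosting arithmetic is float64.
- Voxel rounding is half-away-from-zero (documented; `np.round`'s
  half-to-even would make hit tests depend on parity).
- Max-pool ceil mode pads with -inf; gradient routes to the argmax element.
- The weighted error is clipped before the log; `classifier_coefficient`
  itself rejects 0 and 1.
- Degenerate inputs: single-class training sets warn and proceed; an empty
  candidate list yields the single FROC point (0, 0); FROC requires at
  least one annotation.
- Determinism: every stochastic component takes a seed or a Generator;
  phantom scans are deterministic in (seed, scan index); pipeline stages
  derive their seeds from the root seed.

## Known limitations

- The tiny profile's strided first convolutions change receptive-field
  geometry relative to the published networks; conclusions about the
  *relative* merits of the three scales at desk scale should be drawn
  cautiously.
- Per-element RT-ReLU offset sampling is one reading of the construction;
  per-channel sampling would be cheaper and is not implemented.
- The unsharp-mask scaling factor and RT-ReLU sigma are unpublished;
  both are exposed as configuration with conventional defaults.
- Boosting is fixed at K = 3 rounds (one per network); the framework in
  `ensemble.boost` accepts arbitrary member trainers but the fused model
  of record is the three-member one.
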