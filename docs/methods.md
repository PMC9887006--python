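# Methods

## The chemical model

All computation in `acidbase` reduces to mixing fully dissociated strong
acids (HX) and strong bases (YOH) in water. Three reactions govern the
system: acid dissociation, base dissociation, and neutralization
(H3O+ + OH- -> 2 H2O). Because neutralization couples the two species,
only the *excess* of protons over hydroxide — together with water
autoionization — determines the pH of a mixture.

A `Solution` keeps exact books on three additive quantities: volume
(uL), strong-acid protons (umol), and strong-base hydroxide (umol).
Units are fixed so that umol/uL equals mol/L, eliminating conversion
steps. With the excess concentration `D = (acid - base) / volume`,
charge balance plus `Kw = [H+][OH-] = 1e-14` (25 C) gives the quadratic

    [H+]^2 - D [H+] - Kw = 0,   pH = -log10 of the positive root.

We solve it in closed form. On the basic side (`D < 0`) the naive root
`(D + sqrt(D^2 + 4 Kw))/2` cancels catastrophically, so the conjugate
form `2 Kw / (sqrt(D^2 + 4 Kw) - D)` is used there; the two agree to
the last few ulps at `D = 0` and the tests pin the solver against a
brute-force numeric root to 1e-10 pH units. Assumptions: ideal
solutions (unit activity coefficients), complete dissociation, fixed
temperature. Weak acids, buffers, and indicator equilibria are out of
scope; the pH indicator used for readout is modeled purely as a sign
threshold at pH 7.

## Dual-rail encoding

One signed value is a pair of solutions: the pH rail and its
complement. (acid, base) encodes +1/TRUE, (base, acid) encodes
-1/FALSE. Negation is a zero-cost rail swap; a neutral pair (both at
pH 7) is the undefined midpoint, which is why level 0 is unencodable.

Magnitudes use a maximum encoded value `L` (1 for binary, 4 for the
3-bit scheme with levels {-4..-1, 1..4}). Diluting a rail to
concentration `stock * |v| / L` realizes level `v`. Two equivalent
dilution recipes are provided:

* **eq5** — transfer one full unit of reagent (default 2.4 uL) and add
  `unit * (L/|v|) - unit` of water. Faithful to the protocol's stated
  dilution formula, but rail volume grows to `unit * L/|v|` (9.6 uL at
  `|v| = 1, L = 4`), which exceeds the 4 uL working maximum of a
  1536-well low-dead-volume plate.
* **constant** (default for compiled runs) — transfer
  `unit * |v| / L` of reagent topped up with water to exactly one
  unit. Identical rail concentration, identical solute per pooled
  aliquot, constant rail volume that fits the plate.

Both modes yield bit-for-bit identical pooled signs; the picklist
validator flags the eq5 overflow if that mode is forced onto the small
plate.

The 8-bit-to-3-bit discretization follows the eight inclusive
intensity ranges 0:32, 33:64, ..., 225:255 mapped in order to
-4..-1, 1..4; this table never emits 0. The alternative
`round(8x/255) - 4` formula is kept behind a flag for comparison — it
can emit 0 near mid-scale and disagrees with the table at range
boundaries, so the table is authoritative. Binarization thresholds at
128 (below -> -1, at or above -> +1).

## Majority logic

Mixing an odd number of equal droplets computes the majority function:
the pooled excess is the mean of the input excesses, so the more
frequent sign survives. Majority plus inversion is functionally
complete. Two-input gates add a fresh constant bias droplet as the
third majority input (bias -1 for AND, +1 for OR); NAND/NOR follow
with a free output rail swap. Bias droplets use the same unit volume
and stock concentration as data inputs.

Cascaded stages attenuate: every mixing stage is a volume-weighted
mean of concentrations, so `|pH - 7|` of a majority output never
exceeds the maximum over its inputs, and signals drift toward
neutrality with depth. Circuit evaluation therefore supports signal
restoration — replacing each gate output with fresh full-strength
stock of the same sign before fan-out — and this is the default
policy; with it, chemical evaluation provably equals Boolean netlist
evaluation (tested on 200 random DAGs, all input combinations). Note
the attenuation bound is stated per gate over *its own* inputs: a weak
signal mixed with a fresh bias can legitimately come out farther from
neutral than the weak input alone.

Evaluation order is a deterministic topological sort with ties broken
by gate declaration order, so pH traces are reproducible. The netlist
dialect is one gate per line (`out = KIND(in1, in2)`, plus
`inputs`/`outputs`/`CONST` lines); it is this package's own format,
documented in `acidbase.logic`.

## Binary neural-network inference

A single dense layer with weights in {+1, -1} classifies a flattened
image (row-major, left-to-right then top-to-bottom). Chemically, each
pixel is encoded as a dual-rail pair, the weight is applied as a direct
(+1) or rail-swapped (-1) transfer, and a 200 nL aliquot from every
pixel's pH rail is pooled into the neuron's output pH well (likewise
for the complements). The pooled proton excess is exactly
proportional to `sum_i w_i x_i / L` (proportionality constant:
aliquot volume x stock concentration / L), so the noise-free output
sign equals the integer score's sign — the chemistry computes the
argument of the activation, and the indicator supplies the
nonlinearity. Neurons have no bias term: the protocol transfers only
pixel-derived solutions.

Readout modes:

* **indicator** — only each neuron's sign is visible. Classification
  is the unique positive neuron; if none or several neurons are
  positive the result is UNDECIDED. A sample *matches* the in-silico
  network when the sign pattern is one-hot positive at the in-silico
  argmax; a sample whose scores all share one sign can be classified
  correctly in silico yet cannot match, which is the dominant failure
  mode of indicator readout. UNDECIDED counts as a non-match and as
  an incorrect classification.
* **ph** — the output wells are measured and the most acidic pH rail
  wins; this resolves every case the indicator cannot.

Softmax vs sigmoid activation is irrelevant at inference (both are
monotone), so in-silico scores are raw integers; argmax ties break to
the lowest neuron index and are flagged.

## Training

Weights are trained with straight-through-estimator binarization:
real-valued latent weights clipped to [-1, 1], forward pass through
`sign(latent)` (exact zeros export as +1 for determinism), gradients
passed through where `|latent| <= 1`. Defaults: per-neuron sigmoid +
binary cross-entropy against one-vs-rest targets, learning rate 0.001,
30 epochs, mini-batch 64, plain SGD on the mean batch gradient, 85/15
train/validation split. A softmax + cross-entropy mode is available
behind a flag. The optimizer and the latent initialization
(uniform on [-0.05, 0.05]) are this package's choices; plain SGD is
the closest match to the binarization recipe the method builds on.
The estimator (`BinaryDenseClassifier`) follows the scikit-learn API
and composes with its pipelines and model selection.

## Liquid-handler compilation and simulation

Plates: a 384-well polypropylene source plate (10-60 uL working
volume) laid out as rows of acid, base, and water stocks at 50 uL and
100 mM, and a 1536-well low-dead-volume destination plate (1-4 uL).
Encoding writes, per neuron and per pixel in flatten order, two
consecutive wells whose acid/base order is set by
`sign(pixel) * weight`; water transfers for sub-maximal levels follow
as a second phase. Pooling scans each neuron's block from the first
well, skipping every second well (pH rails at even offsets), into the
neuron's output pair on the source plate. Stock wells are consumed in
rotation, never below the plate's minimum fill.

The simulator replays transfers in order through the exact mixing
chemistry. A transfer out of a declared stock well moves solute at the
well's fixed concentration (withdrawing from a uniform stock cannot
change its concentration), and all volumes are carried in nL and
converted once through a shared helper — together these make the
simulated pipeline reproduce the directly computed chemical neuron
bit-for-bit, which the tests assert as field equality, not approximate
agreement.

Volume noise multiplies each transferred volume by `1 + eps` with
`eps ~ U[-0.10, +0.10]` by default (the instrument spec states only a
maximum deviation; a truncated-Gaussian mode is provided).
Seed-reproducible. For binary inputs the worst-case pooled
perturbation is bounded by `0.1 * pixels` score units, so no sign can
flip while `|score| > 0.1 * pixels`; the tests verify zero flips over
1000 seeded trials for binary and 3-bit inputs under that margin.
Droplet granularity defaults to 25 nL (typical for the instrument
class; configurable) — every protocol volume (2.4 uL, 200 nL) is a
multiple. The picklist CSV dialect is
`Source Plate Name,Source Well,Destination Plate Name,Destination
Well,Transfer Volume` with volumes in nL written via `repr`, so
write/read round trips are bit-exact.

## Synthetic data

The generator (`acidbase.data_io.synth_dataset`) emulates small
digit-like images with three class templates on an `s x s` grid
(default 8): a hollow ring ("0"), a center vertical bar ("1"), and an
S-curve ("2"). Templates are +/-1 grids mapped to intensities 0/255;
each pixel is independently inverted with probability `flip_prob`
(default 0.05) before binarization or 3-bit discretization. Default
dataset sizes are 100-200 samples per class. At zero noise the classes
are linearly separable by a +/-1 weight vector, and `planted_model`
constructs that vector (tie pixels are sign-balanced so no bias term
is needed), giving an exact end-to-end oracle.

What the generator does *not* emulate: handwriting variability,
grayscale texture, correlated pixel noise, and class imbalance. Tests
passing on it demonstrate the correctness of the encoding, logic,
pooling, simulation, and training machinery — not classifier
performance on real handwritten digits, which depends on the deposited
datasets and trained weight tables.

## Numerical choices and degenerate inputs

* NEUTRAL band: `|pH - 7| <= 1e-9` by default, configurable; strict
  mode escalates NEUTRAL signals to errors.
* An even number of majority inputs, level 0, weight outside {+1, -1},
  ragged grids, malformed same-sign dual-rail pairs, empty mixes, and
  transfers from empty wells are all rejected with diagnostics.
* Gate-output restoration is per-evaluation configurable
  (`after-every-gate` | `none`).
* Problem sizes in the test-suite and acceptance runs: exhaustive gate
  and majority enumeration up to n = 9; 10,000 random neuron pairs at
  9-784 pixels; 100 simulated pipelines; 1000 noise trials; 5 training
  seeds at 400 samples each. These sizes give exact (enumerated) or
  tightly concentrated (sampled) checks while keeping a full run in
  seconds.

## Known limitations

* Strong electrolytes only; no buffering, activity, or temperature
  dependence.
* Single-layer networks; no chemical activation cascade, so deeper
  nets would need restoration hardware between layers.
* Fan-out volume accounting is handled only through restoration;
  evaporation and dead volume beyond min-fill checks are not modeled.
* The run-time of a physical experiment is hardware-dependent and out
  of scope.
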