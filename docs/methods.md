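# Methods

## Problem setting

Optical genome mapping (OGM) images long DNA molecules that carry fluorescent
labels at every occurrence of a short sequence motif (here CTTAAG, the DLE-1
recognition site, which is its own reverse complement). A molecule stretched
in a nanochannel appears as a thin horizontal strip; the observed pattern of
label positions along the strip is compared with the expected motif positions
in a reference genome to find where the molecule came from. The pipeline has
three stages: simulate (for training and evaluation), localize, align.

## Image model and the synthetic-data generator

A molecule of length L pixels is modeled as a straight segment on the center
row of a 5-row pixel strip. Label sites arise from independent per-basepair
Bernoulli trials at density 1/4096 per bp over L x 335 bp (335 bp per pixel
is the optical scale of nanochannel OGM instruments). The generator draws the
binomial site count and places that many distinct basepairs uniformly, which
is exactly the Bernoulli process conditioned on its count, then converts to
pixel units. If two sites fall in the same pixel the later one is resampled,
preserving the at-most-one-emitter-per-pixel encoding while keeping the count.

Each emitter contributes an isotropic 2D Gaussian point-spread function of
sigma = 1.5 px, peak amplitude A, centered on the middle row; contributions
sum. The PSF support is truncated at 4 sigma (relative error below 3.4e-4),
a speed/accuracy trade-off that is invisible at the operating SNR. Noise is
additive white Gaussian with standard deviation A / SNR, SNR = 2.33 by
default; this is the simplest noise model consistent with a single scalar
SNR. A Poisson-free additive model slightly understates the signal-dependent
variance of real sCMOS/EMCCD images. Optional per-image uniform multipliers
(off by default) jitter amplitude, SNR and density to emulate molecule-to-
molecule variation.

Molecule lengths are uniform over [100, 1000] px. Half-open intervals and
0-based coordinates are used throughout; an emitter at continuous position x
occupies pixel i = floor(x) with in-pixel offset x - i.

What the generator does **not** emulate: molecule bending and stretch-factor
variation along the molecule, optical aberrations and camera gain structure,
label-efficiency dropout, and background autofluorescence gradients. Passing
tests on this generator therefore demonstrate correctness of the method and
its implementation under the stated model, not performance on instrument
data.

## Localizer network and loss

The localizer is a 1D U-Net: the 5-row strip is treated as a 1D signal with
five channels. Three resolution levels with max-pooling by 2, two
convolutions (kernel 3) + ReLU per level, channel widths 12/24/48, nearest-
neighbour upsampling with skip concatenation, and a kernel-1 head emitting
two numbers per pixel through a sigmoid: occupancy probability Omega_i and
in-pixel relative position Lambda_i.

The loss per molecule is

    L = L_dice(Omega, Omega_hat) + sum_i L_bce(Omega_hat_i, Omega_i)
        + sum_i Omega_hat_i * L_bce(Lambda_hat_i, Lambda_i)

with L_dice smoothed by 1e-5 and L_bce(x, y) = -x log y - (1-x) log(1-y).
Predictions are clamped to [1e-6, 1 - 1e-6] inside the BCE so saturated
outputs stay finite. The BCE takes the ground truth as its first (target)
argument and the clamped prediction as its second; with a binary target the
reverse order is non-finite and cannot be optimized. Note the localization
term is a cross-entropy between two numbers in [0, 1]: its minimum over the
prediction sits at the target but is nonzero for interior targets (ln 2 at
0.5), which is immaterial for gradient-based training.

The network and its backward pass are implemented directly on numpy arrays
(channels-last layout; convolutions evaluated as one GEMM per kernel tap on
the padded input) with an Adam optimizer (learning rate 1e-3, the standard
choice for this family of localization networks). Weights use He
initialization; all randomness is seeded.

Training draws every batch fresh from the generator, so no image is ever
reused and overfitting to a finite training set is impossible; fresh
simulations double as validation. One molecule length is sampled per batch
(uniform over the range, rounded down to the network's length multiple of 4)
and shared by the whole batch, which avoids padding and loss masking while
leaving the length distribution across batches uniform. Full-scale defaults
are 10 000 steps at batch 256; the tested, scaled-down schedule is 3000
steps at batch 64, which trains in under ten minutes on one CPU core and
already reaches the artifact's acceptance levels (precision/recall >= 0.8 at
1 px, RMSE <= 0.5 px). Channel width 12 was likewise chosen so that the
scaled-down schedule is practical on a single core.

Inference: pixels with Omega_i >= threshold become labels at i + Lambda_i;
each run of consecutive super-threshold pixels is suppressed to its single
maximum-occupancy pixel, enforcing the one-emitter-per-pixel readout. The
default threshold is 0.4, the value that maximizes F1 on a held-out
simulated validation stream at the study conditions; at 0.5 this scaled-down
model trades recall for precision asymmetrically (precision ~0.97 vs recall
~0.76). Inputs of arbitrary length are reflect-padded to the next multiple
of 4 and the outputs cropped.

The classical baseline (`peak_finder_localize`) sums the five rows and takes
local maxima above median + 2.5 scaled-MAD with three-point parabolic
refinement. It inherently reports at most one label per diffraction-limited
spot, which is exactly the failure mode the network avoids on close pairs.

## Alignment

Query positions x (pixels) are converted to basepairs q = s x with s = 335.
The score matrix over reference sites r_i and query labels q_j is

    S[i,j] = 1 + max_{i-d <= g < i, j-d <= h < j}
             { S[g,h] - |(r_i - r_g) - (q_j - q_h)| / alpha
                      - ((i-g-1) + (j-h-1)) / beta }

with d = 5, alpha = 500 bp, beta = 10, and S[i,j] = 1 when no admissible
predecessor improves the score: any pair may start a new local alignment.
Each matched pair rewards 1, alpha penalizes stretch mismatch, beta
penalizes skipped labels. The published form of this recurrence typesets
positive-part brackets around the penalty terms; read literally they would
zero every penalty, so the linear-penalty reading consistent with the stated
meanings of alpha and beta is implemented. The best alignment is traced back
from the global maximum cell; ties resolve to the smallest index gap and the
row-major-first maximum, making results deterministic.

The inner loop is compiled with numba (O(|r| |q| d^2)). Molecules enter
nanochannels in either direction, so both the query and its mirror are
scored and the better orientation kept. Genome-wide search aligns against
every reference sequence and both orientations and also reports the
runner-up score as an uncalibrated confidence margin. The implied genomic
interval extends the outermost matched pair by the unaligned molecule
overhangs at scale s. An exhaustive enumeration oracle (feasible up to ~10
reference / ~8 query labels) provides an independent check of the DP in
tests; it is never used in the pipeline itself.

## Evaluation protocol

Ground truth by digital cropping: long parent molecules whose placement is
known exactly (here: simulated from a synthetic genome) are cropped into
random fragments; each fragment inherits the parent placement shifted by
its window offset. Fragments are localized, aligned genome-wide, and a
placement is counted correct iff it lands on the true sequence, in the
forward orientation class, with the aligned interval's midpoint within half
the fragment length of the true midpoint (closed boundary). The midpoint
criterion is robust to end effects from overhang extrapolation while still
rejecting wrong-locus placements. Success rates per fragment length carry
exact 95% Clopper-Pearson bounds (Beta-quantile form; lower bound 0 at
k = 0, upper bound 1 at k = n).

Desk-scale defaults: a 20 Mb genome in 4 chromosomes, 32 parents of 450 kb,
128 fragments per length in {25, 50, 100, 150} kb. Fragments are generated
at exact target lengths rather than binned after the fact. The same
machinery accepts label-list parents (pre-localized molecules, as in BNX
manipulation workflows) for aligner-only evaluation.

## File formats

FASTA references are read with Biopython; motif maps store every overlapping
occurrence, both strands (a single forward scan for the palindromic default
motif), skipping windows containing N. BNX 1.2/1.3 record groups are parsed
into molecule records; label lines are terminated by the molecule length on
write and positions use fixed two-decimal formatting so write -> read ->
write round-trips are bit-identical. Digital cropping deletes labels outside
a half-open window, re-bases the rest, crops per-label quality lines in
parallel, and accumulates the window offset so crops compose exactly.

## Known limitations

- The numpy network trains on CPU only and is sized accordingly; the
  architecture (depth 3, width 12) is the smallest standard U-Net satisfying
  the input/output contract, not a tuned optimum.
- The additive-Gaussian noise model and the absence of stretch variation
  make the simulation easier than instrument data; measured precision/recall
  here are upper bounds on real-data performance.
- The exact DP scans the full reference; at mammalian-genome scale a seeded
  or banded search would be needed for throughput, and is not part of the
  tested surface.
- No calibrated alignment confidence is provided, only the raw score and the
  best-minus-runner-up margin.
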