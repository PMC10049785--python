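# ogmap

Optical genome mapping (OGM) images long DNA molecules carrying fluorescent
labels at every genomic occurrence of a short motif (CTTAAG, the DLE-1 site)
and identifies each molecule by matching its observed label pattern to the
expected motif positions in a reference genome. `ogmap` implements the full
computational pipeline for researchers working with nanochannel OGM data or
developing localization/alignment methods for it:

1. **Simulator** — a generative model of labeled-molecule images: Bernoulli
   motif placement at 1 emitter per 4096 bp, 335 bp/px optical scale, 2D
   Gaussian PSF (sigma 1.5 px) on a 5-row strip, additive noise at SNR 2.33.
   It provides the infinite training stream and all evaluation fixtures.
2. **Localizer** — a 1D-convolutional U-Net that reads the strip as a
   5-channel 1D signal and outputs, per pixel, an occupancy probability
   Omega_i and a sub-pixel label position Lambda_i, trained with the
   composite loss

       L = L_dice(Omega, Omega_hat) + sum_i L_bce(Omega_hat_i, Omega_i)
           + sum_i Omega_hat_i L_bce(Lambda_hat_i, Lambda_i).

   Unlike classical peak finding it separates label pairs closer than the
   diffraction limit, which directly raises alignment success on short
   molecules. The network (and its backward pass) is implemented on plain
   numpy arrays and trains in minutes on one CPU core.
3. **Aligner** — dynamic programming over reference sites r_i and
   basepair-converted query labels q_j = s x_j (s = 335 bp/px):

       S[i,j] = 1 + max_{i-d<=g<i, j-d<=h<j} { S[g,h]
                - |(r_i-r_g) - (q_j-q_h)|/alpha - ((i-g-1)+(j-h-1))/beta }

   with d = 5, alpha = 500 bp, beta = 10; local-alignment base case,
   traceback from the maximum cell, both orientations, genome-wide best
   placement with a runner-up margin. A brute-force enumeration oracle
   cross-checks the DP in tests.
4. **Formats & evaluation** — FASTA motif-map extraction, Bionano BNX
   read/write with digital cropping of localization lists, and the
   crop-fragment protocol: cut long known-placement parents into random
   fragments, align each, and report success rate vs fragment length with
   exact 95% Clopper-Pearson bounds.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from ogmap import (SimulationConfig, LocalizerConfig, AlignmentParams,
                   build_localizer, train_localizer, localize,
                   make_training_example, match_labels)

sim = SimulationConfig()                      # 335 bp/px, 1/4096 bp, SNR 2.33
cfg = LocalizerConfig(training_steps=3000, batch_size=64, seed=7)
model, history = train_localizer(build_localizer(cfg), sim, cfg)

rng = np.random.default_rng(101)
image, truth = make_training_example(sim, rng)
query = localize(image, model)                # sub-pixel label positions (px)
print(match_labels(query.positions_px, truth.emitter_positions_px, radius=1.0))
```

A representative run prints

```
{'n_matched': 30, 'n_predicted': 31, 'n_true': 38,
 'precision': 0.968, 'recall': 0.789, 'rmse_px': 0.444}
```

meaning 30 of the 38 true labels in this molecule were recovered within
1 px (one detection was spurious) with a sub-pixel error of ~0.44 px,
i.e. ~150 bp at the 335 bp/px scale. Aggregated over 256 fresh molecules
the scaled-down model reaches precision ~0.97, recall ~0.83, RMSE ~0.39 px.

The whole pipeline on a synthetic genome:

```python
from ogmap import run_synthetic_evaluation
table = run_synthetic_evaluation(n_per_length=128, localizer_model=model, seed=11)
print(table)
```

```
 fragment_length_bp  n_trials  n_correct  success_rate   ci_low  ci_high
            25000.0       128         42      0.328125 0.247755 0.416654
            50000.0       128        119      0.929688 0.870721 0.967346
           100000.0       128        128      1.000000 0.971592 1.000000
           150000.0       128        128      1.000000 0.971592 1.000000
```

Each row is one fragment length: of 128 random 50 kb crops, 119 aligned to
their true locus (success rate 0.93, exact 95% CI [0.87, 0.97]); placement
is essentially certain from 100 kb up, and degrades for very short
fragments, which carry only ~6 labels on average.

A CLI mirrors the library: `ogmap simulate|train|localize|align|sites|crop-bnx|evaluate`
(see `ogmap --help`).

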