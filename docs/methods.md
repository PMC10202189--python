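# Methods

## Problem and approach

`deepcrop` is a process-based crop growth simulator for greenhouse
horticulture built entirely from neural sequence models. Instead of
hand-derived physiological equations, a modified Transformer learns the
daily mapping from the hourly aerial environment and the recent growth
history to the next day's growth state, and a recursive rollout turns the
trained network into a simulator that needs only the environment and the
growth factors at transplanting. The crop is abstracted as "one big organ"
per organ type: all leaves, stem segments, petioles and harvested fruits of
a plant are summed into per-plant totals, so the output state is a vector
of 21 factors in six groups (status, property, leaf, stem, petiole,
harvest).

## Input features

The encoder consumes seven factors per hour over a window of `L` memory
days (24·L rows): measured temperature (°C), relative humidity (%) and
radiation (W m⁻²), plus four daily-resolution factors broadcast to all 24
hours of their day:

- **DIF** — mean day-period minus mean night-period temperature (°C). The
  day/night split defaults to "hours with radiation > 0"; a fixed clock
  window is configurable. A day with no day or no night hours gets DIF = 0.
- **Daily cumulative radiation** (kJ m⁻² day⁻¹) — a 1-hour rectangle-rule
  integral of the hourly W m⁻² values.
- **Cumulative growing degree days** — daily mean temperature minus the
  base temperature (10 °C, the conventional sweet-pepper base), floored at
  zero per standard agronomic practice so thermal time never decreases,
  then accumulated over the season.
- **Daily VPD** (kPa) — computed from the daily **mean** temperature and
  the daily **mean** relative humidity through the saturation-vapor-pressure
  curve `SVP(T) = 0.6113·exp(5423·(1/273.15 − 1/(273.15+T)))`,
  `VPD = SVP·(1 − RH/100)`. Using daily means (rather than averaging
  hourly VPDs) matches the daily resolution of the other derived inputs;
  both variants are available.

Gaps in raw hourly records are filled by one-dimensional linear
interpolation per variable; unbracketed gaps at the series edge are an
error rather than an extrapolation.

## Labels

Destructive investigations give factor means and standard deviations on a
handful of dates. Daily labels are built by linear interpolation of both
means and SDs, with a virtual day-0 anchor at cultivation start set to 50%
of the first observation. Stochastic augmentation then draws every
(day, factor) label from Normal(mean, SD) truncated at zero; cumulative
factors (season totals of radiation, thermal time and everything harvested)
are re-monotonized with a running maximum. Augmentation adds observation-
scale noise around a shared interpolated mean, so a handful of draws per
cultivation (default 4 in the experiment driver) is enough to regularize
training; the operation itself accepts any draw count.

## Architecture

- **Convolutional embeddings.** Input and output sequences are embedded by
  parallel 1-D convolutions with kernel sizes {1, 3, 5, 7}, each producing
  `d_model / n_branches` channels, concatenated channel-wise: the embedding
  expands the feature dimension rather than compressing it. Padding is
  causal (left-only), so an embedded position never sees later steps — this
  is what lets the decoder guarantee day-wise causality. Embeddings are
  batch-normalized; attention blocks use post-residual layer normalization.
- **Encoder.** Sinusoidal positional encoding plus `n_encoder_blocks`
  blocks of unmasked self-attention and feed-forward layers over the
  24·L hourly rows.
- **Input gate.** The raw feature window, linearly projected to `d_model`,
  is blended with the encoder output through an element-wise sigmoid gate
  `g`: `memory = g⊙encoded + (1−g)⊙projected_raw`. The gate lets decoders
  read the un-encoded environment directly when that is more informative.
- **Six multitask decoders**, structurally identical up to the width of the
  final linear head, one per factor group. Each applies its own output
  embedding, look-ahead-masked self-attention over the L daily positions,
  cross-attention over the full gated memory (the whole input window is
  past-or-current relative to the targets), and a feed-forward block.
  Masked attention weights are exactly zero (the softmax normalizes over
  kept entries only), so causality holds at the bit level.

Desk-scale defaults: `L = 7` days, `d_model = 32`, 4 heads, 2 encoder and
2 decoder blocks, feed-forward width 64, dropout 0.1 (~190 k parameters).
The width was chosen so the default experiment trains in a few minutes on
a single CPU core with the pure-NumPy training loop; on the smooth
synthetic signal this capacity is not the accuracy bottleneck.

## Loss

Training minimizes the unweighted mean of eight MSE terms: one per decoder
(over its factors and the L target days, in standardized space) plus two
vegetative-conservation terms comparing predicted and labelled sums of
leaf + stem + petiole fresh weight and dry weight. The conservation sums
are formed in natural units via the scaler's affine inverse and
re-normalized by the summed scales, so the terms are comparable in
magnitude to the decoder terms and vanish exactly when organ errors cancel
in grams. Optimization is Adam (learning rate 10⁻³, batch 32); the state
with the lowest validation total is returned. Features and factors are
z-scored with training-split statistics only.

## Simulation

Training is teacher-forced: a sample pairs the L days of labelled growth
preceding a target window with the environment and labels of the L target
days. At simulation time the model's own output recursively replaces the
growth history. To produce day *d*, the decoder window holds the L days
preceding the target window [d−L+1, d]; the last output position is the
day-*d* prediction, so each step advances one day. Days before cultivation
start are padded by holding the initial growth vector (and the first day's
environment features) constant.

Cumulative thermal time and radiation are computable from the measured
environment, so with **guidance** on (the default) the two status columns
of the fed-back growth window are replaced by the environment-derived
values instead of the model's own status outputs. During training the
labels are used as-is. An optional sanitation step (off by default) clips
negative predictions and enforces monotone cumulative-harvest trajectories
in the feedback loop.

## Synthetic study conditions

No public cultivation data accompany this problem, so the package ships a
generator that doubles as the reference comparator:

- **Environment**: hourly series for four cultivations (two "years" × two
  seasons: 120/90/110/90 days; planting densities 4.08/3.06/5.95/3.06
  plants m⁻²), with sinusoidal diurnal and seasonal temperature (~21 °C
  season mean, ±4.5 °C diurnal swing), anti-phase relative humidity,
  daylength-limited radiation (peak 370–460 W m⁻² inside the greenhouse)
  and seeded Gaussian/multiplicative noise.
- **Reference grower**: a deliberately minimal radiation-use-efficiency
  model — Beer-law interception (k = 0.65) of daily radiation by a Gompertz
  LAI curve `LAI(TS) = LAI_max·exp(log(LAI_init/LAI_max)·exp(−C_pLAI·TS))`
  over thermal time, RUE 1.9 g DW MJ⁻¹, a logistic thermal-time shift of
  partitioning from vegetative organs (leaf/stem/petiole = 45/35/20) toward
  fruit (up to 65%), fixed dry-matter contents and specific dimensions per
  organ, and discrete harvest events every 3 days once ripening begins
  (70% of the fruit pool per picking, 2–3 pickings per week). It exists to
  give the network a learnable, internally consistent, mass-conserving
  signal, not to reproduce pepper physiology.
- **Observations**: 5 evenly spaced destructive samplings per cultivation
  with multiplicative noise (CV 8%) and SD = CV·mean, mimicking 6-plant
  sampling.

What passing tests on these data do **not** show: robustness to sensor
drift, management interventions (pruning, topping, deliberate fruiting
delays), pest/stress episodes, or the season-to-season physiology shifts of
real cultivations — the synthetic truth is smoother and more stationary
than any greenhouse dataset.

## Evaluation

Per factor, modeling efficiency `EF = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²` (1 = perfect,
0 = as good as the observation mean, unbounded below) and range-normalized
RMSE. A constant baseline equal to the training-period factor means
accompanies every report; aggregates are unweighted means over the
evaluated factor subset. The default experiment trains on the two
first-year cultivations, simulates the held-out next-year spring
cultivation from its initial state and environment only, and scores ten
factors (plant height, leaf area, organ FW/DW, cumulative harvest FW/DW)
against the generator's daily truth. Constant observation series make EF
undefined: the metric primitives raise an error, and the report builder
skips such factors with a warning (e.g. cumulative harvest on labelled
days before the first picking).

## Numerical and design notes

- Zero-variance label columns get scale 1 (with a warning) instead of a
  division by zero.
- Negative interpolated labels are clipped at zero with a warning.
- The softmax stabilizing max is taken over kept entries only, so masked
  logits cannot perturb kept weights even in the last bit.
- All randomness (environment noise, observation noise, augmentation,
  train/validation split, initialization, batching, dropout) derives from
  one global seed through SHA-256-hashed named substreams.
- Network and optimizer run on a small reverse-mode autodiff core over
  NumPy float64 arrays (`deepcrop.nn`); gradients are validated against
  central finite differences in the test suite.
- Checkpoints are single `.npz` archives embedding parameters, buffers,
  the architecture config and both scalers; loading with a mismatched
  decoder map is an error, never a silent reshape.

## Known limitations

- The recursive rollout can drift for factors the loss weighs weakly;
  guidance anchors only the two status inputs.
- Mid-season declines in cumulative predictions are possible when
  sanitation is off (the default), which mirrors simulator behavior rather
  than physical truth.
- The ablation harness retrains each variant from scratch; at realistic
  sizes this is minutes per variant on one core.
- EF on the synthetic truth is an optimistic analogue of skill on real
  destructive observations (n per factor is larger and noise-free).
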