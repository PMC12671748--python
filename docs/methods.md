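# Methods

This note records the models behind each stage, the defaults that matter,
the conventions chosen where the analysis tradition leaves the choice open,
and what the synthetic generator does and does not emulate.

## Data model and normalization

A session is a neuron × frame matrix of extracted calcium activity at a
fixed frame rate (default 10 Hz), either `raw_nonneg` (fluorescence-like,
all values ≥ 0) or `zscore` (per-row mean 0, SD 1). Z-scoring uses the
population SD (ddof 0); constant rows are mapped to all-zero and flagged in
`constant_neurons` instead of producing NaNs, and every downstream
statistic treats flagged rows as missing. Behavior bouts are half-open
intervals `[start, end)` in seconds; frame `f` (0-based) belongs to a bout
iff its midpoint `(f + 0.5)/rate` falls inside. Midpoint membership is a
convention of this package — behavior-scoring tools do not agree on a
discretization — and guarantees the number of ones deviates from
`duration × rate` by at most one frame per bout.

Cross-session neuron identity is consumed as a partial injective map
produced by upstream spatial registration; the package does no registration
itself.

## Ensemble detection

Neurons are clustered on their z-scored traces with k-means (Euclidean
distance, best of `n_restarts = 20` initializations, fixed seed). For
unit-variance rows, squared Euclidean distance equals `2·n·(1 − r)` with
`r` the Pearson correlation, so clustering in trace space is equivalent to
clustering on correlation, matching correlation-clustermap practice.
Clustering runs on traces rather than on the pairwise correlation matrix;
the two views coincide under this metric identity and trace space keeps
the centroid interpretable as an ensemble mean trace.

The number of ensembles is read from the WCSS curve (`k = 1…6` by default)
at the elbow: the interior k maximizing the discrete second difference
`WCSS(k−1) − 2·WCSS(k) + WCSS(k+1)`, ties to the smaller k. A curve whose
largest second difference is below 1% of the smallest-k WCSS is declared
structureless and yields k = 1 with a warning; the 1% floor separates
rounding-level curvature from a real elbow and is configurable only by
editing, deliberately, since silent auto-tuning of a model-selection rule
is worse than a visible constant. `k` can always be overridden (analyses
of this kind commonly fix k = 2 after inspection).

Each neuron's coupling to its ensemble is the Pearson r with the ensemble
mean **including** the neuron itself. Including the neuron inflates r —
exactly to 1 for singleton ensembles, which are therefore flagged — but
mirrors the cited procedure in this literature; a leave-one-out switch
(`exclude_self=True`) is provided. Distributions of r across groups are
compared with the two-sample Kolmogorov–Smirnov test (scipy, asymptotic p).

## Behavior-relevance classification

The statistic is the cosine similarity between the **raw non-negative**
trace and the binary behavior vector, which constrains R to [0, 1]; the
z-scored trace would break that range, so normalization is deliberately not
applied here (z-scored traces are used for mean-activity summaries
instead). The null shuffles the trace by `n_perm = 1000` circular shifts
with uniform random offsets in `[1, n_frames − 1]`. Circular shifting
preserves the full autocorrelation structure of the calcium trace — a
plain frame permutation destroys the indicator-kernel smoothness and
produces an anti-conservative null — and is therefore the default; a
`mode="permutation"` flag provides the plain shuffle for comparison.
Implementation note: the cosine at *every* circular shift is obtained with
a single FFT cross-correlation, and the permutation sample indexes into
it; tests verify exact (1e−12) agreement with an explicit `np.roll` oracle.

Labels use strict inequalities against the empirical 5th/95th percentiles
(linear interpolation): `R > p95` → positive, `R < p05` → negative,
otherwise irrelevant, so an R lying exactly on a percentile is irrelevant.
No multiple-testing correction is applied across neurons; the per-neuron
5% tails are the stated design, and the null-calibration test confirms the
realized false-call rates match them. Ratios are reported against the total
registered population, which may exceed the number of neurons classified
in one session.

## Functional network

Pairwise similarity is again the cosine of raw traces. The null for a pair
preserves each trace's amplitude spectrum (hence mean, power and
autocorrelation) while destroying phase alignment: Fourier phases of all
non-DC, non-Nyquist bins are redrawn i.i.d. uniform(0, 2π) and the signal
inverted back to the real domain. Surrogates may dip below zero; they are
used as-is, since the raw similarity being tested is non-negative and the
comparison is one-sided from above. A link requires the raw similarity to
strictly exceed the 99.17th percentile of 10,000 surrogate pair
similarities; 99.17 is the conventional threshold adopted here as a
parameter (configurable), not derived.

Generating 10,000 fresh surrogate pairs for each of n(n−1)/2 pairs is
wasteful: instead S = 100 surrogates are drawn once per neuron and crossed,
giving S² = 10,000 pair similarities per pair from ~n·S transforms. Because
surrogates of different neurons are mutually independent, the crossed
sample follows the same null law as fresh pairs; a `per_pair_surrogates`
flag enables the literal per-pair mode. Degree centrality (links/(n−1)) is
computed through networkx, and can be partitioned into behavior-linked
(positive ∪ negative) versus irrelevant groups.

## Synthetic sessions

The generator emulates the structure the analysis assumes, with known
ground truth:

- **Bouts**: alternating renewal process — gap ~ Exp(12 s), bout ~ Exp(3 s)
  truncated at 0.5 s — giving ≈20% time-in-bout, typical of scored social
  or object-approach behavior in 10-minute sessions.
- **Events**: per-frame Bernoulli trains. Positive neurons fire at 2 Hz
  inside bouts / 0.2 Hz outside; negative neurons mirror that; irrelevant
  neurons hold a constant 0.5 Hz. These rates define the generator's
  default effect size, at which the classifier's sensitivity is ≥ 0.9.
- **Ensembles**: each ensemble has a latent 0.3 Hz drive train; a drive
  event recruits each member independently with probability 0.6. The
  defaults give moderately coupled networks; the `two_ensemble_config`
  preset (participation 0.9, drive 0.5 Hz, all-irrelevant classes) creates
  clearly separable ensembles for recovery experiments, and
  `hyperconnectivity_config` (participation +0.35, drive ×2) emulates a
  pathologically synchronized network for contrast experiments.
- **Traces**: events convolved with `exp(−t/τ)`, τ = 1 s (GCaMP-like at
  10 Hz; indicator kinetics are a knob, not a claim), plus Gaussian noise
  (SD 0.1) and rectification at 0 so traces remain valid cosine inputs.
- **Paired sessions**: each neuron reappears with probability 0.5 carrying
  its class and ensemble label (traces redrawn); dropped slots are refilled
  with fresh neurons, and the identity map covers exactly the retained set.

Not emulated: photon/shot noise and bleaching, spatial footprints and
crosstalk, non-exponential indicator kinetics, behavioral autocorrelation
beyond the renewal process, and any dependence between bout structure and
ensemble drive. Passing recovery tests therefore demonstrate correctness
of the inference machinery under the generative assumptions, not
performance on real recordings.

## Dose arithmetic

Chow-equivalent concentration of a nutrient =
`(chow_conc·3 g + water_conc·4.8 mL)/3 g` with water density 1 g/mL, so %
w/v mass is concentration × mL; ppm passes through identically. The
baseline is LabDiet 5K54 (Ile 0.74%, Leu 1.49%, Val 0.87%, Ser 0.83%, Zn
81 ppm). The half cocktail stores Ile and Val at 0.225% — half the 0.45%
full BCAA dose and consistent with every effective value the preset must
produce simultaneously — although such labels are often rounded to 0.25%
in print. Full precision is kept internally; display rounding is half-up
at two decimals for percentages and integer ppm.

## Problem sizes and tolerances

Calibration and recovery experiments run at desk scale chosen to make
their statistical tolerances meaningful: null calibration pools 8,000
neurons (20 seeds × 400), judged within 3 binomial SEs of 5%; the network
null pools 4,900 pairs (4 seeds × 50 neurons at 2,000 frames), judged
within 3 binomial SEs of 0.83%; recovery experiments use 20 seeds at 40–60
neurons. Oracle comparisons (FFT vs roll, surrogate spectra) are exact to
1e−10–1e−12. Numerical ties: percentile interpolation is linear; equality
with a threshold never creates a link or a label.

## Known limitations

- The elbow rule is a heuristic; on data without clear ensemble structure
  it returns k = 1 and the warning should be heeded rather than overridden.
- Cosine similarity of non-negative traces has a high baseline driven by
  the shared positive mean; it is informative only against its permutation
  or surrogate null, never as an absolute number.
- The surrogate-pooling shortcut assumes pairwise independence of
  surrogate draws across neurons; it shares one RNG stream, so per-pair
  and pooled modes agree in law but not draw-for-draw.
- Sessions are treated as stationary; drifting baselines would violate
  both nulls and should be detrended upstream.
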