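# Methods

This note documents the models and procedures `phenocube` implements, the
design choices made where several reasonable options existed, and what the
synthetic benchmarks do and do not demonstrate.

## The mapping model

The pipeline assumes that the species of interest is distinguishable not by
its spectrum at any single date but by the *shape* of its vegetation-index
trajectory over years of observations. Four indices are used: NDVI and EVI
(greenness), NDWI (canopy water) and NBR (burn state, because fire history
modulates grass cover). Each index cube is arranged as a matrix with rows =
acquisition dates and columns = pixels, so a singular value decomposition
cleanly separates temporal modes from spatial loadings. A pixel's vector of
leading spatial loadings (six per index, 24 in all) is a compact encoding
of its phenological history: pixels with similar loading combinations had
similar temporal behaviour.

Classification is a forward stepwise logistic regression on those 24
features, guided by BIC: starting from the intercept-only model, the
candidate whose addition most lowers BIC enters, and selection stops when
no addition strictly lowers it (ties never enter; tie-breaks go to the
first feature in canonical column order `ndvi_1 … nbr_6`). BIC rather than
AIC keeps the mapping model parsimonious, which matters because the model
is then applied to every pixel in the scene. A one-hidden-layer neural
network (3 tanh units over all 24 features, standardised inputs, full-batch
L-BFGS to tolerance 1e-6, seeded initialisation) is fitted as a check that
no large nonlinear signal is being left on the table.

The per-pixel probability is the standard rising logistic
P = 1/(1 + e^(−Lin)), Lin = β₀ + Σ βᵢxᵢ. The mirror-image convention
P = 1/(1 + e^(+Lin)) appears in some published formulations; with
coefficients fitted by any standard logistic routine it would invert every
probability, so the rising convention is the default and `logit_sign`
switches it explicitly (with a warning).

### Evaluation protocol

"Bootstrapping" here means repeated stratified random 2/3–1/3
train/validation splits (ten by default), refitting the full selection
procedure on each training set — not resampling with replacement: the
reported training/validation structure only makes sense with fresh splits.
Reported values are mean ± SE with SE = SD over bootstraps / √n_boot.
Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy = (TP+TN)/N at
threshold 0.5; AUC is the Mann–Whitney concordance probability with half
credit for ties. A metric with an empty denominator is reported as
undefined, never as zero. The operating threshold is chosen by maximising
Youden's J = sensitivity + specificity − 1 over observed score cut-points
(ties resolve to the cut nearest 0.5); minimising FP + FN is available as
an alternative objective.

### Numerical choices

* **Mosaic screen:** strict inequalities — cloud fraction < 0.03 AND valid
  fraction > 0.90. A mosaic at exactly 3% cloud or exactly 90% valid is
  excluded.
* **Index safety:** invalid pixels and vanishing denominators propagate as
  missing (never ±∞); residual missing entries on retained dates are filled
  by per-pixel linear interpolation in acquisition time, ends extended with
  the nearest observation. This preserves phenological shape better than
  column-mean fill; the policy is configurable and the imputed-entry count
  is recorded. A pixel with no valid observation at all is an error, not a
  silent zero column.
* **Matrix orientation and flattening:** pixels are flattened row-major
  from the top-left; column j ↔ pixel (j // n_cols, j % n_cols), recorded
  in the matrix container so maps reconstruct unambiguously.
* **No centering by default:** the decomposition acts on raw index values;
  the first component then captures the dominant mean seasonal pattern.
  Mean-centering is left to the caller (the matrices are plain arrays).
* **Feature scaling:** features are the entries of the unit-norm right
  singular vectors, unscaled by singular values (scaling is an option).
  Their magnitudes are therefore ~n_pixels^(−1/2), which is why fitted
  logistic coefficients on real scenes are large.
* **Sign convention:** each singular-vector pair is flipped so the
  largest-magnitude entry of its temporal mode is positive; logistic
  coefficients are sign-sensitive, so this canonicalisation is mandatory
  and idempotent, and leaves the reconstruction unchanged.
* **Randomized SVD:** oversampling 10, four power iterations, seeded. On
  matrices with decaying spectra (which index matrices have) this matches
  the exact decomposition to ~1e-6 relative or better; on matrices with a
  flat spectrum no practical number of power iterations achieves that, so
  the oracle-equivalence tests use seeded geometric-spectrum matrices. The
  pipeline default is the exact decomposition; the randomized path exists
  for scenes too large to decompose exactly.
* **Separation:** a (quasi-)separated logistic fit falls back to a lightly
  ridged refit (L2, C = 1e4) and is flagged in the model metadata. BIC for
  such fits uses the penalised fit's log-likelihood.
* **Stepwise null behaviour:** with k independent candidates, a noise
  feature enters when the largest of k χ²₁ likelihood-ratio statistics
  exceeds ln n. At n = 200 with 24 candidates that happens ~40% of the
  time — BIC's consistency is an asymptotic property. The null-behaviour
  test therefore uses n = 20 000, where ln n ≈ 9.9 sits above the typical
  max-of-24 χ²₁ draw and intercept-only is selected ~96% of the time; the
  small-pool variant (4 candidates, n = 1000) is tested too.

## The synthetic scene generator

The generator produces the statistical structure the method exploits, with
every draw from one seeded `numpy.random.Generator` (identical config +
seed ⇒ bit-identical scene):

* **Acquisitions:** nominal 5-day revisit over 2016–2025 with Bernoulli
  dropout (default 0.70, leaving ~200 dates, ~170 after the mosaic screen).
  The heavy dropout stands in for the combined effect of cloud seasons,
  tile gaps and early-mission cadence.
* **Rainfall:** homogeneous Poisson events (default 4/yr) with exponential
  magnitudes (mean 20 mm-equivalents) — short, discrete pulses, as in arid
  central Australia.
* **Phenology:** each cover class responds to a pulse with a
  rise-then-decay kernel: linear green-up at `rise_rate`/day after
  `lag_days`, exponential senescence with half-life
  `decay_halflife_days`, scaled by `amplitude` per mm, on top of a dry
  `baseline`. Defaults (lag/rise/half-life/amplitude/baseline):
  buffel 2 d / 0.25 / 60 d / 0.035 / 0.15;
  native tussock 6 / 0.10 / 25 d / 0.015 / 0.05;
  spinifex 10 / 0.06 / 40 d / 0.008 / 0.12;
  shrub canopy 12 / 0.05 / 90 d / 0.006 / 0.30;
  bare 0 response / 0.02; riparian woodland 8 / 0.08 / 120 d / 0.010 /
  0.45. No published green-up rates pin these numbers; they are chosen so
  the buffel contrast (strictly shorter lag, higher amplitude, longer
  decay than both native grass classes) holds by construction — the
  generator refuses class sets that violate it — and are tunable to harder
  regimes.
* **Landscape:** three horizontal strata (alluvial plain — buffel-rich,
  granite range — intermediate, dunefield — buffel-free) with 8×8-pixel
  cover patches drawn from stratum-specific class mixtures, plus a
  meandering riparian corridor; half of the corridor pixels carry a 60%
  buffel understory (blended greenness, labelled buffel-present). This
  gives the stratum summaries non-trivial structure.
* **Rendering:** linear mixture reflectance = g·vegetation endmember +
  (1−g)·soil endmember over fixed, plausible 5-band endmembers (simulator
  constants, not literature spectra). Fires (Poisson in time, rectangular
  burn scars, severity U(0.5, 1)) multiply green cover by (1 − severity)
  with recovery along the class's rise limb, and blend a NIR-depressed /
  SWIR-raised char endmember with 240-day-half-life fading, so NBR drops
  at fire dates. Gaussian noise (additive sd 0.02 by default, or
  multiplicative) is applied and everything clipped to [0, 1]. Clouds are
  single contiguous rectangles with Beta-distributed area — the simplest
  shape that makes the <3% area screen meaningful — and occasional edge
  strips emulate partial mosaics; both are flagged in the masks, never
  silently zeroed.

### Benchmark scenes and problem sizes

* **Default benchmark** (`default_benchmark_config`): 64×64 pixels, six
  cover classes, 2016–2025, ~200 acquisitions (~170 retained), noise sd
  0.02, 400 stratified waypoints. Deliberately desk-scale: one full
  pipeline run takes seconds, while preserving every structural element of
  the full-scale problem (the method itself is reported to scale to ~10⁹
  matrix elements per index on a desktop workstation).
* **Rank-6 benchmark** (`rank6_benchmark_config`): 48×48 pixels, 4 years,
  one phenology trace per class, no fires, no understory blending, no
  masking, 5% *multiplicative* reflectance noise. With six classes and one
  temporal pattern each, every noise-free index matrix has at most six
  distinct column types and hence rank ≤ 6 exactly; the top-6 variance
  share then measures signal-to-noise. Multiplicative noise is used here
  because the normalised-difference ratios amplify additive band noise
  ~3×, which at sd 0.05 would swamp a rank-6 signal and turn the benchmark
  into a noise measurement.

### What the synthetic benchmarks do not show

The generator emulates the *structure* of the real problem, not its
difficulty. Real scenes have mixed pixels at every boundary, continuous
cover gradients, spatially correlated rainfall, view/illumination effects,
atmospheric residuals and mislabelled waypoints; the simulated classes are
internally homogeneous apart from independent pixel noise. Classification
accuracy on the default scene (~99%) is therefore an upper bound
demonstrating pipeline correctness — signal in, signal out — not a
prediction of field accuracy, which in comparable real studies sits in the
85–95% range. Conversely, the structural checks (filter semantics,
index closed forms, SVD oracle equivalence, fire/NBR encoding, stratum
accounting) are exact and carry over to real data unchanged.

## Known limitations

* Raster I/O uses plain TIFF with a YAML georeference sidecar; full
  GeoTIFF tags/CRS handling would need a geospatial raster library.
* The synthetic bands share one resolution; real 20-m SWIR must be
  resampled to the 10-m grid before cube assembly.
* Cloud masks are inputs (or simulator outputs); no cloud detection is
  performed.
* `stepwise_logistic` refits each candidate by full maximum likelihood; at
  a few hundred waypoints and 24 features this is fast, but very large
  candidate pools would want score-test screening.
* The fire model ties vegetation recovery to the rain-response rise rate;
  post-fire succession dynamics are not modelled.
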