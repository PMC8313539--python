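# Methods

## The model

`ddmix` models two-choice response times (RTs) as a probabilistic mixture
of two latent processes.

**Diffusion decisions.** With probability `1 − p_o` a trial is a Wiener
diffusion decision: evidence accumulates from a starting point `z`
between absorbing boundaries `0` and `a` with drift `v` and within-trial
noise SD `s`; the boundary reached determines the response (upper =
correct), and the RT is the first-passage time plus a nondecision time
(encoding + motor output). Across trials, drift is Normal(`v`, `η`), the
starting point is uniform with range `s_z` centred on `z`, and
nondecision time is uniform with mean `T_er` and range `s_t`. Drift
variability produces slow errors; starting-point variability produces
fast errors.

**Fast guesses.** With probability `p_o` a trial is a fast guess: the
response is a fair coin (accuracy exactly 0.5 regardless of stimulus)
and the latency is Normal(`μ_g`, `s_g`) on the absolute RT scale,
truncated at zero and renormalised (the truncated mass is < 1e−6 at the
default parameters). Guess latencies are not offset by the diffusion
nondecision time: `μ_g ≈ 0.26 s` is interpreted as a complete
stimulus-independent response latency.

**Design and selective influence.** The experimental design crosses five
speed-accuracy instruction levels (1 = extreme speed stress … 5 =
extreme accuracy stress) with five stimulus contrasts (1 = hardest).
Structurally, `a`, `T_er` and `p_o` vary only with speed stress, `v`
only with contrast, and `η, s_z, s_t, μ_g, s_g` are shared — 25
parameters for 25 conditions. The starting point is unbiased (`z = a/2`)
and `s = 0.1`, the conventional scaling of the model; neither is free.

Default parameter values (in `ddmix.canonical_design()` and
`src/ddmix/data/default_design.yaml`) are across-subject mean estimates
from a 20-subject orientation-discrimination study with this design:
heavy guessing under extreme speed stress (`p_o = 0.735`), some under
high speed stress (0.201), none in the three slower conditions.

## Numerical evaluation of the first-passage distributions

- **Absorption probabilities** use the classical exponential closed
  form, written with `expm1` so the zero-drift limit is exact.
- **Densities** (`fpt_density`) use the small-time and large-time series
  of the drift-free unit density with the standard term-count bounds,
  switching per time point to whichever series needs fewer terms for a
  truncation error of 1e−7.
- **Defective CDFs** (`defective_cdf`) use the large-time
  (eigenfunction) series of the CDF. The uniform across-trial integrals
  are evaluated **in closed form**: the starting-point average of each
  series term is an elementary `∫ exp(cz)·sin(bz) dz`, and the
  nondecision-time average of `exp(−λ(t−u))` is elementary in `u`. Only
  the normal drift variability is integrated numerically
  (Gauss–Hermite, order 20; order 20 vs 60 differ by ~4e−9 at the
  default parameters). Series terms are accumulated until three
  consecutive terms fall below an absolute tolerance (1e−9 in the
  library API, 3e−7 inside the fitting objective, where the difference
  in G² is ~2e−4 on a 5000-trial subject).
  An all-quadrature reference (`defective_cdf_quadrature`,
  Gauss–Hermite × Gauss–Legendre × Gauss–Legendre) is retained and
  cross-checked in the test suite (agreement ≲ 1e−7); the closed-form
  route is the primary implementation because it is exact in two of the
  three integrals and ~100× faster, which the 25-parameter fit needs.
- **Simulation** (`sample_first_passage`) is Euler–Maruyama at
  `dt = 1e−4 s` with Brownian-bridge crossing probabilities between
  steps, which removes the leading `O(√dt)` boundary-crossing bias; the
  simulator is the package's independent oracle for the analytic series
  (KS distance ~2e−3 at 4×10⁵ trials, within sampling noise).
- RTs below 1e−4 s are treated as zero-probability by the CDFs; times at
  or before the minimum nondecision time return exactly 0.

## Synthetic data

`simulate_dataset` emulates the study the model was developed for:
20 subjects × 25 cells × 200 trials (≈5000 per subject) by default. Per
cell, the number of guesses is Binomial(`n`, `p_o`); guesses and
diffusion trials are sampled from their components and shuffled. Each
subject gets an independent child seed of one root seed (subject-major),
so datasets are bit-reproducible and any subject is reproducible alone.
Optional between-subject heterogeneity multiplies each subject's
parameters by log-normal factors (SD 0.1 by default; guess probabilities
are perturbed on the logit scale, zeros stay zero) — the original study
reports only mean parameters, so this dispersion is a fixture choice,
not an estimate. Generated data reproduce the qualitative signatures of
the real experiment: bimodal RT distributions in speeded conditions,
chance accuracy below 300 ms, and the error−correct RT sign flip across
speed stress.

What the generator does **not** emulate: anticipatory key presses (the
real data contain responses at exactly 31 ms, too fast to be responses
to the stimulus), non-normal guess-latency shape, sequential effects,
and parameter drift within a session. Passing tests therefore show that
the estimation machinery is correct under the model's own assumptions,
not that the model is right about any particular dataset.

## Fitting

Each design cell contributes up to 20 bins: the observed 0.1 … 0.9
quantile RTs of each response type (type-7 linear interpolation) cut
that response's mass into 10 bins of observed proportion
`0.1 × n_resp/N`. The model is scored by
`G² = 2 Σ_cells N Σ_bins p_i ln(p_i/π_i)`, where `π_i` are the model's
predicted bin probabilities at the observed quantile edges, floored at
1e−10. A response type with fewer than 11 observations in a cell is
represented by a single bin (its response probability only); the
threshold is the smallest count that defines nine interior quantiles.

All 25 cells are fit simultaneously by Nelder–Mead (scipy, adaptive) on
an unconstrained vector: bounded parameters via logistic transforms,
`s_z` as a fraction of `0.95·min(a)`, `s_t` as a fraction of
`1.9·min(T_er)` — every vector maps to a valid design, so the optimizer
never needs penalties. Starting values are data heuristics (guess
probability from the sub-300-ms fraction per speed condition;
nondecision time from the 0.05 quantile of guess-purged RTs; boundary
from the median decision time via the zero-drift mean first-passage
time `a²/4s²`; drift from accuracy via `acc = 1/(1+exp(−va/s²))`), plus
three restarts perturbed by 10%; the best optimum is kept and restarts
never worsen it.

Two modifications mirror the original procedure: (i) any fitted
`p_o < 0.1` is fixed to zero and the fit re-run, iterated until the zero
set is stable; (ii) `a` and `T_er` are tied across speed conditions 1–2
(default on), because with `p_o ≈ 0.74` the fastest condition's
diffusion parameters are poorly identified. Degrees of freedom are
reported as the conventional 475 − 25 = 450 headline (0.95 critical
value 500.5; fits up to about twice that still grade "good" at this
trial count) alongside the actual free-parameter count (23 when tied,
minus any zeroed `p_o`) and the data df actually present (sparse cells
shrink it below 475).

Problem sizes used by the shipped tests: parameter recovery fits one
subject at 200 trials/cell (the study's per-subject scale);
simulation-oracle comparisons use 10⁶ Euler trials per parameter set;
the G² self-consistency check uses 2000 trials/cell. The default
optimizer budget (12000 evaluations primary + 5000 per restart) fits one
subject in a few minutes on one core.

## Benchmarks

Per speed condition (collapsed over contrast): mean error RT − mean
correct RT; CV = SD/mean of the pooled RTs; and three skewness measures
— moment skewness, quartile skewness `(Q3+Q1−2Q2)/(Q3−Q1)` and Pearson
skewness `3(mean−median)/SD` (SD with ddof = 1). Moment-based SD and
skewness are cutoff- and outlier-sensitive (the test suite demonstrates
a 2 s vs 5 s cutoff shifting them materially while quartile skewness
moves by < 0.02), which is why the robust measures are reported
alongside. Statistics are computed per subject then averaged
(`mode="per_subject"`, default) or on pooled trials (`mode="pooled"`);
the aggregation genuinely matters for the CV and is exposed rather than
chosen silently.

The chance-accuracy diagnostic is a one-sample t test of per-subject
accuracy against 0.5, restricted to responses faster than 300 ms in the
speed-stressed condition (cutoff configurable); Cohen's d is
`|mean − 0.5|` over the between-subject SD. Quantile-probability tables
report, per cell and response, the response proportion and the 0.1, 0.3,
0.5, 0.7, 0.9 quantile RTs, falling back to the median alone when a
response has 15 or fewer observations (the plotting convention of the
original study); the model-side table inverts the mixture CDF by
bisection.

## Known limitations

- The normal guess distribution is a deliberate simplification; a
  right-skewed alternative (e.g. inverse Gaussian) is out of scope.
- Nelder–Mead in 23–25 dimensions can stall on flat ridges; restarts
  mitigate but do not guarantee the global optimum. Drift rates in
  near-chance cells and `η`/`s_z` are weakly identified at 200
  trials/cell — recovery there is approximate even at the true optimum.
- The Euler oracle is itself stochastic; oracle tests use 3-SE bands and
  fixed seeds.
- Degenerate designs (e.g. `p_o = 1` everywhere) leave the diffusion
  parameters unidentified; the fitter returns a flagged result rather
  than failing.
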