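# Methods

This note documents the modelling choices behind `ocplsnir`: the one-class
model itself, the preprocessing and splitting conventions, what the
synthetic-data generator does and does not emulate, and the numerical
decisions a maintainer would otherwise have to reverse-engineer.

## The one-class PLS model

OCPLS treats authentication as a regression of the constant response
**1** on the *uncentered* training spectra of the target class,
`1 = X b + e`, fitted by NIPALS PLS1.  Uncenteredness is essential, not a
convention: column centering makes every predictor column orthogonal to the
constant response, leaving nothing to regress on (a regression test asserts
this failure mode).  PLS1 is run with X-deflation only; the coefficient
vector for every truncation 1..A is accumulated in a single pass via the
recursion r_a = w_a − Σ_j (p_jᵀw_a) r_j, so MCCV evaluates all candidate
component counts at one fit per fold.

**Rank handling.**  On smooth, low-noise spectra the NIPALS weight norm
decays geometrically across components while the score vectors stay
well-conditioned; genuine rank exhaustion instead drives the score norm to
(machine ε)² of the data scale.  The rank test is therefore on the score
norm tᵀt, with threshold (10³ε·‖X‖_F)², and the error names the failing
component.

**Error model and acceptance interval.**  Model errors are assumed
approximately normal; μ̂ₑ and σ̂ are the mean and sample (n−1) standard
deviation of the pooled held-out MCCV errors at the selected component
count, and the acceptance interval is
(1 − μ̂ₑ ± z_{1−α/2}·σ̂), closed at both ends (a boundary prediction is a
measure-zero event; closing the interval fixes determinism).  Pooling
across repeats is the default; an independent re-folding for error
estimation was evaluated and changed the held-out rejection rate by less
than 0.004, so the simpler estimator stands.

**Latent-variable selection.**  "More components do not reduce PRESS
significantly" is operationalised as: the smallest A with
PRESS(A) ≤ 1.02·min PRESS.  The 2% relative tolerance reproduces the
visual-elbow intent deterministically and is configurable.

**MCCV.**  Each repeat leaves out round(0.10·n) samples (≥1) uniformly
without replacement; 100 repeats by default; with n = 40 this pools 400
held-out errors.  `max_components` defaults to 15 — comfortable headroom
over the 5–9 components the study-scale models select, while keeping the
n = 36 fold remainder well above the component count.

**Finite-sample calibration.**  At α = 0.05 and n = 40 training samples the
*expected* held-out false-rejection rate is slightly above α, ≈ 0.055–0.065
rather than 0.050, for quantifiable reasons: (i) σ̂ carries χ²₍₃₉₎ noise and
the rejection probability is convex in σ̂, so Jensen's inequality adds
≈ +0.006; (ii) component selection adapts to the training draw, leaving a
~2% mean underestimate of the new-sample error sd.  The package reports
this honestly (see `examples/06_interval_calibration.py`); it is a property
of the plug-in normal interval at this sample size, not of the
implementation.  The calibration study (`ocplsnir.calibration`) uses the
orthogonal-projection model — the protocol's headline variant — and a
homogeneous (single-batch) pure population, because the question under test
is interval coverage, not batch structure.

## Preprocessing

Three alternative single transforms, never chained:

- **raw** — identity.
- **SNV** — per-spectrum (x − mean)/sd with the sample (n−1) denominator;
  the denominator convention is configurable and immaterial downstream
  because SNV is affine-invariant.
- **OP** — x − s·(sᵀx)/(sᵀs), the rank-one form of (I − s s⁺) for a single
  reference column s; O(p) memory, no p×p projector is ever materialised.
  The reference s is used exactly as read — no normalisation — and must be
  on the identical grid (interpolation is out of scope by design).

## DUPLEX splitting

The simplified pair-alternation variant: repeatedly hand the most mutually
distant remaining pair (Euclidean) to the training set, then to the test
set, training first; when the test quota is reached, all remaining samples
join the training set.  Two underdetermined corners are fixed for
determinism: distance ties resolve to the lexicographically smallest index
pair, and an odd test quota takes only the lower-index member of the final
pair.  A third corner the textbook description does not cover — strict
alternation exhausting the pool before the test quota is met, possible when
n_test approaches n − 2 — diverts the training-turn pair to the test set;
the study-scale case (60 samples, n_test = 20) never triggers it.  The
split is computed once on the raw spectra and reused for all preprocessing
variants so every model sees an identical test composition.

## The synthetic-data generator

Bench studies of this kind rarely deposit their spectra, so the generator
emulates the *statistical structure* the analysis depends on, at the
reference design's exact sample sizes (three pure batches of 17/25/18; sixteen
(adulterant, dose) groups totalling 197).

A pure spectrum is
`x = (c_w·W + S + batch_shift)·m + b₀ + b₁(ν − ν_mid) + ε`, where W and S
are Gaussian-band water and yogurt-solids profiles rebuilt per sample with
independent per-band amplitude and position jitter, c_w ~ N(1, 0.01) is the
common water amplitude, m ~ N(1, 0.035) is multiplicative scatter, b₀, b₁
are baseline offset and slope, and ε is i.i.d. noise (sd 0.002 AU).  An
adulterated spectrum blends a randomly chosen pure spectrum with an
adulterant "solution" — Gaussian signature bands plus a make-up water term
along the water profile — scaled by the doping level, mirroring the
practice of keeping sample thickness constant by adding water.

Two structural choices make the three preprocessing variants separate the
way the protocol expects, and they are the generator's central modelling
statement:

1. **The water amplitude of pure yogurt is stable** (sd 1%).  A model built
   on raw spectra therefore *uses* the water signal as evidence of
   normality — and the make-up water in adulterated samples restores
   exactly that signal, so dilution is nearly invisible to the raw model.
   Projecting out the water direction forces the model onto the solids
   signal, which dilution and signature both perturb.
2. **The water/solids band shapes wander in many independent directions**
   (per-band amplitude and center jitter).  A latent-variable budget of
   ~15 cannot fully model this nuisance from 40 training samples, which is
   what keeps the raw model's error dispersion high and seed-variable —
   qualitatively matching how raw-spectrum class models underperform in
   practice.

Band positions and widths sit in the classic NIR assignment regions (water
combination/overtone bands; C–H/N–H/carbohydrate solids bands; protein-like
signature bands near 4600/5700–5800/6500–6800 cm⁻¹), but no quantitative
spectral library stands behind them: the adulterant signatures are
acknowledged stand-ins, with the two weaker adulterants (industrial
gelatin, soy protein analogues) given ~0.4× the per-dose strength of edible
gelatin so their detection limits fall at higher doses.  All default
magnitudes were calibrated once — jointly against the protocol-level
properties the package promises (specificity ordering raw ≤ SNV ≤ OP on the
frozen default seed, monotone dose response, detection levels existing,
approximate interval calibration) — and then frozen; they are conditions of
the synthetic study, not tuning knobs.

**What passing tests do and do not show.**  The generator is linear in its
latent draws and strictly Gaussian; real diffuse-reflectance spectra add
absorbance nonlinearity, wavelength-dependent scatter, temperature-driven
band shifts and instrument drift.  Synthetic results therefore validate the
*pipeline* — that each stage implements its contract and that the method
behaves as designed under its own assumptions — not field performance on
real yogurt, and the absolute sensitivity/specificity values on synthetic
data are properties of the chosen defaults, not estimates of any real
instrument's figures.

**Grid.**  The default grid has 2074 points from 4000 cm⁻¹ at 3.857 cm⁻¹
spacing (end ≈ 11995.6 cm⁻¹).  A nominal 4000–12000 cm⁻¹ range at that
spacing is inconsistent with 2074 inclusive points by one; the point count
wins because it is the operative dimension everywhere.

**Reproducibility.**  One seed stream per concern (water reference, pure
samples, adulterated samples) derived from a single SeedSequence, so
changing one stage's parameters never perturbs another's draws; the
pipeline additionally derives generation and MCCV seeds separately from the
master seed.

## Evaluation conventions

Pure = positive.  The per-(adulterant, dose) table counts accepted samples;
an adulterant's *detection level* is the smallest designed dose L with zero
accepted samples at L and at every higher dose — absent if even the top
dose had an accepted sample.  Report invariants (margins, group sums) are
re-asserted on every construction.

## Known limitations

- Grids must match exactly between data and reference; no resampling.
- The JCAMP-DX reader handles AFFN-encoded XYDATA/XYPOINTS only (no
  SQZ/DIF/DUP compression).
- The acceptance interval inherits the plug-in normal theory of the method:
  slightly anti-conservative at n = 40 (above), and untested here against
  heavy-tailed error distributions.
- DUPLEX is the simplified pair-alternation variant common in the
  chemometrics literature, not Snee's original farthest-point refinement.
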