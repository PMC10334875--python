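# Methods

## The physical problem and the analysis model

A cell suspension measured between the audio range and ~43.5 GHz shows
three families of dielectric dispersion: a huge MHz-range β process from
interfacial (Maxwell–Wagner) polarization at membranes, intermediate δ-type
relaxations of debated origin below ~1 GHz, and the γ process near 10¹⁰ Hz
from the collective reorientation of water dipoles.  This package targets
the γ process of the *cell interior*.  Its model chain is:

* **Electrode polarization (EP).**  Ion pile-up at the electrodes adds
  ε_EP = A·ω^(−λ) to the measured real permittivity, with ω angular
  frequency, A the amplitude at ω = 1 rad/s and λ ∈ (0, 2.5).  Only the
  functional form is assumed; A and λ are fitted per spectrum.
* **Kramers–Kronig (KK) loss.**  The loss is computed from the real part,
  ε″(ω) = −(2ω/π) P∫₀^∞ [ε′(x) − ε_∞]/(x² − ω²) dx.
  Because dc conductivity contributes σ/(ε₀ω) to the measured ε″ but
  nothing to ε′, the KK-derived loss is conductivity-free — the reason this
  route is used for conductive biological samples at all.
* **Bruggeman–Hanai (BH) mixing.**  For spherical particles at volume
  fraction Φ, ((ε*_s − ε*_p)/(ε*_m − ε*_p))·(ε*_m/ε*_s)^{1/3} = 1 − Φ with
  the ε* = ε′ − iε″ sign convention.  The inverse (cells from
  medium + suspension) is closed-form: with
  B = (1 − Φ)(ε*_s/ε*_m)^{1/3} (principal cube root),
  ε*_p = (B ε*_m − ε*_s)/(B − 1).  Particle–particle interactions and
  membrane (shelled-sphere) structure are deliberately not modelled: both
  matter only far below the γ band analysed here.
* **Relaxation decomposition.**  The loss between 10 MHz and 43.5 GHz is
  fitted as a sum of N Debye terms, N selected by BIC; the two terms with
  τ < 1 ns are the γ pair (bulk-like, subscript 1; hydration, subscript 2),
  summarised by the slow-water fraction Δε₂/(Δε₁+Δε₂) and the retardation
  factor τ₂/τ₁.  Slower terms (β/δ) are nuisance parameters: fitted,
  reported, not interpreted.  A single Cole–Cole shape
  ε_∞ + Δε/(1 + (iωτ)^{1−α}) is available as the broadened one-term
  alternative; at α = 0 it reduces exactly to Debye.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| ε_∞ (KK detrend) | high-frequency permittivity limit | 3.5 | typical for aqueous systems below the far-infrared; only the band edges are sensitive to it |
| KK extrapolation | band continuation | `debye_tail`, 2 decades | truncated KK integrals bias the band edges |
| quadrature density | points/decade of the KK grid | 120 | Simpson error far below data fidelity |
| EP fit band | where A, λ are fitted | lowest 2 decades | EP dominates only there |
| fit band | loss decomposition window | 10 MHz–43.5 GHz | the band the γ analysis is defined on |
| N range | BIC candidates | 1–6 | two γ terms plus up to four slow nuisance terms |
| multi-start | τ initialisations per fit | 16, log-uniform, seeded | replaces hand-tuned initial values |
| τ bounds | per-term relaxation time | 10⁻¹³–1 s | physical range from sub-ps water to electrode-scale processes |
| γ window | τ threshold labelling γ terms | 1 ns | separates water reorientation from β/δ processes |

## Numerical design of the KK transform

The principal value is split exactly into a regularised integrand
[ε′(x) − ε′(ω)]/(x² − ω²), smooth through x = ω, plus
(ε′(ω) − ε_∞)·P∫dx/(x² − ω²) which integrates to a log in closed form.
The regularised part is integrated with Simpson's rule in ln x on a dense
log grid (cubic-spline interpolation of ε′); below the band ε′ is continued
as its low-frequency plateau and above the band by a small causal Debye sum
fitted to the top two decades (value-and-slope matched single term as seed).
The 0→x_lo and x_hi→∞ segments are added analytically; the x_hi→∞ piece
uses the series of atanh(r) − r to avoid catastrophic cancellation at
r = ω/x_hi ≪ 1.  On analytic Debye inputs the transform is accurate to
~2·10⁻⁸ relative at the loss peak.

Two accuracy limits are worth stating plainly:

* **Band-limited continuation.**  The causal continuation of ε′ beyond the
  measured band is not identifiable from band data; for mixture spectra the
  residual ambiguity is ~10⁻² in ε′, which floors the loss accuracy near
  the upper band edge at ~10⁻² absolute even for noiseless input.  This is
  what limits noiseless end-to-end recovery of the slow γ term to a few
  tenths of a percent rather than machine precision.
* **Noise amplification and causal denoising.**  The transform acts like a
  logarithmic derivative, so independent point noise on ε′ maps into loss
  noise of comparable *absolute* size — ruinous in the γ valley where the
  loss is an order of magnitude below ε′.  When the input is detectably
  noisy (robust fourth-difference noise estimate above 10⁻⁴ relative), a
  12-term free-τ Debye-sum regression of ε′ (a discrete relaxation-spectrum
  fit, log residuals) replaces the band values and supplies the
  continuation; clean data pass through untouched.  The regression residual
  reaches the Cramér–Rao scale σ·√(p/N) for the curve, i.e. the estimator
  is close to statistically efficient; the remaining smooth error is the
  irreducible single-sweep limit discussed below.

## Other numerical choices

* **BH forward solver.**  Solved through the cubic
  ε_m u³ − (1−Φ)(ε_m−ε_p)u − ε_p = 0 in u = (ε_s/ε_m)^{1/3}; the physical
  root is the one in the principal cube-root wedge |arg u| < π/3, polished
  by damped Newton to residual < 10⁻¹²; continuation in Φ from the dilute
  limit is the fallback.  A continuity monitor flags branch jumps along
  frequency sweeps.
* **EP fit.**  Plateau estimated at the upper band edge seeds a log–log
  straight-line fit of A, λ; a final least-squares polish on
  log(c + Aω^(−λ)) frees the plateau c, because when EP dominates the whole
  band the edge estimate is itself EP-contaminated.  After subtraction the
  pipeline drops frequencies where the correction exceeded the remaining
  signal: there the residual is fit error amplified by a factor of up to
  10⁴ and carries no sample information.
* **BIC.**  BIC = M ln(RSS/M) + k ln M with k = 2N (loss-only fits carry no
  ε_∞).  The RSS entering BIC is floored at a per-point relative residual
  of 10⁻⁵ — the fidelity of the KK-derived loss — so that residual
  reductions below the data's information content cannot drive model
  selection (they would otherwise make the Gaussian log-likelihood diverge
  on numerically exact fits and over-select N on noiseless data).
* **γ summary fallback.**  γ metrics are taken from the BIC-winning fit;
  when that fit does not contain exactly two terms in the 1 ns window, the
  lowest-BIC candidate that does is used instead (the strict two-term
  requirement lives in `gamma_metrics` itself).
* **Fit parametrisation.**  log₁₀ Δε and log₁₀ τ with bound constraints;
  terms canonicalised ascending in τ; ties in BIC break toward lower RSS,
  then lower N; uniform weights over the log-spaced points.
* **Degenerate inputs.**  Homogeneous suspensions invert to ε_p = ε_m; the
  closed-form inversion raises a dedicated error when B → 1; negative KK
  loss (physically impossible for a conductivity-free spectrum) is clipped
  at zero with a diagnostic when the excursion is large.

## The synthetic generator

The generator emulates a dehydration series of lymphocyte-like cells in
aqueous sucrose at 25 °C, 40 Hz–43.5 GHz, 128 points per decade:

* **Medium** — two-Debye γ process (bulk water Δε 73.2, τ 8.3 ps at zero
  sucrose; hydration fraction 0.16·c and τ₁ slowed by factor (1 + 0.4·c)
  with molarity c), plus dc conductivity σ(c) = 0.05 + 0.02·c S/m added to
  the measured loss only.
* **Cells** — γ pair with τ₁ = 10 ps·(1 + 0.15·t), τ₂ = 5τ₁ (retardation
  held at 5 at every condition), slow fraction 0.08 + 0.14·t where t maps
  0.3→0 and 0.9 M→1; total γ strength shrinking from 62 to 50 with
  dehydration; two slow Debye terms (Δε 1500 at 2 µs, 120 at 30 ns) standing
  in for the membrane β process.
* **Mixing** — BH forward solve at the measured volume fractions
  (0.54, 0.49, 0.45, 0.45 for 0.3–0.9 M); suspension conductivity reduced
  by the insulating cells as σ(1−Φ)^{3/2} (Bruggeman dc limit).
* **Parasitics and noise** — EP with A = 5·10¹⁰, λ = 1.5 on both measured
  real parts; independent multiplicative Gaussian noise (default 1%) on ε′
  and ε″.
* **Osmolarity** — the sucrose table 0.3/0.5/0.7/0.9 M →
  308/518/732/949 mOsm, interpolated monotonically between entries.

All numeric maps are plausibility presets collected at the top of
`synthetic_data.py` and overridable through `SyntheticConfig`; they are not
fitted to any measurement.  What the generator does *not* emulate:
instrument-specific, frequency-dependent noise of a stitched multi-analyzer
sweep; temperature dependence; membrane-permeable solutes; shelled-sphere
membrane physics (the β process is phenomenological).  Passing tests
therefore demonstrate the correctness and stability of the analysis chain
under realistic noise, not the biological accuracy of the presets.

## Statistical precision of a single sweep

With 1% independent noise on ε′ at 128 points/decade, the denoised
suspension curve carries a smooth (decade-scale) uncertainty of ~0.1
absolute; BH extraction roughly doubles it in the cell spectrum.  The
resulting single-sweep standard deviations of the γ summary are ≈0.01 on
the slow-water fraction and ≈0.5–0.7 (10–14%) on the retardation factor at
the isotonic preset, where the slow term holds only 8% of the strength.
These are information limits of the workflow, not fitter shortcomings (the
denoiser sits at the Cramér–Rao scale), and they match the size of the
repeat-measurement error bars such experiments report.  Consequently the
dehydration-sweep test asserts the per-condition slow-water ratios (sd
0.01 against a ±0.02 band) but the no-change claim for the retardation
factor on the pooled estimate across conditions.

## Problem sizes used by the test suite

Unit tests run on 100–300-point spectra.  The Monte-Carlo recovery test
uses 100 seeds × 200 points; the end-to-end sweep analyses four conditions
at the generator's full 1158-point grid with N ∈ 1–6 and 16 starts per fit.
These sizes keep the whole suite within a coffee break on one core while
leaving every statistical assertion comfortably powered.

## Known limitations

* The inverse KK direction (ε′ from ε″) is not implemented.
* ε_∞ is a user-supplied constant, not a fitted parameter; the loss-only
  Debye fits never see it.
* Uncertainty propagation for the cell series uses Φ ± Φ_sd reruns (range,
  not a full covariance); fit-repeatability and Φ contributions are not
  formally combined.
* The EP model is the bare power law; constant-phase-element circuit models
  are out of scope.
* Havriliak–Negami / Cole–Davidson shapes are not provided; the broadened
  alternative is Cole–Cole only.
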