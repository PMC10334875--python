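# dielectrocell

Dielectric-spectroscopy analysis of intracellular water in cell suspensions.

Water inside a living cell is crowded by several hundred mg/ml of
macromolecules, and a measurable fraction of it rotates much more slowly
than bulk water.  Broadband dielectric spectroscopy sees this directly: the
γ relaxation of water near 10¹⁰ Hz splits into a bulk-like component
(relaxation time τ₁ ≈ 10 ps) and a hydration component (τ₂ ≈ 50 ps).  This
package implements the full analysis chain needed to extract those numbers
for the *cells themselves* from measurements of a cell suspension and its
dispersion medium — for example, lymphocyte-like cells osmotically
dehydrated in sucrose solutions, the standard model system for studying
non-permeating cryoprotective agents.

The chain, per condition:

1. **Electrode-polarization removal** — the parasitic low-frequency rise of
   the real permittivity is fitted as ε_EP = A·ω^(−λ) and subtracted
   (`preprocess`).
2. **Kramers–Kronig loss** — the dielectric loss ε″(ω) is computed from the
   real part ε′(ω) through the causality relation
   ε″(ω) = −(2ω/π) P∫₀^∞ [ε′(x) − ε_∞]/(x² − ω²) dx,
   which by construction excludes the ohmic conductivity term σ/(ε₀ω) that
   dominates a measured loss spectrum of a conductive sample
   (`kramers_kronig`).
3. **Bruggeman–Hanai inversion** — the cell-only complex permittivity ε*_p
   is obtained pointwise from the medium ε*_m and suspension ε*_s at cell
   volume fraction Φ through the effective-medium relation
   ((ε*_s − ε*_p)/(ε*_m − ε*_p))·(ε*_m/ε*_s)^{1/3} = 1 − Φ
   (`bh_mixing`; closed-form inverse, cubic/Newton forward solver).
4. **Relaxation decomposition** — the loss is fitted by a sum of Debye terms
   ε″(ω) = Σₙ Δεₙ·ωτₙ/(1 + ω²τₙ²) with the number of terms N chosen by the
   Bayesian information criterion, or by a single Cole–Cole function
   ε* = ε_∞ + Δε/(1 + (iωτ)^{1−α}); the γ process is summarised by the
   slow-water fraction Δε₂/(Δε₁+Δε₂) and the retardation factor τ₂/τ₁
   (`relaxation_fit`).

A first-class synthetic-data generator (`synthetic_data`) builds
ground-truthed medium/cell/suspension spectra — two-Debye γ processes,
slow Maxwell–Wagner-like β terms, dc conductivity, electrode polarization,
seeded multiplicative noise — so the whole chain is verifiable end to end.

## Worked example

```python
import dielectrocell as dc
from dielectrocell.synthetic_data import SyntheticConfig, synthesize_experiment

# isotonic condition (0.3 M sucrose), measured volume fraction 0.54
exp = synthesize_experiment(SyntheticConfig(c_suc=0.3, noise_rel=0.0, seed=1))
cond = dc.Condition(label="isotonic", phi=exp.truth["phi"],
                    medium=exp.medium, suspension=exp.suspension)
report = dc.analyze_condition(cond, fit_opts=dc.FitOptions(seed=3))

g = report.series["cell"].gamma
print(f"slow-water fraction {g.ratio_slow:.4f}   retardation {g.retardation:.3f}")
print(f"truth               {exp.truth['gamma']['ratio_slow']:.4f}"
      f"                {exp.truth['gamma']['retardation']:.3f}")
```

prints

```
slow-water fraction 0.0801   retardation 4.996
truth               0.0800                5.000
```

i.e. for this noiseless isotonic condition the pipeline recovers the cell
interior's hydration-water fraction (8.0% of the γ strength) and the
hydration/bulk retardation factor (5) from nothing but the two "measured"
real-part spectra and Φ.  With the generator's default 1% measurement noise
the recovered slow-water fraction rises monotonically from ≈0.08 to ≈0.22
across the 0.3–0.9 M dehydration sweep while the retardation factor stays
near 5, the behaviour expected of increasingly crowded cytoplasm.

The same chain is scriptable from the shell:

```
dielectrocell synth --c-suc 0.3 --noise 0 --seed 1 --out-dir demo/
dielectrocell ep-subtract demo/suspension.csv --out demo/sus_clean.csv
dielectrocell kk demo/sus_clean.csv --out demo/sus_kk.csv
dielectrocell fit-debye demo/sus_kk.csv --band 1e7:4.35e10
```

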