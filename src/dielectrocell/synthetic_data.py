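"""Ground-truthed synthetic spectra of sucrose media and cell suspensions.

The generator emulates the experimental system the pipeline is built for:
lymphocyte-like cells suspended in aqueous sucrose (0.3 M isotonic to 0.9 M
hypertonic, 25 C), measured from the audio range up to 43.5 GHz.  Each
synthetic experiment is composed forward through the same physics the
analysis inverts:

* a dispersion medium whose gamma process (water orientation, ~1e10 Hz) is a
  sum of two Debye terms — bulk-like water plus sucrose-hydration water —
  with dc conductivity adding an ohmic ``sigma/(eps0 w)`` term to the
  *measured* loss only;
* a cell interior with bulk-like (tau1 ~ 10 ps) and hydration (tau2 ~ 50 ps)
  water, slow-water fraction rising with hypertonicity, plus large slow
  Debye terms standing in for the interfacial (Maxwell-Wagner) beta process
  of membranes;
* Bruggeman-Hanai mixing of cell and medium at volume fraction phi;
* an electrode-polarization power law added to the measured real parts;
* seeded multiplicative Gaussian noise.

All numeric maps below are plausibility presets chosen to reproduce the
qualitative behaviour of such samples (monotone concentration trends, slow
fractions spanning 0.08-0.22, constant retardation factor 5); they are
overridable through :class:`SyntheticConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.constants import epsilon_0

from .bh_mixing import forward_bh
from .preprocess import EPModel
from .relaxation_fit import DebyeModel
from .spectra import PermittivitySpectrum, write_spectrum

# -- preset maps (documented constants, all overridable) -------------------

#: sucrose concentration (M) -> osmolarity (mOsm) for aqueous solutions;
#: sucrose dissociates into a single particle, but non-ideality makes the
#: osmolarity rise faster than 1000*c at high concentration
SUCROSE_OSMOLARITY_TABLE = {0.0: 0.0, 0.3: 308.0, 0.5: 518.0, 0.7: 732.0, 0.9: 949.0}

#: pure water at 25 C: relaxation strength and time of the gamma process
WATER_DELTA_EPS = 73.2
WATER_TAU_S = 8.3e-12

EPS_INF = 3.5

#: medium presets (functions of sucrose molarity c)
MEDIUM_TAU1 = lambda c: WATER_TAU_S * (1.0 + 0.40 * c)        # noqa: E731
#: sucrose-hydration fraction of the medium gamma strength; kept well below
#: the intracellular slow fraction at every condition (cells are the more
#: crowded phase, so their hydration share must stay the larger one)
MEDIUM_SLOW_FRACTION = lambda c: 0.16 * c                      # noqa: E731
MEDIUM_TOTAL_DELTA_EPS = lambda c: WATER_DELTA_EPS - 10.0 * c  # noqa: E731
MEDIUM_RETARDATION = 5.0
MEDIUM_SIGMA_DC = lambda c: 0.05 + 0.02 * c                    # noqa: E731  (S/m)

#: cell presets (functions of sucrose molarity of the surrounding medium)
CELL_TAU1 = lambda c: 10e-12 * (1.0 + 0.15 * _t(c))            # noqa: E731
CELL_RETARDATION = 5.0
CELL_SLOW_RATIO = lambda c: 0.08 + 0.14 * _t(c)                # noqa: E731
CELL_TOTAL_DELTA_EPS = lambda c: 62.0 - 12.0 * _t(c)           # noqa: E731
#: slow Debye stand-ins for the beta process (membrane interfacial
#: polarization); taus are far above the 1 ns gamma window
CELL_BETA_TERMS = ((1500.0, 2e-6), (120.0, 3e-8))

#: electrode polarization default (A at omega = 1 rad/s, exponent)
DEFAULT_EP = EPModel(amplitude_A=5e10, exponent_lambda=1.5)

#: measured volume fractions per condition in this kind of experiment
DEFAULT_PHI = {0.3: 0.54, 0.5: 0.49, 0.7: 0.45, 0.9: 0.45}
DEFAULT_PHI_SD = {0.3: 0.03, 0.5: 0.01, 0.7: 0.03, 0.9: 0.01}


def _t(c_suc: float) -> float:
    """Map molarity onto the 0-1 dehydration coordinate (0.3 M -> 0, 0.9 M -> 1)."""
    return np.clip((c_suc - 0.3) / 0.6, 0.0, 1.0)


def osmolarity_of_sucrose(c_suc: float) -> float:
    """Osmolarity (mOsm) of an aqueous sucrose solution of molarity ``c_suc``.

    Exact table lookup at 0, 0.3, 0.5, 0.7 and 0.9 M; monotone linear
    interpolation between table points, linear extrapolation above 0.9 M.
    """
    if c_suc < 0:
        raise ValueError("sucrose concentration cannot be negative")
    cs = np.array(sorted(SUCROSE_OSMOLARITY_TABLE))
    os_ = np.array([SUCROSE_OSMOLARITY_TABLE[c] for c in cs])
    if c_suc > cs[-1]:
        slope = (os_[-1] - os_[-2]) / (cs[-1] - cs[-2])
        return float(os_[-1] + slope * (c_suc - cs[-1]))
    return float(np.interp(c_suc, cs, os_))


def make_medium_model(c_suc: float) -> tuple[DebyeModel, float]:
    """Two-term gamma model of the sucrose medium plus its dc conductivity.

    At ``c_suc = 0`` the hydration term vanishes and the model reduces to a
    single bulk-water term.  Both the slow fraction and tau1 grow with
    concentration, shifting the loss peak to lower frequency.
    """
    if c_suc < 0:
        raise ValueError("sucrose concentration cannot be negative")
    tau1 = MEDIUM_TAU1(c_suc)
    total = MEDIUM_TOTAL_DELTA_EPS(c_suc)
    f2 = MEDIUM_SLOW_FRACTION(c_suc)
    if f2 <= 0:
        terms = ((total, tau1),)
    else:
        terms = ((total * (1 - f2), tau1), (total * f2, MEDIUM_RETARDATION * tau1))
    return DebyeModel(terms=terms, eps_inf=EPS_INF), float(MEDIUM_SIGMA_DC(c_suc))


def make_cell_model(condition: "str | float", include_beta: bool = True) -> DebyeModel:
    """Gamma (+ optional beta) model of the cell interior.

    ``condition`` is either a sucrose molarity or one of the labels
    ``"isotonic"`` (0.3 M) / ``"hypertonic"`` (0.9 M).  The slow-water ratio
    runs linearly from 0.08 (isotonic) to 0.22 (0.9 M); the retardation
    factor tau2/tau1 is held at 5 at every condition.
    """
    labels = {"isotonic": 0.3, "hypertonic": 0.9}
    c = labels.get(condition, condition)
    if not isinstance(c, (int, float)):
        raise ValueError(f"unknown condition {condition!r}")
    tau1 = CELL_TAU1(c)
    r = CELL_SLOW_RATIO(c)
    total = CELL_TOTAL_DELTA_EPS(c)
    terms = [(total * (1 - r), tau1), (total * r, CELL_RETARDATION * tau1)]
    if include_beta:
        terms += list(CELL_BETA_TERMS)
    return DebyeModel(terms=tuple(terms), eps_inf=EPS_INF)


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions of one synthetic experiment.

    Defaults reproduce the isotonic (0.3 M) condition at its measured volume
    fraction with 1% multiplicative noise on a 40 Hz - 43.5 GHz sweep.
    Model overrides (``gamma_medium``, ``sigma_dc``, ...) replace the preset
    maps when given.
    """

    c_suc: float = 0.3
    phi: float | None = None
    sigma_dc: float | None = None
    gamma_medium: DebyeModel | None = None
    gamma_cell: DebyeModel | None = None
    beta_terms: tuple[tuple[float, float], ...] = CELL_BETA_TERMS
    ep: EPModel = DEFAULT_EP
    noise_rel: float = 0.01
    n_points: int | None = None   # default: 128 points per decade of span
    f_min: float = 40.0
    f_max: float = 43.5e9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c_suc < 0 or self.c_suc > 1.0:
            raise ValueError("c_suc must lie in [0, 1] M")
        if self.phi is not None and not 0.0 < self.phi < 1.0:
            raise ValueError("phi must lie in (0, 1)")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be >= 0")
        if any(t <= 1e-9 for _, t in self.beta_terms):
            raise ValueError("beta-process taus must exceed 1 ns")

    @property
    def n_points_effective(self) -> int:
        if self.n_points is not None:
            return self.n_points
        span = np.log10(self.f_max / self.f_min)
        return int(np.ceil(128.0 * span)) + 1

    @property
    def phi_effective(self) -> float:
        if self.phi is not None:
            return self.phi
        cs = sorted(DEFAULT_PHI)
        return float(np.interp(self.c_suc, cs, [DEFAULT_PHI[c] for c in cs]))


@dataclass(frozen=True)
class SyntheticExperiment:
    """Measured-like spectra plus complete ground truth."""

    medium: PermittivitySpectrum
    suspension: PermittivitySpectrum
    truth: dict

    @property
    def cell_model(self) -> DebyeModel:
        return self.truth["cell_model"]

    @property
    def medium_model(self) -> DebyeModel:
        return self.truth["medium_model"]


def synthesize_experiment(cfg: SyntheticConfig) -> SyntheticExperiment:
    """Compose a medium/suspension pair with full ground truth.

    The relaxational (conductivity-free) complex spectra of medium and cell
    are mixed pointwise through the Bruggeman-Hanai forward solver; the
    ohmic term ``sigma/(eps0 w)`` is then added to the measured losses only
    (medium conductivity, and the suspension's reduced by the insulating
    cells as ``sigma (1-phi)^{3/2}``, the Bruggeman dc limit), the
    electrode-polarization power law is added to the measured real parts,
    and multiplicative Gaussian noise is applied last.
    """
    phi = cfg.phi_effective
    freq = np.geomspace(cfg.f_min, cfg.f_max, cfg.n_points_effective)
    w = 2.0 * np.pi * freq

    med_model, sigma_preset = (cfg.gamma_medium, None) if cfg.gamma_medium \
        else make_medium_model(cfg.c_suc)
    if cfg.gamma_medium is not None:
        sigma_preset = MEDIUM_SIGMA_DC(cfg.c_suc)
    sigma = cfg.sigma_dc if cfg.sigma_dc is not None else sigma_preset

    if cfg.gamma_cell is not None:
        cell_terms = cfg.gamma_cell.terms + tuple(cfg.beta_terms)
        cell_model = DebyeModel(terms=cell_terms, eps_inf=cfg.gamma_cell.eps_inf)
    else:
        gamma_only = make_cell_model(cfg.c_suc, include_beta=False)
        cell_model = DebyeModel(terms=gamma_only.terms + tuple(cfg.beta_terms),
                                eps_inf=gamma_only.eps_inf)

    eps_med = med_model.eps_complex(freq)
    eps_cell = cell_model.eps_complex(freq)
    eps_sus = forward_bh(eps_cell, eps_med, phi)

    ohm_med = sigma / (epsilon_0 * w)
    ohm_sus = sigma * (1.0 - phi) ** 1.5 / (epsilon_0 * w)
    ep_term = cfg.ep.eval(freq)

    rng = np.random.default_rng(cfg.seed)

    def noisy(x):
        if cfg.noise_rel == 0:
            return np.asarray(x, dtype=float)
        return x * (1.0 + cfg.noise_rel * rng.standard_normal(x.shape))

    label = f"c_suc={cfg.c_suc:g}M"
    medium = PermittivitySpectrum(
        freq_hz=freq,
        eps_real=noisy(np.real(eps_med) + ep_term),
        eps_imag=noisy(-np.imag(eps_med) + ohm_med),
        label=f"medium {label}", provenance="synthetic")
    suspension = PermittivitySpectrum(
        freq_hz=freq,
        eps_real=noisy(np.real(eps_sus) + ep_term),
        eps_imag=noisy(-np.imag(eps_sus) + ohm_sus),
        label=f"suspension {label}", provenance="synthetic")

    gamma = sorted(cell_model.terms, key=lambda dt: dt[1])[:2]
    (d1, t1), (d2, t2) = gamma
    truth = {
        "config": cfg,
        "phi": phi,
        "sigma_dc": sigma,
        "osmolarity_mosm": osmolarity_of_sucrose(cfg.c_suc),
        "medium_model": med_model,
        "cell_model": cell_model,
        "suspension_relaxational": PermittivitySpectrum(
            freq_hz=freq, eps_real=np.real(eps_sus), eps_imag=-np.imag(eps_sus),
            label=f"suspension(truth) {label}", provenance="synthetic"),
        "medium_relaxational": PermittivitySpectrum(
            freq_hz=freq, eps_real=np.real(eps_med), eps_imag=-np.imag(eps_med),
            label=f"medium(truth) {label}", provenance="synthetic"),
        "cell_spectrum": PermittivitySpectrum(
            freq_hz=freq, eps_real=np.real(eps_cell), eps_imag=-np.imag(eps_cell),
            label=f"cell(truth) {label}", provenance="synthetic"),
        "gamma": {"delta_eps_1": d1, "tau_1": t1, "delta_eps_2": d2, "tau_2": t2,
                  "ratio_slow": d2 / (d1 + d2), "retardation": t2 / t1},
    }
    return SyntheticExperiment(medium=medium, suspension=suspension, truth=truth)


def write_experiment(exp: SyntheticExperiment, out_dir: "str | Path") -> Path:
    """Write medium.csv, suspension.csv and truth.json into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_spectrum(exp.medium, out_dir / "medium.csv")
    write_spectrum(exp.suspension, out_dir / "suspension.csv")
    t = exp.truth
    serializable = {
        "phi": t["phi"], "sigma_dc": t["sigma_dc"],
        "osmolarity_mosm": t["osmolarity_mosm"],
        "c_suc": t["config"].c_suc, "seed": t["config"].seed,
        "noise_rel": t["config"].noise_rel,
        "medium_model": {"eps_inf": t["medium_model"].eps_inf,
                         "terms": list(t["medium_model"].terms)},
        "cell_model": {"eps_inf": t["cell_model"].eps_inf,
                       "terms": list(t["cell_model"].terms)},
        "gamma": t["gamma"],
    }
    (out_dir / "truth.json").write_text(json.dumps(serializable, indent=1))
    return out_dir
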