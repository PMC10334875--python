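"""Electrode-polarization fitting and subtraction.

Ion accumulation at the electrode interfaces inflates the measured real
permittivity of conductive samples at low frequency.  The parasitic rise is
modelled as a power law in angular frequency,

    eps_EP(w) = A * w**(-lambda),

and removed by subtraction.  ``A`` and ``lambda`` are fitted in log-log space
on a low-frequency band where the polarization dominates, after detrending a
sample plateau estimated at the upper band edge; plateau and power law are
refined alternately for a few rounds since each biases the other's estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .spectra import PermittivitySpectrum

logger = logging.getLogger(__name__)

LAMBDA_BOUNDS = (0.0, 2.5)
#: detrended values must exceed this fraction of the plateau to enter the fit
DOMINANCE_FLOOR = 0.02
#: fitted amplitudes giving an EP below this fraction of the plateau anywhere
#: in the band are reported as negligible
NEGLIGIBLE_REL = 1e-6


class EPFitError(RuntimeError):
    """Electrode polarization is not the dominant term in the chosen band."""


@dataclass(frozen=True)
class EPModel:
    """Power-law electrode-polarization term ``A * omega**(-lambda)``.

    ``amplitude_A`` is the (dimensionless) permittivity contribution at
    ``omega = 1 rad/s``; ``negligible`` flags a null fit.
    """

    amplitude_A: float
    exponent_lambda: float
    negligible: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude_A) or self.amplitude_A < 0:
            raise ValueError("amplitude_A must be finite and >= 0")
        if not LAMBDA_BOUNDS[0] < self.exponent_lambda < LAMBDA_BOUNDS[1]:
            if not (self.negligible or self.amplitude_A == 0.0):
                raise ValueError(
                    f"exponent_lambda must lie in {LAMBDA_BOUNDS}, got "
                    f"{self.exponent_lambda}"
                )

    def eval(self, freq_hz) -> np.ndarray:
        w = 2.0 * np.pi * np.asarray(freq_hz, dtype=float)
        return self.amplitude_A * w ** (-self.exponent_lambda)


def default_ep_band(spec: PermittivitySpectrum) -> tuple[float, float]:
    """Lowest two decades of the spectrum, where the polarization dominates."""
    return float(spec.freq_hz[0]), float(spec.freq_hz[0] * 100.0)


def fit_electrode_polarization(spec: PermittivitySpectrum,
                               band: tuple[float, float] | None = None, *,
                               fix_lambda: float | None = None) -> EPModel:
    """Fit ``A`` and ``lambda`` on a low-frequency band.

    The sample plateau is first estimated from the upper band edge (top
    half-decade median) and subtracted; a straight-line fit in log-log space
    then gives starting values for ``A`` and ``lambda``.  Because the edge
    estimate still contains some EP, the line is polished by least squares
    on ``log(c + A w**-lambda)`` against ``log eps'`` with the plateau ``c``
    as a free nuisance parameter (log residuals weight the whole
    multi-decade dynamic range of the rise evenly).  Returns a
    negligible-EP model when the detrended signal never rises above the
    dominance floor.
    """
    if band is None:
        band = default_ep_band(spec)
    banded = spec.band(*band)
    if len(banded) < 5:
        raise EPFitError(f"need >= 5 points in band {band}, found {len(banded)}")
    w = 2.0 * np.pi * banded.freq_hz
    er = banded.eps_real
    if np.any(er <= 0):
        raise EPFitError("non-positive eps' in EP band")

    top = banded.freq_hz >= band[1] / np.sqrt(10.0)
    if not np.any(top):
        top = np.zeros(len(banded), bool)
        top[-max(3, len(banded) // 10):] = True
    plateau = float(np.median(er[top]))

    detr = er - plateau
    mask = detr > max(DOMINANCE_FLOOR * abs(plateau), 1e-12)
    if np.sum(mask) < 5:
        logger.info("EP negligible in band %s (plateau %.4g)", band, plateau)
        return EPModel(amplitude_A=0.0, exponent_lambda=1.0, negligible=True)
    x, y = np.log(w[mask]), np.log(detr[mask])
    if fix_lambda is not None:
        lam0 = float(fix_lambda)
        a0 = float(np.exp(np.mean(y + lam0 * x)))
    else:
        slope, intercept = np.polyfit(x, y, 1)
        lam0, a0 = -float(slope), float(np.exp(intercept))
    lam0 = float(np.clip(lam0, 0.05, LAMBDA_BOUNDS[1] - 0.05))

    c_hi = float(er.min())  # plateau cannot exceed the smallest eps' in band

    def residual(theta):
        la, lam, c = theta
        lam = lam0 if fix_lambda is not None else lam
        model = c + np.exp(la) * w ** (-lam)
        return np.log(model) - np.log(er)

    sol = least_squares(
        residual, [np.log(max(a0, 1e-300)), lam0, min(plateau, c_hi) * 0.999],
        bounds=([-700.0, LAMBDA_BOUNDS[0] + 1e-6, 0.0],
                [700.0, LAMBDA_BOUNDS[1] - 1e-6, c_hi]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    a, lam = float(np.exp(sol.x[0])), float(sol.x[1])
    if fix_lambda is not None:
        lam = lam0
    if not np.isfinite(a):
        raise EPFitError("power-law fit failed; EP not dominant in chosen band")
    if not LAMBDA_BOUNDS[0] < lam < LAMBDA_BOUNDS[1]:
        raise EPFitError(f"fitted exponent {lam:.3g} outside {LAMBDA_BOUNDS}")
    if np.max(a * w ** (-lam)) < NEGLIGIBLE_REL * abs(plateau):
        return EPModel(amplitude_A=a, exponent_lambda=lam, negligible=True)
    return EPModel(amplitude_A=a, exponent_lambda=lam)


def subtract_electrode_polarization(spec: PermittivitySpectrum,
                                    ep: EPModel) -> PermittivitySpectrum:
    """Subtract ``A w**(-lambda)`` from the real part, pointwise."""
    if ep.amplitude_A == 0.0 or ep.negligible:
        return spec
    er = spec.eps_real - ep.eval(spec.freq_hz)
    frac_low = float(np.mean(er < 1.0))
    if frac_low > 0.05:
        logger.warning(
            "EP subtraction drove eps' below 1 on %.0f%% of points — over-subtraction?",
            100.0 * frac_low,
        )
    return spec.with_values(eps_real=er)


def trim_ep_dominated(spec: PermittivitySpectrum, ep: EPModel,
                      max_ratio: float = 1.0) -> PermittivitySpectrum:
    """Drop low frequencies where the subtracted EP exceeded the signal.

    Where ``A w**-lambda`` was ``max_ratio`` times larger than the remaining
    ``eps'``, the subtraction residual (fit error times a huge correction,
    or measurement noise scaled by the EP magnitude) dominates what is left;
    such points carry no usable sample information.  The cut is a contiguous
    prefix so the grid stays log-regular.
    """
    if ep.negligible or ep.amplitude_A == 0.0:
        return spec
    correction = ep.eval(spec.freq_hz)
    ok = correction <= max_ratio * np.maximum(spec.eps_real, 1.0)
    bad = np.nonzero(~ok)[0]
    if bad.size == 0:
        return spec
    start = int(bad[-1]) + 1
    if start >= len(spec) - 4:
        raise EPFitError("electrode polarization dominates the entire spectrum")
    logger.info("trimming %d EP-dominated low-frequency points (f < %.3g Hz)",
                start, spec.freq_hz[start])
    ei = spec.eps_imag[start:] if spec.eps_imag is not None else None
    return PermittivitySpectrum(freq_hz=spec.freq_hz[start:],
                                eps_real=spec.eps_real[start:], eps_imag=ei,
                                temperature_c=spec.temperature_c,
                                label=spec.label, provenance=spec.provenance)
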