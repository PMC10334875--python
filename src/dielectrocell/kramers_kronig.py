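"""Kramers-Kronig computation of dielectric loss from the real permittivity.

For a causal, passive dielectric the loss is fixed by the dispersion of the
real part:

    eps''(w) = -(2 w / pi) P-int_0^inf [eps'(x) - eps_inf] / (x^2 - w^2) dx

(``w``, ``x`` angular frequencies; ``P`` a Cauchy principal value).  Because
only ``eps'`` enters, the result excludes the ohmic term ``sigma/(eps0 w)``
that dc conductivity adds to a *measured* loss spectrum — that exclusion is
the whole point of using the transform on conductive biological samples.

Numerics: the principal value is split into a regularised part,

    [eps'(x) - eps'(w)] / (x^2 - w^2),

which is smooth through ``x = w`` and integrated with Simpson's rule on a
dense log grid, plus the analytically integrable remainder
``(eps'(w) - eps_inf) * P-int dx/(x^2 - w^2)``.  Band truncation is handled
by optional Debye-tail extrapolation: below the band ``eps'`` is continued
as the low-frequency plateau, above the band by a small causal Debye sum
matched to the edge, and the 0 -> x_lo and x_hi -> inf segments are added
in closed form.  Noisy inputs are optionally denoised by a causal
relaxation-spectrum regression before the transform (see KKOptions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .spectra import PermittivitySpectrum

logger = logging.getLogger(__name__)


class KKValidationError(ValueError):
    pass


class KKQuadratureError(RuntimeError):
    pass


@dataclass(frozen=True)
class KKOptions:
    """Options for the loss transform.

    Parameters
    ----------
    eps_inf_estimate
        High-frequency permittivity limit used to detrend ``eps'``.  Default
        3.5, a typical value for aqueous systems below the far-infrared; it
        must not exceed the smallest observed ``eps'``.
    extrapolation
        ``"debye_tail"`` (default) continues the band analytically on both
        sides before integrating; ``"none"`` truncates at the band edges,
        which biases the loss near those edges.
    n_extrap_decades
        Width of the numerical extension on each side (decades).
    quadrature_points_per_decade
        Density of the trapezoid grid.
    """

    eps_inf_estimate: float = 3.5
    extrapolation: str = "debye_tail"
    n_extrap_decades: float = 2.0
    quadrature_points_per_decade: int = 120
    #: Denoising of eps' before the transform.  The transform acts like a
    #: logarithmic derivative, so point noise on eps' maps into loss noise
    #: of comparable absolute size — ruinous where the loss is far smaller
    #: than eps' (the gamma valley).  "auto" (default) estimates the point
    #: noise from robust fourth differences and, when the data are visibly
    #: noisy, regresses a dense causal Debye sum onto eps' (a discrete
    #: relaxation-spectrum fit) whose evaluation replaces the noisy band
    #: values and supplies the high-frequency continuation; clean data pass
    #: through untouched.  "causal" forces the regression, "savgol" applies
    #: only local Savitzky-Golay smoothing, "none" disables everything.
    denoise: str = "auto"
    #: window for the "savgol" mode ("auto": about one eighth of a decade)
    presmooth_window: "int | str" = "auto"

    def __post_init__(self) -> None:
        if self.eps_inf_estimate < 1.0:
            raise KKValidationError("eps_inf_estimate must be >= 1")
        if self.extrapolation not in ("none", "debye_tail"):
            raise KKValidationError("extrapolation must be 'none' or 'debye_tail'")
        if self.n_extrap_decades < 0:
            raise KKValidationError("n_extrap_decades must be >= 0")
        if self.quadrature_points_per_decade < 8:
            raise KKValidationError("need at least 8 quadrature points per decade")
        if not (self.presmooth_window == "auto"
                or (isinstance(self.presmooth_window, int)
                    and self.presmooth_window >= 0)):
            raise KKValidationError("presmooth_window must be 'auto' or an int >= 0")
        if self.denoise not in ("auto", "causal", "savgol", "none"):
            raise KKValidationError(
                "denoise must be one of 'auto', 'causal', 'savgol', 'none'")


def _pv_log(x: np.ndarray | float, w: np.ndarray | float) -> np.ndarray:
    """Antiderivative of 1/(x^2 - w^2): (1/2w) ln|(x - w)/(x + w)|."""
    return np.log(np.abs((x - w) / (x + w))) / (2.0 * w)


def _match_debye_tail(w_band: np.ndarray, er_band: np.ndarray,
                      eps_inf: float) -> tuple[np.ndarray, np.ndarray]:
    """Debye terms continuing ``eps'`` beyond the upper band edge.

    First a single Debye term is matched in closed form to the edge value
    and log-slope of ``v = eps' - eps_inf``: a Debye relaxation satisfies
    ``g = -dln(v)/dln(w) = 2u/(1+u)`` with ``u = (w tau)^2``, so
    ``u = g/(2-g)``.  That term then seeds a least-squares fit of a small
    causal Debye sum to ``v`` over the top two decades of the band, whose
    only role is to continue the spectrum beyond the edge — a partly
    relaxed mixture is captured far better than by a single shape.  The
    continuation of band-limited data is not fully identifiable; the
    residual ambiguity (about 1e-2 in ``eps'`` for typical suspension
    spectra) sets the accuracy floor of the transform near the upper band
    edge.  Degenerate edges (no dispersion, g <= 0) fall back to a flat
    continuation.

    Returns arrays (delta_eps_k, tau_k); evaluate the continuation as
    ``eps_inf + sum_k delta_eps_k / (1 + (x tau_k)^2)``.
    """
    w_edge = w_band[-1]
    top = w_band >= w_edge / np.sqrt(10.0)
    if np.sum(top) < 3:
        top = np.zeros(w_band.size, bool)
        top[-3:] = True
    v = er_band[top] - eps_inf
    v_edge = max(er_band[-1] - eps_inf, 0.0)
    if v_edge <= 1e-9 or np.any(v <= 0):
        return np.array([v_edge]), np.array([0.0])
    slope = np.polyfit(np.log(w_band[top]), np.log(v), 1)[0]
    g = -float(slope)
    if g <= 1e-6:
        return np.array([v_edge]), np.array([0.0])
    g = min(g, 2.0 - 1e-9)
    u = g / (2.0 - g)
    tau1 = np.sqrt(u) / w_edge
    d1 = v_edge * (1.0 + u)

    # refinement: fit a small Debye sum to eps' over the top two decades and
    # use it (only) to continue the spectrum beyond the edge; the in-band
    # quadrature still consumes the data directly
    wide = w_band >= w_edge / 100.0
    ww, vv = w_band[wide], er_band[wide] - eps_inf
    if ww.size < 8 or np.any(vv <= 0):
        return np.array([d1]), np.array([tau1])

    def resid(theta):
        d = 10.0 ** theta[0::2]
        t = 10.0 ** theta[1::2]
        model = np.sum(d[None, :] / (1.0 + (ww[:, None] * t[None, :]) ** 2), axis=1)
        return np.log(model) - np.log(vv)

    tau1s = max(tau1, 1e-14)
    best_d = np.array([d1])
    best_t = np.array([tau1])
    best_rss = float(np.sum((np.log(d1 / (1.0 + (ww * tau1) ** 2))
                             - np.log(vv)) ** 2))
    for k in (2, 3):
        taus0 = np.geomspace(0.3 / w_edge, 100.0 / w_edge, k)
        theta0 = np.empty(2 * k)
        theta0[0::2] = np.log10(max(float(vv[0]) / k, 1e-6 * v_edge))
        theta0[1::2] = np.log10(taus0)
        theta0[0] = np.log10(max(0.8 * d1, 1e-6 * v_edge))
        theta0[1] = np.log10(tau1s)
        lo = [np.log10(1e-8 * v_edge), -14.0] * k
        hi = [np.log10(1e4 * float(vv[0])), np.log10(1e3 / ww[0])] * k
        sol = least_squares(resid, np.clip(theta0, np.array(lo) + 1e-9,
                                           np.array(hi) - 1e-9),
                            bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        rss = float(np.sum(sol.fun ** 2))
        if rss < best_rss:
            best_rss = rss
            best_d, best_t = 10.0 ** sol.x[0::2], 10.0 ** sol.x[1::2]
    return best_d, best_t


def estimate_point_noise(er: np.ndarray) -> float:
    """Robust absolute point-noise estimate of a smooth sampled curve.

    Fourth central differences annihilate cubics, so on a densely sampled
    relaxation curve they contain essentially only noise; for Gaussian noise
    their variance is 70 sigma^2, and the median of absolute values divides
    by 0.6745 to reach sigma.
    """
    if er.size < 9:
        return 0.0
    d4 = er[4:] - 4 * er[3:-1] + 6 * er[2:-2] - 4 * er[1:-3] + er[:-4]
    return float(np.median(np.abs(d4)) / (0.6745 * np.sqrt(70.0)))


def _fit_causal_model(w: np.ndarray, v: np.ndarray,
                      n_terms: int = 12) -> tuple[np.ndarray, np.ndarray] | None:
    """Regress a dense Debye sum onto the detrended real part ``v``.

    A discrete relaxation-spectrum fit: ``n_terms`` relaxations with free
    strengths and times, log-residuals so every decade of the curve counts
    equally.  Returns (strengths, times) or None when ``v`` is not strictly
    positive (no resolvable dispersion).
    """
    if np.any(v <= 0) or v.size < 4 * n_terms:
        return None
    taus0 = np.geomspace(0.1 / w[-1], 10.0 / w[0], n_terms)
    theta0 = np.empty(2 * n_terms)
    theta0[0::2] = np.log10(max(float(v[0]), 1e-3) / n_terms)
    theta0[1::2] = np.log10(taus0)
    lo = np.tile([-8.0, np.log10(0.01 / w[-1])], n_terms)
    hi = np.tile([6.0, np.log10(100.0 / w[0])], n_terms)

    def resid(theta):
        d = 10.0 ** theta[0::2]
        t = 10.0 ** theta[1::2]
        model = np.sum(d[None, :] / (1.0 + (w[:, None] * t[None, :]) ** 2), axis=1)
        return np.log(model) - np.log(v)

    sol = least_squares(resid, np.clip(theta0, lo + 1e-9, hi - 1e-9),
                        bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12)
    return 10.0 ** sol.x[0::2], 10.0 ** sol.x[1::2]


def _presmooth(er: np.ndarray, f: np.ndarray, window: "int | str") -> np.ndarray:
    """Savitzky-Golay filter of eps' in log-frequency (see KKOptions)."""
    if window == 0:
        return er
    ppd = (f.size - 1) / np.log10(f[-1] / f[0])
    if window == "auto":
        if ppd < 64:        # sparse grid: bias would exceed the noise gain
            return er
        window = int(round(ppd / 8.0)) | 1
    window = max(int(window) | 1, 5)
    if window >= er.size:
        return er
    return savgol_filter(er, window, 3)


def kk_loss_from_real(spec: PermittivitySpectrum,
                      opts: KKOptions | None = None) -> PermittivitySpectrum:
    """Compute ``eps''`` from ``eps'`` by the principal-value transform.

    Returns a spectrum on the same frequency grid with ``eps_imag`` filled in
    and provenance ``"kk"``.  The output contains no conductivity term by
    construction: any ``eps_imag`` present on the input is ignored.
    """
    opts = opts or KKOptions()
    f = spec.freq_hz
    if np.log10(f[-1] / f[0]) < 3.0 - 1e-9:
        raise KKValidationError("spectrum must span at least 3 decades for the transform")
    if opts.eps_inf_estimate > spec.eps_real.min() + 0.5:
        raise KKValidationError(
            f"eps_inf_estimate {opts.eps_inf_estimate:g} exceeds the observed "
            f"eps' minimum {spec.eps_real.min():g}"
        )

    eps_inf = opts.eps_inf_estimate
    w_band = 2.0 * np.pi * f                     # angular band grid
    er_band = spec.eps_real
    causal_model = None
    if opts.denoise in ("auto", "causal"):
        noisy = estimate_point_noise(er_band) > 1e-4 * float(np.median(np.abs(er_band)))
        if opts.denoise == "causal" or noisy:
            causal_model = _fit_causal_model(w_band, er_band - eps_inf)
            if causal_model is not None:
                d_cm, t_cm = causal_model
                er_band = eps_inf + np.sum(
                    d_cm[None, :] / (1.0 + (w_band[:, None] * t_cm[None, :]) ** 2),
                    axis=1)
                logger.info("KK: causal denoising applied (%d terms, point noise "
                            "%.3g)", d_cm.size, estimate_point_noise(spec.eps_real))
    elif opts.denoise == "savgol":
        er_band = _presmooth(er_band, f, opts.presmooth_window)

    # numerical quadrature grid (angular), optionally extended
    if opts.extrapolation == "debye_tail":
        d = opts.n_extrap_decades
    else:
        d = 0.0
    x_lo = w_band[0] / 10.0 ** d
    x_hi = w_band[-1] * 10.0 ** d
    span = np.log10(x_hi / x_lo)
    n_quad = max(int(np.ceil(span * opts.quadrature_points_per_decade)) + 1, 16)
    x = np.geomspace(x_lo, x_hi, n_quad)

    # eps' on the quadrature grid: interpolate in-band (linear in log w),
    # plateau below, Debye tail above matched to the band-edge value and
    # log-slope (a pure 1/x^2 anchor is biased when the top relaxation is
    # only partly relaxed at the band edge)
    logw = np.log(w_band)
    below = x < w_band[0]
    above = x > w_band[-1]
    inband = ~(below | above)
    er_x = np.empty_like(x)
    if w_band.size >= 4:
        er_x[inband] = CubicSpline(logw, er_band)(np.log(x[inband]))
    else:
        er_x[inband] = np.interp(np.log(x[inband]), logw, er_band)
    er_x[below] = er_band[0]
    if causal_model is not None:
        d_tail, tau_tail = causal_model
    else:
        d_tail, tau_tail = _match_debye_tail(w_band, er_band, eps_inf)
    er_x[above] = eps_inf + np.sum(
        d_tail[None, :] / (1.0 + (x[above, None] * tau_tail[None, :]) ** 2), axis=1)
    # beyond the extended grid the matched tail is in its 1/x^2 regime
    # (or negligible); anchor the analytic infinity tail at x_hi
    c_tail = (er_x[-1] - eps_inf) * x_hi ** 2

    # local derivative of eps' wrt x on the quadrature grid (for the
    # removable singularity of the regularised integrand)
    der_x = np.gradient(er_x, x)

    # vectorised over evaluation points: rows = w_j, cols = x
    w_col = w_band[:, None]
    er_w = er_band[:, None]
    denom = x[None, :] ** 2 - w_col ** 2
    num = er_x[None, :] - er_w
    with np.errstate(divide="ignore", invalid="ignore"):
        h = num / denom
    # points numerically on the singularity: use the limit eps''(w)/(2w) -> d eps'/dx / (2w)
    sing = np.abs(x[None, :] - w_col) < 1e-9 * w_col
    if np.any(sing):
        rows, cols = np.nonzero(sing)
        h[rows, cols] = der_x[cols] / (2.0 * w_band[rows])
    if not np.all(np.isfinite(h)):
        raise KKQuadratureError("non-finite regularised integrand; grid too sparse")

    # integrate in u = ln x (uniform spacing) with Simpson's rule
    du = np.log(x[1] / x[0])
    integral = simpson(h * x[None, :], dx=du, axis=1)

    # analytic principal value of the remainder over [x_lo, x_hi]
    integral += (er_band - eps_inf) * (_pv_log(x_hi, w_band) - _pv_log(x_lo, w_band))

    if opts.extrapolation == "debye_tail":
        # 0 -> x_lo with eps' = plateau (no singularity: x_lo < w for all w in band)
        integral += (er_band[0] - eps_inf) * (_pv_log(x_lo, w_band) - 0.0)
        # x_hi -> inf with eps' - eps_inf = c_tail / x^2:
        #   int_xhi^inf dx/(x^2 (x^2-w^2)) = (atanh(r) - r)/w^3,  r = w/x_hi.
        # atanh(r) - r cancels catastrophically for small r; use its series.
        r = w_band / x_hi
        small = r < 1e-3
        atr = np.where(small,
                       r ** 3 / 3.0 + r ** 5 / 5.0 + r ** 7 / 7.0,
                       np.arctanh(np.clip(r, None, 1.0 - 1e-15)) - r)
        integral += c_tail * atr / w_band ** 3

    loss = -(2.0 * w_band / np.pi) * integral
    # a conductivity-free loss is physically non-negative; negative
    # excursions are quadrature residue or input noise mapped through the
    # transform, and are clipped to zero (with a diagnostic when large)
    neg = float(loss.min())
    if neg < -0.02 * max(float(loss.max()), 1.0):
        logger.warning("KK loss dips to %.3g before clipping — noisy input?", neg)
    loss = np.clip(loss, 0.0, None)
    # return the (possibly smoothed) real part alongside the derived loss so
    # downstream consumers see a causally consistent pair
    return spec.with_values(eps_real=er_band, eps_imag=loss, provenance="kk")
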