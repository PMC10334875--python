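"""Bruggeman-Hanai effective-medium relation for concentrated cell suspensions.

The Hanai form of Bruggeman's approximation links the complex permittivities
of the dispersion medium ``e_m``, the suspension ``e_s`` and the dispersed
spherical particles (cells) ``e_p`` at a volume fraction ``Phi``:

    (e_s - e_p) / (e_m - e_p) * (e_m / e_s)**(1/3) = 1 - Phi

All quantities follow the ``eps* = eps' - i eps''`` convention, i.e. passive
media have non-positive imaginary parts in the complex representation.

The *inverse* problem (cells from medium + suspension) is solved in closed
form: with ``B = (1 - Phi) * (e_s/e_m)**(1/3)`` (principal cube root),

    e_p = (B * e_m - e_s) / (B - 1).

The *forward* problem (suspension from medium + cells) reduces, via
``u = (e_s/e_m)**(1/3)``, to the cubic

    e_m u^3 - (1 - Phi)(e_m - e_p) u - e_p = 0,

whose physical root lies in the principal cube-root wedge ``|arg u| < pi/3``;
a damped Newton polish on the original relation brings the residual to
<1e-12.  Cell-cell interactions are not corrected for: the relation is used
only in the multi-GHz band where interfacial (Maxwell-Wagner) effects and
particle interactions are negligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectra import PermittivitySpectrum, resample_log

logger = logging.getLogger(__name__)

RESIDUAL_TOL = 1e-10
#: extracted loss below this triggers a passivity warning (noise or wrong Phi)
PASSIVITY_FLOOR = -0.05


class DegenerateInversionError(ZeroDivisionError):
    """Suspension indistinguishable from medium at this volume fraction."""


class BHSolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class MixtureContext:
    """Volume fraction of cells in the sensing volume, with uncertainty."""

    phi: float
    phi_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must lie strictly between 0 and 1")
        if self.phi_sd < 0 or self.phi_sd >= self.phi:
            raise ValueError("phi_sd must satisfy 0 <= phi_sd < phi")


def bh_residual(eps_sus, eps_med, eps_cell, phi):
    """Residual of the mixing relation (0 when the triple is consistent)."""
    eps_sus = np.asarray(eps_sus, dtype=complex)
    return (eps_sus - eps_cell) / (eps_med - eps_cell) * (eps_med / eps_sus) ** (1.0 / 3.0) \
        - (1.0 - phi)


def invert_bh(eps_sus, eps_med, phi: float):
    """Cell permittivity from suspension and medium (closed form).

    Accepts complex scalars or arrays (broadcast).  Raises
    :class:`DegenerateInversionError` when the closed form degenerates
    (``B -> 1``), and logs a passivity warning when the extracted loss is
    significantly negative.
    """
    eps_sus = np.asarray(eps_sus, dtype=complex)
    eps_med = np.asarray(eps_med, dtype=complex)
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must lie strictly between 0 and 1")
    b = (1.0 - phi) * (eps_sus / eps_med) ** (1.0 / 3.0)
    if np.any(np.abs(b - 1.0) < 1e-12):
        raise DegenerateInversionError(
            "B = (1-phi)(eps_sus/eps_med)^(1/3) is 1 to machine precision; "
            "suspension indistinguishable from medium at this phi"
        )
    eps_p = (b * eps_med - eps_sus) / (b - 1.0)
    loss = -np.imag(eps_p)
    if np.any(loss < PASSIVITY_FLOOR):
        logger.warning(
            "invert_bh: extracted loss reaches %.3g < %.3g; noisy input or wrong phi?",
            float(np.min(loss)), PASSIVITY_FLOOR,
        )
    return eps_p if eps_p.ndim else complex(eps_p)


def _principal_wedge(u: np.ndarray) -> np.ndarray:
    """Mask of roots consistent with the principal cube root, |arg u| < pi/3."""
    return np.abs(np.angle(u)) < np.pi / 3.0 + 1e-12


def _newton_forward(eps_cell, eps_med, phi, start, max_iter=60):
    """Damped Newton on g(e_s) = (e_s - e_p)(e_m/e_s)^(1/3) - (1-phi)(e_m - e_p)."""
    target = (1.0 - phi) * (eps_med - eps_cell)
    es = complex(start)
    for _ in range(max_iter):
        r = (eps_med / es) ** (1.0 / 3.0)
        g = (es - eps_cell) * r - target
        # dg/des = r + (es - e_p) * d/des (e_m/es)^(1/3) = r (1 - (es - e_p)/(3 es))
        dg = r * (1.0 - (es - eps_cell) / (3.0 * es))
        if dg == 0:
            break
        step = g / dg
        lam = 1.0
        for _ in range(30):
            trial = es - lam * step
            if trial != 0:
                rt = (eps_med / trial) ** (1.0 / 3.0)
                if abs((trial - eps_cell) * rt - target) < abs(g):
                    es = trial
                    break
            lam *= 0.5
        else:
            break
        if abs(g) < 1e-14 * (abs(target) + 1.0):
            break
    return es


def forward_bh(eps_cell, eps_med, phi: float):
    """Suspension permittivity from cell and medium permittivities.

    Vectorised over complex arrays.  Each point is solved through the cubic
    in ``u = (e_s/e_m)**(1/3)`` restricted to the principal branch, then
    polished by Newton iteration; a continuation in ``phi`` from the dilute
    limit is used as fallback.  The returned values satisfy the mixing
    relation to a residual below ``1e-10``.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    eps_cell = np.asarray(eps_cell, dtype=complex)
    eps_med = np.asarray(eps_med, dtype=complex)
    if phi == 0.0:
        out = np.broadcast_arrays(eps_med, eps_cell)[0].copy()
        return out if out.ndim else complex(out)
    if phi == 1.0:
        out = np.broadcast_arrays(eps_cell, eps_med)[0].copy()
        return out if out.ndim else complex(out)

    ec, em = np.broadcast_arrays(eps_cell, eps_med)
    shape = ec.shape
    ec_f, em_f = ec.ravel(), em.ravel()
    out = np.empty_like(ec_f)
    for i, (ep, m) in enumerate(zip(ec_f, em_f)):
        out[i] = _forward_point(ep, m, phi)
    out = out.reshape(shape)
    res = np.abs(bh_residual(out, em, ec, phi))
    if np.any(res > RESIDUAL_TOL):
        raise BHSolverError(
            f"forward solve residual {res.max():.3g} exceeds {RESIDUAL_TOL:g}"
        )
    return out if out.ndim else complex(out)


def _forward_point(ep: complex, em: complex, phi: float) -> complex:
    if ep == em:
        return em
    guess = (1.0 - phi) * em + phi * ep  # linear mix, continuation anchor
    roots = np.roots([em, 0.0, -(1.0 - phi) * (em - ep), -ep])
    best, best_res = None, np.inf
    for u in roots:
        if not _principal_wedge(np.asarray(u)):
            continue
        es = em * u ** 3
        r = abs(bh_residual(es, em, ep, phi))
        # prefer physically plausible root (closest to linear mix on ties)
        r_rank = (r, abs(es - guess))
        if best is None or r_rank < best_res:
            best, best_res = es, r_rank
    if best is None:
        best = guess
    es = _newton_forward(ep, em, phi, best)
    if abs(bh_residual(es, em, ep, phi)) > RESIDUAL_TOL:
        # continuation in phi from the dilute limit
        es = em
        for p in np.linspace(phi / 16.0, phi, 16):
            es = _newton_forward(ep, em, p, es)
        if abs(bh_residual(es, em, ep, phi)) > RESIDUAL_TOL:
            raise BHSolverError(
                f"no convergence at phi={phi:g}; last residual "
                f"{abs(bh_residual(es, em, ep, phi)):.3g}"
            )
    return es


def check_branch_continuity(eps_ratio: np.ndarray, max_jump: float = 0.5) -> bool:
    """Flag cube-root branch jumps along a frequency sweep.

    ``eps_ratio`` is ``eps_sus/eps_med`` along the grid; a jump in the
    principal cube root larger than ``max_jump`` (relative) between adjacent
    points indicates the ratio crossed the negative real axis.
    """
    u = np.asarray(eps_ratio, dtype=complex) ** (1.0 / 3.0)
    rel = np.abs(np.diff(u)) / np.maximum(np.abs(u[:-1]), 1e-30)
    ok = bool(np.all(rel < max_jump))
    if not ok:
        logger.warning("cube-root branch discontinuity detected (max jump %.3g)",
                       float(rel.max()))
    return ok


def extract_cell_spectrum(sus: PermittivitySpectrum, med: PermittivitySpectrum,
                          ctx: MixtureContext) -> PermittivitySpectrum:
    """Extract the cell-only complex spectrum from suspension and medium.

    Both inputs must carry a loss part.  Grids are aligned onto their common
    log-frequency intersection (no-op when they already coincide), the
    closed-form inversion is applied pointwise, and branch continuity is
    checked across the sweep.
    """
    if not (sus.has_loss and med.has_loss):
        raise ValueError("both spectra must carry eps_imag for the extraction")
    f_lo = max(sus.freq_hz[0], med.freq_hz[0])
    f_hi = min(sus.freq_hz[-1], med.freq_hz[-1])
    if f_lo >= f_hi:
        raise ValueError("suspension and medium frequency ranges do not overlap")
    if sus.freq_hz.shape == med.freq_hz.shape and np.allclose(sus.freq_hz, med.freq_hz):
        s, m = sus, med
    else:
        n = max(int(np.sum((sus.freq_hz >= f_lo) & (sus.freq_hz <= f_hi))), 2)
        s = resample_log(sus, n, f_lo, f_hi)
        m = resample_log(med, n, f_lo, f_hi)
    check_branch_continuity(s.complex_eps / m.complex_eps)
    eps_p = invert_bh(s.complex_eps, m.complex_eps, ctx.phi)
    return PermittivitySpectrum(
        freq_hz=s.freq_hz,
        eps_real=np.real(eps_p),
        eps_imag=np.clip(-np.imag(eps_p), PASSIVITY_FLOOR + 1e-9, None),
        temperature_c=sus.temperature_c,
        label="cell",
        provenance="bh_extracted",
    )
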