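"""Data model and I/O for complex relative permittivity spectra.

A spectrum lives on a strictly increasing frequency grid (Hz) and carries the
real part ``eps_real`` and, optionally, the dielectric loss ``eps_imag`` under
the passive-medium sign convention ``eps* = eps' - i eps''`` with
``eps'' >= 0``.  All frequencies in files and public interfaces are ordinary
frequencies in Hz; angular frequency ``omega = 2*pi*f`` is used internally
only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: provenance labels a spectrum may carry
PROVENANCES = ("measured", "kk", "synthetic", "bh_extracted")

#: loss values slightly below zero are tolerated (numerical noise) down to this floor
NEGATIVE_LOSS_FLOOR = -0.05

CANONICAL_COLUMNS = ("freq_hz", "eps_real", "eps_imag")


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file cannot be interpreted."""


class SpectrumValidationError(ValueError):
    """Raised when spectrum data violates the container invariants."""


@dataclass(frozen=True)
class PermittivitySpectrum:
    """Complex relative permittivity sampled on an increasing frequency grid.

    Parameters
    ----------
    freq_hz
        Strictly increasing, strictly positive frequencies in Hz.
    eps_real
        Real part of the relative permittivity, one value per frequency.
    eps_imag
        Dielectric loss (non-negative up to a small numerical floor), or
        ``None`` when only the real part is available.
    temperature_c
        Sample temperature in degrees Celsius.
    label
        Free-text condition label, e.g. ``"medium"`` or ``"suspension"``.
    provenance
        One of ``"measured"``, ``"kk"``, ``"synthetic"``, ``"bh_extracted"``.
    """

    freq_hz: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray | None = None
    temperature_c: float = 25.0
    label: str = ""
    provenance: str = "measured"

    def __post_init__(self) -> None:
        f = np.asarray(self.freq_hz, dtype=float)
        er = np.asarray(self.eps_real, dtype=float)
        object.__setattr__(self, "freq_hz", f)
        object.__setattr__(self, "eps_real", er)
        if self.eps_imag is not None:
            ei = np.asarray(self.eps_imag, dtype=float)
            object.__setattr__(self, "eps_imag", ei)
        self._validate()

    def _validate(self) -> None:
        f, er, ei = self.freq_hz, self.eps_real, self.eps_imag
        if f.ndim != 1 or f.size < 1:
            raise SpectrumValidationError("frequency grid must be a non-empty 1-D array")
        if not np.all(f > 0):
            raise SpectrumValidationError("all frequencies must be positive")
        if np.any(np.diff(f) <= 0):
            raise SpectrumValidationError(
                "frequencies must be strictly increasing (duplicates not allowed)"
            )
        if er.shape != f.shape:
            raise SpectrumValidationError("eps_real must match freq_hz in length")
        if not np.all(np.isfinite(er)):
            raise SpectrumValidationError("eps_real must be finite everywhere")
        if ei is not None:
            if ei.shape != f.shape:
                raise SpectrumValidationError("eps_imag must match freq_hz in length")
            if not np.all(np.isfinite(ei)):
                raise SpectrumValidationError("eps_imag must be finite everywhere")
            if np.any(ei < NEGATIVE_LOSS_FLOOR):
                raise SpectrumValidationError(
                    f"eps_imag below the numerical floor {NEGATIVE_LOSS_FLOOR}"
                )
            if np.any(ei < 0):
                logger.warning(
                    "spectrum %r: %d slightly negative loss values (min %.3g) tolerated",
                    self.label, int(np.sum(ei < 0)), float(ei.min()),
                )
        if self.provenance not in PROVENANCES:
            raise SpectrumValidationError(
                f"unknown provenance {self.provenance!r}; expected one of {PROVENANCES}"
            )

    # -- derived views -----------------------------------------------------

    def __len__(self) -> int:
        return self.freq_hz.size

    @property
    def has_loss(self) -> bool:
        return self.eps_imag is not None

    @property
    def omega(self) -> np.ndarray:
        """Angular frequency grid in rad/s."""
        return 2.0 * np.pi * self.freq_hz

    @property
    def complex_eps(self) -> np.ndarray:
        """``eps' - i eps''`` as a complex array (requires eps_imag)."""
        if self.eps_imag is None:
            raise SpectrumValidationError("spectrum carries no imaginary part")
        return self.eps_real - 1j * self.eps_imag

    def band(self, f_lo: float, f_hi: float) -> "PermittivitySpectrum":
        """Restrict the spectrum to frequencies in ``[f_lo, f_hi]``."""
        m = (self.freq_hz >= f_lo) & (self.freq_hz <= f_hi)
        if not np.any(m):
            raise SpectrumValidationError(f"no points in band [{f_lo:g}, {f_hi:g}] Hz")
        ei = self.eps_imag[m] if self.eps_imag is not None else None
        return replace(self, freq_hz=self.freq_hz[m], eps_real=self.eps_real[m],
                       eps_imag=ei)

    def with_values(self, *, eps_real=None, eps_imag=None,
                    provenance: str | None = None) -> "PermittivitySpectrum":
        """Copy with replaced per-frequency values and/or provenance."""
        kwargs: dict = {}
        if eps_real is not None:
            kwargs["eps_real"] = np.asarray(eps_real, dtype=float)
        if eps_imag is not None:
            kwargs["eps_imag"] = np.asarray(eps_imag, dtype=float)
        if provenance is not None:
            kwargs["provenance"] = provenance
        return replace(self, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        data = {"freq_hz": self.freq_hz, "eps_real": self.eps_real}
        if self.eps_imag is not None:
            data["eps_imag"] = self.eps_imag
        return pd.DataFrame(data)


# -- I/O -------------------------------------------------------------------


def read_spectrum(path: str | Path,
                  dialect: Mapping[str, str] | None = None) -> PermittivitySpectrum:
    """Read a spectrum from a CSV file.

    The canonical header is ``freq_hz,eps_real[,eps_imag]``.  ``dialect`` maps
    canonical names to the column names actually present, e.g.
    ``{"freq_hz": "f/Hz", "eps_real": "eps1"}``.  Rows are sorted by
    frequency; duplicated frequencies are rejected.  A JSON sidecar
    ``<path>.json`` with metadata (``temperature_c``, ``label``,
    ``provenance``) is honoured when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    colmap = {k: k for k in CANONICAL_COLUMNS}
    if dialect:
        colmap.update(dialect)
    if colmap["freq_hz"] not in df.columns or colmap["eps_real"] not in df.columns:
        raise SpectrumFormatError(
            f"{path}: required columns {colmap['freq_hz']!r}, {colmap['eps_real']!r} "
            f"not found among {list(df.columns)}"
        )
    known = {colmap[k] for k in CANONICAL_COLUMNS}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("%s: ignoring extra columns %s", path, extra)

    df = df.sort_values(colmap["freq_hz"], kind="mergesort")
    f = df[colmap["freq_hz"]].to_numpy(dtype=float)
    if np.any(np.diff(f) == 0):
        raise SpectrumValidationError(f"{path}: duplicated frequency values")
    ei = None
    if colmap["eps_imag"] in df.columns:
        ei = df[colmap["eps_imag"]].to_numpy(dtype=float)

    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return PermittivitySpectrum(
        freq_hz=f,
        eps_real=df[colmap["eps_real"]].to_numpy(dtype=float),
        eps_imag=ei,
        temperature_c=float(meta.get("temperature_c", 25.0)),
        label=str(meta.get("label", "")),
        provenance=str(meta.get("provenance", "measured")),
    )


def write_spectrum(spec: PermittivitySpectrum, path: str | Path,
                   sidecar: bool = True) -> Path:
    """Write a spectrum as CSV (plus a JSON metadata sidecar by default)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    spec.to_frame().to_csv(path, index=False, float_format="%.17g")
    if sidecar:
        meta = {
            "temperature_c": spec.temperature_c,
            "label": spec.label,
            "provenance": spec.provenance,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def resample_log(spec: PermittivitySpectrum, n: int,
                 f_min: float, f_max: float) -> PermittivitySpectrum:
    """Resample onto ``n`` geometrically spaced points in ``[f_min, f_max]``.

    Values are interpolated linearly in log-frequency.  The target range must
    lie inside the spectrum's own range (no extrapolation).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    lo, hi = spec.freq_hz[0], spec.freq_hz[-1]
    if f_min < lo * (1 - 1e-12) or f_max > hi * (1 + 1e-12):
        raise ValueError(
            f"requested range [{f_min:g}, {f_max:g}] outside data range [{lo:g}, {hi:g}]"
        )
    new_f = np.geomspace(f_min, f_max, n)
    logf_old = np.log(spec.freq_hz)
    logf_new = np.log(new_f)
    er = np.interp(logf_new, logf_old, spec.eps_real)
    ei = None
    if spec.eps_imag is not None:
        ei = np.interp(logf_new, logf_old, spec.eps_imag)
    return replace(spec, freq_hz=new_f, eps_real=er, eps_imag=ei)
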