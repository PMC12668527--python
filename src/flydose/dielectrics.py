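"""Insect-tissue dielectric properties.

Tissue is modelled with a Cole-Cole relaxation,

    eps_hat(w) = eps_inf + sum_k  d_eps_k / (1 + (i w tau_k)^(1 - alpha_k))
                 + sigma_s / (i w eps0),

using the e^{+i w t} time convention, so Im(eps_hat) < 0 for a lossy medium.
The effective (total) conductivity reported to the solver is
sigma(w) = -w eps0 Im(eps_hat), which folds dipolar loss and ionic (static)
conductivity into a single value — exactly what a single-frequency harmonic
FDTD run needs.

The packaged default parameter set is a single-pole Cole-Cole with a
water-like relaxation time, whose dispersion strength and static conductivity
are solved in closed form so that the model passes exactly through the
anchor point eps_r = 42, sigma = 2.8 S/m at 3.6 GHz used for insect tissue.
All seven tissues share this one property set; per-tissue overrides can be
supplied by the caller wherever a `TissueProperties` is accepted.

A tabulated fallback (`interpolate_properties`, log-frequency piecewise
linear) covers users who prefer to supply measured values as CSV with
columns frequency_Hz, eps_r, sigma_S_per_m.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import EPS0

__all__ = [
    "ColeColeParams",
    "TissueProperties",
    "cole_cole_eval",
    "default_insect_params",
    "default_insect_table",
    "interpolate_properties",
    "load_table",
    "save_table",
    "PAPER_FREQUENCIES_HZ",
]

#: Frequencies (Hz) at which far-field dosimetry is tabulated: 1-240 GHz.
PAPER_FREQUENCIES_HZ = tuple(
    f * 1e9 for f in (1.0, 2.45, 3.6, 6.0, 12.0, 24.0, 60.0, 90.0, 120.0, 240.0)
)

_ANCHOR_F_HZ = 3.6e9
_ANCHOR_EPS = 42.0
_ANCHOR_SIGMA = 2.8  # S/m


@dataclass(frozen=True)
class ColeColeParams:
    """Parameters of a (possibly multi-pole) Cole-Cole dispersion.

    ``delta_eps``, ``tau`` and ``alpha`` are per-pole sequences of equal
    length; ``alpha = 0`` reduces a pole to a Debye relaxation.
    """

    eps_inf: float
    delta_eps: tuple[float, ...]
    tau: tuple[float, ...]  # seconds
    alpha: tuple[float, ...]  # in [0, 1)
    sigma_s: float = 0.0  # static (ionic) conductivity, S/m

    def __post_init__(self) -> None:
        n = len(self.delta_eps)
        if not (len(self.tau) == len(self.alpha) == n):
            raise ValueError("delta_eps, tau and alpha must have equal length")
        if self.eps_inf < 1.0:
            raise ValueError(f"eps_inf must be >= 1, got {self.eps_inf}")
        if any(t <= 0 for t in self.tau):
            raise ValueError("all relaxation times tau must be > 0")
        if any(not (0.0 <= a < 1.0) for a in self.alpha):
            raise ValueError("all alpha must lie in [0, 1)")
        if self.sigma_s < 0:
            raise ValueError(f"sigma_s must be >= 0, got {self.sigma_s}")

    def complex_permittivity(self, f_hz: float | np.ndarray) -> np.ndarray:
        """Relative complex permittivity eps_hat at frequency ``f_hz`` (> 0)."""
        f = np.asarray(f_hz, dtype=float)
        if np.any(f <= 0):
            raise ValueError("frequency must be > 0")
        w = 2.0 * np.pi * f
        eps = np.full_like(f, self.eps_inf, dtype=complex)
        for de, tau, alpha in zip(self.delta_eps, self.tau, self.alpha):
            eps = eps + de / (1.0 + (1j * w * tau) ** (1.0 - alpha))
        eps = eps + self.sigma_s / (1j * w * EPS0)
        return eps


@dataclass(frozen=True, order=True)
class TissueProperties:
    """Real permittivity and effective conductivity at one frequency."""

    frequency: float  # Hz
    eps_r: float
    sigma: float  # S/m

    def __post_init__(self) -> None:
        if self.eps_r < 1.0:
            raise ValueError(f"eps_r must be >= 1, got {self.eps_r}")
        if self.sigma < 0.0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


def cole_cole_eval(params: ColeColeParams, f_hz: float) -> TissueProperties:
    """Evaluate a Cole-Cole model at one frequency.

    Returns ``eps_r = Re eps_hat`` and the effective conductivity
    ``sigma = -w eps0 Im eps_hat`` (>= 0 for passive parameters).
    """
    if f_hz <= 0:
        raise ValueError(f"frequency must be > 0, got {f_hz}")
    eps = complex(params.complex_permittivity(f_hz))
    w = 2.0 * np.pi * f_hz
    return TissueProperties(
        frequency=f_hz, eps_r=float(eps.real), sigma=float(-w * EPS0 * eps.imag)
    )


def default_insect_params(
    eps_inf: float = 5.0, tau: float = 8.27e-12, alpha: float = 0.10
) -> ColeColeParams:
    """Single-pole Cole-Cole parameters for insect tissue.

    The relaxation time defaults to that of bulk water at room temperature
    (8.27 ps, i.e. a ~19 GHz relaxation) with a mild Cole-Cole broadening
    typical of hydrated biological tissue.  The dispersion strength and
    static conductivity are then the unique solution of the two linear
    equations pinning the model to the 3.6 GHz insect-tissue anchor
    (eps_r = 42, sigma = 2.8 S/m).
    """
    w = 2.0 * np.pi * _ANCHOR_F_HZ
    pole = 1.0 / (1.0 + (1j * w * tau) ** (1.0 - alpha))
    # eps_inf + d_eps*Re(pole) = 42 ;  -w eps0 d_eps Im(pole) + sigma_s = 2.8
    d_eps = (_ANCHOR_EPS - eps_inf) / pole.real
    sigma_s = _ANCHOR_SIGMA + w * EPS0 * d_eps * pole.imag
    if sigma_s < 0:
        raise ValueError("anchor not reachable with the requested pole shape")
    return ColeColeParams(
        eps_inf=eps_inf,
        delta_eps=(float(d_eps),),
        tau=(tau,),
        alpha=(alpha,),
        sigma_s=float(sigma_s),
    )


# ---------------------------------------------------------------------------
# Tabulated properties


def load_table(path: str | Path) -> list[TissueProperties]:
    """Read a dielectric table CSV (frequency_Hz, eps_r, sigma_S_per_m)."""
    rows: list[TissueProperties] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"frequency_Hz", "eps_r", "sigma_S_per_m"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"dielectric table must have columns {sorted(required)}")
        for rec in reader:
            rows.append(
                TissueProperties(
                    frequency=float(rec["frequency_Hz"]),
                    eps_r=float(rec["eps_r"]),
                    sigma=float(rec["sigma_S_per_m"]),
                )
            )
    rows.sort(key=lambda t: t.frequency)
    return rows


def save_table(table: Sequence[TissueProperties], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frequency_Hz", "eps_r", "sigma_S_per_m"])
        for t in sorted(table, key=lambda t: t.frequency):
            writer.writerow([repr(t.frequency), repr(t.eps_r), repr(t.sigma)])


def default_insect_table() -> list[TissueProperties]:
    """The packaged 1-240 GHz insect dielectric table."""
    with resources.as_file(
        resources.files("flydose.data") / "insect_dielectric_1_240GHz.csv"
    ) as p:
        return load_table(p)


def interpolate_properties(
    table: Sequence[TissueProperties], f_hz: float
) -> TissueProperties:
    """Piecewise-linear interpolation in log-frequency.

    ``table`` must be sorted by frequency and bracket ``f_hz``; requests
    outside the tabulated span are rejected rather than extrapolated.
    """
    if len(table) < 2:
        raise ValueError("need at least two table rows to interpolate")
    freqs = np.array([t.frequency for t in table])
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("table must be sorted by strictly increasing frequency")
    if f_hz < freqs[0] or f_hz > freqs[-1]:
        raise ValueError(
            f"frequency {f_hz:g} Hz outside tabulated span "
            f"[{freqs[0]:g}, {freqs[-1]:g}] Hz; extrapolation is not supported"
        )
    logf = np.log(freqs)
    x = np.log(f_hz)
    eps = float(np.interp(x, logf, [t.eps_r for t in table]))
    sig = float(np.interp(x, logf, [t.sigma for t in table]))
    return TissueProperties(frequency=f_hz, eps_r=eps, sigma=sig)
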