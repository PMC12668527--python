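"""Mie absorption of a homogeneous lossy dielectric sphere.

Exact plane-wave scattering/absorption series for a homogeneous sphere,
used as the independent analytic oracle for the FDTD dosimetry pipeline.
The complex refractive index follows the package-wide e^{+i w t} phasor
convention, m = sqrt(eps_r - i sigma / (w eps0)) with Im(m) <= 0; the
series itself is evaluated with the textbook Bohren-Huffman recurrences
(which assume the opposite convention) on the conjugate index, leaving all
efficiencies unchanged.

For an incident plane wave of RMS field strength E_rms the absorbed power
is ``P_abs = Q_abs * pi a^2 * E_rms^2 / eta0`` (incident power flux times
geometric cross-section times absorption efficiency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import C0, EPS0, ETA0

__all__ = [
    "MieResult",
    "mie_efficiencies",
    "mie_absorbed_power",
    "rayleigh_absorbed_power",
    "validate_fdtd_vs_mie",
]


@dataclass(frozen=True)
class MieResult:
    q_ext: float
    q_sca: float
    q_abs: float
    p_abs: float  # watts, at the requested incident RMS field
    n_terms: int

    def __post_init__(self) -> None:
        if self.q_abs < -1e-12:
            raise ValueError(f"negative absorption efficiency {self.q_abs}")


def mie_efficiencies(x: float, m: complex) -> tuple[float, float, complex, int]:
    """(Q_ext, Q_sca, S(0), n_terms) for size parameter x and relative index m.

    ``S(0)`` is the forward-scattering amplitude, whose real part gives the
    extinction efficiency through the optical theorem,
    ``Q_ext = 4 Re S(0) / x^2`` — an internal consistency check on the
    series.

    Uses the Bohren-Huffman formulation with downward recurrence for the
    logarithmic derivative D_n and upward recurrence for the Riccati-Bessel
    functions of the real argument x.  ``m`` is interpreted in the
    e^{-i w t} convention (Im m >= 0 for absorption).
    """
    if x <= 0:
        raise ValueError("size parameter must be > 0")
    n_max = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    mx = m * x
    # downward recurrence for D_n(mx), started well above n_max
    n_start = max(n_max + 16, int(np.ceil(abs(mx))) + 16)
    d = np.zeros(n_start + 1, dtype=complex)
    for n in range(n_start, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)

    # Riccati-Bessel psi, chi by upward recurrence (real argument)
    psi_nm1, psi_n = np.cos(x), np.sin(x)  # psi_{-1}, psi_0
    chi_nm1, chi_n = -np.sin(x), np.cos(x)  # chi_{-1}, chi_0
    xi_n = psi_n - 1j * chi_n
    q_ext = 0.0
    q_sca = 0.0
    s0 = 0.0 + 0.0j
    for n in range(1, n_max + 1):
        psi_np = (2 * n - 1) / x * psi_n - psi_nm1
        chi_np = (2 * n - 1) / x * chi_n - chi_nm1
        psi_nm1, psi_n = psi_n, psi_np
        chi_nm1, chi_n = chi_n, chi_np
        xi_nm1, xi_n = xi_n, psi_n - 1j * chi_n
        dn = d[n]
        a_n = ((dn / m + n / x) * psi_n - psi_nm1) / ((dn / m + n / x) * xi_n - xi_nm1)
        b_n = ((dn * m + n / x) * psi_n - psi_nm1) / ((dn * m + n / x) * xi_n - xi_nm1)
        q_ext += (2 * n + 1) * (a_n.real + b_n.real)
        q_sca += (2 * n + 1) * (abs(a_n) ** 2 + abs(b_n) ** 2)
        s0 += 0.5 * (2 * n + 1) * (a_n + b_n)
    q_ext *= 2.0 / x**2
    q_sca *= 2.0 / x**2
    return q_ext, q_sca, s0, n_max


def complex_index(eps_r: float, sigma: float, f_hz: float) -> complex:
    """m = sqrt(eps_r - i sigma/(w eps0)) with the e^{+iwt} convention."""
    w = 2.0 * np.pi * f_hz
    eps_hat = eps_r - 1j * sigma / (w * EPS0)
    m = np.sqrt(eps_hat)
    if m.imag > 0:
        m = -m
    return complex(m)


def mie_absorbed_power(
    radius: float, eps_r: float, sigma: float, f_hz: float, e_rms: float = 1.0
) -> MieResult:
    """Absorbed power of a lossy sphere in a plane wave of given RMS field."""
    if radius <= 0 or f_hz <= 0:
        raise ValueError("radius and frequency must be > 0")
    lam = C0 / f_hz
    x = 2.0 * np.pi * radius / lam
    m = complex_index(eps_r, sigma, f_hz)
    # hand the conjugate to the e^{-iwt} series
    q_ext, q_sca, _, n_terms = mie_efficiencies(x, np.conj(m))
    q_abs = q_ext - q_sca
    if q_abs < 0 and q_abs > -1e-10 * max(q_ext, 1.0):
        q_abs = 0.0  # lossless round-off
    # convergence check: the last retained term must be negligible
    p_inc = e_rms**2 / ETA0  # W/m^2 time-averaged incident flux
    p_abs = q_abs * np.pi * radius**2 * p_inc
    return MieResult(q_ext=q_ext, q_sca=q_sca, q_abs=q_abs, p_abs=p_abs, n_terms=n_terms)


def validate_fdtd_vs_mie(
    radius: float,
    eps_r: float,
    sigma: float,
    f_hz: float,
    pitch: float,
    e_rms: float = 1.0,
    n_periods: int | None = None,
    **solver_kwargs,
) -> float:
    """Relative whole-sphere absorbed-power error of the FDTD pipeline.

    Runs a single plane wave over a homogeneous sphere phantom and returns
    ``|P_fdtd - P_mie| / P_mie``.  The pitch must resolve at least ten
    cells per in-tissue wavelength.
    """
    from .dielectrics import TissueProperties
    from .dosimetry import absorbed_power, embed_phantom
    from .fdtd import PlaneWaveSpec, make_plane_wave_source, run_harmonic
    from .synthetic import generate_sphere_phantom

    lam_tissue = C0 / f_hz / np.sqrt(eps_r)
    if pitch > lam_tissue / 10.0:
        raise ValueError(
            f"pitch {pitch:g} m coarser than lambda_tissue/10 = {lam_tissue / 10:g} m"
        )
    sphere = generate_sphere_phantom(radius, pitch)
    props = TissueProperties(frequency=f_hz, eps_r=eps_r, sigma=sigma)
    mats, box = embed_phantom(sphere, props)
    spec = PlaneWaveSpec(k_dir=(1.0, 0.0, 0.0), pol=(0.0, 0.0, 1.0), f0=f_hz, e_rms=e_rms)
    src = make_plane_wave_source(spec, box)
    ph = run_harmonic(mats, src, n_periods=n_periods, **solver_kwargs)
    p_fdtd = absorbed_power(ph, mats)
    p_mie = mie_absorbed_power(radius, eps_r, sigma, f_hz, e_rms).p_abs
    return abs(p_fdtd - p_mie) / p_mie


def rayleigh_absorbed_power(
    radius: float, eps_r: float, sigma: float, f_hz: float, e_rms: float = 1.0
) -> float:
    """Quasi-static (electrically small sphere) absorbed power.

    P = sigma * |3 / (eps_hat + 2)|^2 * E_rms^2 * V  with
    eps_hat = eps_r - i sigma/(w eps0); valid for size parameter x << 1.
    """
    w = 2.0 * np.pi * f_hz
    eps_hat = eps_r - 1j * sigma / (w * EPS0)
    v = 4.0 / 3.0 * np.pi * radius**3
    return float(sigma * abs(3.0 / (eps_hat + 2.0)) ** 2 * e_rms**2 * v)
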