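"""Exposure protocols and absorbed-power bookkeeping.

Whole-body and per-tissue absorbed power follow the conduction-loss
integral

    P_abs = integral_V sigma |E_rms|^2 dV
          = sum_cells sigma_cell * E_rms,cell^2 * pitch^3,

with ``E_rms^2 = (1/2) sum_c |E_c|^2`` from the steady-state phasors.
Two exposure protocols are provided: the far-field ensemble of twelve
plane waves (six axis-aligned propagation directions, two orthogonal
grid-aligned polarizations each) and the near-field protocol of a
3.6 GHz dipole antenna with the phantom at twelve locations (six azimuths
around the antenna at an 11 mm near ring and a 34 mm far ring) in two
orientations of the body axis relative to the antenna arm.

Doses computed at a reference field strength rescale quadratically to
measured exposures (free-space scaling; standing waves deliberately
ignored), and a dose converts back to the equivalent far-field strength
through the inverse relation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .dielectrics import TissueProperties
from .fdtd import (
    DipoleSpec,
    MaterialGrid,
    PlaneWaveSpec,
    make_dipole_source,
    make_material_grid,
    make_plane_wave_source,
    run_harmonic,
)
from .fdtd.solver import PhasorField
from .phantom import VoxelPhantom

__all__ = [
    "DoseReport",
    "NearFieldPlacement",
    "absorbed_power",
    "farfield_ensemble",
    "farfield_ensemble_dose",
    "nearfield_protocol",
    "nearfield_dose",
    "rescale_dose",
    "equivalent_farfield_strength",
    "dose_ratio",
    "embed_phantom",
]

#: ICNIRP general-public reference level at 3.6 GHz, V/m (30-min average).
ICNIRP_GENERAL_PUBLIC_E_FIELD = 61.5


# ---------------------------------------------------------------------------
# Absorbed power


def absorbed_power(
    phasors: PhasorField,
    materials: MaterialGrid,
    mask: np.ndarray | str | int | None = None,
) -> float:
    """Absorbed power (W) in the masked cells (all tissue when None)."""
    if phasors.Ex.shape != materials.dims:
        raise ValueError(
            f"phasor grid {phasors.Ex.shape} and material grid "
            f"{materials.dims} differ"
        )
    if mask is None or isinstance(mask, (str, int)):
        mask = materials.tissue_mask(mask)
    if not np.any(mask):
        warnings.warn("absorbed_power: mask selects zero cells", stacklevel=2)
        return 0.0
    e2 = phasors.e_rms_sq()[mask]
    return float(np.sum(materials.sigma[mask] * e2) * phasors.pitch**3)


def _per_tissue_powers(
    phasors: PhasorField, materials: MaterialGrid
) -> dict[str, float]:
    out = {}
    for code, name in sorted(materials.tissue_table.items()):
        m = materials.labels == code
        if np.any(m):
            out[name] = absorbed_power(phasors, materials, m)
        else:
            out[name] = 0.0
    return out


# ---------------------------------------------------------------------------
# Dose report


@dataclass
class DoseReport:
    """Per-configuration whole-body and per-tissue absorbed power (W)."""

    frequency: float
    config_labels: list[str]
    per_tissue: dict[str, np.ndarray]  # tissue -> per-configuration W
    reference: dict[str, float]  # e.g. {"e_rms_V_per_m": 1.0} or input power
    extra: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.config_labels)
        for name, vals in self.per_tissue.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (n,):
                raise ValueError(f"tissue {name!r}: expected {n} values")
            if np.any(vals < 0):
                raise ValueError(f"tissue {name!r}: negative absorbed power")
            self.per_tissue[name] = vals

    @property
    def whole_body(self) -> np.ndarray:
        """Whole-body P_abs per configuration: exact sum over tissues."""
        return np.sum(list(self.per_tissue.values()), axis=0)

    def summary(self) -> dict[str, float]:
        wb = self.whole_body
        return {
            "mean_W": float(wb.mean()),
            "min_W": float(wb.min()),
            "max_W": float(wb.max()),
            "sd_W": float(wb.std()),  # population sd
        }

    def to_dataframe(self) -> pd.DataFrame:
        data = {"configuration": self.config_labels}
        data.update({name: vals for name, vals in self.per_tissue.items()})
        df = pd.DataFrame(data)
        df["whole_body"] = self.whole_body
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10e")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "frequency_Hz": self.frequency,
            "reference": self.reference,
            "summary": self.summary(),
            "configurations": self.config_labels,
            "whole_body_W": [float(v) for v in self.whole_body],
            "per_tissue_W": {k: [float(x) for x in v] for k, v in self.per_tissue.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Grid embedding shared by the protocols


def embed_phantom(
    phantom: VoxelPhantom,
    props: TissueProperties,
    pml_cells: int = 10,
    gap: int = 4,
    tf_margin: int = 2,
) -> tuple[MaterialGrid, tuple[int, int, int, int, int, int]]:
    """Embed a phantom and place a TF/SF box ``tf_margin`` cells around it."""
    padding = pml_cells + gap + tf_margin
    mats = make_material_grid(
        phantom, props, padding, pml_cells=pml_cells, tf_margin=tf_margin
    )
    box = []
    for n_ph in phantom.labels.shape:
        lo = pml_cells + gap
        hi = lo + tf_margin + n_ph + tf_margin
        box.extend([lo, hi])
    return mats, tuple(box)  # type: ignore[return-value]


def _check_resolution(pitch: float, f0: float, eps_r: float) -> None:
    lam_tissue = 299_792_458.0 / f0 / np.sqrt(eps_r)
    if pitch > lam_tissue / 10.0:
        raise ValueError(
            f"grid step {pitch:g} m exceeds one tenth of the in-tissue "
            f"wavelength {lam_tissue:g} m at {f0:g} Hz; refine the phantom pitch"
        )


# ---------------------------------------------------------------------------
# Far-field protocol


def farfield_ensemble(f0: float, e_rms: float = 1.0) -> list[PlaneWaveSpec]:
    """The 12-plane-wave far-field ensemble.

    Six axis-aligned propagation directions, each with the two grid-axis
    polarizations orthogonal to it.
    """
    specs = []
    axes = np.eye(3)
    for ax in range(3):
        for s in (+1.0, -1.0):
            k = tuple(s * axes[ax])
            for pax in range(3):
                if pax == ax:
                    continue
                specs.append(
                    PlaneWaveSpec(k_dir=k, pol=tuple(axes[pax]), f0=f0, e_rms=e_rms)
                )
    # 6 directions x 2 polarizations, in k-major order
    assert len(specs) == 12
    return specs


def farfield_ensemble_dose(
    phantom: VoxelPhantom,
    props: TissueProperties,
    f0: float,
    e_rms: float = 1.0,
    n_periods: int | None = None,
    pml_cells: int = 10,
    gap: int = 4,
    tf_margin: int = 2,
    safety: float = 0.99,
) -> DoseReport:
    """Run the 12-polarization ensemble and report P_abs per configuration."""
    _check_resolution(phantom.pitch, f0, props.eps_r)
    mats, box = embed_phantom(phantom, props, pml_cells, gap, tf_margin)
    labels = []
    tissues: dict[str, list[float]] = {
        name: [] for _, name in sorted(mats.tissue_table.items())
    }
    for spec in farfield_ensemble(f0, e_rms):
        src = make_plane_wave_source(spec, box)
        ph = run_harmonic(
            mats, src, n_periods=n_periods, pml_cells=pml_cells, safety=safety
        )
        per = _per_tissue_powers(ph, mats)
        k = np.asarray(spec.k_dir)
        p = np.asarray(spec.pol)
        labels.append(
            f"k={'xyz'[int(np.argmax(np.abs(k)))]}{'+' if k.sum() > 0 else '-'}"
            f",E={'xyz'[int(np.argmax(np.abs(p)))]}"
        )
        for name in tissues:
            tissues[name].append(per.get(name, 0.0))
    return DoseReport(
        frequency=f0,
        config_labels=labels,
        per_tissue={k: np.array(v) for k, v in tissues.items()},
        reference={"e_rms_V_per_m": e_rms},
    )


# ---------------------------------------------------------------------------
# Near-field protocol


@dataclass(frozen=True)
class NearFieldPlacement:
    """One phantom placement relative to the antenna, in the phantom frame.

    ``dipole_offset`` is the vector from the phantom centre to the antenna
    feed point (m); ``dipole_axis`` the arm direction in the phantom frame;
    ``label`` identifies location and orientation.
    """

    dipole_offset: tuple[float, float, float]
    dipole_axis: tuple[float, float, float]
    label: str


def nearfield_protocol(
    near_distance: float = 11e-3,
    far_distance: float = 34e-3,
    n_azimuths: int = 6,
    height: float | None = None,
    f0: float = 3.6e9,
) -> list[NearFieldPlacement]:
    """The 12-location x 2-orientation near-field exposure protocol.

    Six vial azimuths around a vertical antenna, with the phantom either at
    the near ring (11 mm from the antenna axis, the vial wall closest to
    the antenna) or the far ring (34 mm, the opposite wall), each in two
    body-axis orientations: ``par`` (parallel to the antenna arm) and
    ``orth`` (orthogonal, pointing at the antenna).  Placements are
    expressed in the phantom frame, where the body axis is grid axis 0.
    """
    h = (299_792_458.0 / f0 / 4.0) if height is None else height
    z_f = h / 2.0  # phantom at mid-arm height
    out = []
    for ring, dist in (("near", near_distance), ("far", far_distance)):
        for m in range(n_azimuths):
            phi = 2.0 * np.pi * m / n_azimuths
            rho_hat = np.array([np.cos(phi), np.sin(phi), 0.0])
            phi_hat = np.array([-np.sin(phi), np.cos(phi), 0.0])
            z_hat = np.array([0.0, 0.0, 1.0])
            fly_pos = dist * rho_hat + z_f * z_hat
            for orient in ("par", "orth"):
                if orient == "par":
                    basis = np.stack([z_hat, -phi_hat, rho_hat])  # rows: ex,ey,ez
                else:
                    basis = np.stack([-rho_hat, phi_hat, -z_hat])
                offset = basis @ (-fly_pos)
                axis = basis @ z_hat
                out.append(
                    NearFieldPlacement(
                        dipole_offset=tuple(offset),
                        dipole_axis=tuple(axis),
                        label=f"{ring}-az{m}-{orient}",
                    )
                )
    return out


def nearfield_dose(
    phantom: VoxelPhantom,
    props: TissueProperties,
    placements: list[NearFieldPlacement],
    radiated_power: float,
    f0: float = 3.6e9,
    half_length: float | None = None,
    n_periods: int | None = None,
    pml_cells: int = 10,
    gap: int = 4,
    tf_margin: int = 2,
    safety: float = 0.99,
) -> DoseReport:
    """Absorbed power for each near-field placement of the phantom."""
    _check_resolution(phantom.pitch, f0, props.eps_r)
    mats, box = embed_phantom(phantom, props, pml_cells, gap, tf_margin)
    centre = np.array(mats.dims) * phantom.pitch / 2.0
    labels = []
    tissues: dict[str, list[float]] = {
        name: [] for _, name in sorted(mats.tissue_table.items())
    }
    for pl in placements:
        spec = DipoleSpec(
            position=tuple(centre + np.asarray(pl.dipole_offset)),
            axis=pl.dipole_axis,
            f0=f0,
            radiated_power=radiated_power,
            half_length=half_length,
        )
        src = make_dipole_source(spec, box, phantom.pitch)
        ph = run_harmonic(
            mats, src, n_periods=n_periods, pml_cells=pml_cells, safety=safety
        )
        per = _per_tissue_powers(ph, mats)
        labels.append(pl.label)
        for name in tissues:
            tissues[name].append(per.get(name, 0.0))
    return DoseReport(
        frequency=f0,
        config_labels=labels,
        per_tissue={k: np.array(v) for k, v in tissues.items()},
        reference={"radiated_power_W": radiated_power},
    )


# ---------------------------------------------------------------------------
# Rescaling algebra


def rescale_dose(p_ref: float, e_ref: float, e_target: float) -> float:
    """Rescale a dose computed at ``e_ref`` to field strength ``e_target``.

    Free-space quadratic scaling: P = P_ref (E_target / E_ref)^2.
    """
    if e_ref <= 0:
        raise ValueError("reference field strength must be > 0")
    return p_ref * (e_target / e_ref) ** 2


def equivalent_farfield_strength(p_target: float, p_at_1vpm: float) -> float:
    """Far-field strength (V/m) whose dose equals ``p_target``.

    Inverse of the quadratic scaling with a 1 V/m baseline dose.
    """
    if p_at_1vpm <= 0:
        raise ValueError("baseline dose at 1 V/m must be > 0")
    return float(np.sqrt(p_target / p_at_1vpm))


def dose_ratio(p_near: float, p_far: float) -> float:
    """Ratio of two doses (e.g. near-field over far-field exposure)."""
    if p_far <= 0:
        raise ValueError("denominator dose must be > 0")
    return p_near / p_far
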