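"""Shared fixtures.

The expensive FDTD runs (the lossy-sphere oracle run and the coarse fly
ensemble) are session-scoped so several tests can interrogate one solve.
"""

from __future__ import annotations

import numpy as np
import pytest

from flydose.dielectrics import TissueProperties, cole_cole_eval, default_insect_params
from flydose.dosimetry import absorbed_power, embed_phantom, farfield_ensemble_dose
from flydose.fdtd import (
    MaterialGrid,
    PlaneWaveSpec,
    make_plane_wave_source,
    poynting_flux_box,
    run_harmonic,
)
from flydose.mie import mie_absorbed_power
from flydose.synthetic import FlyPhantomSpec, generate_fly_phantom, generate_sphere_phantom

# the insect-tissue anchor used throughout: eps_r 42, sigma 2.8 S/m at 3.6 GHz
ANCHOR = dict(eps_r=42.0, sigma=2.8)


@pytest.fixture(scope="session")
def insect_params():
    return default_insect_params()


@pytest.fixture(scope="session")
def fly_default():
    """Default 7-tissue fly phantom at 20 um pitch."""
    return generate_fly_phantom()


@pytest.fixture(scope="session")
def fly_coarse():
    """Coarse (100 um) fly phantom used for solver-level tests."""
    return generate_fly_phantom(
        FlyPhantomSpec(voxel_pitch=100e-6, cuticle_thickness=300e-6)
    )


@pytest.fixture(scope="session")
def sphere_oracle_run():
    """The lossy-sphere validation solve: 1 mm sphere of insect tissue in a
    1 V/m RMS plane wave at 6 GHz, 50 um pitch, full steady-state schedule.

    Returns the FDTD absorbed power, the Mie-series reference, and the net
    inward Poynting flux through a box two cells outside the sphere.
    """
    radius, pitch, f0 = 1e-3, 50e-6, 6e9
    sphere = generate_sphere_phantom(radius, pitch)
    props = TissueProperties(frequency=f0, **ANCHOR)
    mats, box = embed_phantom(sphere, props)
    spec = PlaneWaveSpec(k_dir=(1.0, 0, 0), pol=(0, 0, 1.0), f0=f0, e_rms=1.0)
    ph = run_harmonic(mats, make_plane_wave_source(spec, box))
    pad = (mats.dims[0] - sphere.labels.shape[0]) // 2
    flux_cells = tuple(slice(pad - 2, pad + s + 2) for s in sphere.labels.shape)
    return {
        "p_fdtd": absorbed_power(ph, mats),
        "p_mie": mie_absorbed_power(radius, f_hz=f0, e_rms=1.0, **ANCHOR).p_abs,
        "flux": poynting_flux_box(ph, flux_cells),
        "phasors": ph,
        "materials": mats,
    }


@pytest.fixture(scope="session")
def fly_ensemble_report(fly_coarse, insect_params):
    """12-polarization far-field ensemble on the coarse fly at 3.6 GHz.

    Four periods suffice on this deeply subwavelength grid (the domain
    transit time is ~2% of the source period); steady-state insensitivity
    is checked separately on the sphere.
    """
    props = cole_cole_eval(insect_params, 3.6e9)
    return farfield_ensemble_dose(fly_coarse, props, 3.6e9, e_rms=1.0, n_periods=4)


@pytest.fixture(scope="session")
def empty_grid_run():
    """Plane wave through an empty (vacuum) grid: TF/SF fidelity probe."""
    pitch, f0 = 100e-6, 6e9
    dims = (40, 40, 40)
    mats = MaterialGrid(eps_r=np.ones(dims), sigma=np.zeros(dims), pitch=pitch)
    box = (14, 25, 14, 25, 14, 25)
    spec = PlaneWaveSpec(k_dir=(1.0, 0, 0), pol=(0, 0, 1.0), f0=f0, e_rms=1.0)
    ph = run_harmonic(mats, make_plane_wave_source(spec, box), n_periods=4)
    return {"phasors": ph, "box": box, "pitch": pitch, "f0": f0, "dims": dims}
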