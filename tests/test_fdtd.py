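"""FDTD solver: grid rules, TF/SF fidelity, sources, material assignment."""

import numpy as np
import pytest

from flydose.constants import C0, ETA0
from flydose.dielectrics import TissueProperties
from flydose.dosimetry import absorbed_power, embed_phantom
from flydose.fdtd import (
    DipoleSpec,
    MaterialGrid,
    PlaneWaveSpec,
    SimulationGrid,
    courant_timestep,
    dipole_phasors,
    dipole_radiated_flux,
    make_dipole_source,
    make_material_grid,
    make_plane_wave_source,
    numeric_wavenumber,
    run_harmonic,
)
from flydose.synthetic import generate_sphere_phantom

ANCHOR = dict(eps_r=42.0, sigma=2.8)


class TestGridRules:
    def test_courant_closed_form_at_20um(self):
        dt = courant_timestep(20e-6, 1.0)
        assert dt == pytest.approx(20e-6 / (C0 * np.sqrt(3.0)), rel=1e-14)
        assert dt == pytest.approx(3.85e-14, rel=2e-3)

    def test_timestep_monotone_in_pitch_and_linear_in_safety(self):
        assert courant_timestep(40e-6) > courant_timestep(20e-6)
        assert courant_timestep(20e-6, 0.5) == pytest.approx(
            0.5 * courant_timestep(20e-6, 1.0)
        )

    def test_invalid_safety_rejected(self):
        with pytest.raises(ValueError):
            courant_timestep(20e-6, 0.0)
        with pytest.raises(ValueError):
            courant_timestep(20e-6, 1.5)

    def test_grid_rejects_unstable_dt_and_thin_pml(self):
        with pytest.raises(ValueError, match="Courant"):
            SimulationGrid(dims=(20, 20, 20), pitch=20e-6, dt=1e-13, pml_cells=10)
        dt = courant_timestep(20e-6, 0.9)
        with pytest.raises(ValueError, match="PML"):
            SimulationGrid(dims=(20, 20, 20), pitch=20e-6, dt=dt, pml_cells=4)

    def test_numeric_wavenumber_close_to_vacuum_value(self):
        omega = 2 * np.pi * 6e9
        k = numeric_wavenumber(omega, np.array([1.0, 0, 0]), 100e-6, 1.9e-13)
        assert k == pytest.approx(omega / C0, rel=1e-3)


class TestMaterialGrid:
    def test_sphere_phantom_maps_to_exact_lossy_cell_count(self):
        sphere = generate_sphere_phantom(0.5e-3, 50e-6)
        props = TissueProperties(frequency=3.6e9, **ANCHOR)
        mats = make_material_grid(sphere, props, padding=16)
        assert int(np.count_nonzero(mats.sigma > 0)) == sphere.tissue_voxel_count
        assert np.all(mats.eps_r[mats.sigma > 0] == 42.0)
        assert np.all(mats.eps_r[mats.sigma == 0] == 1.0)

    def test_insufficient_padding_rejected(self):
        sphere = generate_sphere_phantom(0.5e-3, 50e-6)
        props = TissueProperties(frequency=3.6e9, **ANCHOR)
        with pytest.raises(ValueError, match="padding"):
            make_material_grid(sphere, props, padding=5)

    def test_material_bounds_enforced(self):
        with pytest.raises(ValueError, match="eps_r"):
            MaterialGrid(eps_r=0.5 * np.ones((4, 4, 4)), sigma=np.zeros((4, 4, 4)), pitch=1e-5)
        with pytest.raises(ValueError, match="sigma"):
            MaterialGrid(eps_r=np.ones((4, 4, 4)), sigma=-np.ones((4, 4, 4)), pitch=1e-5)


class TestPlaneWaveTFSF:
    def test_interior_rms_matches_incident_within_one_percent(self, empty_grid_run):
        """1 V/m RMS source reproduces 1 V/m total field inside the box."""
        rms = np.sqrt(empty_grid_run["phasors"].e_rms_sq())
        interior = rms[17:23, 17:23, 17:23]
        assert np.all(np.abs(interior - 1.0) < 0.01)

    def test_scattered_region_leakage_below_minus_40_db(self, empty_grid_run):
        rms = np.sqrt(empty_grid_run["phasors"].e_rms_sq())
        sl = [slice(11, 13), slice(28, 30), slice(11, 30)]
        ext = np.concatenate(
            [
                rms[sl[0], sl[2], sl[2]].ravel(), rms[sl[1], sl[2], sl[2]].ravel(),
                rms[sl[2], sl[0], sl[2]].ravel(), rms[sl[2], sl[1], sl[2]].ravel(),
                rms[sl[2], sl[2], sl[0]].ravel(), rms[sl[2], sl[2], sl[1]].ravel(),
            ]
        )
        assert 20 * np.log10(ext.max()) < -40.0

    def test_phase_advance_gives_vacuum_propagation_speed(self, empty_grid_run):
        """Phasor phase along the propagation axis advances at c within 0.5%."""
        ph = empty_grid_run["phasors"]
        ez = ph.Ez[15:25, 20, 20]
        dphi = -np.angle(ez[1:] / ez[:-1])  # e^{-ikx} convention
        k_meas = dphi.mean() / empty_grid_run["pitch"]
        c_meas = 2 * np.pi * empty_grid_run["f0"] / k_meas
        assert c_meas == pytest.approx(C0, rel=5e-3)

    def test_phasor_field_hdf5_round_trip(self, empty_grid_run, tmp_path):
        ph = empty_grid_run["phasors"]
        ph.to_hdf5(tmp_path / "ph.h5")
        back = type(ph).from_hdf5(tmp_path / "ph.h5")
        np.testing.assert_array_equal(back.Ez, ph.Ez)
        assert back.f0 == ph.f0 and back.pitch == ph.pitch

    def test_polarization_must_be_orthogonal_to_propagation(self):
        with pytest.raises(ValueError, match="perpendicular"):
            PlaneWaveSpec(k_dir=(1.0, 0, 0), pol=(1.0, 0, 0), f0=6e9)
        with pytest.raises(ValueError, match="unit"):
            PlaneWaveSpec(k_dir=(2.0, 0, 0), pol=(0, 0, 1.0), f0=6e9)

    def test_box_in_pml_rejected(self):
        dims = (40, 40, 40)
        mats = MaterialGrid(eps_r=np.ones(dims), sigma=np.zeros(dims), pitch=1e-4)
        spec = PlaneWaveSpec(k_dir=(1.0, 0, 0), pol=(0, 0, 1.0), f0=6e9)
        src = make_plane_wave_source(spec, (5, 35, 14, 25, 14, 25))
        with pytest.raises(ValueError, match="PML"):
            run_harmonic(mats, src, n_periods=1)

    def test_box_intersecting_phantom_rejected(self):
        sphere = generate_sphere_phantom(0.5e-3, 100e-6)
        props = TissueProperties(frequency=6e9, **ANCHOR)
        mats = make_material_grid(sphere, props, padding=14)
        spec = PlaneWaveSpec(k_dir=(1.0, 0, 0), pol=(0, 0, 1.0), f0=6e9)
        n = mats.dims[0]
        bad_box = (11, 13, 11, n - 12, 11, n - 12)  # phantom pokes out in x
        src = make_plane_wave_source(spec, bad_box)
        with pytest.raises(ValueError, match="intersects the phantom"):
            run_harmonic(mats, src, n_periods=1)

    def test_zero_amplitude_source_leaves_zero_phasors(self):
        dims = (30, 30, 30)
        mats = MaterialGrid(eps_r=np.ones(dims), sigma=np.zeros(dims), pitch=1e-4)
        spec = PlaneWaveSpec(k_dir=(1.0, 0, 0), pol=(0, 0, 1.0), f0=6e9, e_rms=0.0)
        ph = run_harmonic(mats, make_plane_wave_source(spec, (13, 17, 13, 17, 13, 17)), n_periods=1)
        assert np.all(ph.Ez == 0.0)
        assert np.all(ph.Hx == 0.0)


class TestLossyUpdate:
    def test_near_perfect_conductor_cell_pins_field(self):
        """A huge-conductivity cell stays bounded and far below the drive."""
        dims = (34, 34, 34)
        sigma = np.zeros(dims)
        sigma[16, 16, 16] = 1e6
        mats = MaterialGrid(eps_r=np.ones(dims), sigma=sigma, pitch=1e-4)
        spec = PlaneWaveSpec(k_dir=(1.0, 0, 0), pol=(0, 0, 1.0), f0=6e9)
        ph = run_harmonic(mats, make_plane_wave_source(spec, (13, 20, 13, 20, 13, 20)), n_periods=4)
        pinned = np.sqrt(ph.e_rms_sq()[16, 16, 16])
        assert np.isfinite(pinned)
        assert pinned < 0.05  # vs the 1 V/m incident RMS

    def test_absorbed_power_insensitive_to_extra_periods(self):
        """Extending the run 16 -> 24 periods moves sphere P_abs by < 1%."""
        sphere = generate_sphere_phantom(0.5e-3, 100e-6)
        props = TissueProperties(frequency=6e9, **ANCHOR)
        mats, box = embed_phantom(sphere, props)
        spec = PlaneWaveSpec(k_dir=(1.0, 0, 0), pol=(0, 0, 1.0), f0=6e9)
        p = []
        for n_periods in (16, 24):
            ph = run_harmonic(mats, make_plane_wave_source(spec, box), n_periods=n_periods)
            p.append(absorbed_power(ph, mats))
        assert abs(p[1] - p[0]) / p[0] < 0.01


class TestDipoleSource:
    P_235_DBM = 10 ** (23.5 / 10) / 1000.0  # 223.87 mW

    def test_radiated_flux_matches_requested_power(self):
        """Poynting integral over a vacuum sphere reproduces 23.5 dBm."""
        spec = DipoleSpec(
            position=(0, 0, 0), axis=(0, 0, 1.0), f0=3.6e9,
            radiated_power=self.P_235_DBM,
        )
        flux = dipole_radiated_flux(spec, radius=0.05)
        assert flux == pytest.approx(self.P_235_DBM, rel=0.05)
        assert flux == pytest.approx(0.22387, rel=0.05)

    def test_far_zone_field_falls_off_as_inverse_distance(self):
        spec = DipoleSpec(
            position=(0, 0, 0), axis=(0, 0, 1.0), f0=3.6e9, radiated_power=0.1
        )
        lam = C0 / 3.6e9
        rs = np.array([20 * lam, 40 * lam])
        pts = np.stack([rs, np.zeros(2), np.zeros(2)], axis=-1)
        e, _ = dipole_phasors(pts, spec)
        mags = np.linalg.norm(e, axis=-1)
        assert mags[0] / mags[1] == pytest.approx(2.0, rel=0.03)

    def test_field_scales_as_square_root_of_power(self):
        pt = np.array([[0.02, 0.0, 0.01]])
        e1, _ = dipole_phasors(pt, DipoleSpec((0, 0, 0), (0, 0, 1.0), 3.6e9, 0.1))
        e2, _ = dipole_phasors(pt, DipoleSpec((0, 0, 0), (0, 0, 1.0), 3.6e9, 0.2))
        ratio = np.linalg.norm(e2) / np.linalg.norm(e1)
        assert ratio == pytest.approx(np.sqrt(2.0), rel=1e-9)

    def test_far_field_impedance_is_free_space(self):
        spec = DipoleSpec((0, 0, 0), (0, 0, 1.0), 3.6e9, 0.1)
        pt = np.array([[30 * C0 / 3.6e9, 0.0, 0.0]])
        e, h = dipole_phasors(pt, spec)
        assert np.linalg.norm(e) / np.linalg.norm(h) == pytest.approx(ETA0, rel=0.01)

    def test_feed_point_inside_total_field_box_rejected(self):
        spec = DipoleSpec(
            position=(1.5e-3, 1.5e-3, 1.5e-3), axis=(0, 0, 1.0), f0=3.6e9,
            radiated_power=0.1,
        )
        with pytest.raises(ValueError, match="inside the total-field box"):
            make_dipole_source(spec, (10, 20, 10, 20, 10, 20), pitch=1e-4)


class TestLinearity:
    def test_phasors_and_power_scale_exactly_with_amplitude(self):
        """Doubling the source scales phasors x2 and P_abs x4 to 1e-10."""
        sphere = generate_sphere_phantom(0.4e-3, 80e-6)
        props = TissueProperties(frequency=6e9, **ANCHOR)
        mats, box = embed_phantom(sphere, props)
        powers = []
        fields = []
        for e_rms in (1.0, 2.0):
            spec = PlaneWaveSpec(k_dir=(1.0, 0, 0), pol=(0, 0, 1.0), f0=6e9, e_rms=e_rms)
            ph = run_harmonic(mats, make_plane_wave_source(spec, box), n_periods=3)
            powers.append(absorbed_power(ph, mats))
            fields.append(ph.Ez[mats.dims[0] // 2, mats.dims[1] // 2, mats.dims[2] // 2])
        assert abs(powers[1] / powers[0] - 4.0) <= 1e-10
        assert abs(fields[1] / fields[0] - 2.0) <= 1e-10
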