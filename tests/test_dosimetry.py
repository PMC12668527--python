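"""Absorbed-power bookkeeping, exposure protocols and rescaling algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flydose.dielectrics import cole_cole_eval
from flydose.dosimetry import (
    DoseReport,
    absorbed_power,
    dose_ratio,
    equivalent_farfield_strength,
    farfield_ensemble,
    nearfield_dose,
    nearfield_protocol,
    rescale_dose,
)
from flydose.fdtd import MaterialGrid
from flydose.fdtd.solver import PhasorField
from flydose.synthetic import generate_sphere_phantom


def _uniform_phasors(dims, pitch, ez_amp):
    zero = np.zeros(dims, complex)
    return PhasorField(
        Ex=zero.copy(), Ey=zero.copy(), Ez=np.full(dims, ez_amp, complex),
        Hx=zero.copy(), Hy=zero.copy(), Hz=zero.copy(), f0=3.6e9, pitch=pitch,
    )


class TestAbsorbedPower:
    def test_uniform_field_closed_form(self):
        """n cells of conductivity sigma in field E_rms: n sigma E^2 d^3."""
        dims, pitch, sigma = (5, 5, 5), 2e-5, 2.8
        labels = np.zeros(dims, np.uint8)
        labels[1:4, 1:4, 1:4] = 1  # 27 cells
        mats = MaterialGrid(
            eps_r=np.where(labels > 0, 42.0, 1.0),
            sigma=np.where(labels > 0, sigma, 0.0),
            pitch=pitch, labels=labels, tissue_table={1: "tissue"},
        )
        e_rms = 3.0
        ph = _uniform_phasors(dims, pitch, ez_amp=np.sqrt(2.0) * e_rms)
        expect = 27 * sigma * e_rms**2 * pitch**3
        assert absorbed_power(ph, mats) == pytest.approx(expect, rel=1e-12)

    def test_zero_conductivity_absorbs_nothing(self):
        dims = (4, 4, 4)
        labels = np.ones(dims, np.uint8)
        mats = MaterialGrid(
            eps_r=np.full(dims, 42.0), sigma=np.zeros(dims), pitch=1e-5,
            labels=labels, tissue_table={1: "tissue"},
        )
        ph = _uniform_phasors(dims, 1e-5, 1.0)
        assert absorbed_power(ph, mats) == 0.0

    def test_empty_mask_warns_and_returns_zero(self):
        dims = (4, 4, 4)
        labels = np.ones(dims, np.uint8)
        mats = MaterialGrid(
            eps_r=np.full(dims, 42.0), sigma=np.full(dims, 2.8), pitch=1e-5,
            labels=labels, tissue_table={1: "tissue"},
        )
        ph = _uniform_phasors(dims, 1e-5, 1.0)
        with pytest.warns(UserWarning, match="zero cells"):
            assert absorbed_power(ph, mats, np.zeros(dims, bool)) == 0.0

    def test_tissue_masks_partition_whole_body_exactly(self):
        """Per-tissue sub-integrals sum to the whole-body integral."""
        rng = np.random.default_rng(0)
        dims, pitch = (6, 6, 6), 1e-5
        labels = rng.integers(0, 4, size=dims).astype(np.uint8)
        if not labels.any():
            labels[0, 0, 0] = 1
        mats = MaterialGrid(
            eps_r=np.where(labels > 0, 42.0, 1.0),
            sigma=np.where(labels > 0, 2.8, 0.0),
            pitch=pitch, labels=labels,
            tissue_table={1: "a", 2: "b", 3: "c"},
        )
        ph = _uniform_phasors(dims, pitch, 1.0 + 0.5j)
        ph.Ex += rng.normal(size=dims)
        whole = absorbed_power(ph, mats)
        parts = sum(absorbed_power(ph, mats, t) for t in ("a", "b", "c"))
        assert parts == whole  # identical float sums over a partition

    def test_grid_mismatch_rejected(self):
        mats = MaterialGrid(
            eps_r=np.ones((4, 4, 4)), sigma=np.zeros((4, 4, 4)), pitch=1e-5
        )
        ph = _uniform_phasors((5, 5, 5), 1e-5, 1.0)
        with pytest.raises(ValueError, match="differ"):
            absorbed_power(ph, mats)


class TestFarFieldProtocol:
    def test_ensemble_enumerates_six_directions_twice(self):
        specs = farfield_ensemble(3.6e9)
        assert len(specs) == 12
        dirs = {tuple(s.k_dir) for s in specs}
        assert len(dirs) == 6
        for s in specs:
            assert abs(np.dot(s.k_dir, s.pol)) < 1e-12

    def test_resolution_guard_rejects_coarse_grids(self, fly_coarse, insect_params):
        from flydose.dosimetry import farfield_ensemble_dose

        props = cole_cole_eval(insect_params, 240e9)  # lambda_tissue/10 ~ 51 um
        with pytest.raises(ValueError, match="tenth of the in-tissue wavelength"):
            farfield_ensemble_dose(fly_coarse, props, 240e9)


class TestNearFieldProtocol:
    def test_protocol_has_twelve_locations_two_orientations(self):
        placements = nearfield_protocol()
        assert len(placements) == 24
        near = [p for p in placements if p.label.startswith("near")]
        orth = [p for p in placements if p.label.endswith("orth")]
        assert len(near) == 12 and len(orth) == 12

    def test_rings_sit_at_protocol_distances(self):
        for p in nearfield_protocol():
            offset = np.asarray(p.dipole_offset)
            axis = np.asarray(p.dipole_axis)
            # radial distance from the arm's axis line
            radial = np.linalg.norm(offset - (offset @ axis) * axis)
            expected = 11e-3 if p.label.startswith("near") else 34e-3
            assert radial == pytest.approx(expected, rel=1e-9)

    def test_near_ring_doses_dominate_and_orthogonal_wins_close_in(
        self, fly_coarse, insect_params
    ):
        """11 mm doses exceed 34 mm for matched orientation; at the near
        ring the radial (orthogonal) body orientation absorbs more."""
        props = cole_cole_eval(insect_params, 3.6e9)
        placements = nearfield_protocol(n_azimuths=1)
        rep = nearfield_dose(
            fly_coarse, props, placements, radiated_power=0.22387, n_periods=4
        )
        by_label = dict(zip(rep.config_labels, rep.whole_body))
        assert by_label["near-az0-par"] > by_label["far-az0-par"]
        assert by_label["near-az0-orth"] > by_label["far-az0-orth"]
        assert by_label["near-az0-orth"] > by_label["near-az0-par"]

    def test_mirrored_sphere_placements_absorb_equally(self, insect_params):
        sphere = generate_sphere_phantom(0.5e-3, 100e-6)
        props = cole_cole_eval(insect_params, 3.6e9)
        base = nearfield_protocol(n_azimuths=1)[0]
        mirrored = type(base)(
            dipole_offset=(
                base.dipole_offset[0], -base.dipole_offset[1], base.dipole_offset[2]
            ),
            dipole_axis=base.dipole_axis, label="mirror",
        )
        rep = nearfield_dose(
            sphere, props, [base, mirrored], radiated_power=0.1, n_periods=3
        )
        a, b = rep.whole_body
        assert a == pytest.approx(b, rel=0.03)

    def test_dose_scales_linearly_with_radiated_power(self, insect_params):
        sphere = generate_sphere_phantom(0.5e-3, 100e-6)
        props = cole_cole_eval(insect_params, 3.6e9)
        pl = nearfield_protocol(n_azimuths=1)[:1]
        p1 = nearfield_dose(sphere, props, pl, radiated_power=0.1, n_periods=2)
        p2 = nearfield_dose(sphere, props, pl, radiated_power=0.025, n_periods=2)
        assert p2.whole_body[0] == pytest.approx(0.25 * p1.whole_body[0], rel=1e-9)


class TestRescalingAlgebra:
    def test_behavioural_dose_rescaling_reproduces_printed_value(self):
        """3.56 nW at 5.4 V/m rescales to the 9.88 nW upper bound at 9 V/m."""
        assert rescale_dose(3.56e-9, 5.4, 9.0) == pytest.approx(9.88e-9, rel=0.005)

    def test_identity_and_quadratic_scaling(self):
        assert rescale_dose(2.0e-9, 5.0, 5.0) == 2.0e-9
        assert rescale_dose(2.0e-9, 5.0, 10.0) == pytest.approx(8.0e-9)

    def test_equivalent_field_strength_inverts_baseline(self):
        assert equivalent_farfield_strength(1.0e-7, 1.0e-7) == 1.0
        assert equivalent_farfield_strength(4.0e-7, 1.0e-7) == 2.0
        assert equivalent_farfield_strength(1.91e-3, 1.2224e-7) == pytest.approx(
            125.0, rel=1e-3
        )

    @given(
        p_ref=st.floats(1e-12, 1e-3), e_ref=st.floats(0.1, 100.0),
        e_target=st.floats(0.1, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_rescale_then_invert_round_trips(self, p_ref, e_ref, e_target):
        p_at_1 = rescale_dose(p_ref, e_ref, 1.0)
        p_t = rescale_dose(p_ref, e_ref, e_target)
        assert equivalent_farfield_strength(p_t, p_at_1) == pytest.approx(
            e_target, rel=1e-12
        )

    def test_dose_ratio_examples(self):
        assert dose_ratio(1.91e-3, 9.88e-9) >= 300.0
        assert dose_ratio(5.0, 5.0) == 1.0
        assert dose_ratio(0.215e-3, 9.88e-9) == pytest.approx(2.176e4, rel=1e-3)

    def test_non_positive_references_rejected(self):
        with pytest.raises(ValueError):
            rescale_dose(1.0, 0.0, 2.0)
        with pytest.raises(ValueError):
            equivalent_farfield_strength(1.0, 0.0)
        with pytest.raises(ValueError):
            dose_ratio(1.0, 0.0)


class TestDoseReport:
    def test_summary_and_csv_export(self, tmp_path, fly_ensemble_report):
        rep = fly_ensemble_report
        s = rep.summary()
        assert s["min_W"] <= s["mean_W"] <= s["max_W"]
        rep.to_csv(tmp_path / "dose.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "dose.csv")
        assert len(df) == 12
        tissues = [c for c in df.columns if c not in ("configuration", "whole_body")]
        np.testing.assert_allclose(
            df[tissues].sum(axis=1), df["whole_body"], rtol=1e-9
        )

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            DoseReport(
                frequency=3.6e9, config_labels=["a"],
                per_tissue={"t": np.array([-1.0])}, reference={},
            )
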