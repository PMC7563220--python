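"""Time-domain solver: material assignment, propagation physics, symmetry."""

import numpy as np
import pytest
from scipy.special import hankel2

from htplan.fdtd import (
    EPS0,
    MU0,
    ApplicatorModel,
    ChannelFieldSet,
    SolverError,
    SolverSettings,
    SourceTerm,
    assign_material_grids,
    solve_all_channels,
    solve_channel,
    solve_simultaneous,
    _run_2d,
    load_fieldset,
    save_fieldset,
)
from htplan.fixtures import disk_phantom, homogeneous_block_materials
from htplan.phantom import PhantomParams, generate_phantom
from htplan.tissues import SegmentationScheme, build_scheme


MUSCLE = (66.0, 0.708, 1090.0)


def _gamma(eps_r, sigma, f=1e8):
    omega = 2 * np.pi * f
    return np.sqrt(1j * omega * MU0 * (sigma + 1j * omega * eps_r * EPS0))


@pytest.fixture(scope="module")
def phantom():
    return generate_phantom(PhantomParams(), 1)


class TestMaterialAssignment:
    def test_urine_under_clinical_gets_muscle_properties(self, phantom, table):
        app = ApplicatorModel()
        st = SolverSettings()
        mats = assign_material_grids(phantom, build_scheme("clinical"), table, app, st)
        urine = mats.detailed_labels == 8  # urine code in the detailed volume
        assert urine.any()
        assert np.all(mats.eps_r[urine] == 66.0)
        assert np.all(mats.sigma[urine] == 0.708)
        assert np.all(mats.rho[urine] == 1090.0)

    def test_urine_under_bladder_scheme_keeps_urine_properties(self, phantom, table):
        app = ApplicatorModel()
        st = SolverSettings()
        mats = assign_material_grids(phantom, build_scheme("bladder"), table, app, st)
        urine = mats.detailed_labels == 8
        assert np.all(mats.eps_r[urine] == 49.9)
        assert np.all(mats.sigma[urine] == 1.750)
        assert np.all(mats.rho[urine] == 1024.0)

    def test_bolus_water_and_exterior_air(self, phantom, table):
        app = ApplicatorModel()
        st = SolverSettings()
        mats = assign_material_grids(phantom, build_scheme("detailed"), table, app, st)
        ci = mats.center[0]
        # just inside the shell but outside the body: water bolus
        j_bolus = ci + int((app.shell_inner_radius_mm - 15) / mats.spacing_mm)
        assert mats.eps_r[ci, j_bolus] == 80.9
        # beyond the shell: free space
        assert mats.eps_r[ci, -1] == 1.0
        assert mats.sigma[ci, -1] == 0.0

    def test_unmapped_label_error_names_the_label(self, phantom, table):
        partial = SegmentationScheme("clinical", {"muscle": "muscle"})
        with pytest.raises(Exception, match="urine|sat"):
            assign_material_grids(
                phantom, partial, table, ApplicatorModel(), SolverSettings()
            )


class TestPropagationPhysics:
    def test_plane_wave_attenuation_and_phase_in_muscle(self):
        """Lossy-medium closed form: gamma = sqrt(jwmu(sigma + jweps))."""
        eps_r, sigma, rho = MUSCLE
        n, m = 120, 300
        mats = homogeneous_block_materials((n, m), eps_r, sigma, rho, 2.5)
        j0 = 30
        src = SourceTerm(cells=[(i, j0) for i in range(n)])
        ph = _run_2d(mats, [src], 1e8, SolverSettings())
        j = np.arange(j0 + 15, m - 60)
        d = (j - j0) * 2.5e-3
        prof = ph[n // 2, j]
        alpha_fit = -np.polyfit(d, np.log(np.abs(prof)), 1)[0]
        beta_fit = -np.polyfit(d, np.unwrap(np.angle(prof)), 1)[0]
        gamma = _gamma(eps_r, sigma)
        assert alpha_fit == pytest.approx(gamma.real, rel=0.05)
        assert beta_fit == pytest.approx(gamma.imag, rel=0.05)

    def test_point_source_matches_2d_greens_function(self):
        """Cylindrical-wave oracle |H0^(2)(kr)| for a vacuum line source."""
        n = 161
        mats = homogeneous_block_materials((n, n), 1.0, 0.0, 1.2, 5.0)
        f = 1e9  # shorter wavelength so kr spans ~1.3..4.5 inside the grid
        ph = _run_2d(
            mats, [SourceTerm([(n // 2, n // 2)])], f, SolverSettings(periods=12)
        )
        k = 2 * np.pi * f / 299792458.0
        r_cells = np.arange(12, 65)
        r = r_cells * 5e-3
        measured = np.abs(ph[n // 2, n // 2 + r_cells])
        oracle = np.abs(hankel2(0, k * r))
        ratio = measured / oracle
        ratio /= ratio[0]
        assert np.abs(ratio - 1).max() < 0.10

    def test_steady_state_after_default_periods(self):
        """Phasor over final vs penultimate period differs by < 1 % RMS."""
        n = 121
        mats = homogeneous_block_materials((n, n), 66.0, 0.708, 1090.0, 5.0)
        final, prev = _run_2d(
            mats, [SourceTerm([(20, n // 2)])], 1e8, SolverSettings(),
            collect_penultimate=True,
        )
        num = np.sqrt(np.mean(np.abs(final - prev) ** 2))
        den = np.sqrt(np.mean(np.abs(final) ** 2))
        assert num / den < 0.01

    def test_unstable_time_step_raises(self):
        n = 61
        mats = homogeneous_block_materials((n, n), 1.0, 0.0, 1.2, 5.0)
        with pytest.raises(SolverError, match="time step"):
            _run_2d(
                mats, [SourceTerm([(n // 2, n // 2)])], 1e8,
                SolverSettings(courant=1.15, periods=15),
            )


class TestChannelSolves:
    def test_zero_drive_amplitude_gives_zero_field(self, table):
        ph = disk_phantom(radius_mm=60, target_radius_mm=15)
        app = ApplicatorModel(
            n_channels=2, ring_radius_mm=120, shell_inner_radius_mm=140,
            air_margin_mm=25,
        )
        st = SolverSettings(periods=2)
        mats = assign_material_grids(ph, build_scheme("detailed"), table, app, st)
        f = solve_channel(mats, app, 0, st, amplitude=0.0)
        assert np.all(f == 0.0)

    def test_superposition_of_two_channels(self, table):
        """Simultaneous drive equals the sum of the same-waveform solves."""
        ph = disk_phantom(radius_mm=60, target_radius_mm=15)
        app = ApplicatorModel(
            n_channels=2, ring_radius_mm=120, shell_inner_radius_mm=140,
            air_margin_mm=25,
        )
        st = SolverSettings(periods=8)
        mats = assign_material_grids(ph, build_scheme("detailed"), table, app, st)
        w = [0.8 * np.exp(0.3j), 0.5 * np.exp(1.1j)]
        fa = solve_channel(mats, app, 0, st, abs(w[0]), float(np.angle(w[0])))
        fb = solve_channel(mats, app, 1, st, abs(w[1]), float(np.angle(w[1])))
        fab = solve_simultaneous(mats, app, st, w)
        rel = np.sqrt(np.mean(np.abs(fab - (fa + fb)) ** 2)) / np.sqrt(
            np.mean(np.abs(fa + fb) ** 2)
        )
        assert rel < 1e-6

    def test_mirrored_channels_give_mirrored_fields(self, disk_setup, disk_applicator):
        mats, fields = disk_setup
        # channels 1 and 11 are mirror images in the left-right plane
        f1, f11 = fields.fields[1], fields.fields[11]
        err = np.abs(f1[::-1, :, :] - f11).max() / np.abs(f1).max()
        assert err < 1e-9

    def test_fieldset_shape_and_channel_count(self, disk_setup, disk_applicator):
        mats, fields = disk_setup
        assert fields.n_channels == disk_applicator.n_channels
        assert fields.grid_shape == mats.shape
        fields.validate_against(mats)

    def test_grid_mismatch_detected(self, disk_setup, table):
        mats, fields = disk_setup
        other = homogeneous_block_materials((10, 10), 1.0, 0.0, 1.2, 5.0)
        with pytest.raises(ValueError, match="grid"):
            fields.validate_against(other)

    def test_nonfinite_fields_rejected(self):
        bad = np.full((1, 4, 4, 1), np.nan, complex)
        with pytest.raises(SolverError, match="finite"):
            ChannelFieldSet(bad, 5.0, 1e8, "2d")

    def test_single_channel_applicator(self, table):
        ph = disk_phantom(radius_mm=60, target_radius_mm=15)
        app = ApplicatorModel(
            n_channels=1, ring_radius_mm=120, shell_inner_radius_mm=140,
            air_margin_mm=25,
        )
        st = SolverSettings(periods=4)
        mats = assign_material_grids(ph, build_scheme("detailed"), table, app, st)
        fs = solve_all_channels(mats, app, st)
        assert fs.n_channels == 1

    def test_out_of_range_channel_rejected(self, disk_setup, disk_applicator):
        mats, _ = disk_setup
        with pytest.raises(ValueError, match="channel"):
            solve_channel(mats, disk_applicator, 99, SolverSettings())


class TestThreeDimensional:
    def test_superposition_and_finiteness(self, table):
        n = 25
        mats = homogeneous_block_materials((n, n, n), 1.0, 0.0, 1.2, 5.0)
        app = ApplicatorModel(
            n_channels=2, ring_radius_mm=40, shell_inner_radius_mm=50,
            ring_z_offsets_mm=(0.0,),
        )
        st = SolverSettings(mode="3d", periods=3)
        f0 = solve_channel(mats, app, 0, st)
        f1 = solve_channel(mats, app, 1, st)
        both = solve_simultaneous(mats, app, st, [1.0, 1.0])
        assert np.all(np.isfinite(f0)) and np.abs(f0).max() > 0
        assert f0.shape == (n, n, n, 3)
        rel = np.sqrt(np.mean(np.abs(both - (f0 + f1)) ** 2)) / np.sqrt(
            np.mean(np.abs(f0 + f1) ** 2)
        )
        assert rel < 1e-6

    def test_zero_drive_3d(self, table):
        n = 15
        mats = homogeneous_block_materials((n, n, n), 1.0, 0.0, 1.2, 5.0)
        app = ApplicatorModel(
            n_channels=1, ring_radius_mm=20, shell_inner_radius_mm=30,
            ring_z_offsets_mm=(0.0,),
        )
        f = solve_channel(mats, app, 0, SolverSettings(mode="3d", periods=2), 0.0)
        assert np.all(f == 0.0)


def test_fieldset_hdf5_roundtrip(tmp_path, disk_setup):
    _, fields = disk_setup
    path = tmp_path / "fields.h5"
    save_fieldset(fields, path)
    loaded = load_fieldset(path)
    assert np.array_equal(loaded.fields, fields.fields)
    assert loaded.frequency_hz == fields.frequency_hz
    assert loaded.mode == fields.mode
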