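import numpy as np
import pytest

from palmcount import (
    Cell,
    PhotokineticsParams,
    SceneParams,
    SyntheticScene,
    apply_quality_filter,
    counts_per_frame,
    fit_base_level,
    generate_scene,
    merge_localizations,
    simulate_fov,
    write_fov,
)


def quiet_kinetics(**overrides) -> PhotokineticsParams:
    """No spurious signal, no torches, no quality outliers."""
    base = dict(
        spurious_amplitude=0.0,
        torch_rate=0.0,
        outlier_fraction=0.0,
        activation_rate=0.02,
    )
    base.update(overrides)
    return PhotokineticsParams(**base)


def single_molecule_scene(x_nm=5000.0, y_nm=20000.0) -> SyntheticScene:
    params = SceneParams(n_cells_per_plane=1, torch_fraction=0.0)
    cell = Cell(
        cx_nm=x_nm, cy_nm=y_nm, phi=0.0, tilt=0.0, depth_um=0.0,
        length_um=2.0, width_um=1.0,
    )
    return SyntheticScene(
        params=params,
        cells=[cell],
        mol_x_nm=np.array([x_nm]),
        mol_y_nm=np.array([y_nm]),
        mol_depth_um=np.array([0.0]),
        mol_cell=np.array([0]),
    )


class TestSceneGeneration:
    def test_zero_density_gives_zero_molecules(self):
        scene = generate_scene(SceneParams(molecule_density=0.0), seed=1)
        assert scene.mol_x_nm.size == 0

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            SceneParams(fov_width_um=-1.0)
        with pytest.raises(ValueError):
            SceneParams(cell_width_um=0.0)
        with pytest.raises(ValueError):
            SceneParams(plane_depths_um=(0.0, 4.5, 4.5))
        with pytest.raises(ValueError):
            SceneParams(torch_fraction=1.5)

    def test_coverslip_cells_are_horizontal(self):
        """horizontal_fraction(0)=1: every depth-0 cell projects full length."""
        scene = generate_scene(SceneParams(n_cells_per_plane=40), seed=3)
        full_half = (2.0 - 1.0) * 1000.0 / 2.0
        for cell in scene.cells_at(0.0):
            assert cell.tilt == 0.0
            assert cell.seg_half_nm == pytest.approx(full_half)

    def test_molecules_inside_owning_footprint(self):
        scene = generate_scene(SceneParams(n_cells_per_plane=10), seed=5)
        for i in range(scene.mol_x_nm.size):
            cell = scene.cells[scene.mol_cell[i]]
            assert cell.contains(scene.mol_x_nm[i], scene.mol_y_nm[i])

    def test_tilted_footprint_never_larger_than_horizontal(self):
        horizontal = Cell(0, 0, 0.0, 0.0, 0.0, 2.0, 1.0)
        for tilt in np.linspace(0, np.pi / 2, 7):
            tilted = Cell(0, 0, 0.0, float(tilt), 9.0, 2.0, 1.0)
            assert tilted.area_um2 <= horizontal.area_um2 + 1e-12

    def test_depth0_total_footprint_largest(self):
        """Horizontal base layer projects more area than isotropic planes."""
        for seed in range(5):
            scene = generate_scene(SceneParams(n_cells_per_plane=30), seed=seed)
            a0 = scene.footprint_area_um2(0.0)
            assert a0 >= scene.footprint_area_um2(13.5)

    def test_poisson_molecule_count(self):
        """20 cells of 2 um^2 footprint at 50 um^-2: mean 2000 over 100 seeds."""
        # spherocylinder with W=1: area = (L-1) + pi/4 = 2  =>  L = 3 - pi/4
        length = 3.0 - np.pi / 4.0
        params = SceneParams(
            plane_depths_um=(0.0,),
            n_cells_per_plane=20,
            cell_length_um=length,
            cell_width_um=1.0,
            horizontal_fraction=1.0,
            molecule_density=50.0,
            torch_fraction=0.0,
        )
        counts = [generate_scene(params, seed=s).mol_x_nm.size for s in range(100)]
        expected = 50.0 * 20 * 2.0
        se = np.sqrt(expected / 100)
        assert abs(np.mean(counts) - expected) <= 3 * se


class TestFovSimulation:
    def test_no_spurious_no_torch_gives_empty_pre(self):
        scene = generate_scene(SceneParams(torch_fraction=0.0), seed=2)
        pre, _act, _ = simulate_fov(scene, quiet_kinetics(), 0.0, seed=9)
        assert len(pre) == 0

    def test_single_molecule_recovered_as_one(self):
        scene = single_molecule_scene()
        kin = quiet_kinetics(
            activation_rate=0.9, mean_on_frames=3.0,
            detection_efficiency=1.0, loc_sigma_nm=5.0,
        )
        pre, act, truth = simulate_fov(scene, kin, 0.0, seed=4)
        assert len(pre) == 0
        assert truth.n_detected == 1
        assert len(act) >= 1
        assert np.all(np.abs(act.x - 5000.0) < 5 * 5.0)
        assert np.all(np.abs(act.y - 20000.0) < 5 * 5.0)
        assert np.all(np.diff(act.frame) == 1)  # one consecutive run
        assert len(merge_localizations(act)) == 1

    def test_500_separated_molecules_recovered_exactly(self):
        """Zero localization noise + separation: merged count == ground truth."""
        params = SceneParams(n_cells_per_plane=1, torch_fraction=0.0)
        cell = Cell(5000.0, 20000.0, np.pi / 2, 0.0, 0.0, 38.0, 8.0)
        gx, gy = np.meshgrid(
            np.linspace(2000.0, 8000.0, 20), np.linspace(2000.0, 38000.0, 25)
        )
        scene = SyntheticScene(
            params=params,
            cells=[cell],
            mol_x_nm=gx.ravel(),
            mol_y_nm=gy.ravel(),
            mol_depth_um=np.zeros(500),
            mol_cell=np.zeros(500, dtype=int),
        )
        kin = quiet_kinetics(
            activation_rate=0.05, detection_efficiency=1.0, loc_sigma_nm=0.0
        )
        _pre, act, truth = simulate_fov(scene, kin, 0.0, seed=6)
        assert truth.n_detected == 500
        assert len(merge_localizations(act)) == 500

    def test_emitter_id_conservation(self):
        """Distinct act-table emitter IDs equal the detected-molecule count."""
        scene = generate_scene(SceneParams(seed=8), seed=8)
        _pre, _act, truth = simulate_fov(scene, PhotokineticsParams(), 4.5, seed=8)
        assert truth.n_distinct_act_emitters == truth.n_detected

    def test_spurious_decay_continues_across_videos(self):
        scene = generate_scene(SceneParams(n_cells_per_plane=0), seed=1)
        kin = PhotokineticsParams(
            spurious_amplitude=40.0, spurious_decay=0.002,
            torch_rate=0.0, outlier_fraction=0.0,
        )
        pre, act, _ = simulate_fov(scene, kin, 0.0, seed=2)
        # act-video spurious count must continue the decay, not restart
        expected = (40.0 / 0.002) * (np.exp(-0.002 * 1000) - np.exp(-0.002 * 2000))
        assert len(act) == pytest.approx(expected, rel=0.1)
        restarted = (40.0 / 0.002) * (1.0 - np.exp(-0.002 * 1000))
        assert abs(len(act) - expected) < abs(len(act) - restarted)

    def test_spurious_exponential_rate_recovered(self):
        """Log-linear fit on a simulated pre-video recovers the decay constant."""
        scene = generate_scene(SceneParams(n_cells_per_plane=0), seed=1)
        kin = PhotokineticsParams(
            spurious_amplitude=80.0, spurious_decay=0.003,
            torch_rate=0.0, outlier_fraction=0.0,
            n_pre_frames=2000, n_act_frames=1,
        )
        pre, _act, _ = simulate_fov(scene, kin, 0.0, seed=12)
        series = counts_per_frame(pre, (1, 2000))
        fit = fit_base_level(series, fit_window=(1, 2000))
        assert fit.decay == pytest.approx(0.003, rel=0.05)

    def test_outlier_fraction_violates_filter(self):
        scene = generate_scene(SceneParams(seed=2), seed=2)
        kin = PhotokineticsParams(outlier_fraction=0.3)
        _pre, act, truth = simulate_fov(scene, kin, 0.0, seed=3)
        kept = apply_quality_filter(act)
        # exactly the outlier rows are removed
        assert len(kept) == len(act) - int(truth.act_outlier.sum())

    def test_byte_identical_given_seed(self, tmp_path):
        scene = generate_scene(SceneParams(seed=7), seed=7)
        kin = PhotokineticsParams()
        out = {}
        for tag in ("a", "b"):
            pre, act, truth = simulate_fov(scene, kin, 0.0, seed=99)
            paths = write_fov(pre, act, truth, tmp_path / tag, "fov")
            out[tag] = {k: p.read_bytes() for k, p in paths.items()}
        assert out["a"] == out["b"]

    def test_unknown_depth_rejected(self):
        scene = generate_scene(SceneParams(), seed=1)
        with pytest.raises(ValueError, match="depth"):
            simulate_fov(scene, PhotokineticsParams(), 7.7, seed=1)
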