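import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fvheeplan as fp
from fvheeplan.phantoms import StructureSet, VoxelGrid


class TestVoxelGrid:
    def test_world_index_roundtrip(self):
        grid = VoxelGrid((-1.0, 0.5, 2.0), (0.25, 0.5, 1.0), (10, 20, 5))
        idx = np.array([[0, 0, 0], [9, 19, 4], [3, 7, 2]], dtype=float)
        assert np.allclose(grid.world_to_index(grid.index_to_world(idx)), idx)

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            VoxelGrid((0, 0, 0), (0.0, 1, 1), (2, 2, 2))

    def test_invalid_dims(self):
        with pytest.raises(ValueError):
            VoxelGrid((0, 0, 0), (1, 1, 1), (0, 2, 2))


class TestWaterBox:
    def test_construction(self):
        phantom, structures = fp.make_water_box((20, 20, 30), 0.25)
        assert phantom.grid.dims == (80, 80, 120)
        assert np.all(phantom.density == 1.0)
        assert structures["BODY"].all()

    def test_unit_cube_mass(self):
        phantom, _ = fp.make_water_box((1, 1, 1), 1.0)
        assert phantom.grid.dims == (1, 1, 1)
        assert phantom.mass == pytest.approx(1.0)

    def test_total_mass(self):
        # sum(density * voxel volume) oracle: 20*20*30 cm^3 of unit density
        phantom, _ = fp.make_water_box((20, 20, 30), 0.25)
        assert phantom.mass == pytest.approx(12_000.0, rel=1e-9)

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            fp.make_water_box((0, 10, 10), 0.25)
        with pytest.raises(ValueError):
            fp.make_water_box((10, 10, 10), -0.25)

    def test_centered_at_isocenter(self):
        phantom, _ = fp.make_water_box((10, 10, 10), 0.5)
        centers = [phantom.grid.voxel_centers(a) for a in range(3)]
        for c in centers:
            assert c.mean() == pytest.approx(0.0, abs=1e-12)


class TestExpandMask:
    def test_zero_margin_identity(self):
        rng = np.random.default_rng(0)
        mask = rng.random((12, 12, 12)) < 0.2
        out = fp.expand_mask(mask, 0.0, (0.25, 0.25, 0.25))
        assert np.array_equal(out, mask)

    def test_single_voxel_ball(self):
        # brute-force distance oracle: voxel at the center, m = 0.5 cm on a
        # 0.25 cm grid -> ball of radius 2 voxels
        mask = np.zeros((11, 11, 11), dtype=bool)
        mask[5, 5, 5] = True
        out = fp.expand_mask(mask, 0.5, (0.25, 0.25, 0.25))
        ii, jj, kk = np.meshgrid(*[np.arange(11)] * 3, indexing="ij")
        dist = 0.25 * np.sqrt((ii - 5) ** 2 + (jj - 5) ** 2 + (kk - 5) ** 2)
        assert np.array_equal(out, dist <= 0.5 + 1e-12)

    def test_sphere_margin_equals_larger_sphere(self):
        # margin 0.5 applied to a r=1 cm sphere equals the r=1.5 cm
        # voxelized sphere by the center-distance rule
        grid = VoxelGrid((-2.375, -2.375, -2.375), (0.25,) * 3, (20, 20, 20))
        x, y, z = grid.coordinate_mesh()
        small = x**2 + y**2 + z**2 <= 1.0**2
        out = fp.expand_mask(small, 0.5, grid.spacing)
        # oracle: brute-force all-pairs distance thresholding
        pts = np.stack([x, y, z], axis=-1).reshape(-1, 3)
        src = pts[small.ravel()]
        d2 = ((pts[:, None, :] - src[None, :, :]) ** 2).sum(-1).min(axis=1)
        brute = (d2 <= 0.5**2 + 1e-12).reshape(small.shape)
        assert np.array_equal(out, brute)

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            fp.expand_mask(np.ones((3, 3, 3), dtype=bool), -0.1, (1, 1, 1))

    @settings(max_examples=20, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        m1=st.floats(0.0, 1.0),
        m2=st.floats(0.0, 1.0),
    )
    def test_monotone_in_margin(self, seed, m1, m2):
        rng = np.random.default_rng(seed)
        mask = rng.random((8, 8, 8)) < 0.15
        lo, hi = sorted([m1, m2])
        small = fp.expand_mask(mask, lo, (0.3, 0.25, 0.4))
        big = fp.expand_mask(mask, hi, (0.3, 0.25, 0.4))
        assert not np.any(small & ~big)
        assert not np.any(mask & ~small)


class TestPlanningCases:
    @pytest.fixture(scope="class")
    def lateral(self):
        return fp.make_planning_case(fp.case_template("F"), "lateral", voxel_size_cm=0.4)

    def test_lateral_geometry(self, lateral):
        phantom, structures = lateral
        from fvheeplan.spot_grid import mask_centroid

        centroid = mask_centroid(structures["PTV"], phantom.grid)
        assert np.linalg.norm(centroid[:2]) >= 3.0
        assert not np.any(structures["PTV"] & structures["contralateral"])

    def test_central_geometry(self):
        phantom, structures = fp.make_planning_case(
            fp.case_template("P1"), "central", voxel_size_cm=0.4
        )
        from fvheeplan.spot_grid import mask_centroid

        centroid = mask_centroid(structures["PTV"], phantom.grid)
        assert np.linalg.norm(centroid[:2]) < 0.4
        # rectum-like rod abuts the posterior PTV surface (within one voxel)
        rod = structures["rectum_like"]
        assert rod.any()
        dist = fp.expand_mask(structures["PTV"], 2 * 0.4, phantom.grid.spacing)
        assert np.any(rod & dist)

    def test_ptv_volume_analytic(self, lateral):
        phantom, structures = lateral
        r, h = 1.5, 0.4
        vol = structures["PTV"].sum() * phantom.grid.voxel_volume
        shell = 4 * np.pi * r**2 * h * np.sqrt(3)
        assert abs(vol - 4 / 3 * np.pi * r**3) <= shell

    def test_ptv_inside_body(self, lateral):
        _, structures = lateral
        structures.validate_for_planning()

    def test_bilateral(self):
        _, structures = fp.make_planning_case(fp.case_template("B"), "bilateral", voxel_size_cm=0.5)
        assert structures["PTV"].any()
        assert not np.any(structures["PTV"] & structures["central_rod"])

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            fp.make_planning_case(fp.case_template("B"), "diagonal")


class TestCaseTemplates:
    def test_table_parameters(self):
        b = fp.case_template("B")
        assert b.prescription_gy == 12.0 and b.normalization == "D95"
        assert b.beam_angles_deg == (-130.0, -90.0, 130.0)
        l1 = fp.case_template("L1")
        assert l1.prescription_gy == 60.0 and l1.normalization == "D50"
        f = fp.case_template("F")
        assert f.prescription_gy == 46.5 and f.fractions == 10
        assert f.fraction_dose_gy == pytest.approx(4.65)

    def test_json_roundtrip(self, tmp_path):
        t = fp.case_template("L2")
        t.to_json(tmp_path / "t.json")
        assert fp.CaseTemplate.from_json(tmp_path / "t.json") == t

    def test_invalid_template(self):
        with pytest.raises(ValueError):
            fp.CaseTemplate("X", (0.0,), 250.0, -0.1, 0.36, 60.0, 30, "D50")
        with pytest.raises(ValueError):
            fp.CaseTemplate("X", (0.0,), 250.0, 0.1, 0.36, 60.0, 30, "D77")


class TestStructureSet:
    def test_requires_ptv_and_body(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (3, 3, 3))
        s = StructureSet(grid, {"BODY": np.ones((3, 3, 3), dtype=bool)})
        with pytest.raises(ValueError):
            s.validate_for_planning()

    def test_shape_mismatch(self):
        grid = VoxelGrid((0, 0, 0), (1, 1, 1), (3, 3, 3))
        with pytest.raises(ValueError):
            StructureSet(grid, {"PTV": np.ones((2, 3, 3), dtype=bool)})


class TestVolumeIO:
    @pytest.mark.parametrize("suffix", [".nrrd", ".nii"])
    def test_phantom_roundtrip(self, tmp_path, suffix):
        phantom, _ = fp.make_water_box((4, 4, 6), 0.5)
        from fvheeplan.volume_io import read_phantom, write_volume

        path = tmp_path / f"box{suffix}"
        write_volume(phantom, path)
        back = read_phantom(path)
        assert back.grid == phantom.grid
        assert np.array_equal(back.density, phantom.density)

    @pytest.mark.parametrize("suffix", [".nrrd", ".nii"])
    def test_mask_roundtrip_preserves_count(self, tmp_path, suffix):
        from fvheeplan.volume_io import read_volume, write_volume

        grid = VoxelGrid((0, 0, 0), (0.25, 0.25, 0.25), (16, 16, 16))
        rng = np.random.default_rng(3)
        flat = np.zeros(16**3, dtype=bool)
        flat[rng.choice(flat.size, 1234, replace=False)] = True
        mask = flat.reshape(16, 16, 16)
        path = tmp_path / f"mask{suffix}"
        write_volume(mask, path, grid=grid)
        back, back_grid = read_volume(path)
        assert back.dtype == bool
        assert back.sum() == 1234
        assert np.array_equal(back, mask)
        assert back_grid == grid

    def test_2d_rejected(self, tmp_path):
        import nibabel as nib

        path = tmp_path / "flat.nii"
        nib.save(nib.Nifti1Image(np.zeros((4, 4), dtype=np.float32), np.eye(4)), str(path))
        from fvheeplan.volume_io import read_volume

        with pytest.raises(ValueError):
            read_volume(path)

    def test_grid_mismatch_rejected(self, tmp_path):
        from fvheeplan.volume_io import read_volume, write_volume

        phantom, _ = fp.make_water_box((4, 4, 4), 0.5)
        path = tmp_path / "box.nrrd"
        write_volume(phantom, path)
        other = VoxelGrid((0, 0, 0), (1, 1, 1), (8, 8, 8))
        with pytest.raises(ValueError):
            read_volume(path, expect_grid=other)
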