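"""Virtual implantation: compression, position metrics, seal property."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from laaoflow import anatomy as an
from laaoflow import implant as imp


class _ToyLumen:
    """Constant-diameter lumen stand-in for compression arithmetic."""

    def __init__(self, diameter):
        self._d = diameter

    def lumen_diameter(self, s):
        return self._d


class TestCompression:
    def test_reference_oversizing(self):
        # 24 mm plug in a 21.4 mm lumen: ~11% compression
        dev = imp.watchman(27)
        pl = imp.Placement(anchor=np.zeros(3), axis=(0, 0, 1.0))
        comp = imp.landing_zone_compression(dev, pl, _ToyLumen(21.4))
        assert comp == pytest.approx(0.11, abs=0.005)

    def test_matched_lumen_zero_with_warning(self, coarse_grid, default_anatomy):
        dev = imp.DeviceSpec(family="non_pacifier", nominal_size=21,
                             deployed_diameter=21.0, body_length=16.0)
        assert imp.compression_rate(21.0, 21.0) == 0.0
        pl = imp.Placement(anchor=np.zeros(3), axis=(0, 0, 1.0))
        assert imp.landing_zone_compression(dev, pl, _ToyLumen(21.0)) == 0.0

    def test_deploy_warns_outside_release_window(self, default_anatomy):
        g = an.discretize(default_anatomy, 2.0)
        # grossly undersized device: compression below 8%
        dev = imp.DeviceSpec(family="non_pacifier", nominal_size=21,
                             deployed_diameter=21.3, body_length=16.0)
        pl = imp.make_placement(default_anatomy, depth_offset=0.0)
        with pytest.warns(imp.ReleaseCriterionWarning):
            res = imp.deploy(dev, pl, g)
        assert res.release_warning

    def test_paper_sizings_within_release_window(self, default_anatomy):
        for size, depth in ((27, 0.0), (24, 27.0)):
            dev = imp.watchman(size)
            pl = imp.make_placement(default_anatomy, depth_offset=depth)
            comp = imp.landing_zone_compression(dev, pl, default_anatomy)
            assert 0.08 <= comp <= 0.20


class TestDeviceSolid:
    def test_voxel_volume_matches_analytic(self, default_anatomy):
        # voxelize the plug in free space and compare with the closed form
        dev = imp.watchman(27)
        h = 0.5
        n = int(np.ceil((dev.deployed_diameter + 4) / h))
        nz = int(np.ceil((dev.body_length + 8) / h))
        ax = h * (np.arange(n) + 0.5) - (dev.deployed_diameter + 4) / 2
        az = h * (np.arange(nz) + 0.5) - 4.0
        X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
        rho = np.sqrt(X ** 2 + Y ** 2)
        inside = imp.device_sdf(dev, Z, rho) < 0
        vox = inside.sum() * h ** 3
        assert vox == pytest.approx(imp.device_volume(dev), rel=0.02)

    def test_pacifier_volume(self):
        dev = imp.amulet(25)
        h = 0.15
        n = int(np.ceil((dev.deployed_diameter + 4) / h))
        nz = int(np.ceil((dev.disc_thickness + 10) / h))
        ax = h * (np.arange(n) + 0.5) - (dev.deployed_diameter + 4) / 2
        az = h * (np.arange(nz) + 0.5) - 5.0
        X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
        rho = np.sqrt(X ** 2 + Y ** 2)
        vox = (imp.device_sdf(dev, Z, rho) < 0).sum() * h ** 3
        # thin disc: staircase alignment bias dominates the voxel estimate
        assert vox == pytest.approx(imp.device_volume(dev), rel=0.04)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            imp.DeviceSpec(family="plug", nominal_size=1, deployed_diameter=10)
        with pytest.raises(ValueError):
            imp.DeviceSpec(family="non_pacifier", nominal_size=1,
                           deployed_diameter=10, body_length=5, cove_radius=6)


class TestMeasurePosition:
    def test_ostium_fitted_not_deep(self, default_anatomy):
        dev = imp.watchman(27)
        pl = imp.make_placement(default_anatomy, depth_offset=0.0)
        pos = imp.measure_position(pl, dev, default_anatomy)
        assert pos.lupv_ridge_length == pytest.approx(0.0, abs=1.0)
        assert not pos.deep_flag
        assert pos.device_ridge_angle == pytest.approx(180.0, abs=0.5)

    def test_deep_offset_flags_deep(self, default_anatomy):
        dev = imp.watchman(24)
        pl = imp.make_placement(default_anatomy, depth_offset=27.0)
        pos = imp.measure_position(pl, dev, default_anatomy)
        assert pos.deep_flag
        assert pos.lupv_ridge_length == pytest.approx(27.0, abs=1.0)

    def test_deep_flag_threshold_on_constructed_placements(self, default_anatomy):
        dev = imp.amulet(22)
        for depth in (2.0, 8.0, 10.5, 15.5, 20.0):
            pl = imp.make_placement(default_anatomy, depth_offset=depth)
            pos = imp.measure_position(pl, dev, default_anatomy)
            assert pos.deep_flag == (pos.lupv_ridge_length > 10.0)

    def test_tilt_maps_to_supplementary_angle(self):
        # toy anatomy with an untapered neck: alpha = 180 - tilt exactly
        p = an.AnatomyParams(laa_neck_drop=0.0, laa_taper=1.0)
        A = an.build_anatomy(p)
        dev = imp.watchman(27)
        pl = imp.make_placement(A, depth_offset=0.0, tilt=14.0)
        pos = imp.measure_position(pl, dev, A)
        assert pos.device_ridge_angle == pytest.approx(166.0, abs=1.0)

    def test_proximal_face_reports_zero_ridge(self, default_anatomy):
        dev = imp.watchman(27)
        pl = imp.make_placement(default_anatomy, depth_offset=-15.0)
        pos = imp.measure_position(pl, dev, default_anatomy)
        assert pos.lupv_ridge_length == 0.0
        assert pos.proximal_flag

    def test_determinism(self, default_anatomy):
        dev = imp.watchman(27)
        pl = imp.make_placement(default_anatomy, depth_offset=3.0, tilt=5.0)
        a = imp.measure_position(pl, dev, default_anatomy)
        b = imp.measure_position(pl, dev, default_anatomy)
        assert a == b


def _laa_connected_to_body(grid, anatomy):
    """Is any live fluid path left between the atrial body and the deep
    appendage?  (flood fill over fluid cells)"""
    pts = grid.cell_centers().reshape(-1, 3)
    s, _ = anatomy.laa_coords(pts)
    s = s.reshape(grid.shape)
    fluid = grid.fluid_mask
    lab, _ = ndimage.label(fluid)
    body_labels = set(np.unique(lab[fluid & (s < 0)]).tolist()) - {0}
    deep_labels = set(np.unique(lab[fluid & (s > 12.0)
                                    & grid.anatomy.in_laa(pts).reshape(grid.shape)]).tolist()) - {0}
    return bool(body_labels & deep_labels)


class TestSealProperty:
    @pytest.mark.parametrize("sid", ["np_os", "np_cl", "np_ds", "lp_os", "sp_os"])
    def test_seated_devices_seal_the_appendage(self, default_anatomy, sid):
        (fam, size), pkw = imp.SCENARIO_TABLE[sid]
        dev = imp._FACTORIES[fam](size)
        g = an.discretize(default_anatomy, 2.0)
        pl = imp.make_placement(default_anatomy, **pkw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = imp.deploy(dev, pl, g)
        # nothing distal of the device stays connected to the atrium
        if sid == "np_ds":
            # deep plug: the open cul-de-sac is proximal of the device; the
            # region distal of its atrial face must be sealed
            pts = g.cell_centers().reshape(-1, 3)
            z = ((pts - pl.anchor) @ pl.axis).reshape(g.shape)
            live_distal = g.fluid_mask & (z > dev.distal_extent)
            assert live_distal.sum() == 0
        else:
            assert not _laa_connected_to_body(g, default_anatomy)

    def test_tilted_device_leaks(self, default_anatomy):
        (fam, size), pkw = imp.SCENARIO_TABLE["np_tl"]
        dev = imp._FACTORIES[fam](size)
        g = an.discretize(default_anatomy, 2.0)
        pl = imp.make_placement(default_anatomy, **pkw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = imp.deploy(dev, pl, g)
        assert _laa_connected_to_body(g, default_anatomy)
        assert res.sealed_cells <= 5


class TestScenarioSuite:
    def test_nine_scenarios(self):
        cfgs = imp.scenario_suite()
        assert len(cfgs) == 9
        ids = [c.scenario_id for c in cfgs]
        assert ids[0] == "pre_laao" and len(set(ids)) == 9

    def test_deep_plug_uses_smaller_size(self):
        cfgs = {c.scenario_id: c for c in imp.scenario_suite()}
        assert cfgs["np_ds"].device.nominal_size == 24
        assert cfgs["np_os"].device.nominal_size == 27
        assert cfgs["lp_os"].device.deployed_diameter == 32.0
        assert cfgs["sp_os"].device.deployed_diameter == 28.0

    def test_deep_ridge_targets_encoded(self):
        cfgs = {c.scenario_id: c for c in imp.scenario_suite()}
        assert cfgs["sp_ds"].placement_kwargs["depth_offset"] == pytest.approx(15.5)
        assert cfgs["lp_ds"].placement_kwargs["depth_offset"] == pytest.approx(10.1)

    def test_pre_laao_has_no_device(self):
        cfgs = {c.scenario_id: c for c in imp.scenario_suite()}
        assert cfgs["pre_laao"].device is None
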