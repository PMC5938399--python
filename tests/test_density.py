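"""Voxelization, 2D projections and hotspot-centre estimation."""

import numpy as np
import pytest

from projquant import (
    DensityVolume,
    GridSpec,
    InjectionSite,
    NoSignalError,
    aggregate_centers,
    find_hotspot_center,
    generate_bulk_density,
    hotspot_table,
    project2d,
    voxelize,
)
from projquant.morphometry import cable_length
from projquant.regions import DEFAULT_PROJECTION_CENTERS


class TestVoxelize:
    def test_axis_aligned_segment_uniform_split(self):
        grid = GridSpec(origin=(0.0, 0.0, 0.0), shape=(20, 4, 4), voxel_mm=0.05)
        chain = [(0.0, 0.025, 0.025), (1.0, 0.025, 0.025)]
        vol = voxelize([chain], grid)
        col = vol.values[:, 0, 0]
        assert np.allclose(col, 0.05)
        assert vol.total_mass() == pytest.approx(1.0, rel=1e-12)

    def test_conserves_neuron_cable(self, model, cohort):
        n = cohort.neurons[0]
        vol = voxelize(n)
        expected = cable_length(n, "axon")
        assert vol.total_mass() + vol.out_of_bounds_mm == pytest.approx(
            expected, rel=1e-9
        )
        assert vol.out_of_bounds_mm == 0.0

    def test_out_of_grid_cable_counted_and_warned(self):
        grid = GridSpec(origin=(0.0, 0.0, 0.0), shape=(4, 4, 4), voxel_mm=0.05)
        chain = [(0.1, 0.1, 0.1), (0.1, 0.1, 5.0)]
        with pytest.warns(UserWarning, match="outside the density grid"):
            vol = voxelize([chain], grid)
        assert vol.total_mass() + vol.out_of_bounds_mm == pytest.approx(4.9)

    def test_empty_input_gives_zero_volume(self):
        vol = voxelize([], GridSpec(shape=(5, 5, 5)))
        assert vol.total_mass() == 0.0


class TestProject2d:
    def test_single_voxel(self):
        vol = GridSpec(shape=(4, 4, 4), voxel_mm=0.05).empty_volume()
        vol.values[1, 2, 3] = 2.0
        m, _ = project2d(vol, "horizontal")
        assert m[1, 2] == 2.0
        assert np.count_nonzero(m) == 1

    @pytest.mark.parametrize("plane", ["coronal", "horizontal"])
    def test_mass_conserved(self, plane):
        rng = np.random.default_rng(1)
        vol = GridSpec(shape=(6, 7, 8)).empty_volume()
        vol.values[:] = rng.random(vol.shape)
        m, _ = project2d(vol, plane)
        assert m.sum() == pytest.approx(vol.total_mass(), rel=1e-12)

    def test_offset_in_collapsed_axis_is_invisible(self):
        a = GridSpec(shape=(6, 6, 10)).empty_volume()
        b = GridSpec(shape=(6, 6, 10)).empty_volume()
        a.values[2, 3, 1] = 1.5
        b.values[2, 3, 7] = 1.5  # same ml/ap, different depth
        ma, _ = project2d(a, "horizontal")
        mb, _ = project2d(b, "horizontal")
        assert np.array_equal(ma, mb)

    def test_unknown_plane_rejected(self):
        with pytest.raises(ValueError):
            project2d(GridSpec(shape=(2, 2, 2)).empty_volume(), "sagittal")


class TestFindHotspotCenter:
    def test_single_pixel_returns_its_centre(self):
        vol = GridSpec(origin=(0, 0, 0), shape=(10, 10, 4), voxel_mm=0.1) \
            .empty_volume()
        vol.values[3, 7, 0] = 1.0
        c = find_hotspot_center(vol, (0, 1), (0, 1), sigma_mm=0.0)
        assert c == pytest.approx((0.35, 0.75))

    def test_planted_gaussian_blob_recovered(self):
        from projquant.synthetic import _add_gaussian_blob

        vol = GridSpec().empty_volume()
        center = DEFAULT_PROJECTION_CENTERS["wS2"]["bregma"]
        _add_gaussian_blob(vol, (center[0], center[1], 0.6), 0.1, 10.0)
        c = find_hotspot_center(vol, (center[0] - 0.4, center[0] + 0.4),
                                (center[1] - 0.4, center[1] + 0.4))
        assert abs(c[0] - center[0]) < 0.02
        assert abs(c[1] - center[1]) < 0.02

    def test_two_equal_blobs_centroid_midway(self):
        from projquant.synthetic import _add_gaussian_blob

        vol = GridSpec().empty_volume()
        _add_gaussian_blob(vol, (-3.0, -1.0, 0.5), 0.05, 5.0)
        _add_gaussian_blob(vol, (-2.0, -1.0, 0.5), 0.05, 5.0)
        c = find_hotspot_center(vol, (-3.5, -1.5), (-1.5, -0.5))
        assert c[0] == pytest.approx(-2.5, abs=0.05)

    def test_no_signal_raises(self):
        vol = GridSpec(shape=(5, 5, 5)).empty_volume()
        with pytest.raises(NoSignalError):
            find_hotspot_center(vol, (-5.0, -4.8), (-3.0, -2.8))


class TestAggregateCenters:
    def test_zero_sd_recovers_table_exactly(self, model):
        """With all across-animal SDs at zero every blob sits at the table
        mean, the aggregate means match the planted centres, and SDs vanish."""
        centers = {
            name: {**entry, "offset_sd": (0.0, 0.0)}
            for name, entry in DEFAULT_PROJECTION_CENTERS.items()
        }
        res = generate_bulk_density(
            n_animals=3, centers=centers, model=model, site_sd=(0.0, 0.0),
            seed=0,
        )
        est = {e.region: e for e in aggregate_centers(res.volumes, model)}
        assert len(est) == len(model.names)
        for name, e in est.items():
            planted = res.planted_centers[name][0]
            assert np.abs(e.mean_bregma - planted).max() < 0.01
            assert np.abs(e.sd_bregma).max() < 1e-9
            offset = np.asarray(DEFAULT_PROJECTION_CENTERS[name]["offset"])
            assert np.abs(e.mean_offset - offset).max() < 0.02

    def test_frame_duality_with_known_sites(self, model):
        """bregma mean minus site equals injection-frame mean exactly when the
        per-animal sites are supplied."""
        res = generate_bulk_density(n_animals=2, model=model, seed=3)
        est = aggregate_centers(res.volumes, model, sites=res.sites)
        site = np.array([[s.bregma_ml, s.bregma_ap] for s in res.sites])
        for e in est:
            assert np.allclose(e.centers_offset, e.centers_bregma - site)
            assert np.allclose(
                e.mean_offset, e.mean_bregma - site.mean(axis=0), atol=1e-12
            )

    def test_single_animal_sd_undefined(self, model):
        res = generate_bulk_density(n_animals=1, model=model, seed=2)
        est = aggregate_centers(res.volumes, model)
        assert all(e.n_animals == 1 for e in est)
        assert all(np.isnan(e.sd_bregma).all() for e in est)

    def test_region_without_signal_omitted_with_warning(self, model):
        centers = {
            k: dict(v) for k, v in DEFAULT_PROJECTION_CENTERS.items()
        }
        centers["PP"]["mass_mm"] = 0.0
        with pytest.warns(UserWarning):
            res = generate_bulk_density(
                n_animals=2, centers=centers, model=model, seed=5
            )
        with pytest.warns(UserWarning, match="PP"):
            est = aggregate_centers(res.volumes, model)
        assert "PP" not in {e.region for e in est}

    def test_table_layout(self, model):
        res = generate_bulk_density(n_animals=2, model=model, seed=6)
        df = hotspot_table(aggregate_centers(res.volumes, model))
        assert list(df.region) == model.names
        assert {"offset_ml_mean", "bregma_ap_sd", "n_animals"} <= set(df.columns)


def test_h5_round_trip(tmp_path):
    vol = GridSpec(shape=(4, 5, 6)).empty_volume()
    vol.values[1, 2, 3] = 4.5
    vol.out_of_bounds_mm = 0.25
    path = tmp_path / "v.h5"
    vol.save_h5(path)
    back = DensityVolume.load_h5(path)
    assert np.array_equal(back.values, vol.values)
    assert back.voxel_mm == vol.voxel_mm
    assert np.array_equal(back.origin, vol.origin)
    assert back.out_of_bounds_mm == 0.25
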