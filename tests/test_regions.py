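"""Frame transforms, region containment and polyline clipping."""

import numpy as np
import pytest

from projquant import (
    InjectionSite,
    RegionDef,
    RegionModel,
    bregma_to_injection,
    clip_polyline_to_regions,
    default_region_model,
    effective_interior_box,
    injection_to_bregma,
    locate_point,
    locate_points,
    read_region_model,
    write_region_model,
)
from projquant.morphology import FrameError
from projquant.regions import DEFAULT_PROJECTION_CENTERS, ELSEWHERE


SITE = InjectionSite(-3.02, -1.65)


class TestFrameTransforms:
    def test_zero_offset_is_the_site(self):
        assert injection_to_bregma((0.0, 0.0), SITE) == pytest.approx(
            [-3.02, -1.65]
        )

    def test_whisker_motor_cortex_ml(self):
        b = injection_to_bregma((2.21, 2.70), SITE)
        assert b[0] == pytest.approx(-0.81, abs=5e-3)

    def test_temporal_association_ml(self):
        b = injection_to_bregma((-1.43, -0.36), SITE)
        assert b[0] == pytest.approx(-4.45, abs=5e-3)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 2)) * 3
        back = bregma_to_injection(injection_to_bregma(pts, SITE), SITE)
        assert np.abs(back - pts).max() < 1e-12

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            injection_to_bregma((np.nan, 0.0), SITE)


class TestLocatePoint:
    def test_ws2_center_at_mid_depth(self, model):
        c = DEFAULT_PROJECTION_CENTERS["wS2"]["bregma"]
        assert locate_point((c[0], c[1], 0.5), model) == "wS2"

    def test_midline_is_in_no_region(self, model):
        assert locate_point((0.0, 0.0, 0.5), model) == ELSEWHERE

    def test_contralateral_is_elsewhere(self, model):
        assert locate_point((3.83, -1.63, 0.5), model) == ELSEWHERE

    def test_frame_checked(self, model):
        with pytest.raises(FrameError):
            locate_point((0, 0, 0), model, frame="section-local")

    def test_matches_brute_force_containment(self, model):
        """Oracle: per point, scan regions in priority order with plain
        comparisons."""
        rng = np.random.default_rng(42)
        pts = np.column_stack(
            [
                rng.uniform(-5.5, 0.5, 10_000),
                rng.uniform(-4.0, 2.5, 10_000),
                rng.uniform(0.0, 4.0, 10_000),
            ]
        )
        labels = locate_points(pts, model)
        ordered = sorted(model.regions, key=lambda r: r.priority)
        for p, lab in zip(pts, labels):
            expected = ELSEWHERE
            for r in ordered:
                if (
                    abs(p[0] - r.center_ml) <= r.half_ml
                    and abs(p[1] - r.center_ap) <= r.half_ap
                    and r.dv_min <= p[2] <= r.dv_max
                ):
                    expected = r.name
                    break
            assert lab == expected


class TestClipPolyline:
    def test_segment_wholly_inside_ws2(self, model):
        c = DEFAULT_PROJECTION_CENTERS["wS2"]["bregma"]
        chain = [(c[0] - 0.2, c[1], 0.5), (c[0] + 0.2, c[1], 0.5),
                 (c[0] + 0.2, c[1] + 0.2, 0.5)]
        out = clip_polyline_to_regions(chain, model)
        assert set(out) == {"wS2"}
        assert out["wS2"] == pytest.approx(0.6, rel=1e-12)

    def test_halfway_entry_symmetry(self, model):
        """A segment ending exactly at a region centre leaves half its length
        inside and half outside."""
        c = DEFAULT_PROJECTION_CENTERS["PP"]["bregma"]
        r = model["PP"]
        start = (c[0], c[1] - 2 * r.half_ap, 0.5)  # one half-extent outside
        end = (c[0], c[1], 0.5)
        out = clip_polyline_to_regions([start, end], model)
        assert out["PP"] == pytest.approx(r.half_ap, rel=1e-9)
        assert out[ELSEWHERE] == pytest.approx(r.half_ap, rel=1e-9)

    def test_conserves_total_length(self, model):
        rng = np.random.default_rng(7)
        for _ in range(20):
            chain = np.column_stack(
                [
                    rng.uniform(-5.0, 0.0, 12),
                    rng.uniform(-3.5, 2.0, 12),
                    rng.uniform(0.0, 3.8, 12),
                ]
            )
            total = float(np.linalg.norm(np.diff(chain, axis=0), axis=1).sum())
            out = clip_polyline_to_regions(chain, model)
            assert sum(out.values()) == pytest.approx(total, rel=1e-9)

    def test_against_dense_resampling_oracle(self, model):
        """Subdivide edges into ~1 µm pieces and label midpoints: per-region
        lengths agree within 0.1%."""
        rng = np.random.default_rng(3)
        chain = np.column_stack(
            [
                rng.uniform(-4.5, -2.0, 8),
                rng.uniform(-2.5, 0.5, 8),
                rng.uniform(0.0, 2.0, 8),
            ]
        )
        out = clip_polyline_to_regions(chain, model)
        oracle: dict[str, float] = {}
        for p0, p1 in zip(chain[:-1], chain[1:]):
            seg = float(np.linalg.norm(p1 - p0))
            k = max(1, int(np.ceil(seg / 0.001)))
            ts = (np.arange(k) + 0.5) / k
            mids = p0 + np.outer(ts, p1 - p0)
            for lab in locate_points(mids, model):
                oracle[lab] = oracle.get(lab, 0.0) + seg / k
        total = sum(oracle.values())
        for name in set(out) | set(oracle):
            assert abs(out.get(name, 0.0) - oracle.get(name, 0.0)) <= 1e-3 * total

    def test_translation_equivariance(self, model):
        """Shifting the model and the points together changes nothing."""
        delta = (0.37, -1.21)
        shifted = model.translated(delta)
        rng = np.random.default_rng(12)
        pts = np.column_stack(
            [
                rng.uniform(-5.0, 0.0, 500),
                rng.uniform(-3.5, 2.0, 500),
                rng.uniform(0.0, 3.8, 500),
            ]
        )
        moved = pts + np.array([delta[0], delta[1], 0.0])
        assert locate_points(pts, model) == locate_points(moved, shifted)

    def test_too_short_chain_rejected(self, model):
        with pytest.raises(ValueError):
            clip_polyline_to_regions([(0, 0, 0)], model)


class TestRegionModel:
    def test_duplicate_names_rejected(self):
        r = RegionDef("A", "box", 0, 0, 1, 1, 0, 1, 0)
        with pytest.raises(ValueError, match="unique"):
            RegionModel([r, r])

    def test_reserved_name_rejected(self):
        with pytest.raises(ValueError, match="reserved"):
            RegionDef(ELSEWHERE, "box", 0, 0, 1, 1, 0, 1, 0)

    def test_bad_extents_rejected(self):
        with pytest.raises(ValueError):
            RegionDef("A", "box", 0, 0, -1, 1, 0, 1, 0)
        with pytest.raises(ValueError):
            RegionDef("A", "box", 0, 0, 1, 1, 2, 1, 0)

    def test_config_round_trip(self, model, tmp_path):
        path = write_region_model(model, tmp_path / "model.csv")
        loaded = read_region_model(path)
        assert loaded.names == model.names
        assert loaded.injection_site == model.injection_site
        for a, b in zip(loaded.regions, model.regions):
            assert a == b

    def test_interior_box_points_belong_to_region(self, model):
        """Every point of a region's interior box is assigned to that region."""
        for name in model.names:
            box = effective_interior_box(model, name)
            g = np.linspace(0.0, 1.0, 5)
            pts = np.array(
                [
                    box[0] + np.array([u, v, w]) * (box[1] - box[0])
                    for u in g for v in g for w in g
                ]
            )
            labels = set(locate_points(pts, model))
            assert labels == {name}
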