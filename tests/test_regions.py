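"""Region assignment: quadrants, concentric rings, aggregation, symmetry."""

import numpy as np
import pandas as pd
import pytest

from conftest import disc_mask, random_blob_mask
from qflap.ingest import Box, BoxGrid, FlapROI, build_box_grid
from qflap.regions import (
    RegionError,
    WHOLE_BREAST,
    aggregate_region_metrics,
    assign_all,
    assign_concentric,
    assign_quadrants,
    radial_positions,
)
from qflap.synthetic import generate_case


def manual_grid(centers, centroid, shape=(200, 200), laterality="right", size=14):
    boxes = [Box(i, int(r - (size - 1) / 2), int(c - (size - 1) / 2), size)
             for i, (r, c) in enumerate(centers)]
    return BoxGrid(size, boxes, centroid, shape, laterality)


class TestQuadrants:
    def test_right_breast_convention(self):
        # centroid at (100, 100); box centred above-left of it
        grid = manual_grid([(80.5, 80.5)], (100.0, 100.0), laterality="right")
        assert assign_quadrants(grid).iloc[0] == "UOQ"

    def test_left_breast_mirrors_to_inner(self):
        grid = manual_grid([(80.5, 80.5)], (100.0, 100.0), laterality="left")
        assert assign_quadrants(grid).iloc[0] == "UIQ"

    def test_vertical_split_tie_goes_inner(self):
        grid = manual_grid([(120.5, 99.5)], (100.0, 99.5), laterality="right")
        assert assign_quadrants(grid).iloc[0] == "LIQ"
        grid = manual_grid([(120.5, 99.5)], (100.0, 99.5), laterality="left")
        assert assign_quadrants(grid).iloc[0] == "LIQ"

    def test_unknown_laterality_rejected(self):
        grid = manual_grid([(80.5, 80.5)], (100.0, 100.0))
        with pytest.raises(ValueError):
            assign_quadrants(grid, "bilateral")


class TestConcentric:
    def test_disc_radial_position(self):
        """u = r / R on a disc, so r=30 of R=70 is inner half, middle third."""
        mask = disc_mask(200, 200, 70.0)
        roi = FlapROI(mask)
        grid = manual_grid([(99.5, 99.5 + 30.0)], roi.centroid, laterality="right")
        u = radial_positions(grid, roi).iloc[0]
        assert u == pytest.approx(30.0 / 70.0, abs=0.02)
        assert assign_concentric(grid, roi, "halves").iloc[0] == "inner"
        assert assign_concentric(grid, roi, "thirds").iloc[0] == "middle"

    def test_box_at_centroid_is_inner_everywhere(self):
        mask = disc_mask(200, 200, 70.0)
        roi = FlapROI(mask)
        grid = manual_grid([roi.centroid], roi.centroid)
        assert radial_positions(grid, roi).iloc[0] == 0.0
        assert assign_concentric(grid, roi, "halves").iloc[0] == "inner"
        assert assign_concentric(grid, roi, "thirds").iloc[0] == "inner"

    def test_inner_half_fraction_on_disc_matches_area_scaling(self):
        """Inner half (u <= 1/2) covers ~1/4 of a disc; check per-box labels
        against an independent analytic rasterisation."""
        mask = disc_mask(220, 220, 90.0)
        roi = FlapROI(mask)
        grid = build_box_grid(roi, 14)
        halves = assign_concentric(grid, roi, "halves")
        cy, cx = roi.centroid
        n_match = 0
        n_boundary = 0
        for b in grid.boxes:
            r, c = b.center
            u_true = np.hypot(r - cy, c - cx) / 90.0
            if abs(u_true - 0.5) < 0.02:
                n_boundary += 1
                continue
            expected = "inner" if u_true <= 0.5 else "outer"
            n_match += halves.loc[b.box_id] == expected
        assert n_match == len(grid.boxes) - n_boundary
        frac = (halves == "inner").mean()
        assert abs(frac - 0.25) < 0.06

    def test_centroid_outside_mask_rejected(self):
        ring = disc_mask(200, 200, 70.0) & ~disc_mask(200, 200, 40.0)
        roi = FlapROI(ring)
        grid = build_box_grid(roi, 14)
        with pytest.raises(RegionError):
            radial_positions(grid, roi)


class TestPartitionAndMirror:
    def test_every_box_gets_one_label_per_scheme(self, rng):
        for _ in range(10):
            mask = random_blob_mask(rng)
            roi = FlapROI(mask, "right")
            grid = build_box_grid(roi, 14)
            asg = assign_all(grid, roi)
            assert len(asg) == len(grid.boxes)
            assert asg.notna().all().all()
            assert set(asg["quadrant"]) <= {"UIQ", "UOQ", "LIQ", "LOQ"}
            assert set(asg["half"]) <= {"inner", "outer"}
            assert set(asg["third"]) <= {"inner", "middle", "outer"}

    def test_mirror_symmetry_under_laterality_flip(self, rng):
        """Flipping the mask left-right and toggling laterality preserves the
        box partition, all labels and hence all region means."""
        for _ in range(10):
            mask = random_blob_mask(rng)
            roi_r = FlapROI(mask, "right")
            roi_l = FlapROI(mask[:, ::-1].copy(), "left")
            grid_r = build_box_grid(roi_r, 14)
            grid_l = build_box_grid(roi_l, 14)
            assert len(grid_r.boxes) == len(grid_l.boxes)

            w = mask.shape[1]
            # boxes must correspond one-to-one under column mirroring
            centers_r = {(b.center[0], w - 1 - b.center[1]): b.box_id
                         for b in grid_r.boxes}
            mapping = {}
            for b in grid_l.boxes:
                key = (b.center[0], b.center[1])
                assert key in centers_r
                mapping[b.box_id] = centers_r[key]

            asg_r = assign_all(grid_r, roi_r)
            asg_l = assign_all(grid_l, roi_l)
            for bl, br in mapping.items():
                assert asg_l.loc[bl, "quadrant"] == asg_r.loc[br, "quadrant"]
                assert asg_l.loc[bl, "half"] == asg_r.loc[br, "half"]
                assert asg_l.loc[bl, "third"] == asg_r.loc[br, "third"]

            # region means of a fixed spatial field are then identical
            def field(r, c):
                return 0.3 * r + 0.11 * c + 0.001 * r * c

            def mil(grid, transform):
                rows = {}
                for b in grid.boxes:
                    r, c = b.center
                    rows[b.box_id] = {"F_max": field(*transform(r, c)), "valid": True}
                return pd.DataFrame.from_dict(rows, orient="index")

            reg_r = aggregate_region_metrics(mil(grid_r, lambda r, c: (r, c)),
                                             asg_r)
            reg_l = aggregate_region_metrics(mil(grid_l, lambda r, c: (r, w - 1 - c)),
                                             asg_l)
            assert np.allclose(reg_r["F_max"], reg_l["F_max"], rtol=1e-12,
                               equal_nan=True)
            assert (reg_r["n_boxes"] == reg_l["n_boxes"]).all()


class TestAggregation:
    def _mil(self, rows):
        return pd.DataFrame.from_dict(rows, orient="index")

    def _asg(self, rows):
        return pd.DataFrame.from_dict(rows, orient="index")

    def test_regional_mean_of_two_boxes(self):
        mil = self._mil({0: {"F_max": 10.0, "valid": True},
                         1: {"F_max": 20.0, "valid": True}})
        asg = self._asg({0: {"quadrant": "UIQ", "half": "inner", "third": "inner"},
                         1: {"quadrant": "UIQ", "half": "inner", "third": "inner"}})
        reg = aggregate_region_metrics(mil, asg)
        assert reg.loc["UIQ", "F_max"] == 15.0
        assert reg.loc[WHOLE_BREAST, "F_max"] == 15.0
        assert reg.loc["LOQ", "n_boxes"] == 0
        assert np.isnan(reg.loc["LOQ", "F_max"])  # empty region: missing, not 0

    def test_invalid_box_excluded_from_mean_and_count(self):
        mil = self._mil({0: {"F_max": 10.0, "valid": True},
                         1: {"F_max": 99.0, "valid": False}})
        asg = self._asg({0: {"quadrant": "UIQ", "half": "inner", "third": "inner"},
                         1: {"quadrant": "UIQ", "half": "inner", "third": "inner"}})
        reg = aggregate_region_metrics(mil, asg)
        assert reg.loc["UIQ", "F_max"] == 10.0
        assert reg.loc["UIQ", "n_boxes"] == 1

    def test_disjoint_box_ids_rejected(self):
        mil = self._mil({0: {"F_max": 1.0, "valid": True}})
        asg = self._asg({5: {"quadrant": "UIQ", "half": "inner", "third": "inner"}})
        with pytest.raises(RegionError):
            aggregate_region_metrics(mil, asg)

    def test_centre_gradient_orders_concentric_means(self):
        """A centre-brighter synthetic flap has inner-third Fmax above outer."""
        from qflap.ingest import extract_box_series
        from qflap.metrics import milestones_for_boxes
        from qflap.synthetic import CohortSpec, Geometry

        geom = Geometry(width=160, height=120, frame_rate=5, duration_s=60,
                        box_size=14)
        spec = CohortSpec("g", 1, metrics={"Fmax": (90.0, 0.0),
                                           "latency": (10.0, 0.0),
                                           "Tmax": (20.0, 0.0)},
                          noise_sd=0.0, drift_amp=0.0, box_cv=0.0,
                          baseline_sd=0.0, centre_multiplier=1.6)
        case = generate_case(spec, 0, seed=2, geometry=geom)
        grid = build_box_grid(case.roi, 14)
        series = extract_box_series(case.stack, grid, case.roi)
        mil = milestones_for_boxes(series, 5)
        reg = aggregate_region_metrics(mil, assign_all(grid, case.roi))
        assert reg.loc["inner_third", "F_max"] > reg.loc["outer_third", "F_max"]
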