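import json

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from spatialcoloc import ValidationError
from spatialcoloc.colocalization import ColocConfig, coloc_score
from spatialcoloc.io import write_geojson, write_result_table
from spatialcoloc.synthetic import SimulationSpec, generate
from spatialcoloc.tls import (
    TLSConfig,
    detect_tls,
    tls_distance_composition,
    tls_proximity_summary,
)
from spatialcoloc.tls import _ols_slope_ci, _single_linkage_components

from conftest import make_cells


def tls_sim(seed=0, centers=((300, 500), (700, 500)), n_b=150, n_t=120,
            n_tph=60, n_dc=40, n_bg=300, **geometry):
    return generate(SimulationSpec(
        pattern="tls_tissue", seed=seed,
        n_cells={"B/plasma": n_b, "T": n_t, "Tph/Tfh": n_tph,
                 "mregDC": n_dc, "Stromal": n_bg},
        geometry={"core_centers": [list(c) for c in centers], **geometry},
    ))


def core_sim(seed=0, centers=((500, 500),), n_b=150, n_t=120, n_bg=300):
    """Intermixed T/B aggregate (no peripheral shells): the detectable
    object for capture/IoU scoring."""
    return generate(SimulationSpec(
        pattern="tls_tissue", seed=seed,
        n_cells={"B/plasma": n_b, "T": n_t, "Stromal": n_bg},
        geometry={"core_centers": [list(c) for c in centers],
                  "shells": {"T": (0.0, 25.0)}},
    ))


def tb_field(cells, radius=10.0):
    return coloc_score(cells, "T", "B/plasma",
                       ColocConfig(radius_um=radius))


DETECT_CFG = TLSConfig(score_quantile=0.1, linkage_radius_um=30.0,
                       min_cells=20)


class TestDetect:
    def test_all_zero_scores_empty_set(self):
        cells = make_cells(
            [[0, 0], [200, 0], [400, 0], [600, 0]],
            ["T", "B/plasma", "T", "B/plasma"],
        )
        regions = detect_tls(tb_field(cells), cells, DETECT_CFG)
        assert len(regions) == 0

    def test_single_aggregate_recovered(self):
        sim = core_sim(centers=((500, 500),))
        regions = detect_tls(tb_field(sim.cells), sim.cells, DETECT_CFG)
        assert len(regions) == 1
        planted = np.flatnonzero(
            np.array(sim.truth["region_of_cell"]) >= 0
        )
        detected = set(regions.regions[0].member_rows.tolist())
        captured = len(detected & set(planted.tolist()))
        assert captured / len(planted) >= 0.9

    def test_two_aggregates_two_regions(self):
        sim = tls_sim(centers=((400, 500), (600, 500)))  # 200 um apart
        regions = detect_tls(tb_field(sim.cells), sim.cells, DETECT_CFG)
        assert len(regions) == 2

    def test_regions_ordered_by_size_and_disjoint(self):
        sim = tls_sim()
        regions = detect_tls(tb_field(sim.cells), sim.cells, DETECT_CFG)
        sizes = [len(r.member_rows) for r in regions.regions]
        assert sizes == sorted(sizes, reverse=True)
        all_rows = np.concatenate(
            [r.member_rows for r in regions.regions]
        )
        assert len(all_rows) == len(set(all_rows.tolist()))

    def test_hull_contains_members(self):
        sim = tls_sim()
        regions = detect_tls(tb_field(sim.cells), sim.cells, DETECT_CFG)
        coords = sim.cells.coords
        for r in regions.regions:
            hull = r.hull.buffer(1e-9)
            assert all(
                hull.contains(Point(coords[i])) for i in r.member_rows
            )

    def test_deterministic_and_order_invariant(self):
        sim = tls_sim(seed=2)
        r1 = detect_tls(tb_field(sim.cells), sim.cells, DETECT_CFG)
        perm = np.random.default_rng(0).permutation(sim.cells.n_cells)
        from spatialcoloc import CellMap

        shuffled = CellMap(
            sim.cells.table.iloc[perm].reset_index(drop=True)
        )
        r2 = detect_tls(tb_field(shuffled), shuffled, DETECT_CFG)
        ids1 = [sorted(r.member_cells) for r in r1.regions]
        ids2 = [sorted(r.member_cells) for r in r2.regions]
        assert ids1 == ids2

    def test_single_linkage_matches_union_find(self, rng):
        xy = rng.uniform(0, 200, size=(400, 2))
        radius = 12.0
        labels = _single_linkage_components(xy, radius)
        # brute-force union-find oracle over the thresholded distance matrix
        parent = list(range(len(xy)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(xy)):
            for j in range(i + 1, len(xy)):
                if np.hypot(*(xy[i] - xy[j])) <= radius:
                    parent[find(i)] = find(j)
        roots = [find(i) for i in range(len(xy))]
        same_mine = labels[:, None] == labels[None, :]
        roots = np.array(roots)
        same_oracle = roots[:, None] == roots[None, :]
        np.testing.assert_array_equal(same_mine, same_oracle)

    def test_geojson_and_table_outputs(self, tmp_path):
        sim = tls_sim()
        regions = detect_tls(tb_field(sim.cells), sim.cells, DETECT_CFG)
        write_result_table(regions, tmp_path / "tls.tsv")
        write_geojson(regions, tmp_path / "tls.geojson")
        gj = json.loads((tmp_path / "tls.geojson").read_text())
        assert gj["type"] == "FeatureCollection"
        assert len(gj["features"]) == len(regions)
        table = pd.read_csv(tmp_path / "tls.tsv", sep="\t")
        assert set(table["region_id"]) == {r.region_id
                                           for r in regions.regions}


class TestDistanceComposition:
    def test_b_cells_in_zero_bin(self):
        sim = tls_sim()
        regions = detect_tls(tb_field(sim.cells), sim.cells, DETECT_CFG)
        comp = tls_distance_composition(sim.cells, regions, "B/plasma")
        b = comp[comp.cell_type == "B/plasma"]
        assert b[b.bin_lo == 0.0]["proportion"].iloc[0] == pytest.approx(
            1.0
        )

    def test_curves_sum_to_one(self):
        sim = tls_sim()
        regions = detect_tls(tb_field(sim.cells), sim.cells, DETECT_CFG)
        comp = tls_distance_composition(sim.cells, regions, "B/plasma")
        sums = comp.groupby("cell_type")["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_planted_ring_modal_bin(self):
        # Tph/Tfh planted at 5-10 um beyond the B core edge
        sim = tls_sim(n_tph=150)
        regions = detect_tls(tb_field(sim.cells), sim.cells, DETECT_CFG)
        comp = tls_distance_composition(sim.cells, regions, "B/plasma")
        tph = comp[comp.cell_type == "Tph/Tfh"]
        modal = tph.loc[tph["proportion"].idxmax()]
        assert (modal["bin_lo"], modal["bin_hi"]) == (5.0, 10.0)

    def test_uniform_background_near_flat(self):
        # big core, stroma displaced outside it: annulus areas (hence the
        # CSR background's bin shares) change slowly across 3 wide bins
        sim = generate(SimulationSpec(
            pattern="tls_tissue", seed=1, extent_um=600.0,
            n_cells={"B/plasma": 1200, "T": 300, "Stromal": 5000},
            geometry={"core_centers": [[300, 300]], "core_radius": 100,
                      "shells": {"T": (0.0, 100.0)},
                      "background_exclude_cores": True},
        ))
        regions = detect_tls(tb_field(sim.cells), sim.cells, DETECT_CFG)
        comp = tls_distance_composition(
            sim.cells, regions, "B/plasma",
            bins=np.array([0.0, 25.0, 50.0, 75.0]),
        )
        st = comp[comp.cell_type == "Stromal"]
        assert st["n_cells"].sum() >= 500
        props = st["proportion"].to_numpy()
        assert props.max() / props.min() < 2.0

    def test_no_regions_raises(self):
        cells = make_cells([[0, 0], [500, 0]], ["T", "B/plasma"])
        from spatialcoloc.tls import TLSRegionSet

        with pytest.raises(ValidationError):
            tls_distance_composition(
                cells, TLSRegionSet(regions=[], cells=cells), "B/plasma"
            )


class TestProximitySummary:
    def test_three_bin_closed_form_slope(self):
        # single B core at origin; probe type at exact radial distances
        b = [[0, 0]] * 0 or [
            [np.cos(t), np.sin(t)] for t in np.linspace(0, 2 * np.pi, 24,
                                                        endpoint=False)
        ]
        b = (np.array(b) * 0.5).tolist()  # tight B cluster near origin
        t_cells = (np.array(b) + [1.0, 0]).tolist()  # T on top for score
        probe = []
        for radius, count in ((5.0, 6), (15.0, 3), (25.0, 1)):
            for k in range(count):
                ang = 2 * np.pi * k / count + 0.1
                probe.append([radius * np.cos(ang),
                              radius * np.sin(ang)])
        coords = np.array(b + t_cells + probe)
        types = (["B/plasma"] * len(b) + ["T"] * len(t_cells)
                 + ["Probe"] * len(probe))
        cells = make_cells(coords, types)
        regions = detect_tls(
            tb_field(cells), cells,
            TLSConfig(score_quantile=0.05, linkage_radius_um=30,
                      min_cells=5),
        )
        assert len(regions) == 1
        # distances to nearest region B cell land in bins [0,10),[10,20),
        # [20,30) with proportions .6/.3/.1 at midpoints 5/15/25
        summary = tls_proximity_summary(
            cells, regions, "B/plasma", near_radius=10.0,
            bins=np.array([0.0, 10.0, 20.0, 30.0]),
        )
        row = summary[summary.cell_type == "Probe"].iloc[0]
        assert row["slope_per_um"] == pytest.approx(-0.025, abs=1e-12)
        assert row["pct_within_near_radius"] == pytest.approx(60.0)

    def test_ols_closed_form_oracle(self):
        slope, lo, hi = _ols_slope_ci(
            np.array([5.0, 15.0, 25.0]), np.array([0.6, 0.3, 0.1])
        )
        assert slope == pytest.approx(-0.025, abs=1e-12)
        assert lo < slope < hi

    def test_concentrated_type_extreme(self):
        # probe found only within 10 um of B: share 100%, strongly
        # negative slope over fine bins
        b = (np.array(
            [[np.cos(t), np.sin(t)] for t in
             np.linspace(0, 2 * np.pi, 24, endpoint=False)]
        ) * 0.5).tolist()
        t_cells = (np.array(b) + [1.0, 0]).tolist()
        probe = []
        for radius, count in ((2.0, 6), (5.0, 3), (8.0, 1)):
            for k in range(count):
                ang = 2 * np.pi * k / count + 0.1
                probe.append([radius * np.cos(ang),
                              radius * np.sin(ang)])
        cells = make_cells(
            np.array(b + t_cells + probe),
            ["B/plasma"] * len(b) + ["T"] * len(t_cells)
            + ["Probe"] * len(probe),
        )
        regions = detect_tls(
            tb_field(cells), cells,
            TLSConfig(score_quantile=0.05, linkage_radius_um=30,
                      min_cells=5),
        )
        summary = tls_proximity_summary(
            cells, regions, "B/plasma", near_radius=10.0,
            bins=np.array([0.0, 3.0, 6.0, 9.0]),
        )
        row = summary[summary.cell_type == "Probe"].iloc[0]
        assert row["pct_within_near_radius"] == pytest.approx(100.0)
        assert row["slope_per_um"] < -0.05

    def test_sim_proximity_ordering(self):
        sim = tls_sim(n_tph=100)
        regions = detect_tls(tb_field(sim.cells), sim.cells, DETECT_CFG)
        summary = tls_proximity_summary(sim.cells, regions, "B/plasma")
        tph = summary[summary.cell_type == "Tph/Tfh"].iloc[0]
        b = summary[summary.cell_type == "B/plasma"].iloc[0]
        assert b["pct_within_near_radius"] == pytest.approx(100.0)
        assert tph["pct_within_near_radius"] > 50.0

    def test_uniform_type_ci_covers_zero(self):
        sim = generate(SimulationSpec(
            pattern="tls_tissue", seed=3,
            n_cells={"B/plasma": 400, "T": 300, "Stromal": 4000},
            geometry={"core_centers": [[500, 500]], "core_radius": 100,
                      "shells": {"T": (0.0, 100.0)}},
        ))
        regions = detect_tls(tb_field(sim.cells), sim.cells, DETECT_CFG)
        summary = tls_proximity_summary(
            sim.cells, regions, "B/plasma",
            bins=np.array([0.0, 10.0, 20.0, 30.0]),
        )
        st = summary[summary.cell_type == "Stromal"].iloc[0]
        assert st["slope_ci_lo"] <= 0.0 <= st["slope_ci_hi"]

    def test_few_bins_slope_na(self):
        sim = tls_sim()
        regions = detect_tls(tb_field(sim.cells), sim.cells, DETECT_CFG)
        summary = tls_proximity_summary(
            sim.cells, regions, "B/plasma",
            bins=np.array([0.0, 25.0, 50.0]),  # only 2 bins
        )
        assert summary["slope_per_um"].isna().all()
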