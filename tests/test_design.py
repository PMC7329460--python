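import numpy as np
import pandas as pd
import pytest

import semifield as sf
from semifield.design import (LayoutError, MODEL_PRESETS, build_layout,
                              neighbor_incidence, spatial_incidence)


def grid_layout(beds=2, rows=10, lines=("A", "B", "C", "D", "E")):
    recs = [{"bed": b, "row": w, "line": lines[(b * rows + w) % len(lines)]}
            for b in range(1, beds + 1) for w in range(1, rows + 1)]
    return build_layout(pd.DataFrame(recs))


class TestBuildLayout:
    def test_field_size_two_beds_150(self):
        lay = grid_layout(beds=2, rows=150)
        assert lay.n_locations == 310

    def test_field_size_one_bed_10(self):
        lay = grid_layout(beds=1, rows=10)
        assert lay.n_locations == 20

    def test_four_beds_share_pair_levels(self):
        lay = grid_layout(beds=4, rows=150)
        assert lay.n_locations == 310  # both pairs map onto the same field
        # same within-pair position -> same spatial column across pairs
        assert lay.location_of(1, 7) == lay.location_of(3, 7)

    def test_separate_pair_fields_option(self):
        recs = [{"bed": b, "row": w, "line": "A"}
                for b in range(1, 5) for w in range(1, 11)]
        lay = build_layout(pd.DataFrame(recs), share_pair_levels=False)
        assert lay.n_locations == 2 * (20 + 10)
        assert lay.location_of(1, 7) != lay.location_of(3, 7)

    def test_middle_row_neighbors(self):
        lay = grid_layout(beds=1, rows=10)
        t = lay.table
        line_at = {int(r.position): r.line for r in t.itertuples()}
        west, east = lay.neighbor_map[(1, 5)]
        assert west == line_at[4] and east == line_at[6]

    def test_neighbors_mutually_consistent(self):
        lay = grid_layout(beds=2, rows=20)
        t = lay.table
        for r in t.itertuples():
            west, east = lay.neighbor_map[(r.bed, r.row)]
            nxt = t[(t["pair"] == r.pair) & (t["position"] == r.position + 1)]
            if len(nxt):
                nb = nxt.iloc[0]
                assert east == nb["line"]
                assert lay.neighbor_map[(nb["bed"], nb["row"])][0] == r.line

    def test_ends_have_one_missing_neighbor(self):
        lay = grid_layout(beds=1, rows=10)
        first = lay.table.loc[lay.table["position"] == 1].iloc[0]
        last = lay.table.loc[lay.table["position"] == 10].iloc[0]
        assert lay.neighbor_map[(first["bed"], first["row"])][0] is None
        assert lay.neighbor_map[(last["bed"], last["row"])][1] is None

    def test_duplicate_row_rejected(self):
        df = pd.DataFrame([{"bed": 1, "row": 1, "line": "A"},
                           {"bed": 1, "row": 1, "line": "B"}])
        with pytest.raises(LayoutError, match="duplicate"):
            build_layout(df)

    def test_position_gap_rejected(self):
        df = pd.DataFrame([{"bed": 1, "row": 1, "line": "A", "position": 1, "pair": 1},
                           {"bed": 1, "row": 2, "line": "B", "position": 3, "pair": 1}])
        with pytest.raises(LayoutError, match="consecutive"):
            build_layout(df)
        build_layout(df, allow_gaps=True)  # declared gaps accepted

    def test_missing_column_rejected(self):
        with pytest.raises(LayoutError, match="missing columns"):
            build_layout(pd.DataFrame({"bed": [1], "row": [1]}))


class TestNeighborIncidence:
    def test_interior_and_border_rows(self):
        lay = grid_layout(beds=1, rows=6, lines=("A", "B", "C", "D", "E", "F"))
        t = lay.table
        recs = t[["bed", "row", "line"]].copy()
        lines = sorted(t["line"].unique())
        Z = neighbor_incidence(lay, recs, lines)
        sums = Z.sum(axis=1)
        by_pos = {int(r.position): i for i, r in enumerate(t.itertuples())}
        assert sums[by_pos[1]] == 1 and sums[by_pos[6]] == 1
        assert all(sums[by_pos[p]] == 2 for p in range(2, 6))

    def test_same_line_both_sides_counts_two(self):
        df = pd.DataFrame([{"bed": 1, "row": 1, "line": "A"},
                           {"bed": 1, "row": 2, "line": "B"},
                           {"bed": 1, "row": 3, "line": "A"}])
        lay = build_layout(df)
        recs = pd.DataFrame([{"bed": 1, "row": 2, "line": "B"}])
        Z = neighbor_incidence(lay, recs, ["A", "B"])
        np.testing.assert_array_equal(Z, [[2.0, 0.0]])

    def test_unknown_row_errors(self):
        lay = grid_layout()
        with pytest.raises(LayoutError, match="unknown row"):
            neighbor_incidence(lay, pd.DataFrame([{"bed": 9, "row": 9, "line": "A"}]),
                               ["A"])


class TestSpatialIncidence:
    def test_interior_window(self):
        lay = grid_layout(beds=1, rows=30)
        rec = lay.table.loc[lay.table["position"] == 15, ["bed", "row"]]
        Z = spatial_incidence(lay, rec)
        (row,) = Z
        c = lay.location_of(rec["bed"].iloc[0], rec["row"].iloc[0])
        assert row.sum() == 11
        assert set(np.flatnonzero(row)) == set(range(c - 5, c + 6))

    def test_westmost_row_uses_virtual_columns(self):
        lay = grid_layout(beds=1, rows=30)
        rec = lay.table.loc[lay.table["position"] == 1, ["bed", "row"]]
        (row,) = spatial_incidence(lay, rec)
        assert row.sum() == 11
        assert row[:5].sum() == 5  # the 5 virtual columns below position 1

    def test_other_area_records_zero_rows(self):
        lay = grid_layout(beds=1, rows=12)
        recs = lay.table[["bed", "row"]].copy()
        recs["area"] = ["wet", "dry"] * 6
        Z = spatial_incidence(lay, recs, area="wet")
        sums = Z.sum(axis=1)
        np.testing.assert_array_equal(sums, [11, 0] * 6)

    def test_covariance_triangle_law(self):
        # rows i,j at distance d share (11-d) window locations for d<=10
        lay = grid_layout(beds=1, rows=40)
        recs = lay.table.sort_values("position")[["bed", "row"]]
        Z = spatial_incidence(lay, recs)
        S = Z @ Z.T
        for i in range(40):
            for j in range(40):
                d = abs(i - j)
                assert S[i, j] == (11 - d if d <= 10 else 0)


class TestAssembleModel:
    def test_gm1_shapes(self, small_sim, small_g, gm1_bundle):
        b = gm1_bundle
        assert b.X.shape[1] == 2 * 2  # beds x areas cell means
        assert [blk.label for blk in b.blocks] == ["g", "l", "r", "s1", "s2"]
        g_blk, l_blk = b.blocks[0], b.blocks[1]
        assert g_blk.K is not None and l_blk.K is None
        np.testing.assert_array_equal(g_blk.Z, l_blk.Z)  # shared line incidence

    def test_gm2_adds_neighbor_blocks(self, gm2_bundle, small_g):
        labels = [blk.label for blk in gm2_bundle.blocks]
        assert labels == ["g", "l", "g_n", "l_n", "r", "s1", "s2"]
        gn = next(blk for blk in gm2_bundle.blocks if blk.label == "g_n")
        assert gn.n_levels == len(small_g.line_ids)
        assert gn.K is not None
        sums = gn.Z.sum(axis=1)
        assert set(np.unique(sums)) <= {0.0, 1.0, 2.0}

    def test_eight_fixed_columns_at_paper_size(self):
        cfg = sf.SimulationConfig(seed=0, n_lines=20, n_markers=100, beds=4,
                                  rows_per_bed=20)
        ds = sf.simulate_trait(cfg)
        G = sf.vanraden_g(ds.markers)
        b = sf.assemble_model("GM1", ds.records, ds.layout, G, trait="value")
        assert b.X.shape[1] == 8
        r_blk = next(blk for blk in b.blocks if blk.label == "r")
        assert r_blk.n_levels == 80  # all facility rows

    def test_rm2_shapes(self, root_sim):
        G = sf.vanraden_g(root_sim.markers)
        b = sf.assemble_model("RM2", root_sim.records, root_sim.layout, G,
                              trait="value")
        # 2 bed cells + 3 camera contrasts + 3 interval contrasts
        assert b.X.shape[1] == 2 + 3 + 3
        assert [blk.label for blk in b.blocks] == ["g", "l", "r", "s"]
        r_blk = next(blk for blk in b.blocks if blk.label == "r")
        assert r_blk.n_levels == len(root_sim.records[["bed", "row"]].drop_duplicates())

    def test_rm1_shapes(self, root_sim):
        G = sf.vanraden_g(root_sim.markers)
        rec = root_sim.records.groupby(["bed", "row"], as_index=False).agg(
            line=("line", "first"), camera=("camera", "first"), value=("value", "sum"))
        b = sf.assemble_model("RM1", rec, root_sim.layout, G, trait="value")
        assert b.X.shape[1] == 2 + 3
        assert [blk.label for blk in b.blocks] == ["g", "l", "s"]

    def test_spatial_row_sums(self, gm1_bundle):
        s1 = next(blk for blk in gm1_bundle.blocks if blk.label == "s1")
        s2 = next(blk for blk in gm1_bundle.blocks if blk.label == "s2")
        total = s1.Z.sum(axis=1) + s2.Z.sum(axis=1)
        np.testing.assert_array_equal(total, np.full(gm1_bundle.n_records, 11.0))

    def test_missing_line_in_g_errors(self, small_sim, small_g):
        recs = small_sim.records.copy()
        recs.loc[0, "line"] = "UNSEEN"
        with pytest.raises(LayoutError, match="absent from G"):
            sf.assemble_model("GM1", recs, small_sim.layout, small_g, trait="value")

    def test_missing_response_column(self, small_sim, small_g):
        with pytest.raises(LayoutError, match="response column"):
            sf.assemble_model("GM1", small_sim.records, small_sim.layout,
                              small_g, trait="nope")

    def test_record_order_invariance(self, small_sim, small_g):
        recs = small_sim.records
        fit1 = sf.reml_fit(sf.assemble_model("GM1", recs, small_sim.layout,
                                             small_g, trait="value"), max_iter=60)
        perm = recs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit2 = sf.reml_fit(sf.assemble_model("GM1", perm, small_sim.layout,
                                             small_g, trait="value"), max_iter=60)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-5)
        for k in fit1.vcs:
            assert fit1.vcs[k] == pytest.approx(fit2.vcs[k], abs=1e-5)

    def test_nan_responses_dropped(self, small_sim, small_g):
        recs = small_sim.records.copy()
        recs.loc[:4, "value"] = np.nan
        b = sf.assemble_model("GM1", recs, small_sim.layout, small_g, trait="value")
        assert b.n_records == len(recs) - 5
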