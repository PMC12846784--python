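"""Cell-interaction-graph feature extraction: oracles and invariants."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest

from emtpath._stats import six_stats
from emtpath.cellgraph import (
    AGG_NAMES,
    EDGE_GROUPS,
    PAIR_TYPES,
    CellMap,
    build_patch_graph,
    canonicalize_feature_names,
    edge_length_stats,
    pair_label,
    partition_subnetworks,
    patch_feature_names,
    patch_features,
    read_cell_segmentation,
    tile_wsi,
    wsi_features,
)
from emtpath.io import write_cell_map_csv

from conftest import random_cell_map


# ---------------------------------------------------------------- oracles

def brute_force_edges(cm: CellMap, k=5, max_len=50.0):
    """Independent all-pairs kNN + filter + rank-symmetrisation oracle."""
    n = len(cm)
    pts = np.column_stack([cm.x, cm.y])
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    edges = {}
    for i in range(n):
        order = np.argsort(np.where(np.arange(n) == i, np.inf, d[i]))
        for rank, j in enumerate(order[: min(k, n - 1)], start=1):
            key = (min(i, j), max(i, j))
            if key not in edges or rank < edges[key][1]:
                edges[key] = (d[i, j], rank)
    return {k_: v for k_, v in edges.items() if v[0] <= max_len}


def brute_force_mst_weight(edges, n):
    """Minimum total spanning-forest weight by exhaustive enumeration."""
    keys = list(edges)
    # connected components under the retained edges
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in keys:
        parent[find(i)] = find(j)
    comps = {}
    for v in range(n):
        comps.setdefault(find(v), []).append(v)

    total = 0.0
    for comp in comps.values():
        if len(comp) == 1:
            continue
        cedges = [(i, j) for (i, j) in keys if i in comp]
        need = len(comp) - 1
        best = np.inf
        for sub in itertools.combinations(cedges, need):
            p2 = {v: v for v in comp}

            def f2(a):
                while p2[a] != a:
                    a = p2[a]
                return a

            ok = True
            for i, j in sub:
                ri, rj = f2(i), f2(j)
                if ri == rj:
                    ok = False
                    break
                p2[ri] = rj
            if ok:
                w = sum(edges[e][0] for e in sub)
                best = min(best, w)
        total += best
    return total


# ------------------------------------------------------------ graph tests

def test_edge_filter_discards_long_edges():
    cm = CellMap([0.0, 60.0], [0.0, 0.0], ["T", "T"], 4096)
    assert len(build_patch_graph(cm).edges) == 0


def test_single_close_pair_is_mst_edge():
    cm = CellMap([0.0, 30.0], [0.0, 0.0], ["T", "I"], 4096)
    g = build_patch_graph(cm)
    assert len(g.edges) == 1
    e = g.edges.iloc[0]
    assert e["length"] == pytest.approx(30.0)
    assert e["nn_rank"] == 1
    assert bool(e["mst"])
    assert e["pair_type"] == "T-I"


def test_fewer_than_two_cells_gives_empty_graph():
    assert len(build_patch_graph(CellMap([1.0], [1.0], ["T"], 64)).edges) == 0
    empty = CellMap(np.empty(0), np.empty(0), np.empty(0, dtype=object), 64)
    assert len(build_patch_graph(empty).edges) == 0


@pytest.mark.parametrize("trial", range(20))
def test_graph_matches_brute_force_oracle(trial):
    rng = np.random.default_rng(1000 + trial)
    cm = random_cell_map(rng, 8, size=120.0)
    g = build_patch_graph(cm, k=5, max_len=50.0)
    oracle = brute_force_edges(cm, k=5, max_len=50.0)

    got = {(int(r.i), int(r.j)): (r.length, int(r.nn_rank))
           for r in g.edges.itertuples()}
    assert set(got) == set(oracle)
    for key in oracle:
        assert got[key][0] == pytest.approx(oracle[key][0])
        assert got[key][1] == oracle[key][1]

    mst_w = g.edges.loc[g.edges["mst"], "length"].sum()
    assert mst_w == pytest.approx(brute_force_mst_weight(oracle, len(cm)))


def test_partition_is_disjoint_and_exhaustive(rng):
    cm = random_cell_map(rng, 60, size=150.0)
    g = build_patch_graph(cm)
    parts = partition_subnetworks(g)
    assert set(parts) == set(PAIR_TYPES)
    assert sum(len(p) for p in parts.values()) == len(g.edges)
    for pt, sub in parts.items():
        for r in sub.itertuples():
            assert pair_label(cm.types[int(r.i)], cm.types[int(r.j)]) == pt


def test_t_only_graph_has_only_tt_edges(rng):
    cm = random_cell_map(rng, 30, size=100.0, types=("T",))
    parts = partition_subnetworks(build_patch_graph(cm))
    assert all(len(parts[pt]) == 0 for pt in PAIR_TYPES if pt != "T-T")
    assert len(parts["T-T"]) > 0


# --------------------------------------------------------------- stats

def test_edge_stats_degenerate_conventions():
    assert np.allclose(edge_length_stats([10, 10, 10]), [10, 10, 10, 0, 0, 0])
    assert np.isnan(edge_length_stats([])).all()


def test_edge_stats_match_moment_formulas():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    m3 = ((x - m) ** 3).mean()
    m4 = ((x - m) ** 4).mean()
    got = edge_length_stats(x)
    assert np.allclose(got, [1, 4, m, m2, m3 / m2**1.5, m4 / m2**2 - 3])


# --------------------------------------------------------------- tiling

def test_tile_boundary_is_half_open():
    cm = CellMap([4096.0, 0.0], [0.0, 0.0], ["T", "T"], 4096)
    tiles = tile_wsi(cm, 4096)
    ids = {t.patch_id for t in tiles}
    assert ids == {"r0_c0", "r0_c1"}


def test_tile_membership_matches_floor_division(rng):
    x = rng.uniform(0, 3 * 512, 10)
    y = rng.uniform(0, 3 * 512, 10)
    cm = CellMap(x, y, np.array(["T"] * 10, dtype=object), 512)
    tiles = tile_wsi(cm, 512)
    assert sum(len(t) for t in tiles) == 10
    seen = set()
    for t in tiles:
        r, c = (int(s[1:]) for s in t.patch_id.split("_"))
        for lx, ly in zip(t.x, t.y):
            gx, gy = lx + c * 512, ly + r * 512
            assert (int(gx // 512), int(gy // 512)) == (c, r)
            seen.add((round(gx, 6), round(gy, 6)))
    assert seen == {(round(a, 6), round(b, 6)) for a, b in zip(x, y)}


# ----------------------------------------------------------- features

def test_patch_features_shape_and_missing():
    empty = CellMap(np.empty(0), np.empty(0), np.empty(0, dtype=object), 64)
    f = patch_features(empty)
    assert len(f) == 252 and f.isna().all()

    rng = np.random.default_rng(3)
    t_only = random_cell_map(rng, 40, size=120.0, types=("T",))
    f2 = patch_features(t_only)
    non_tt = [n for n in f2.index if not n.startswith("T-T")]
    assert f2[non_tt].isna().all()
    assert f2[[n for n in f2.index if n.startswith("T-T_all")]].notna().all()


def test_patch_features_match_straight_line_reference(rng):
    cm = random_cell_map(rng, 12, size=100.0)
    got = patch_features(cm)
    oracle_edges = brute_force_edges(cm)
    mst_flags = {
        (int(r.i), int(r.j)): bool(r.mst)
        for r in build_patch_graph(cm).edges.itertuples()
    }
    for pt in PAIR_TYPES:
        sub = {e: v for e, v in oracle_edges.items()
               if pair_label(cm.types[e[0]], cm.types[e[1]]) == pt}
        for grp in EDGE_GROUPS:
            if grp == "all":
                lens = [v[0] for v in sub.values()]
            elif grp == "mst":
                lens = [v[0] for e, v in sub.items() if mst_flags[e]]
            else:
                lens = [v[0] for v in sub.values() if v[1] == int(grp[1])]
            expect = six_stats(lens)
            block = got[[f"{pt}_{grp}_{s}" for s in
                         ("min", "max", "mean", "variance", "skewness",
                          "kurtosis")]].to_numpy()
            assert np.allclose(block, expect, equal_nan=True)


def test_wsi_vector_has_1008_features(rng):
    patches = [patch_features(random_cell_map(rng, 50, 150.0))
               for _ in range(3)]
    wf = wsi_features(patches)
    assert len(wf.values) == 1008
    assert len(PAIR_TYPES) * len(EDGE_GROUPS) * 6 * len(AGG_NAMES) == 1008


def test_wsi_aggregation_degenerate_and_hand_values():
    names = patch_feature_names()
    p1 = pd.Series(np.nan, index=names)
    p1[names[0]] = 2.0
    wf1 = wsi_features([p1])
    assert wf1.values[f"{names[0]}_mean"] == pytest.approx(2.0)
    assert wf1.values[f"{names[0]}_variance"] == 0.0
    assert wf1.values[f"{names[0]}_skewness"] == 0.0
    assert wf1.n_patches_used[names[0]] == 1
    # feature observed in no patch -> 0 with n_used 0
    assert wf1.values[f"{names[1]}_mean"] == 0.0
    assert wf1.n_patches_used[names[1]] == 0

    p2 = p1.copy()
    p2[names[0]] = 4.0
    wf2 = wsi_features([p1, p2])
    assert wf2.values[f"{names[0]}_mean"] == pytest.approx(3.0)
    assert wf2.values[f"{names[0]}_variance"] == pytest.approx(1.0)

    with pytest.raises(ValueError):
        wsi_features([])


def test_rigid_motion_invariance(rng):
    cm = random_cell_map(rng, 40, size=400.0)
    # shrink into the centre so the moved copy stays in the tile
    x = cm.x / 4 + 150
    y = cm.y / 4 + 150
    base = patch_features(CellMap(x, y, cm.types, 400))
    th = 0.3
    cx, cy = 200.0, 200.0
    xr = cx + np.cos(th) * (x - cx) - np.sin(th) * (y - cy) + 5.0
    yr = cy + np.sin(th) * (x - cx) + np.cos(th) * (y - cy) - 3.0
    moved = patch_features(CellMap(xr, yr, cm.types, 400))
    assert np.allclose(base.to_numpy(), moved.to_numpy(),
                       atol=1e-9, equal_nan=True)


def test_scale_covariance(rng):
    cm = random_cell_map(rng, 30, size=100.0)
    c = 1.7
    base = patch_features(cm, max_len=50.0)
    scaled = patch_features(
        CellMap(cm.x * c, cm.y * c, cm.types, int(100 * c) + 1),
        max_len=50.0 * c)
    for name in base.index:
        b, s = base[name], scaled[name]
        if np.isnan(b):
            assert np.isnan(s)
        elif name.endswith(("_min", "_max", "_mean")):
            assert s == pytest.approx(b * c)
        elif name.endswith("_variance"):
            assert s == pytest.approx(b * c**2)
        else:
            assert s == pytest.approx(b, abs=1e-9)


# --------------------------------------------------------------- reading

def test_csv_reader_maps_and_drops_classes(tmp_path):
    p = tmp_path / "cells.csv"
    p.write_text("x,y,class\n1,2,neoplastic\n3,4,inflammatory\n5,6,dead\n")
    maps = read_cell_segmentation(p, "csv")
    assert len(maps) == 1 and len(maps[0]) == 2
    assert list(maps[0].types) == ["T", "I"]


def test_hovernet_json_reader(tmp_path):
    p = tmp_path / "nuc.json"
    p.write_text(json.dumps({"nuc": {
        "1": {"centroid": [10.5, 20.5], "type": 1},
        "2": {"centroid": [30.0, 40.0], "type": 3},
        "3": {"centroid": [1.0, 1.0], "type": 5},
    }}))
    (cm,) = read_cell_segmentation(p, "hovernet-json")
    assert len(cm) == 2
    assert list(cm.types) == ["T", "S"]


def test_empty_file_returns_empty_list(tmp_path):
    p = tmp_path / "empty.csv"
    p.write_text("")
    assert read_cell_segmentation(p, "csv") == []


def test_unknown_dialect_raises(tmp_path):
    with pytest.raises(ValueError):
        read_cell_segmentation(tmp_path / "x", "xml")


def test_cell_map_csv_round_trip(tmp_path, rng):
    cm = random_cell_map(rng, 15, 64.0)
    p = tmp_path / "cells.csv"
    write_cell_map_csv(cm, p)
    (back,) = read_cell_segmentation(p, "csv", patch_size_px=64)
    pd.testing.assert_frame_equal(cm.to_frame(), back.to_frame())


def test_sd_alias_canonicalisation():
    assert canonicalize_feature_names(["I-I_all_sd_mean", "T-S_v1_mean_sd"]) \
        == ["I-I_all_variance_mean", "T-S_v1_mean_variance"]
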