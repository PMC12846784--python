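"""Cell-interaction-graph pathomics features from nucleus segmentations.

A whole-slide image (WSI) is represented by its table of segmented
nucleus centroids, each labelled tumor (T), immune/lymphocyte (I) or
stromal (S).  The slide is tiled into square patches (default
4096 x 4096 px at 40x, 0.25 um/px); within each patch a cell-interaction
graph is built from the union of every cell's k nearest neighbours
(k = 5), edges longer than 50 px are discarded, and the minimum spanning
tree of the retained graph is marked.  Edge-length distributions are
summarised per interaction subnetwork (T-T, T-I, T-S, I-I, I-S, S-S),
per edge group (nearest-neighbour ranks v1..v5, all retained edges, and
the MST backbone) with six moments, giving 252 patch features; these are
aggregated across patches with four moments into the 1,008-dimensional
WSI feature vector.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree

from ._stats import STAT_NAMES, six_stats

logger = logging.getLogger(__name__)

CELL_TYPES = ("T", "I", "S")
_TYPE_ORDER = {"T": 0, "I": 1, "S": 2}

PAIR_TYPES = ("T-T", "T-I", "T-S", "I-I", "I-S", "S-S")
EDGE_GROUPS = ("v1", "v2", "v3", "v4", "v5", "all", "mst")

#: PanNuke class-id -> cell-type mapping used by HoverNet outputs.
#: Dead cells (4) and non-neoplastic epithelium (5) are dropped.
PANNUKE_CLASS_MAP = {1: "T", 2: "I", 3: "S"}

_CSV_CLASS_ALIASES = {
    "t": "T", "tumor": "T", "tumour": "T", "neoplastic": "T",
    "i": "I", "immune": "I", "lymphocyte": "I", "inflammatory": "I",
    "s": "S", "stroma": "S", "stromal": "S", "connective": "S",
}


def pair_label(a: str, b: str) -> str:
    """Canonical unordered subnetwork label for endpoint types *a*, *b*."""
    if _TYPE_ORDER[a] <= _TYPE_ORDER[b]:
        return f"{a}-{b}"
    return f"{b}-{a}"


@dataclass
class CellMap:
    """Segmented nuclei of one patch (or slide): coordinates in pixels at 40x."""

    x: np.ndarray
    y: np.ndarray
    types: np.ndarray
    patch_size_px: int = 4096
    patch_id: str | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.types = np.asarray(self.types, dtype=object)
        if not (len(self.x) == len(self.y) == len(self.types)):
            raise ValueError("x, y and types must have equal length")
        unknown = set(self.types) - set(CELL_TYPES)
        if unknown:
            raise ValueError(f"unknown cell types: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "type": self.types})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, patch_size_px: int = 4096,
                   patch_id: str | None = None) -> "CellMap":
        return cls(df["x"].to_numpy(), df["y"].to_numpy(),
                   df["type"].to_numpy(), patch_size_px, patch_id)


@dataclass
class CellGraph:
    """Filtered k-NN interaction graph of one patch with its MST backbone.

    ``edges`` columns: i, j, length, nn_rank, pair_type, mst.
    """

    n_cells: int
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)


def read_cell_segmentation(path, dialect: str = "csv",
                           patch_size_px: int = 4096) -> list[CellMap]:
    """Read nucleus segmentations into ``CellMap`` objects.

    ``dialect='hovernet-json'`` parses HoverNet-style JSON
    (``{nucleus_id: {"centroid": [x, y], "type": int}}``, optionally
    wrapped under a top-level ``"nuc"`` key) with PanNuke class ids;
    classes without a T/I/S mapping are dropped with a logged count.
    ``dialect='csv'`` expects columns x, y and class/type with named or
    single-letter labels.
    """
    if dialect == "hovernet-json":
        with open(path) as fh:
            raw = json.load(fh)
        if isinstance(raw, dict) and "nuc" in raw:
            raw = raw["nuc"]
        xs, ys, ts, dropped = [], [], [], 0
        for rec in raw.values():
            t = PANNUKE_CLASS_MAP.get(int(rec["type"]))
            if t is None:
                dropped += 1
                continue
            cx, cy = rec["centroid"]
            xs.append(float(cx))
            ys.append(float(cy))
            ts.append(t)
        if dropped:
            logger.warning("dropped %d nuclei with unmapped PanNuke class", dropped)
        return [CellMap(np.array(xs), np.array(ys), np.array(ts, dtype=object),
                        patch_size_px)]
    if dialect == "csv":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            return []
        if df.empty:
            return []
        col = "class" if "class" in df.columns else "type"
        mapped = df[col].astype(str).str.strip().str.lower().map(_CSV_CLASS_ALIASES)
        dropped = int(mapped.isna().sum())
        if dropped:
            logger.warning("dropped %d cells with unmappable class label", dropped)
        keep = mapped.notna()
        return [CellMap(df.loc[keep, "x"].to_numpy(dtype=float),
                        df.loc[keep, "y"].to_numpy(dtype=float),
                        mapped[keep].to_numpy(dtype=object), patch_size_px)]
    raise ValueError(f"unsupported segmentation dialect: {dialect!r}")


def tile_wsi(cells: CellMap, patch_size_px: int = 4096) -> list[CellMap]:
    """Split slide-level coordinates into half-open square tiles.

    Tile (r, c) covers ``[c*s, (c+1)*s) x [r*s, (r+1)*s)``; each cell
    falls in exactly one tile and empty tiles are omitted.  Coordinates
    are re-based to the tile origin.
    """
    if len(cells) and (cells.x.min() < 0 or cells.y.min() < 0):
        raise ValueError("slide coordinates must be non-negative")
    s = patch_size_px
    col = np.floor(cells.x / s).astype(int)
    row = np.floor(cells.y / s).astype(int)
    out = []
    for (r, c) in sorted(set(zip(row.tolist(), col.tolist()))):
        m = (row == r) & (col == c)
        out.append(CellMap(cells.x[m] - c * s, cells.y[m] - r * s,
                           cells.types[m], s, patch_id=f"r{r}_c{c}"))
    return out


def build_patch_graph(cells: CellMap, k: int = 5, max_len: float = 50.0) -> CellGraph:
    """Build the filtered k-NN cell-interaction graph of one patch.

    Candidate edges are the union over cells of their *k* nearest
    neighbours by Euclidean pixel distance, symmetrised with
    ``nn_rank = min(rank of j among i, rank of i among j)``.  Edges
    longer than *max_len* pixels are discarded.  ``mst`` flags edges of
    the minimum spanning forest of the retained graph.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    n = len(cells)
    cols = ["i", "j", "length", "nn_rank", "pair_type", "mst"]
    if n < 2:
        return CellGraph(n, pd.DataFrame(columns=cols))

    pts = np.column_stack([cells.x, cells.y])
    kq = min(k + 1, n)
    tree = cKDTree(pts)
    dist, idx = tree.query(pts, k=kq)

    best: dict[tuple[int, int], tuple[float, int]] = {}
    for i in range(n):
        rank = 0
        for col in range(1, kq):
            j = int(idx[i, col])
            if j == i:
                continue
            rank += 1
            key = (i, j) if i < j else (j, i)
            d = float(dist[i, col])
            prev = best.get(key)
            if prev is None or rank < prev[1]:
                best[key] = (d, rank)

    rows = [(i, j, d, r) for (i, j), (d, r) in best.items() if d <= max_len]
    if not rows:
        return CellGraph(n, pd.DataFrame(columns=cols))
    edges = pd.DataFrame(rows, columns=["i", "j", "length", "nn_rank"])
    edges = edges.sort_values(["i", "j"], ignore_index=True)
    edges["pair_type"] = [
        pair_label(cells.types[i], cells.types[j])
        for i, j in zip(edges["i"], edges["j"])
    ]

    # +1 shift keeps zero-length edges (coincident nuclei) explicit in the
    # sparse graph; a constant offset per edge does not change the MST.
    g = coo_matrix((edges["length"] + 1.0, (edges["i"], edges["j"])), shape=(n, n))
    mst = minimum_spanning_tree(g).tocoo()
    in_mst = {(min(i, j), max(i, j)) for i, j in zip(mst.row, mst.col)}
    edges["mst"] = [(i, j) in in_mst for i, j in zip(edges["i"], edges["j"])]
    return CellGraph(n, edges)


def partition_subnetworks(graph: CellGraph) -> dict[str, pd.DataFrame]:
    """Split the edge set by unordered endpoint-type pair.

    Always returns all six subnetwork keys; the six edge lists are a
    disjoint, exhaustive partition of ``graph.edges``.
    """
    out = {}
    for pt in PAIR_TYPES:
        if len(graph.edges):
            out[pt] = graph.edges[graph.edges["pair_type"] == pt]
        else:
            out[pt] = graph.edges
    return out


def edge_length_stats(lengths) -> np.ndarray:
    """Six edge-length moments; see :func:`emtpath._stats.six_stats`."""
    return six_stats(lengths)


def patch_feature_names() -> list[str]:
    return [f"{p}_{g}_{s}" for p in PAIR_TYPES for g in EDGE_GROUPS for s in STAT_NAMES]


def patch_features(cells: CellMap, k: int = 5, max_len: float = 50.0) -> pd.Series:
    """Compute the 252 named edge-length statistics of one patch.

    For each of the 6 subnetworks x 7 edge groups (nn_rank exactly 1..5,
    all retained edges, MST edges), the six moments of the edge-length
    distribution.  Groups with no edges are NaN (missing).
    """
    graph = build_patch_graph(cells, k=k, max_len=max_len)
    parts = partition_subnetworks(graph)
    vals = np.empty(len(PAIR_TYPES) * len(EDGE_GROUPS) * 6)
    pos = 0
    for pt in PAIR_TYPES:
        sub = parts[pt]
        for grp in EDGE_GROUPS:
            if len(sub) == 0:
                lengths = np.empty(0)
            elif grp == "all":
                lengths = sub["length"].to_numpy()
            elif grp == "mst":
                lengths = sub.loc[sub["mst"], "length"].to_numpy()
            else:
                r = int(grp[1])
                lengths = sub.loc[sub["nn_rank"] == r, "length"].to_numpy()
            vals[pos:pos + 6] = six_stats(lengths)
            pos += 6
    return pd.Series(vals, index=patch_feature_names())


AGG_NAMES = ("mean", "variance", "skewness", "kurtosis")


@dataclass
class WSIFeatureVector:
    """1,008 named WSI-level features with per-feature patch counts."""

    values: pd.Series
    n_patches_used: pd.Series

    def __len__(self) -> int:
        return len(self.values)


def wsi_feature_names() -> list[str]:
    return [f"{f}_{a}" for f in patch_feature_names() for a in AGG_NAMES]


def wsi_features(patch_vectors: list[pd.Series] | pd.DataFrame) -> WSIFeatureVector:
    """Aggregate patch feature vectors into the 1,008-dim WSI descriptor.

    Each of the 252 patch features is summarised across patches by mean,
    variance, skewness and kurtosis (population moments, missing patches
    excluded).  Features observed in no patch get 0 with
    ``n_patches_used = 0`` so the vector stays dense.
    """
    if isinstance(patch_vectors, pd.DataFrame):
        mat = patch_vectors
    else:
        if len(patch_vectors) == 0:
            raise ValueError("at least one patch is required")
        mat = pd.DataFrame(patch_vectors)
    if mat.shape[0] == 0:
        raise ValueError("at least one patch is required")
    mat = mat.reindex(columns=patch_feature_names())

    vals = np.empty(mat.shape[1] * 4)
    n_used = np.empty(mat.shape[1], dtype=int)
    for ci, col in enumerate(mat.columns):
        v = mat[col].dropna().to_numpy()
        n_used[ci] = v.size
        if v.size == 0:
            vals[ci * 4:ci * 4 + 4] = 0.0
        else:
            vals[ci * 4:ci * 4 + 4] = six_stats(v)[2:]
    return WSIFeatureVector(
        pd.Series(vals, index=wsi_feature_names()),
        pd.Series(n_used, index=mat.columns),
    )


def canonicalize_feature_names(names) -> list[str]:
    """Map the ``sd`` alias used in some feature tables to ``variance``."""
    out = []
    for n in names:
        n = n.replace("_sd_", "_variance_")
        if n.endswith("_sd"):
            n = n[:-3] + "_variance"
        out.append(n)
    return out
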