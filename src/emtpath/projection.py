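"""KNN projection of bulk/cell-line profiles onto a single-cell trajectory.

Reference single cells (with pseudotime annotations) and query bulk or
cell-line profiles are embedded jointly: genes are intersected,
expression log-normalised, optionally batch-adjusted (reference vs
query as two batches, empirical-Bayes location/scale), and reduced by
PCA.  Each query is assigned the median pseudotime of its k nearest
reference cells (k = 50 by default) and an EMT macrostate via the
fitted mixture boundaries.  The number of modes in the kernel density
of the estimates diagnoses whether the chosen k preserves the
trajectory's macrostate structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA

from ._batch import combat_adjust
from .macrostates import MacrostateModel, assign_states


def _log_normalize(expr: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Library-size normalise to *scale* counts per cell and log1p.

    Matrices containing negative values are assumed to be already
    normalised and are returned unchanged.
    """
    X = expr.to_numpy(dtype=float)
    if (X < 0).any():
        return expr.astype(float)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return pd.DataFrame(np.log1p(X / lib * scale), index=expr.index,
                        columns=expr.columns)


def joint_embed(ref_expr: pd.DataFrame, query_expr: pd.DataFrame,
                n_pcs: int = 30, batch_adjust: bool = True,
                min_shared_genes: int = 50):
    """Embed reference cells and query profiles in a shared PCA space.

    Returns ``(ref_coords, query_coords)`` DataFrames.  Both inputs are
    cells/samples x genes; genes are intersected (error below
    *min_shared_genes*), log-normalised, optionally batch-adjusted
    treating reference and query as two batches, and projected onto the
    top *n_pcs* components of the joint matrix.
    """
    shared = ref_expr.columns.intersection(query_expr.columns)
    if len(shared) < min_shared_genes:
        raise ValueError(f"only {len(shared)} shared genes "
                         f"(need >= {min_shared_genes})")
    joint = pd.concat([_log_normalize(ref_expr[shared]),
                       _log_normalize(query_expr[shared])], axis=0)
    if batch_adjust:
        batch = np.r_[np.zeros(len(ref_expr)), np.ones(len(query_expr))]
        joint = combat_adjust(joint, batch)
    n_pcs = min(n_pcs, joint.shape[0] - 1, joint.shape[1])
    pca = PCA(n_components=n_pcs, random_state=0)
    coords = pca.fit_transform(joint.to_numpy() - joint.to_numpy().mean(axis=0))
    ref_coords = pd.DataFrame(coords[:len(ref_expr)], index=ref_expr.index)
    query_coords = pd.DataFrame(coords[len(ref_expr):], index=query_expr.index)
    return ref_coords, query_coords


@dataclass
class ProjectionResult:
    """Per-query pseudotime estimates and macrostate assignments."""

    estimates: pd.Series
    states: pd.Series | None
    neighbor_ids: pd.DataFrame
    neighbor_pseudotimes: pd.DataFrame
    k: int


def project_knn(ref_coords: pd.DataFrame, query_coords: pd.DataFrame,
                ref_pseudotime: pd.Series, k: int = 50,
                model: MacrostateModel | None = None) -> ProjectionResult:
    """Estimate query pseudotimes as the median of k nearest reference cells.

    Neighbours are Euclidean in the joint embedding; distance ties break
    deterministically by reference cell position.  When a macrostate
    *model* is given, each estimate is also assigned an EMT state via
    the model boundaries.
    """
    if k < 1 or k > len(ref_coords):
        raise ValueError("k must be between 1 and the number of reference cells")
    pt = ref_pseudotime.reindex(ref_coords.index).to_numpy(dtype=float)
    R = ref_coords.to_numpy(dtype=float)
    Q = query_coords.to_numpy(dtype=float)
    # full distance matrix + stable argsort => deterministic tie-breaks
    d2 = ((Q[:, None, :] - R[None, :, :]) ** 2).sum(axis=2)
    nbr = np.argsort(d2, axis=1, kind="stable")[:, :k]
    nbr_pt = pt[nbr]
    est = pd.Series(np.median(nbr_pt, axis=1), index=query_coords.index,
                    name="pseudotime_estimate")
    states = assign_states(est, model) if model is not None else None
    return ProjectionResult(
        estimates=est,
        states=states,
        neighbor_ids=pd.DataFrame(ref_coords.index.to_numpy()[nbr],
                                  index=query_coords.index),
        neighbor_pseudotimes=pd.DataFrame(nbr_pt, index=query_coords.index),
        k=k,
    )


def density_peak_count(estimates, grid_size: int = 512,
                       min_rel_height: float = 0.05) -> int:
    """Count strict local maxima of the Gaussian KDE of the estimates.

    Silverman's rule sets the bandwidth; the density is evaluated on a
    *grid_size*-point grid padded by three bandwidths, and a peak is a
    grid point strictly above both neighbours.  Maxima below
    *min_rel_height* of the global density maximum are ignored - they
    are sampling ripples in the far tails, not modes.
    """
    x = np.asarray(pd.Series(estimates).dropna(), dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 estimates")
    kde = gaussian_kde(x, bw_method="silverman")
    h = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    d = kde(grid)
    is_peak = (d[1:-1] > d[:-2]) & (d[1:-1] > d[2:]) \
        & (d[1:-1] >= min_rel_height * d.max())
    return int(is_peak.sum())
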