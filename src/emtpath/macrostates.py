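"""EMT scoring and macrostate segmentation of a pseudotime axis.

Per-cell epithelial and mesenchymal module scores are plain means of
log-normalised marker expression; the EMT score is mesenchymal minus
epithelial.  The pseudotime distribution of mesenchyme-like epithelial
cells is modelled as a three-component univariate Gaussian mixture
(unequal variances, EM), and the intersection points of adjacent
weighted component densities define two data-driven boundaries
segmenting the axis into EMT-early, EMT-stable and EMT-late
macrostates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

#: Canonical epithelial markers (keratins and junctional genes).
EPITHELIAL_MARKERS = (
    "KRT14", "KRT17", "KRT6A", "KRT5", "KRT19", "KRT8", "KRT16",
    "KRT18", "KRT6B", "KRT15", "KRT6C", "KRTCAP3", "SFN", "EPCAM",
)

#: Canonical mesenchymal markers (EMT transcription factors, matrix genes).
MESENCHYMAL_MARKERS = (
    "VIM", "CDH2", "FOXC2", "SNAI1", "SNAI2", "TWIST1", "FN1", "ITGB6",
    "MMP2", "MMP3", "MMP9", "SOX10", "GSC", "ZEB1", "ZEB2", "TWIST2",
)

STATE_NAMES = ("EMT-early", "EMT-stable", "EMT-late")


@dataclass(frozen=True)
class MarkerPanels:
    epithelial: tuple[str, ...] = EPITHELIAL_MARKERS
    mesenchymal: tuple[str, ...] = MESENCHYMAL_MARKERS

    def __post_init__(self):
        if not self.epithelial or not self.mesenchymal:
            raise ValueError("marker panels must be non-empty")
        if set(self.epithelial) & set(self.mesenchymal):
            raise ValueError("marker panels must be disjoint")


def module_score(expr: pd.DataFrame, panel) -> pd.Series:
    """Mean log-normalised expression of *panel* genes, per cell.

    *expr* is cells x genes.  Panel genes absent from the matrix are
    dropped with a warning; if none are present an error is raised.
    """
    panel = list(panel)
    present = [g for g in panel if g in expr.columns]
    if not present:
        raise ValueError(f"no panel gene present in matrix: {panel}")
    if len(present) < len(panel):
        missing = sorted(set(panel) - set(present))
        warnings.warn(f"{len(missing)} panel genes absent, dropped: {missing}")
    return expr[present].mean(axis=1)


def emt_score(expr: pd.DataFrame, panels: MarkerPanels = MarkerPanels()) -> pd.Series:
    """EMT score = mesenchymal module score - epithelial module score."""
    return module_score(expr, panels.mesenchymal) - module_score(expr, panels.epithelial)


@dataclass
class MacrostateModel:
    """Three-component 1-D Gaussian mixture with ordered state boundaries."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    boundaries: tuple[float, float] | None = field(default=None)

    def __post_init__(self):
        order = np.argsort(self.means)
        self.weights = np.asarray(self.weights, float)[order]
        self.means = np.asarray(self.means, float)[order]
        self.sds = np.asarray(self.sds, float)[order]

    def density(self, x) -> np.ndarray:
        x = np.asarray(x, float)[..., None]
        comp = self.weights * np.exp(-0.5 * ((x - self.means) / self.sds) ** 2) \
            / (self.sds * np.sqrt(2 * np.pi))
        return comp.sum(axis=-1)


_SIGMA_FLOOR = 1e-6


def _em_fit(x: np.ndarray, w, mu, sd, tol: float, max_iter: int):
    """EM for a 1-D Gaussian mixture from one initialisation.

    Returns (w, mu, sd, loglik, n_iter, converged).  The log-likelihood
    is checked to be non-decreasing at every step.
    """
    n = x.size
    prev_ll = -np.inf
    ll = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        log_comp = (np.log(w) - np.log(sd) - 0.5 * np.log(2 * np.pi)
                    - 0.5 * ((x[:, None] - mu) / sd) ** 2)
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.sum())
        if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
            raise AssertionError("EM log-likelihood decreased")
        resp = np.exp(log_comp - log_norm[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, _SIGMA_FLOOR**2))
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
    return w, mu, sd, ll, it, converged


def fit_macrostate_model(pseudotime, n_init: int = 10, tol: float = 1e-8,
                         max_iter: int = 500, seed: int = 0) -> MacrostateModel:
    """Fit the 3-component Gaussian mixture to pseudotime values by EM.

    The best of *n_init* initialisations (quantile-based starting means,
    jittered after the first) by final log-likelihood is kept; component
    variances are unequal with a standard-deviation floor of 1e-6.
    Boundaries are attached via :func:`component_boundaries`.
    """
    x = np.asarray(pd.Series(pseudotime).to_numpy(), dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 30:
        raise ValueError("need at least 30 cells to fit the mixture")
    if np.unique(x).size < 3:
        raise ValueError("pseudotime must have at least 3 distinct values")
    rng = np.random.default_rng(seed)

    best = None
    for i in range(n_init):
        if i == 0:
            qs = np.array([1 / 6, 3 / 6, 5 / 6])
        else:
            qs = np.sort(rng.uniform(0.02, 0.98, size=3))
        mu0 = np.quantile(x, qs)
        mu0 = mu0 + rng.normal(0, 1e-6, 3) if np.unique(mu0).size < 3 else mu0
        sd0 = np.full(3, max(x.std() / 3, _SIGMA_FLOOR))
        w0 = np.full(3, 1 / 3)
        try:
            fit = _em_fit(x, w0, mu0, sd0, tol, max_iter)
        except FloatingPointError:
            continue
        if best is None or fit[3] > best[3]:
            best = fit
    w, mu, sd, ll, n_iter, converged = best
    model = MacrostateModel(w, mu, sd, ll, n_iter, converged)
    model.boundaries = component_boundaries(model)
    return model


def _intersection(w1, m1, s1, w2, m2, s2, mixture_density) -> float:
    """Root of w1*N(x;m1,s1) = w2*N(x;m2,s2) inside [m1, m2].

    Solved from the quadratic obtained by equating log-densities.  If
    both quadratic roots fall in the interval the one with higher
    mixture density is taken; if none, the midpoint of the means is used
    with a warning.  The result is clamped into [m1, m2].
    """
    a = 0.5 / s2**2 - 0.5 / s1**2
    b = m1 / s1**2 - m2 / s2**2
    c = (m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2)
         + np.log(w1 / s1) - np.log(w2 / s2))
    if abs(a) < 1e-14:
        roots = [] if abs(b) < 1e-14 else [-c / b]
    else:
        disc = b**2 - 4 * a * c
        roots = [] if disc < 0 else [(-b + np.sqrt(disc)) / (2 * a),
                                     (-b - np.sqrt(disc)) / (2 * a)]
    inside = [r for r in roots if m1 <= r <= m2]
    if not inside:
        warnings.warn("no density intersection between component means; "
                      "using midpoint")
        return 0.5 * (m1 + m2)
    if len(inside) == 2:
        inside.sort(key=lambda r: -mixture_density(r))
    return float(np.clip(inside[0], m1, m2))


def component_boundaries(model: MacrostateModel) -> tuple[float, float]:
    """Weighted-density intersection boundaries (b1, b2) between adjacent
    mixture components, with mu1 <= b1 <= mu2 <= b2 <= mu3."""
    w, m, s = model.weights, model.means, model.sds
    b1 = _intersection(w[0], m[0], s[0], w[1], m[1], s[1],
                       lambda x: model.density(x))
    b2 = _intersection(w[1], m[1], s[1], w[2], m[2], s[2],
                       lambda x: model.density(x))
    return (b1, b2)


def assign_states(pseudotime, model: MacrostateModel) -> pd.Series:
    """Assign EMT-early / EMT-stable / EMT-late by boundary thresholding.

    Intervals are left-closed: a cell exactly at b1 is EMT-stable, at b2
    EMT-late.
    """
    if model.boundaries is None:
        model.boundaries = component_boundaries(model)
    b1, b2 = model.boundaries
    pt = pd.Series(pseudotime, dtype=float)
    states = np.where(pt < b1, STATE_NAMES[0],
                      np.where(pt < b2, STATE_NAMES[1], STATE_NAMES[2]))
    return pd.Series(pd.Categorical(states, categories=list(STATE_NAMES)),
                     index=pt.index)
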