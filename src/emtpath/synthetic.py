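"""Synthetic data with the statistical structure the pipeline assumes.

Every generator is bit-reproducible given (seed, config): a single
global integer seed is split into named per-generator substreams via
``numpy.random.SeedSequence(seed, spawn_key=(stream_id,))``.  Each
simulated dataset ships a :class:`GroundTruth` carrying the generating
labels/parameters so downstream recovery tests can score themselves.

What is emulated:

* 3-class (T/I/S) spatial point patterns per patch, uniform or with
  Thomas-process-style clustering (Poisson parents, Gaussian offspring);
* survival cohorts whose hazard is log-linear in chosen features, with
  exponential event times and independent exponential censoring;
* a 1-D pseudotime drawn from a 3-component Gaussian mixture, with
  epithelial markers ramping down and mesenchymal markers ramping up
  linearly in pseudotime plus homoscedastic Gaussian noise;
* spot lattices with one gene decaying, one rising and one flat with
  ring distance from designated niche-center spots;
* perturbation libraries in which a controllable fraction of drugs
  reverse a planted disease signature, with one target whose drugs are
  all reversers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cellgraph import CellMap
from .macrostates import EPITHELIAL_MARKERS, MESENCHYMAL_MARKERS
from .reversal import PerturbationSet, Signature
from .spatial import SpatialGrid

_STREAMS = {"cellmap": 0, "cohort": 1, "features": 2, "pseudotime": 3,
            "grid": 4, "drugs": 5}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the global seed (documented splitting scheme)."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class SimConfig:
    """All tunable parameters of the synthetic generators.

    ``mixture`` triples are (weight, mean, sd) with weights summing to 1
    and strictly increasing means; ``cluster_intensity`` 0 means
    complete spatial randomness, larger values mean tighter Thomas-style
    clusters; ``noise_sd`` is the shared additive-Gaussian noise level
    of the expression generators.
    """

    seed: int = 0
    patch_size_px: int = 4096
    n_cells_per_type: dict = field(
        default_factory=lambda: {"T": 120, "I": 90, "S": 90})
    cluster_intensity: float = 0.0
    n_patients: int = 400
    hazard_weights: dict = field(default_factory=dict)
    censor_rate: float = 0.3
    mixture: tuple = ((1 / 3, 0.0, 0.5), (1 / 3, 5.0, 0.5), (1 / 3, 10.0, 0.5))
    n_cells: int = 3000
    n_genes: int = 60
    grid_shape: tuple = (30, 30)
    n_drugs: int = 100
    n_profiles_per_drug: int = 3
    reversal_fraction: float = 0.2
    noise_sd: float = 0.2

    def __post_init__(self):
        w = np.array([m[0] for m in self.mixture])
        mu = np.array([m[1] for m in self.mixture])
        sd = np.array([m[2] for m in self.mixture])
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(sd <= 0):
            raise ValueError("mixture sds must be positive")
        if np.any(np.diff(mu) <= 0):
            raise ValueError("mixture means must be strictly increasing")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0, 1]")
        if not 0.0 <= self.reversal_fraction <= 1.0:
            raise ValueError("reversal_fraction must be in [0, 1]")
        if any(v < 0 for v in self.n_cells_per_type.values()):
            raise ValueError("cell counts must be non-negative")
        if self.patch_size_px <= 0:
            raise ValueError("patch_size_px must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Generating labels stored alongside every simulated dataset."""

    macrostate_labels: pd.Series | None = None
    linear_predictor: pd.Series | None = None
    reversal_strength: pd.Series | None = None
    niche_profiles: pd.DataFrame | None = None
    gene_classes: dict | None = None
    enriched_target: str | None = None
    seed_spots: list | None = None


def gen_cell_map(cfg: SimConfig) -> CellMap:
    """Simulate one patch of T/I/S nucleus centroids.

    ``cluster_intensity = 0`` places cells uniformly at random;
    positive values use a Thomas-style process (uniform parent points,
    Gaussian offspring with sd shrinking as intensity grows, wrapped
    toroidally into the patch).
    """
    rng = stream_rng(cfg.seed, "cellmap")
    s = float(cfg.patch_size_px)
    xs, ys, ts = [], [], []
    for ctype in ("T", "I", "S"):
        n = int(cfg.n_cells_per_type.get(ctype, 0))
        if n == 0:
            continue
        if cfg.cluster_intensity <= 0:
            x = rng.uniform(0, s, n)
            y = rng.uniform(0, s, n)
        else:
            n_parents = max(1, int(round(n / 25)))
            px = rng.uniform(0, s, n_parents)
            py = rng.uniform(0, s, n_parents)
            sd = s / (10.0 * (1.0 + cfg.cluster_intensity))
            parent = rng.integers(0, n_parents, n)
            x = np.mod(px[parent] + rng.normal(0, sd, n), s)
            y = np.mod(py[parent] + rng.normal(0, sd, n), s)
        xs.append(x)
        ys.append(y)
        ts.append(np.full(n, ctype, dtype=object))
    if not xs:
        return CellMap(np.empty(0), np.empty(0), np.empty(0, dtype=object),
                       cfg.patch_size_px)
    return CellMap(np.concatenate(xs), np.concatenate(ys), np.concatenate(ts),
                   cfg.patch_size_px)


def gen_feature_matrix(cfg: SimConfig, n_features: int = 10,
                       prefix: str = "f") -> pd.DataFrame:
    """Standard-normal patient x feature matrix (plumbing for cohort tests)."""
    rng = stream_rng(cfg.seed, "features")
    cols = [f"{prefix}{i + 1}" for i in range(n_features)]
    return pd.DataFrame(rng.normal(size=(cfg.n_patients, n_features)),
                        columns=cols,
                        index=[f"P{i + 1:04d}" for i in range(cfg.n_patients)])


#: Baseline hazard of the simulated cohorts (events on a ~1 year scale).
BASELINE_HAZARD = 1.0 / 365.0


def gen_survival_cohort(cfg: SimConfig, features: pd.DataFrame
                        ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate survival outcomes whose hazard is log-linear in *features*.

    Event times are exponential with rate ``BASELINE_HAZARD * exp(lp)``
    where ``lp = features @ hazard_weights``; censoring times are an
    independent exponential calibrated so the expected censored fraction
    is about ``censor_rate``.  Returns a (time, event, cohort) table
    aligned with *features* and the true linear predictors.
    """
    unknown = set(cfg.hazard_weights) - set(features.columns)
    if unknown:
        raise ValueError(f"hazard_weights refer to unknown features: {sorted(unknown)}")
    rng = stream_rng(cfg.seed, "cohort")
    n = len(features)
    lp = np.zeros(n)
    for name, w in cfg.hazard_weights.items():
        lp = lp + w * features[name].to_numpy(dtype=float)
    rate = BASELINE_HAZARD * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)

    if cfg.censor_rate <= 0:
        time, event = t_event, np.ones(n, dtype=int)
    elif cfg.censor_rate >= 1:
        time = rng.exponential(1.0 / BASELINE_HAZARD, n)
        event = np.zeros(n, dtype=int)
    else:
        # calibrate the censoring rate c so that mean_i c/(c+r_i), the
        # expected censored fraction, equals censor_rate
        from scipy.optimize import brentq
        target = cfg.censor_rate

        def _frac(log_c):
            c = np.exp(log_c)
            return np.mean(c / (c + rate)) - target

        log_c = brentq(_frac, np.log(rate.min()) - 20, np.log(rate.max()) + 20)
        t_cens = rng.exponential(np.exp(-log_c), n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)

    surv = pd.DataFrame({"time": time, "event": event, "cohort": "sim"},
                        index=features.index)
    return surv, GroundTruth(linear_predictor=pd.Series(lp, index=features.index))


def gen_pseudotime_population(cfg: SimConfig
                              ) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Sample cells along a 3-component Gaussian-mixture pseudotime.

    Epithelial markers decrease and mesenchymal markers increase
    linearly in pseudotime (per-gene slopes fixed by the seed), with
    additive Gaussian noise of sd ``noise_sd``; filler genes are flat
    noise.  Returns (cells x genes expression, pseudotime, ground truth
    with the true component label per cell).
    """
    if cfg.n_cells < 3:
        raise ValueError("n_cells must be >= 3")
    rng = stream_rng(cfg.seed, "pseudotime")
    w = np.array([m[0] for m in cfg.mixture])
    mu = np.array([m[1] for m in cfg.mixture])
    sd = np.array([m[2] for m in cfg.mixture])
    comp = rng.choice(3, size=cfg.n_cells, p=w)
    pt = rng.normal(mu[comp], sd[comp])
    cells = [f"C{i + 1:05d}" for i in range(cfg.n_cells)]

    epi = list(EPITHELIAL_MARKERS)
    mes = list(MESENCHYMAL_MARKERS)
    n_fill = max(0, cfg.n_genes - len(epi) - len(mes))
    fillers = [f"FILLER{i + 1}" for i in range(n_fill)]
    genes = epi + mes + fillers

    span = max(pt.max() - pt.min(), 1e-12)
    u = (pt - pt.min()) / span  # in [0, 1], strictly monotone in pt
    slopes = rng.uniform(0.5, 1.5, size=len(genes))
    cols = {}
    for gi, g in enumerate(genes):
        noise = rng.normal(0, cfg.noise_sd, cfg.n_cells) if cfg.noise_sd > 0 else 0.0
        if g in EPITHELIAL_MARKERS:
            base = 2.0 - slopes[gi] * u
        elif g in MESENCHYMAL_MARKERS:
            base = 0.5 + slopes[gi] * u
        else:
            base = 1.0
        cols[g] = base + noise
    expr = pd.DataFrame(cols, index=cells)
    pt_s = pd.Series(pt, index=cells, name="pseudotime")
    gt = GroundTruth(macrostate_labels=pd.Series(comp, index=cells, name="component"))
    return expr, pt_s, gt


def gen_spatial_grid(cfg: SimConfig) -> tuple[SpatialGrid, GroundTruth]:
    """Simulate a square spot lattice with niche-centered gradients.

    The central spot is the seed ("niche center"); expected expression
    of gene DECAY falls exponentially with rook-lattice distance from
    the seed, RISING does the opposite, FLAT is constant; Gaussian noise
    of sd ``noise_sd`` is added.  Ground truth records the expected
    per-level profiles and the planted trend class of each gene.
    """
    rows, cols = cfg.grid_shape
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2 to form rings")
    rng = stream_rng(cfg.seed, "grid")
    yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    xx = xx.ravel()
    yy = yy.ravel()
    ids = [f"S{y:03d}_{x:03d}" for y, x in zip(yy, xx)]
    spots = pd.DataFrame({"spot_id": ids, "x": xx, "y": yy})

    cy, cx = rows // 2, cols // 2
    seed_mask = pd.Series((xx == cx) & (yy == cy), index=spots.index)
    # rook lattice distance from the single seed = Manhattan distance
    level = np.abs(xx - cx) + np.abs(yy - cy)

    decay = 10.0 * np.exp(-0.3 * level)
    rising = 10.0 * (1.0 - np.exp(-0.3 * level))
    flat = np.full(level.shape, 5.0)
    noise = (lambda: rng.normal(0, cfg.noise_sd, level.size)) \
        if cfg.noise_sd > 0 else (lambda: 0.0)
    expr = pd.DataFrame({"DECAY": decay + noise(),
                         "RISING": rising + noise(),
                         "FLAT": flat + noise()})

    max_level = int(level.max())
    lv = np.arange(max_level + 1)
    profiles = pd.DataFrame({
        "DECAY": 10.0 * np.exp(-0.3 * lv),
        "RISING": 10.0 * (1.0 - np.exp(-0.3 * lv)),
        "FLAT": 5.0,
    }, index=lv)
    gt = GroundTruth(
        niche_profiles=profiles,
        gene_classes={"DECAY": "colocalized", "RISING": "excluded",
                      "FLAT": "flat"},
        seed_spots=[ids[i] for i in np.flatnonzero(seed_mask.to_numpy())],
    )
    return SpatialGrid(spots, expr, seed_mask), gt


def gen_perturbation_library(cfg: SimConfig
                             ) -> tuple[PerturbationSet, Signature,
                                        pd.DataFrame, GroundTruth]:
    """Simulate a perturbation library around a planted disease signature.

    10% of genes form the up set and 10% the down set.  A fraction
    ``reversal_fraction`` of drugs are reversers: a reverser of strength
    s in (0, 1] pushes that fraction of the signature genes opposite to
    the disease direction; the remaining drugs mimic the signature with
    uniform(0, 1] strength, so with no reversers planted no profile is
    anti-correlated with the signature.  Each drug carries
    ``n_profiles_per_drug`` condition replicates and at least one
    target; target TGT01 is the planted enriched target - all of its
    drugs are reversers.
    """
    if cfg.n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    if cfg.n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    rng = stream_rng(cfg.seed, "drugs")
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    n_sig = max(3, cfg.n_genes // 10)
    up = genes[:n_sig]
    down = genes[n_sig:2 * n_sig]
    sig = Signature(up, down)
    pattern = np.zeros(cfg.n_genes)
    pattern[:n_sig] = 1.0
    pattern[n_sig:2 * n_sig] = -1.0

    drugs = [f"D{i + 1:03d}" for i in range(cfg.n_drugs)]
    n_rev = int(round(cfg.reversal_fraction * cfg.n_drugs))
    # the first reverser is the unique strongest (full signature affected);
    # the rest stay below the quantisation ceiling so ranks are unambiguous
    rev_strength = rng.uniform(0.3, 0.9, n_rev)
    if n_rev:
        rev_strength[0] = 1.0
    mim_strength = rng.uniform(0.1, 1.0, cfg.n_drugs - n_rev)
    strength = pd.Series(np.concatenate([-rev_strength, mim_strength]),
                         index=drugs, name="strength")

    # interleave up/down gene indices so any affected prefix hits both sets
    sig_idx = np.column_stack([np.arange(n_sig),
                               np.arange(n_sig, 2 * n_sig)]).ravel()
    profile_rows, meta_rows = [], []
    for d in drugs:
        s = strength[d]
        n_aff = max(2, int(round(abs(s) * 2 * n_sig)))
        affected = sig_idx[:n_aff]
        base = np.zeros(cfg.n_genes)
        base[affected] = np.sign(s) * pattern[affected]
        for r in range(cfg.n_profiles_per_drug):
            jitter = rng.uniform(-1e-6, 1e-6, cfg.n_genes)
            noise = rng.normal(0, cfg.noise_sd, cfg.n_genes) \
                if cfg.noise_sd > 0 else 0.0
            pid = f"{d}_p{r + 1}"
            profile_rows.append(base + jitter + noise)
            meta_rows.append((pid, d, f"CL{r + 1}", 10.0 * (r + 1), 24.0))
    profiles = pd.DataFrame(
        profile_rows, columns=genes,
        index=[m[0] for m in meta_rows])
    metadata = pd.DataFrame(
        meta_rows, columns=["profile_id", "drug", "cell_line", "dose", "time"]
    ).set_index("profile_id")
    pset = PerturbationSet(profiles, metadata)

    # targets: TGT01 gets only reversers (the planted enriched target,
    # present only when reversers exist); every drug gets >= 1 target
    n_targets = max(3, cfg.n_drugs // 5)
    targets = [f"TGT{i + 1:02d}" for i in range(n_targets)]
    rows = []
    enriched = None
    if n_rev >= 2:
        enriched = targets[0]
        for d in drugs[:min(5, n_rev)]:
            rows.append((d, enriched))
    other = targets[1:] if enriched else targets
    for d in drugs:
        rows.append((d, other[rng.integers(0, len(other))]))
    drug_targets = pd.DataFrame(rows, columns=["drug", "target"])

    gt = GroundTruth(reversal_strength=strength, enriched_target=enriched)
    return pset, sig, drug_targets, gt
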