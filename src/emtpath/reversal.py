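"""Signature-reversal drug screening and target enrichment.

A disease signature (up/down gene sets from a tumor-vs-normal contrast)
is scored against each perturbation expression profile with the classic
connectivity-map Kolmogorov-Smirnov statistic: a positive connectivity
score means the perturbation mimics the disease signature, a negative
score means it reverses it.  Multi-condition profiles per drug are
collapsed by picking the profile closest to the drug's median score;
drugs are ranked most-reversing-first, and drug-target annotations are
tested for enrichment at the top of the ranked list with a weighted-KS
(ssGSEA-style) running sum against a membership-permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Signature:
    """Disease signature: disjoint up- and down-regulated gene sets."""

    up: frozenset
    down: frozenset

    def __post_init__(self):
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        if not self.up or not self.down:
            raise ValueError("up and down sets must be non-empty")
        if self.up & self.down:
            raise ValueError("up and down sets must be disjoint")

    def swapped(self) -> "Signature":
        return Signature(self.down, self.up)


@dataclass
class PerturbationSet:
    """Perturbation profiles (profile x gene values) with per-profile
    metadata (drug, cell_line, dose, time)."""

    profiles: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        if self.profiles.index.duplicated().any():
            raise ValueError("profile ids must be unique")
        if self.profiles.shape[1] < 10:
            raise ValueError("need at least 10 genes")


def _ks_es(positions: np.ndarray, n: int) -> float:
    """Classic (unweighted) CMap KS enrichment of a gene set whose members
    sit at 1-based *positions* of an n-gene ranked list."""
    pos = np.sort(positions)
    t = pos.size
    j = np.arange(1, t + 1)
    a = np.max(j / t - pos / n)
    b = np.max(pos / n - (j - 1) / t)
    return float(a) if a > b else float(-b)


def rank_profile(profile: pd.Series) -> pd.Index:
    """Order genes most-upregulated first (descending value, stable)."""
    return profile.sort_values(ascending=False, kind="stable").index


def connectivity_score(sig: Signature, profile: pd.Series) -> float:
    """CMap connectivity of a disease signature with one profile.

    ES_up and ES_down are the unweighted KS statistics of the up and
    down sets against the profile's descending ranking; the score is
    ``(ES_up - ES_down) / 2`` when their signs differ and 0 otherwise.
    Positive = the perturbation mimics the disease signature, negative
    = it reverses it.
    """
    order = rank_profile(profile)
    n = len(order)
    pos = pd.Series(np.arange(1, n + 1), index=order)
    up_pos = pos.reindex(sig.up).dropna().to_numpy()
    down_pos = pos.reindex(sig.down).dropna().to_numpy()
    if up_pos.size == 0 or down_pos.size == 0:
        raise ValueError("no signature gene present in the profile universe")
    es_up = _ks_es(up_pos, n)
    es_down = _ks_es(down_pos, n)
    if np.sign(es_up) == np.sign(es_down):
        return 0.0
    return (es_up - es_down) / 2


def score_profiles(sig: Signature, pset: PerturbationSet) -> pd.Series:
    """Connectivity score of every profile in the set."""
    return pd.Series(
        {pid: connectivity_score(sig, pset.profiles.loc[pid])
         for pid in pset.profiles.index},
        name="score",
    )


def summarize_profiles(scores: pd.Series, metadata: pd.DataFrame) -> pd.DataFrame:
    """Collapse multi-condition profiles to one representative per drug.

    The profile whose score is closest to the drug's median score is
    selected; distance ties are broken toward the more negative
    (more reversing) score, then by profile id.
    """
    meta = metadata.copy()
    if "drug" not in meta.columns:
        raise ValueError("metadata must have a 'drug' column")
    meta = meta.assign(score=scores.reindex(meta.index))
    rows = []
    for drug, grp in meta.groupby("drug", sort=True):
        med = grp["score"].median()
        cand = grp.assign(dist=(grp["score"] - med).abs()) \
            .reset_index(names="profile_id") \
            .sort_values(["dist", "score", "profile_id"], kind="stable")
        sel = cand.iloc[0]
        rows.append((drug, sel["profile_id"], float(sel["score"])))
    return pd.DataFrame(rows, columns=["drug", "profile_id", "score"]) \
        .set_index("drug")


def rank_drugs(summaries: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Rank drugs by reversal score, most reversing (most negative) first.

    Returns a DataFrame indexed by drug with ``score`` and ``rank``
    (1..n, a permutation); score ties break by drug id.
    """
    if isinstance(summaries, pd.DataFrame):
        scores = summaries["score"]
    else:
        scores = summaries
    if len(scores) < 2:
        raise ValueError("need at least 2 drugs to rank")
    out = scores.to_frame("score").sort_index(kind="stable") \
        .sort_values("score", kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _ssgsea_es(in_mask: np.ndarray, weights: np.ndarray) -> float:
    """ssGSEA running-sum ES of the set flagged by *in_mask* over a ranked
    list with per-position *weights*."""
    n = in_mask.size
    m = in_mask.sum()
    w_in = np.where(in_mask, weights, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~in_mask) / (n - m)
    return float(np.sum(p_in - p_out))


def target_enrichment(ranked: pd.DataFrame, drug_targets: pd.DataFrame,
                      n_perm: int = 1000, seed: int = 0,
                      weight_exponent: float = 0.25) -> pd.DataFrame:
    """Test each drug target for enrichment at the top of the ranked list.

    The ranked list is weighted by ``(n - rank + 1) ** weight_exponent``
    (top-ranked, most-reversing drugs weigh most) and each target's drug
    set is scored with the ssGSEA running sum.  Significance comes from
    permuting set membership over the fixed list *n_perm* times:
    ``p = (1 + #{|ES_perm| >= |ES|}) / (n_perm + 1)`` and
    ``NES = ES / mean |ES_perm|``.  Targets with fewer than 2 drugs in
    the list are skipped with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    order = ranked.sort_values("rank").index.to_numpy()
    n = order.size
    weights = (n - np.arange(n)).astype(float) ** weight_exponent
    rng = np.random.default_rng(seed)

    rows = []
    for target, grp in drug_targets.groupby("target", sort=True):
        members = set(grp["drug"]) & set(order)
        m = len(members)
        if m < 2:
            warnings.warn(f"target {target!r} has < 2 drugs in the list; skipped")
            continue
        in_mask = np.isin(order, list(members))
        es = _ssgsea_es(in_mask, weights)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=m, replace=False)] = True
            null[b] = _ssgsea_es(perm, weights)
        p = (1 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1)
        nes = es / np.mean(np.abs(null))
        rows.append((target, es, nes, p, m))
    return pd.DataFrame(rows, columns=["target", "es", "nes", "p", "n_drugs"]) \
        .set_index("target")
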