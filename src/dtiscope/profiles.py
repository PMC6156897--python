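"""Replicate aggregation: from trial sets to credible representative profiles.

A perturbation entity (drug or gene knockdown) is typically measured in
several replicate trials of uneven quality. The aggregation rule keeps at
most two representatives per entity:

* ``S1`` — the centroid of the most internally consistent k-means cluster of
  trials, where consistency is the mean pairwise Pearson correlation within
  the cluster and k is a step function of the replicate count;
* ``S2`` — the grand mean of all trials, retained so that no replicate
  information is discarded outright.

With one or two trials there is nothing to cluster and the grand mean alone
is kept. If S1 and S2 coincide (all trials concordant) the duplicate row is
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "TrialSet",
    "CredibleSet",
    "pearson_matrix",
    "choose_k",
    "intra_class_correlation",
    "select_credible_set",
    "read_trials",
    "write_credible_sets",
    "read_credible_sets",
]


@dataclass
class TrialSet:
    """All replicate Z-score profiles for one perturbation entity."""

    entity_id: str
    trials: np.ndarray  # (n_trials, n_features)
    feature_ids: List[str]

    def __post_init__(self) -> None:
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        if self.trials.shape[0] < 1:
            raise ValueError(f"{self.entity_id!r}: TrialSet needs >= 1 trial")
        if self.trials.shape[1] != len(self.feature_ids):
            raise ValueError(
                f"{self.entity_id!r}: {self.trials.shape[1]} columns but "
                f"{len(self.feature_ids)} feature ids"
            )
        if not np.isfinite(self.trials).all():
            raise ValueError(f"{self.entity_id!r}: non-finite trial values")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]


@dataclass
class CredibleSet:
    """The 1-2 representative profiles of an entity, tagged S1/S2."""

    entity_id: str
    profiles: np.ndarray  # (1 or 2, n_features)
    provenance: List[str]  # per-row tag, subset of {"S1", "S2"}

    def __post_init__(self) -> None:
        self.profiles = np.atleast_2d(np.asarray(self.profiles, dtype=float))
        if self.profiles.shape[0] not in (1, 2):
            raise ValueError(f"{self.entity_id!r}: credible set must have 1 or 2 rows")
        if len(self.provenance) != self.profiles.shape[0]:
            raise ValueError(f"{self.entity_id!r}: provenance/row count mismatch")
        if not np.isfinite(self.profiles).all():
            raise ValueError(f"{self.entity_id!r}: non-finite credible profiles")


def pearson_matrix(trials: TrialSet) -> np.ndarray:
    """Pairwise Pearson correlation matrix of the trials (rows).

    Requires at least two trials, each with nonzero variance. Symmetric with
    unit diagonal; entries clipped to [-1, 1] against round-off.
    """
    X = trials.trials
    if X.shape[0] < 2:
        raise ValueError(f"{trials.entity_id!r}: need >= 2 trials for a correlation matrix")
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"{trials.entity_id!r}: zero-variance trial at row index {bad[0]}"
        )
    R = np.corrcoef(X)
    R = np.clip(R, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return R


def choose_k(n_trials: int) -> Optional[int]:
    """Number of k-means clusters as a step function of the replicate count.

    Returns None for n <= 2 (no clustering), 2 for 2 < n <= 5, 3 for
    5 < n <= 15, and 4 beyond. Boundary counts go to the smaller k so the
    rule is closed and monotone.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    if n_trials <= 2:
        return None
    if n_trials <= 5:
        return 2
    if n_trials <= 15:
        return 3
    return 4


def intra_class_correlation(trials: TrialSet, member_indices: Sequence[int]) -> float:
    """Mean pairwise Pearson correlation among the indexed trials.

    A singleton cluster scores 1.0 by convention: there is nothing to
    disagree with, and the convention avoids a 0/0.
    """
    idx = list(member_indices)
    if len(idx) == 0:
        raise ValueError("empty member index set")
    if len(idx) == 1:
        return 1.0
    sub = TrialSet(trials.entity_id, trials.trials[idx], trials.feature_ids)
    R = pearson_matrix(sub)
    iu = np.triu_indices(len(idx), k=1)
    return float(R[iu].mean())


def _kmeans_labels(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(X)


def select_credible_set(trials: TrialSet, seed: int = 0) -> CredibleSet:
    """Aggregate a TrialSet into its credible set {S1, S2}.

    With <= 2 trials, the grand mean alone is returned. Otherwise the trials
    are partitioned by seeded k-means (Euclidean on the raw Z-score vectors,
    k from :func:`choose_k`, 10 restarts); S1 is the centroid of the cluster
    with maximal intra-class correlation (ties to the lowest cluster label),
    and S2 the grand mean. Rows equal within 1e-9 per element collapse to S1.

    Only clusters with at least two members compete for S1 when any exist:
    a singleton's intra-class correlation is 1.0 by convention, so letting
    singletons into the arg-max would hand S1 to any isolated outlier trial,
    defeating the purpose of the selection.
    """
    grand_mean = trials.trials.mean(axis=0)
    k = choose_k(trials.n_trials)
    if k is None:
        return CredibleSet(trials.entity_id, grand_mean[None, :], ["S1"])

    labels = _kmeans_labels(trials.trials, k, seed)
    candidates = [l for l in sorted(set(labels)) if (labels == l).sum() >= 2]
    if not candidates:
        candidates = sorted(set(labels))
    best_label, best_icc = None, -np.inf
    for lbl in candidates:
        members = np.flatnonzero(labels == lbl)
        icc = intra_class_correlation(trials, members)
        if icc > best_icc:  # strict: ties keep the lowest label
            best_label, best_icc = lbl, icc
    s1 = trials.trials[labels == best_label].mean(axis=0)

    if np.allclose(s1, grand_mean, rtol=0.0, atol=1e-9):
        return CredibleSet(trials.entity_id, s1[None, :], ["S1"])
    return CredibleSet(trials.entity_id, np.vstack([s1, grand_mean]), ["S1", "S2"])


def read_trials(path: str | Path) -> Dict[str, TrialSet]:
    """Read a trial TSV (entity_id column + feature columns) into TrialSets."""
    df = pd.read_csv(path, sep="\t")
    if "entity_id" not in df.columns:
        raise ValueError(f"{path}: missing entity_id column")
    feature_ids = [c for c in df.columns if c != "entity_id"]
    out: Dict[str, TrialSet] = {}
    for eid, grp in df.groupby("entity_id", sort=True):
        out[str(eid)] = TrialSet(
            entity_id=str(eid),
            trials=grp[feature_ids].to_numpy(dtype=float),
            feature_ids=feature_ids,
        )
    return out


def write_credible_sets(
    credible: Dict[str, CredibleSet], feature_ids: Sequence[str], path: str | Path
) -> None:
    """Write credible sets as TSV: entity_id, provenance, then features."""
    rows = []
    for eid in sorted(credible):
        cs = credible[eid]
        for tag, prof in zip(cs.provenance, cs.profiles):
            rows.append([eid, tag, *prof])
    df = pd.DataFrame(rows, columns=["entity_id", "provenance", *feature_ids])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_credible_sets(path: str | Path) -> Dict[str, CredibleSet]:
    """Inverse of :func:`write_credible_sets`."""
    df = pd.read_csv(path, sep="\t")
    feature_ids = [c for c in df.columns if c not in ("entity_id", "provenance")]
    out: Dict[str, CredibleSet] = {}
    for eid, grp in df.groupby("entity_id", sort=True):
        out[str(eid)] = CredibleSet(
            entity_id=str(eid),
            profiles=grp[feature_ids].to_numpy(dtype=float),
            provenance=[str(t) for t in grp["provenance"]],
        )
    return out
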