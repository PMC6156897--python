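"""Sample construction: fusing drug and gene profiles into labelled pairs.

Every (drug, gene) pair falls into one of three classes. A pair recorded in
the gold-standard edge list is *positive*. A pair whose gene is a known
target of some other drug, but whose specific edge is unrecorded, is
*unlabeled* — the prediction universe. A pair whose gene targets nothing at
all is *negative*. Classifier inputs are serial concatenations (drug block
first) of one drug profile and one gene profile, so a panel with n landmark
features yields 2n-dimensional samples.

Class imbalance is handled by keeping every positive sample and drawing
negatives deterministically at uniform intervals over a canonical
(gene-major) ordering of the negative space, at a configurable
positive:negative ratio (default 1:2). Labels live on entity pairs; every
credible-set row combination of a pair inherits its label, and k-fold
splitting assigns whole entity pairs to folds so that no pair leaks across
the train/validation boundary at the row level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from dtiscope.profiles import CredibleSet

__all__ = [
    "EntityMatrix",
    "LabelMatrix",
    "FusedSample",
    "SamplePool",
    "fuse",
    "classify_pair",
    "sample_negatives",
    "build_pool",
    "kfold_split",
    "read_edges",
    "write_pool",
    "read_pool",
]

PairKey = Tuple[str, str]  # (drug_id, gene_id)
RowKey = Tuple[str, int, str, int]  # (drug_id, drug_row, gene_id, gene_row)


@dataclass
class EntityMatrix:
    """Stacked credible-set profiles for one role (drug or gene).

    ``rows[i]`` is one representative profile and ``row_entity[i]`` names the
    entity it belongs to; entities with a two-row credible set contribute two
    consecutive rows.
    """

    role: str  # "drug" | "gene"
    rows: np.ndarray
    row_entity: List[str]
    feature_ids: List[str]

    def __post_init__(self) -> None:
        if self.role not in ("drug", "gene"):
            raise ValueError(f"role must be 'drug' or 'gene', got {self.role!r}")
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if not np.isfinite(self.rows).all():
            raise ValueError("EntityMatrix rows must be finite")
        if self.rows.shape[0] != len(self.row_entity):
            raise ValueError("row/entity count mismatch")

    @classmethod
    def from_credible_sets(
        cls, role: str, credible: Dict[str, CredibleSet], feature_ids: Sequence[str]
    ) -> "EntityMatrix":
        rows, ents = [], []
        for eid in sorted(credible):
            for prof in credible[eid].profiles:
                rows.append(prof)
                ents.append(eid)
        return cls(role, np.asarray(rows), ents, list(feature_ids))

    def entity_rows(self, entity_id: str) -> List[int]:
        return [i for i, e in enumerate(self.row_entity) if e == entity_id]

    @property
    def entity_ids(self) -> List[str]:
        return sorted(set(self.row_entity))


@dataclass
class LabelMatrix:
    """Known-interaction edges plus the derived set of targeted genes."""

    known_edges: Set[PairKey]
    target_gene_ids: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        derived = {g for _, g in self.known_edges}
        if not self.target_gene_ids:
            self.target_gene_ids = derived
        elif not derived <= self.target_gene_ids:
            raise ValueError("every edge's gene must be in target_gene_ids")


@dataclass
class FusedSample:
    """One classifier input: a (drug row, gene row) concatenation with label."""

    drug_id: str
    gene_id: str
    drug_row: int
    gene_row: int
    vector: np.ndarray
    label: str  # "positive" | "negative" | "unlabeled"


@dataclass
class SamplePool:
    positives: List[FusedSample]
    negatives: List[FusedSample]
    unlabeled: List[FusedSample]
    ratio: float
    n_features: int

    def __post_init__(self) -> None:
        keys = [
            (s.drug_row, s.gene_row)
            for part in (self.positives, self.negatives, self.unlabeled)
            for s in part
        ]
        if len(keys) != len(set(keys)):
            raise ValueError("sample partitions overlap on (drug_row, gene_row)")


def fuse(drug_profile: np.ndarray, gene_profile: np.ndarray) -> np.ndarray:
    """Serial fusion: exact concatenation, drug block first, values untouched."""
    drug_profile = np.asarray(drug_profile, dtype=float).ravel()
    gene_profile = np.asarray(gene_profile, dtype=float).ravel()
    if drug_profile.size != gene_profile.size:
        raise ValueError(
            f"profile length mismatch: drug {drug_profile.size}, gene {gene_profile.size}"
        )
    return np.concatenate([drug_profile, gene_profile])


def classify_pair(
    drug_id: str,
    gene_id: str,
    lm: LabelMatrix,
    drug_ids: Optional[Set[str]] = None,
    gene_ids: Optional[Set[str]] = None,
) -> str:
    """Trichotomy of a (drug, gene) pair: positive / unlabeled / negative."""
    if drug_ids is not None and drug_id not in drug_ids:
        raise KeyError(f"unknown drug id {drug_id!r}")
    if gene_ids is not None and gene_id not in gene_ids:
        raise KeyError(f"unknown gene id {gene_id!r}")
    if (drug_id, gene_id) in lm.known_edges:
        return "positive"
    if gene_id in lm.target_gene_ids:
        return "unlabeled"
    return "negative"


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def sample_negatives(
    negative_space: Sequence,
    n_pos: int,
    ratio: float,
    rng: Optional[np.random.Generator] = None,
) -> List:
    """Select round(ratio * n_pos) negatives from the ordered negative space.

    The default is deterministic systematic sampling: indices
    floor(j * |space| / needed) for j = 0..needed-1 over the canonically
    ordered space, so repeated runs select the same keys on any platform.
    Passing ``rng`` switches to seeded uniform sampling without replacement.
    If the space is smaller than the request, all of it is returned.
    """
    if n_pos < 1:
        raise ValueError("n_pos must be >= 1")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if len(negative_space) == 0:
        raise ValueError("negative space is empty but positives exist")
    needed = _round_half_away(ratio * n_pos)
    m = len(negative_space)
    if m <= needed:
        return list(negative_space)
    if rng is not None:
        idx = np.sort(rng.choice(m, size=needed, replace=False))
        return [negative_space[int(i)] for i in idx]
    return [negative_space[(j * m) // needed] for j in range(needed)]


def _canonical_row_space(
    dm: EntityMatrix, gm: EntityMatrix, pair_class: Dict[PairKey, str], cls: str
) -> List[RowKey]:
    """Row-level keys of one class in gene-major canonical order."""
    gene_rows: Dict[str, List[int]] = {}
    for i, g in enumerate(gm.row_entity):
        gene_rows.setdefault(g, []).append(i)
    drug_rows: Dict[str, List[int]] = {}
    for i, d in enumerate(dm.row_entity):
        drug_rows.setdefault(d, []).append(i)
    out: List[RowKey] = []
    for g in sorted(gene_rows):
        for gr in gene_rows[g]:
            for d in sorted(drug_rows):
                if pair_class[(d, g)] != cls:
                    continue
                for dr in drug_rows[d]:
                    out.append((d, dr, g, gr))
    return out


def _fuse_key(dm: EntityMatrix, gm: EntityMatrix, key: RowKey, label: str) -> FusedSample:
    d, dr, g, gr = key
    return FusedSample(
        drug_id=d,
        gene_id=g,
        drug_row=dr,
        gene_row=gr,
        vector=fuse(dm.rows[dr], gm.rows[gr]),
        label=label,
    )


def build_pool(
    dm: EntityMatrix,
    gm: EntityMatrix,
    lm: LabelMatrix,
    ratio: float = 2.0,
    rng: Optional[np.random.Generator] = None,
) -> SamplePool:
    """Assemble the classification sample pool from the entity matrices.

    Positives are every row combination of every known edge; negatives are
    drawn from the negative row space by :func:`sample_negatives` at
    ``ratio`` negatives per positive; unlabeled pairs are all fused and kept
    for prediction.
    """
    if dm.feature_ids != gm.feature_ids:
        raise ValueError("drug and gene matrices disagree on feature ids")
    drug_ids = set(dm.row_entity)
    gene_ids = set(gm.row_entity)
    for d, g in lm.known_edges:
        if d not in drug_ids:
            raise KeyError(f"edge drug {d!r} absent from drug matrix")
        if g not in gene_ids:
            raise KeyError(f"edge gene {g!r} absent from gene matrix")

    pair_class: Dict[PairKey, str] = {
        (d, g): classify_pair(d, g, lm) for d in drug_ids for g in gene_ids
    }
    positives = [
        _fuse_key(dm, gm, k, "positive")
        for k in _canonical_row_space(dm, gm, pair_class, "positive")
    ]
    if not positives:
        raise ValueError("no positive edges: cannot build a training pool")

    neg_space = _canonical_row_space(dm, gm, pair_class, "negative")
    chosen = sample_negatives(neg_space, len(positives), ratio, rng=rng)
    negatives = [_fuse_key(dm, gm, k, "negative") for k in chosen]
    unlabeled = [
        _fuse_key(dm, gm, k, "unlabeled")
        for k in _canonical_row_space(dm, gm, pair_class, "unlabeled")
    ]
    return SamplePool(positives, negatives, unlabeled, ratio, len(dm.feature_ids))


def kfold_split(
    pool: SamplePool, k: int, seed: int = 0
) -> List[Tuple[List[FusedSample], List[FusedSample]]]:
    """Stratified k-fold partition of positives+negatives at entity-pair level.

    Entity pairs (not rows) are shuffled with ``seed`` and dealt round-robin
    to folds within each label class, so all row combinations of a pair land
    in the same fold. Returns k (train, validation) lists; unlabeled samples
    never enter any fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(pool.positives) < k:
        raise ValueError(f"need >= {k} positive samples for {k} folds")
    labelled = pool.positives + pool.negatives
    if k > len(labelled):
        raise ValueError(f"k={k} exceeds the {len(labelled)} labelled samples")

    rng = np.random.default_rng(seed)
    fold_of_pair: Dict[PairKey, int] = {}
    for label in ("positive", "negative"):
        pairs = sorted({(s.drug_id, s.gene_id) for s in labelled if s.label == label})
        order = rng.permutation(len(pairs))
        for pos, idx in enumerate(order):
            fold_of_pair[pairs[idx]] = pos % k
    folds: List[List[FusedSample]] = [[] for _ in range(k)]
    for s in labelled:
        folds[fold_of_pair[(s.drug_id, s.gene_id)]].append(s)
    out = []
    for f in range(k):
        train = [s for g in range(k) if g != f for s in folds[g]]
        out.append((train, folds[f]))
    return out


def read_edges(path: str | Path) -> Set[PairKey]:
    """Read a two-column TSV edge list; whitespace-trimmed, de-duplicated."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs two columns")
    return {
        (str(d).strip(), str(g).strip())
        for d, g in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


def write_pool(pool: SamplePool, directory: str | Path) -> Dict[str, Path]:
    """Persist a pool as labelled.tsv + unlabeled.tsv under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = pool.n_features
    cols = ["drug_id", "gene_id", "drug_row", "gene_row", "label"] + [
        f"f{j}" for j in range(2 * n)
    ]

    def frame(samples: List[FusedSample]) -> pd.DataFrame:
        rows = [
            [s.drug_id, s.gene_id, s.drug_row, s.gene_row, s.label, *s.vector]
            for s in samples
        ]
        return pd.DataFrame(rows, columns=cols)

    paths = {
        "labelled": directory / "labelled.tsv",
        "unlabeled": directory / "unlabeled.tsv",
    }
    frame(pool.positives + pool.negatives).to_csv(
        paths["labelled"], sep="\t", index=False, float_format="%.17g"
    )
    frame(pool.unlabeled).to_csv(
        paths["unlabeled"], sep="\t", index=False, float_format="%.17g"
    )
    return paths


def read_pool(directory: str | Path, ratio: float = 2.0) -> SamplePool:
    """Inverse of :func:`write_pool`."""
    directory = Path(directory)
    parts: Dict[str, List[FusedSample]] = {"positive": [], "negative": [], "unlabeled": []}
    width = None
    for name in ("labelled", "unlabeled"):
        df = pd.read_csv(directory / f"{name}.tsv", sep="\t")
        fcols = [c for c in df.columns if c.startswith("f")]
        width = len(fcols) // 2
        for _, row in df.iterrows():
            parts[row["label"]].append(
                FusedSample(
                    drug_id=str(row["drug_id"]),
                    gene_id=str(row["gene_id"]),
                    drug_row=int(row["drug_row"]),
                    gene_row=int(row["gene_row"]),
                    vector=row[fcols].to_numpy(dtype=float),
                    label=str(row["label"]),
                )
            )
    return SamplePool(
        parts["positive"], parts["negative"], parts["unlabeled"], ratio, width or 0
    )
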