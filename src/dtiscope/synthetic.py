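"""Synthetic L1000-like perturbation panels with planted drug-target structure.

The generator emulates the statistical shape of Level-4 (Z-score) landmark-gene
panels: each perturbation entity (a drug or a gene knockdown) is measured in a
variable number of replicate trials that correlate within the entity, with a
configurable fraction of mismatched outlier trials.

The planted interaction mechanism: every gene ``g`` carries a latent unit
signature ``s_g`` over the landmark features. Knocking ``g`` down produces
trials centred on ``-signal_strength * s_g`` (loss of function inverts the
signature); a drug centred on the summed signatures of its target genes. A
drug and its true target therefore share (anti-)correlated structure in the
fused sample, which is exactly the signal the classifier must learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Tuple

import numpy as np
import pandas as pd

from dtiscope.profiles import TrialSet

__all__ = ["PanelConfig", "SyntheticPanel", "simulate_panel", "write_panel"]


@dataclass(frozen=True)
class PanelConfig:
    """Configuration for :func:`simulate_panel`.

    Parameters
    ----------
    n_landmark : int
        Number of landmark features per profile (the real assay measures 978).
    n_genes, n_drugs : int
        Number of knockdown entities and drug entities.
    targets_per_drug : (int, int)
        Inclusive range for the number of true target genes planted per drug.
    trials_per_entity : (int, int)
        Inclusive range of replicate trial counts, drawn uniformly per entity.
        The default 1-25 exercises every k-selection branch downstream.
    signal_strength : float
        Scale of the planted signature in entity means; 0 removes all signal.
    trial_noise_sd : float
        Standard deviation of i.i.d. Gaussian trial noise.
    outlier_fraction : float
        Probability that a trial is a mismatch: its planted signature is
        replaced by an unrelated random direction of the same scale (zero
        mean over outliers, uncorrelated with the entity), the way a swapped
        or failed well still yields a full-amplitude Z-score profile.
    druggable_fraction : float
        Fraction of genes eligible to be drug targets. Real interaction
        gold standards concentrate on a small druggable subset of the
        profiled genes (a few hundred targets among thousands of knockdowns,
        with several drugs sharing each target), and that multiplicity is
        what lets a classifier generalize across drug-gene pairs; 1.0 makes
        every gene eligible.
    seed : int
        Seed for all randomness; identical config implies identical panel.
    """

    n_landmark: int = 978
    n_genes: int = 20
    n_drugs: int = 10
    targets_per_drug: Tuple[int, int] = (1, 3)
    trials_per_entity: Tuple[int, int] = (1, 25)
    signal_strength: float = 2.0
    trial_noise_sd: float = 0.5
    outlier_fraction: float = 0.0
    druggable_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_landmark < 2:
            raise ValueError(f"n_landmark must be >= 2, got {self.n_landmark}")
        if self.n_drugs < 1 or self.n_genes < 1:
            raise ValueError("n_drugs and n_genes must be >= 1")
        for name in ("targets_per_drug", "trials_per_entity"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} exceeds max {hi}")
            if lo < 1:
                raise ValueError(f"{name}: min must be >= 1, got {lo}")
        if self.targets_per_drug[1] > self.n_genes:
            raise ValueError(
                f"targets_per_drug max {self.targets_per_drug[1]} exceeds "
                f"n_genes {self.n_genes}"
            )
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be nonnegative")
        if self.trial_noise_sd <= 0:
            raise ValueError("trial_noise_sd must be positive")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must lie in [0, 1)")
        if not 0 < self.druggable_fraction <= 1:
            raise ValueError("druggable_fraction must lie in (0, 1]")

    @property
    def n_druggable(self) -> int:
        """Size of the druggable subset; never below the max targets per drug."""
        return max(self.targets_per_drug[1], round(self.druggable_fraction * self.n_genes))


@dataclass
class SyntheticPanel:
    """A simulated perturbation panel with known ground truth.

    Attributes
    ----------
    drug_trials, gene_trials : dict of entity id -> TrialSet
    truth_edges : frozenset of (drug_id, gene_id)
        The planted interactions.
    gene_signatures : dict of gene id -> latent unit signature (for tests).
    feature_ids : list of landmark feature names.
    """

    drug_trials: Dict[str, TrialSet]
    gene_trials: Dict[str, TrialSet]
    truth_edges: FrozenSet[Tuple[str, str]]
    gene_signatures: Dict[str, np.ndarray] = field(default_factory=dict)
    feature_ids: List[str] = field(default_factory=list)
    signal_strength: float = 0.0

    def __post_init__(self) -> None:
        for d, g in self.truth_edges:
            if d not in self.drug_trials:
                raise ValueError(f"truth edge references unknown drug {d!r}")
            if g not in self.gene_trials:
                raise ValueError(f"truth edge references unknown gene {g!r}")
        for ts in list(self.drug_trials.values()) + list(self.gene_trials.values()):
            if ts.trials.shape[0] < 1:
                raise ValueError(f"entity {ts.entity_id!r} has no trials")

    def entity_mean(self, kind: str, entity_id: str) -> np.ndarray:
        """Noise-free mean profile the entity's trials were drawn around."""
        sig = np.zeros(len(self.feature_ids))
        if kind == "gene":
            return -self.signal_strength * self.gene_signatures[entity_id]
        for d, g in self.truth_edges:
            if d == entity_id:
                sig = sig + self.gene_signatures[g]
        return self.signal_strength * sig


def _simulate_trials(
    rng: np.random.Generator,
    mean: np.ndarray,
    n_trials: int,
    noise_sd: float,
    outlier_fraction: float,
    outlier_scale: float = 0.0,
) -> np.ndarray:
    noise = rng.normal(0.0, noise_sd, size=(n_trials, mean.size))
    trials = mean[None, :] + noise
    if outlier_fraction > 0:
        is_outlier = rng.random(n_trials) < outlier_fraction
        for i in np.flatnonzero(is_outlier):
            if outlier_scale > 0:
                u = rng.standard_normal(mean.size)
                u /= np.linalg.norm(u)
            else:
                u = np.zeros(mean.size)
            trials[i] = outlier_scale * u + noise[i]
    return trials


def simulate_panel(config: PanelConfig) -> SyntheticPanel:
    """Simulate a perturbation panel under ``config``.

    Each gene gets an i.i.d. standard-normal latent signature, unit-normalized.
    A knockdown entity's mean is the negated signature scaled by
    ``signal_strength``; a drug's mean is the scaled sum of its planted
    targets' signatures. Trials are the mean plus Gaussian noise, except
    outlier trials, whose planted signature is swapped for an unrelated
    random direction of the same scale. Fully deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(max(config.n_genes, config.n_drugs)))
    gene_ids = [f"G{i:0{width}d}" for i in range(config.n_genes)]
    drug_ids = [f"D{i:0{width}d}" for i in range(config.n_drugs)]
    feature_ids = [f"L{j:04d}" for j in range(config.n_landmark)]

    signatures: Dict[str, np.ndarray] = {}
    for g in gene_ids:
        v = rng.standard_normal(config.n_landmark)
        signatures[g] = v / np.linalg.norm(v)

    lo_t, hi_t = config.targets_per_drug
    druggable = list(rng.choice(gene_ids, size=config.n_druggable, replace=False))
    truth: set[Tuple[str, str]] = set()
    drug_targets: Dict[str, List[str]] = {}
    for d in drug_ids:
        k = int(rng.integers(lo_t, hi_t + 1))
        targets = list(rng.choice(druggable, size=k, replace=False))
        drug_targets[d] = targets
        truth.update((d, g) for g in targets)

    lo_n, hi_n = config.trials_per_entity
    gene_trials: Dict[str, TrialSet] = {}
    for g in gene_ids:
        n = int(rng.integers(lo_n, hi_n + 1))
        mean = -config.signal_strength * signatures[g]
        mat = _simulate_trials(
            rng, mean, n, config.trial_noise_sd, config.outlier_fraction,
            outlier_scale=config.signal_strength,
        )
        gene_trials[g] = TrialSet(entity_id=g, trials=mat, feature_ids=feature_ids)

    drug_trials: Dict[str, TrialSet] = {}
    for d in drug_ids:
        n = int(rng.integers(lo_n, hi_n + 1))
        mean = config.signal_strength * np.sum(
            [signatures[g] for g in drug_targets[d]], axis=0
        )
        mat = _simulate_trials(
            rng, mean, n, config.trial_noise_sd, config.outlier_fraction,
            outlier_scale=config.signal_strength,
        )
        drug_trials[d] = TrialSet(entity_id=d, trials=mat, feature_ids=feature_ids)

    return SyntheticPanel(
        drug_trials=drug_trials,
        gene_trials=gene_trials,
        truth_edges=frozenset(truth),
        gene_signatures=signatures,
        feature_ids=feature_ids,
        signal_strength=config.signal_strength,
    )


def _trials_frame(trial_sets: Dict[str, TrialSet], feature_ids: List[str]) -> pd.DataFrame:
    rows = []
    index = []
    for eid in sorted(trial_sets):
        ts = trial_sets[eid]
        for row in ts.trials:
            rows.append(row)
            index.append(eid)
    df = pd.DataFrame(np.asarray(rows), columns=feature_ids)
    df.insert(0, "entity_id", index)
    return df


def write_panel(panel: SyntheticPanel, directory: str | Path) -> Dict[str, Path]:
    """Write a panel as three TSV files into ``directory``.

    ``drug_trials.tsv`` / ``gene_trials.tsv``: one row per trial, first column
    ``entity_id``, remaining columns the landmark features. ``truth_edges.tsv``:
    two-column edge list. Round-trips losslessly through
    :func:`dtiscope.profiles.read_trials` and :func:`dtiscope.dataset.read_edges`.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "drug_trials": directory / "drug_trials.tsv",
            "gene_trials": directory / "gene_trials.tsv",
            "truth_edges": directory / "truth_edges.tsv",
        }
        _trials_frame(panel.drug_trials, panel.feature_ids).to_csv(
            paths["drug_trials"], sep="\t", index=False, float_format="%.17g"
        )
        _trials_frame(panel.gene_trials, panel.feature_ids).to_csv(
            paths["gene_trials"], sep="\t", index=False, float_format="%.17g"
        )
        edges = pd.DataFrame(sorted(panel.truth_edges), columns=["drug_id", "gene_id"])
        edges.to_csv(paths["truth_edges"], sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"failed writing panel under {directory}: {exc}") from exc
    return paths
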