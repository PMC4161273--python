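"""Cross-validated model search and knowledge-source integration.

For one knowledge matrix, `run_cv` evolves a classifier on each of five
training folds and scores the fold's best-ever solution on the held-out
fifth (balanced accuracy and ROC AUC).  The run's *best model* is the model
identified most often across the five folds, where two models count as the
same if they use the same set of input features — weights and topology are
free to differ.  Ties fall through a fixed ladder: most folds, then highest
mean held-out balanced accuracy, then fewest features, then lexicographic
feature names.

`integrate` pools the best-model features of several per-source runs into
one combined matrix and reruns the cross-validated search on it, looking
for interactions that cross knowledge sources.

Folds are stratified by default: with heavy class imbalance an unstratified
split can produce folds with no positive samples at all, leaving balanced
accuracy undefined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .evolution import (
    EvolutionConfig,
    FitnessEvaluator,
    FitnessRecord,
    run_evolution,
)
from .io import PhenotypeVector, SerializedModel, serialize_model, write_model
from .model import NetworkModel
from .transform import KnowledgeMatrix, concat_features

__all__ = [
    "FoldSplit",
    "FoldResult",
    "CVRunResult",
    "IntegrationResult",
    "make_folds",
    "roc_auc",
    "run_cv",
    "select_best_model",
    "integrate",
    "report",
]


@dataclass
class FoldSplit:
    """Assignment of every sample to exactly one of k folds."""

    fold_assignments: dict[str, int]
    n_folds: int

    def __post_init__(self) -> None:
        folds = set(self.fold_assignments.values())
        if folds - set(range(self.n_folds)):
            raise ValueError("fold indices out of range")

    def test_indices(self, sample_ids: Sequence[str], fold: int) -> list[int]:
        return [
            i for i, s in enumerate(sample_ids) if self.fold_assignments[s] == fold
        ]

    def train_indices(self, sample_ids: Sequence[str], fold: int) -> list[int]:
        return [
            i for i, s in enumerate(sample_ids) if self.fold_assignments[s] != fold
        ]


def make_folds(
    labels: PhenotypeVector,
    k: int = 5,
    stratified: bool = True,
    seed: int = 0,
) -> FoldSplit:
    """Split samples into k near-equal folds, deterministic from *seed*.

    Stratification keeps each fold's positive count within one of the
    ideal; it requires at least k members per class.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = labels.labels
    if stratified:
        n_pos = int(y.sum())
        if min(n_pos, len(y) - n_pos) < k:
            raise ValueError(
                f"stratified {k}-fold split needs >= {k} members per class"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignments: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros_like(y), y)):
        for i in test_idx:
            assignments[labels.sample_ids[int(i)]] = fold
    return FoldSplit(assignments, k)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann–Whitney AUC (ties count one half); both classes required."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class FoldResult:
    fold: int
    record: FitnessRecord
    test_balanced_accuracy: float
    test_auc: float

    @property
    def features(self) -> frozenset[str]:
        assert self.record.model is not None
        return self.record.model.features_used


@dataclass
class CVRunResult:
    source_name: str
    per_fold: list[FoldResult]
    best_model: NetworkModel
    best_model_support: int
    best_model_fold: int

    @property
    def best_test_balanced_accuracy(self) -> float:
        return max(f.test_balanced_accuracy for f in self.per_fold)

    @property
    def mean_test_balanced_accuracy(self) -> float:
        return float(np.mean([f.test_balanced_accuracy for f in self.per_fold]))

    @property
    def sd_test_balanced_accuracy(self) -> float:
        return float(np.std([f.test_balanced_accuracy for f in self.per_fold], ddof=1))

    @property
    def best_test_auc(self) -> float:
        """AUC of the fold with the best held-out balanced accuracy."""
        best = max(self.per_fold, key=lambda f: f.test_balanced_accuracy)
        return best.test_auc

    @property
    def best_model_features(self) -> frozenset[str]:
        return self.best_model.features_used

    def feature_support(self, feature_id: str) -> int:
        """Number of folds whose best model uses *feature_id*.

        This is the per-variable consistency ("4/5"-style) companion to
        ``best_model_support``, which counts whole identical feature sets.
        """
        return sum(1 for fr in self.per_fold if feature_id in fr.features)


def select_best_model(per_fold: Sequence[FoldResult]) -> tuple[int, int]:
    """Pick the run's best model from the per-fold winners.

    Model identity is the set of input feature names.  Returns (index of
    the chosen fold's result, support = number of folds identifying that
    feature set).  Tie ladder: support, mean held-out balanced accuracy of
    the folds sharing the set, fewer features, lexicographic feature names.
    """
    groups: dict[frozenset[str], list[FoldResult]] = {}
    for fr in per_fold:
        groups.setdefault(fr.features, []).append(fr)

    def rank(item: tuple[frozenset[str], list[FoldResult]]):
        feats, members = item
        mean_ba = float(np.mean([m.test_balanced_accuracy for m in members]))
        return (-len(members), -mean_ba, len(feats), tuple(sorted(feats)))

    feats, members = min(groups.items(), key=rank)
    # within the winning group, represent it by its best held-out fold
    rep = max(members, key=lambda m: (m.test_balanced_accuracy, -m.fold))
    return per_fold.index(rep), len(members)


def run_cv(
    matrix: KnowledgeMatrix,
    labels: PhenotypeVector,
    config: EvolutionConfig,
    split: FoldSplit,
    usage_hook: Optional[Callable[[int, str, list[str]], None]] = None,
    log: Optional[list[dict]] = None,
) -> CVRunResult:
    """Five-fold (or k-fold) cross-validated evolutionary model search.

    Each fold evolves on the other k-1 folds with a fold-specific seed
    derived from ``config.seed``, then the fold's best solution is scored
    on the held-out samples.  ``usage_hook(fold, role, sample_ids)`` is
    called with every train/test partition, for instrumentation.
    """
    if matrix.sample_ids != labels.sample_ids:
        raise ValueError("matrix and labels are not sample-aligned")
    per_fold: list[FoldResult] = []
    for fold in range(split.n_folds):
        train_idx = split.train_indices(matrix.sample_ids, fold)
        test_idx = split.test_indices(matrix.sample_ids, fold)
        train_m = matrix.subset_samples(train_idx)
        test_m = matrix.subset_samples(test_idx)
        train_y = labels.subset(train_idx)
        test_y = labels.subset(test_idx)
        if not (train_y.both_classes_present() and test_y.both_classes_present()):
            raise ValueError(
                f"fold {fold} lacks a class in train or test; "
                "use a stratified split"
            )
        if usage_hook is not None:
            usage_hook(fold, "train", list(train_m.sample_ids))
            usage_hook(fold, "test", list(test_m.sample_ids))
        fold_seed = int(
            np.random.SeedSequence([config.seed, fold]).generate_state(1)[0]
            % 2**31
        )
        fold_log: Optional[list[dict]] = [] if log is not None else None
        best = run_evolution(
            train_m, train_y, replace(config, seed=fold_seed), log=fold_log
        )
        if log is not None and fold_log is not None:
            for row in fold_log:
                log.append({"fold": fold, **row})
        assert best.model is not None  # generation 0 is all-functional
        test_eval = FitnessEvaluator(test_m, test_y)
        test_ba = test_eval.fitness_of_model(best.model)
        from .model import evaluate_scores

        scores = evaluate_scores(best.model, test_m.columns())
        test_auc = roc_auc(scores, test_y.labels)
        per_fold.append(FoldResult(fold, best, test_ba, test_auc))
    rep_idx, support = select_best_model(per_fold)
    rep = per_fold[rep_idx]
    return CVRunResult(
        source_name=matrix.source_name,
        per_fold=per_fold,
        best_model=rep.record.model,
        best_model_support=support,
        best_model_fold=rep.fold,
    )


@dataclass
class IntegrationResult:
    pooled_features: list[str]
    final: CVRunResult
    per_source: dict[str, frozenset[str]] = field(default_factory=dict)


def integrate(
    sources: Sequence[CVRunResult],
    matrices: Sequence[KnowledgeMatrix],
    labels: PhenotypeVector,
    config: EvolutionConfig,
    split: FoldSplit,
    log: Optional[list[dict]] = None,
) -> IntegrationResult:
    """Rerun the CV search on the pooled best-model features of each source.

    Feature columns keep their source-prefixed names, so the final model is
    directly readable as a cross-source interaction.
    """
    if len(sources) != len(matrices):
        raise ValueError("sources and matrices must align")
    pooled: list[str] = []
    per_source: dict[str, frozenset[str]] = {}
    sub_matrices: list[KnowledgeMatrix] = []
    for res, mat in zip(sources, matrices):
        feats = sorted(res.best_model_features)
        per_source[res.source_name] = frozenset(feats)
        feats = [f for f in feats if f not in pooled]  # dedup across pool
        if feats:
            pooled.extend(feats)
            sub_matrices.append(mat.select_features(feats))
    if not pooled:
        raise ValueError("no features pooled from the source best models")
    combined = concat_features(sub_matrices, source_name="INTEGRATION")
    final = run_cv(combined, labels, config, split, log=log)
    return IntegrationResult(pooled, final, per_source)


def report(
    results: Sequence[CVRunResult | IntegrationResult],
    out_dir: str | Path,
) -> Path:
    """Write a performance table plus serialized best models.

    The table has one row per result — data type, best held-out balanced
    accuracy and that fold's AUC, and mean ± sd across folds — with values
    formatted to four decimals.  Each best model is written next to it with
    a JSON provenance sidecar.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = out_dir / "performance.tsv"
    with open(table, "w", encoding="utf-8") as fh:
        fh.write(
            "data_type\tbalanced_accuracy\tAUC\t"
            "mean_test_balanced_accuracy\tsd_test_balanced_accuracy\t"
            "best_model_support\n"
        )
        for res in results:
            cv = res.final if isinstance(res, IntegrationResult) else res
            name = cv.source_name or "unnamed"
            fh.write(
                f"{name}\t{cv.best_test_balanced_accuracy:.4f}\t"
                f"{cv.best_test_auc:.4f}\t{cv.mean_test_balanced_accuracy:.4f}\t"
                f"{cv.sd_test_balanced_accuracy:.4f}\t{cv.best_model_support}\n"
            )
            provenance = {
                "source": name,
                "best_model_fold": cv.best_model_fold,
                "best_model_support": cv.best_model_support,
                "per_fold": [
                    {
                        "fold": fr.fold,
                        "train_fitness": fr.record.fitness,
                        "test_balanced_accuracy": fr.test_balanced_accuracy,
                        "test_auc": fr.test_auc,
                        "features": sorted(fr.features),
                    }
                    for fr in cv.per_fold
                ],
            }
            write_model(
                serialize_model(cv.best_model, provenance),
                out_dir / f"best_model_{name}.txt",
            )
    return table
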