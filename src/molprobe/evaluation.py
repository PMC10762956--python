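"""Robustness statistics and experiment orchestration.

Given a fitted backend and a labeled molecule set, this module computes:

* hold-out accuracy (erroneous completions count as incorrect);
* the correctly-predicted filter - perturbation analyses are restricted
  to molecules whose complete canonical SMILES already yields the true
  label, so disagreement measures sensitivity, not baseline error;
* per-molecule agreement rates under ablation, and their breakdown matrix
  binned by number of tests (columns) and agreement decile (rows, with
  dedicated exact-0% and exact-100% rows);
* per-molecule consistency levels across non-canonical renderings, and
  counts of erroneous (non-label) completions;
* learning-curve and training-augmentation experiments.

All randomized experiments are seeded per arm from a root seed and report
the seed used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ablation import AblationVariant
from .backends import ERRONEOUS, BackendContract, PredictionRecord, parse_completion
from .errors import EnumerationExhaustedError
from .labeling import ClassificationTask, assign_class, learning_curve_subsets, split_random
from .smiles import PromptCompletionPair, enumerate_noncanonical
from .synthetic import MoleculeRecord, child_seed

logger = logging.getLogger(__name__)


def accuracy(predictions: Sequence, truths: Sequence[int]) -> float:
    """Fraction of predictions matching the true labels.

    ``predictions`` may be :class:`PredictionRecord` objects or raw parsed
    labels; ERRONEOUS never matches, so it counts as incorrect.
    """
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must have equal length")
    if not predictions:
        raise ValueError("empty prediction list")
    labels = [
        p.parsed_label if isinstance(p, PredictionRecord) else p for p in predictions
    ]
    return sum(1 for l, t in zip(labels, truths) if l == t) / len(labels)


def build_prompt_pairs(
    records: Sequence[MoleculeRecord],
    task: ClassificationTask,
    n_noncanonical: int = 0,
    seed: int = 0,
) -> list[PromptCompletionPair]:
    """Prompt-completion pairs for a molecule set.

    With ``n_noncanonical > 0`` each molecule additionally contributes
    that many non-canonical renderings (same completion), the augmentation
    used to make a text classifier robust to representation variety.
    Molecules too small to enumerate keep only their canonical pair.
    """
    pairs = []
    for i, r in enumerate(records):
        label = str(assign_class(r.properties[task.property_name], task))
        pairs.append(PromptCompletionPair(r.smiles, label))
        if n_noncanonical > 0:
            try:
                variants = enumerate_noncanonical(
                    r.smiles, n_noncanonical, child_seed(seed, i)
                )
            except EnumerationExhaustedError:
                continue
            pairs.extend(PromptCompletionPair(v, label) for v in variants)
    return pairs


def correctly_predicted_filter(
    records: Sequence[MoleculeRecord],
    backend: BackendContract,
    task: ClassificationTask,
) -> list[MoleculeRecord]:
    """Molecules whose complete canonical SMILES yields the true label."""
    kept = []
    for r in records:
        truth = assign_class(r.properties[task.property_name], task)
        if parse_completion(backend.complete(r.smiles), task.n_classes) == truth:
            kept.append(r)
    logger.info(
        "correctly-predicted filter kept %d of %d molecules", len(kept), len(records)
    )
    return kept


@dataclass(frozen=True)
class AgreementResult:
    """Per-molecule ablation robustness: fraction of variants whose
    prediction matches the complete-SMILES prediction."""

    molecule_id: str
    n_tests: int
    n_agree: int

    def __post_init__(self):
        if not 0 <= self.n_agree <= self.n_tests or self.n_tests < 1:
            raise ValueError("need 0 <= n_agree <= n_tests and n_tests >= 1")

    @property
    def agreement_rate(self) -> float:
        return self.n_agree / self.n_tests


def agreement_analysis(
    backend: BackendContract,
    molecule: MoleculeRecord,
    variants: Sequence[AblationVariant],
    task: ClassificationTask,
) -> AgreementResult | None:
    """Agreement between complete and perturbed predictions.

    Returns None when there are no variants (the molecule is simply
    excluded from the breakdown). An erroneous (non-label) completion for
    a variant counts as disagreement: it is not the same prediction.
    """
    if not variants:
        return None
    reference = parse_completion(backend.complete(molecule.smiles), task.n_classes)
    n_agree = sum(
        1
        for v in variants
        if parse_completion(backend.complete(v.variant_text), task.n_classes)
        == reference
    )
    return AgreementResult(molecule.id, len(variants), n_agree)


# ---------------------------------------------------------------------------
# Breakdown matrix


def _rate_row_label(rate: float) -> str:
    if rate == 0.0:
        return "0%"
    if rate == 1.0:
        return "100%"
    decile = int(np.ceil(rate * 10))  # 1..10
    if decile >= 10:
        return "(90%, 100%)"
    return f"({(decile - 1) * 10}%, {decile * 10}%]"


def _rate_row_labels() -> list[str]:
    rows = ["0%"]
    rows += [f"({i * 10}%, {(i + 1) * 10}%]" for i in range(9)]
    rows += ["(90%, 100%)", "100%"]
    return rows


@dataclass(frozen=True)
class BreakdownMatrix:
    """Molecule counts binned by test count (columns) and agreement rate
    (rows). Interior rate intervals are left-open/right-closed deciles,
    with dedicated rows for exactly 0% and exactly 100%; the last test
    -count column is open-ended."""

    table: pd.DataFrame = field(compare=False)

    @property
    def total(self) -> int:
        return int(self.table.to_numpy().sum())

    def cell(self, n_tests_bin: str, rate_bin: str) -> int:
        return int(self.table.loc[rate_bin, n_tests_bin])


def breakdown_matrix(
    results: Sequence[AgreementResult],
    col_width: int = 10,
    n_cols: int = 7,
) -> BreakdownMatrix:
    """Bin agreement results into the breakdown matrix.

    Columns are ``1-10``, ``11-20``, ... with the last column open-ended
    (``>60`` by default); each molecule lands in exactly one cell, so the
    cells sum to the number of results.
    """
    col_labels = [
        f"{i * col_width + 1}-{(i + 1) * col_width}" for i in range(n_cols - 1)
    ] + [f">{(n_cols - 1) * col_width}"]
    row_labels = _rate_row_labels()
    table = pd.DataFrame(
        0, index=row_labels, columns=col_labels, dtype=int
    )
    for r in results:
        col = col_labels[min((r.n_tests - 1) // col_width, n_cols - 1)]
        row = _rate_row_label(r.agreement_rate)
        table.loc[row, col] += 1
    return BreakdownMatrix(table)


# ---------------------------------------------------------------------------
# Non-canonical consistency


@dataclass(frozen=True)
class ConsistencyResult:
    """Per-molecule representation robustness.

    ``level`` counts non-canonical renderings predicted like the canonical
    one; ``n_erroneous`` counts non-label completions among them. The
    remainder (``n_mismatch``) received a different but valid label, so
    level + n_mismatch + n_erroneous = n_tests.
    """

    molecule_id: str
    level: int
    n_erroneous: int
    n_tests: int = 10

    def __post_init__(self):
        if self.level + self.n_erroneous > self.n_tests:
            raise ValueError("level + n_erroneous cannot exceed n_tests")

    @property
    def n_mismatch(self) -> int:
        return self.n_tests - self.level - self.n_erroneous


def consistency_analysis(
    backend: BackendContract,
    molecule: MoleculeRecord,
    task: ClassificationTask,
    n_noncanonical: int = 10,
    seed: int = 0,
    variants: Sequence[str] | None = None,
) -> ConsistencyResult:
    """Prediction consistency across non-canonical renderings.

    ``variants`` may be supplied to evaluate several backends on the same
    renderings; otherwise they are enumerated here (propagating
    :class:`EnumerationExhaustedError` for molecules that admit too few).
    """
    if variants is None:
        variants = enumerate_noncanonical(molecule.smiles, n_noncanonical, seed)
    reference = parse_completion(backend.complete(molecule.smiles), task.n_classes)
    level = 0
    n_err = 0
    for v in variants:
        parsed = parse_completion(backend.complete(v), task.n_classes)
        if parsed is ERRONEOUS:
            n_err += 1
        elif parsed == reference and reference is not ERRONEOUS:
            level += 1
    return ConsistencyResult(molecule.id, level, n_err, len(variants))


def run_consistency_analysis(
    backend: BackendContract,
    records: Sequence[MoleculeRecord],
    task: ClassificationTask,
    n_noncanonical: int = 10,
    seed: int = 0,
) -> tuple[list[ConsistencyResult], int]:
    """Consistency for a molecule set; enumeration-exhausted molecules are
    excluded and their count returned (and logged)."""
    results, skipped = [], 0
    for i, r in enumerate(records):
        try:
            results.append(
                consistency_analysis(
                    backend, r, task, n_noncanonical, child_seed(seed, i)
                )
            )
        except EnumerationExhaustedError:
            skipped += 1
    if skipped:
        logger.info("consistency analysis skipped %d molecules", skipped)
    return results, skipped


def consistency_histograms(
    results: Sequence[ConsistencyResult], n_tests: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """(level histogram, erroneous-count histogram), each of length
    n_tests + 1 and summing to the number of analyzed molecules."""
    levels = np.bincount([r.level for r in results], minlength=n_tests + 1)
    errs = np.bincount([r.n_erroneous for r in results], minlength=n_tests + 1)
    return levels, errs


# ---------------------------------------------------------------------------
# Experiments


def run_learning_curve(
    records: Sequence[MoleculeRecord],
    task: ClassificationTask,
    backend_factory: Callable[[int], BackendContract],
    fractions: Sequence[float],
    seeds: Sequence[int],
) -> pd.DataFrame:
    """Hold-out accuracy vs training fraction, averaged over seeds.

    For each seed, nested subsets of a shuffled 80% pool share one 20%
    hold-out; one backend is fitted per (fraction, seed). Returns a table
    with columns fraction, mean_accuracy, sd_accuracy, n_train.
    """
    acc: dict[float, list[float]] = {f: [] for f in fractions}
    n_train: dict[float, int] = {}
    for seed in seeds:
        specs = learning_curve_subsets(records, fractions, seed=seed)
        for f, spec in zip(fractions, specs):
            train, test = spec.select(records)
            backend = backend_factory(seed).fit(build_prompt_pairs(train, task))
            truths = [
                assign_class(r.properties[task.property_name], task) for r in test
            ]
            preds = [
                parse_completion(backend.complete(r.smiles), task.n_classes)
                for r in test
            ]
            acc[f].append(accuracy(preds, truths))
            n_train[f] = len(train)
    return pd.DataFrame(
        {
            "fraction": list(fractions),
            "n_train": [n_train[f] for f in fractions],
            "mean_accuracy": [float(np.mean(acc[f])) for f in fractions],
            "sd_accuracy": [float(np.std(acc[f], ddof=1)) if len(seeds) > 1 else 0.0
                            for f in fractions],
        }
    )


@dataclass(frozen=True)
class AugmentationReport:
    """Paired consistency statistics for canonical-only vs augmented
    training, evaluated on identical non-canonical test renderings."""

    canonical_results: tuple[ConsistencyResult, ...]
    augmented_results: tuple[ConsistencyResult, ...]
    n_skipped: int
    seed: int

    def level_histograms(self, n_tests: int = 10) -> tuple[np.ndarray, np.ndarray]:
        return (
            consistency_histograms(self.canonical_results, n_tests)[0],
            consistency_histograms(self.augmented_results, n_tests)[0],
        )

    def erroneous_histograms(self, n_tests: int = 10) -> tuple[np.ndarray, np.ndarray]:
        return (
            consistency_histograms(self.canonical_results, n_tests)[1],
            consistency_histograms(self.augmented_results, n_tests)[1],
        )

    @property
    def mean_level_canonical(self) -> float:
        return float(np.mean([r.level for r in self.canonical_results]))

    @property
    def mean_level_augmented(self) -> float:
        return float(np.mean([r.level for r in self.augmented_results]))


def run_augmentation_experiment(
    records: Sequence[MoleculeRecord],
    task: ClassificationTask,
    backend_factory: Callable[[int], BackendContract],
    n_train_aug: int = 5,
    n_test_noncanon: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> AugmentationReport:
    """Canonical-only vs non-canonical-augmented training, compared on the
    same test renderings.

    Two backends are fitted: one on canonical prompts only, one on
    canonical prompts plus ``n_train_aug`` non-canonical renderings per
    training molecule. Both are evaluated on each test molecule's
    canonical prompt plus the same ``n_test_noncanon`` renderings, so any
    difference in consistency is attributable to training alone.
    """
    spec = split_random(records, test_fraction, seed=child_seed(seed, 0))
    train, test = spec.select(records)

    pairs_canonical = build_prompt_pairs(train, task)
    pairs_augmented = build_prompt_pairs(
        train, task, n_noncanonical=n_train_aug, seed=child_seed(seed, 1)
    )
    backend_canonical = backend_factory(seed).fit(pairs_canonical)
    backend_augmented = backend_factory(seed).fit(pairs_augmented)

    canonical_results, augmented_results = [], []
    skipped = 0
    for i, r in enumerate(test):
        try:
            variants = enumerate_noncanonical(
                r.smiles, n_test_noncanon, child_seed(seed, 2 + i)
            )
        except EnumerationExhaustedError:
            skipped += 1
            continue
        canonical_results.append(
            consistency_analysis(backend_canonical, r, task, variants=variants)
        )
        augmented_results.append(
            consistency_analysis(backend_augmented, r, task, variants=variants)
        )
    if skipped:
        logger.info("augmentation experiment skipped %d molecules", skipped)
    return AugmentationReport(
        tuple(canonical_results), tuple(augmented_results), skipped, seed
    )
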