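"""Class labeling and dataset splitting.

Continuous properties are discretized with equal-range thresholds: the
[min, max] range of the labeling population is segmented into k equal-width
intervals, giving class labels 0..k-1 from low to high. A value lying
exactly on a boundary goes to the *higher* class; this tie rule is a
convention of this package (any consistent rule would do) and is asserted
by the tests.

Four split types are provided: a random train/test fraction, nested
learning-curve subsets sharing one hold-out, stratified k-fold, and the
fragment-family holdout in which every molecule containing a named
conjugated fragment is removed from training.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateRangeError, StratificationError
from .groups import Fragment, load_fragment_library
from .smiles import mol_from_smiles
from .synthetic import MoleculeRecord


@dataclass(frozen=True)
class ClassificationTask:
    """A property name, class count, and the equal-range thresholds."""

    property_name: str
    n_classes: int
    thresholds: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "thresholds", tuple(self.thresholds))
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.thresholds) != self.n_classes - 1:
            raise ValueError("need exactly n_classes - 1 thresholds")
        if any(a >= b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def labels(self) -> tuple[str, ...]:
        """The valid completion strings, "0" .. str(n_classes - 1)."""
        return tuple(str(i) for i in range(self.n_classes))


def compute_thresholds(
    values: Sequence[float], n_classes: int, property_name: str = "value"
) -> ClassificationTask:
    """Equal-width class boundaries over [min(values), max(values)].

    threshold_i = min + i * (max - min) / n_classes for i in 1..n_classes-1.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise DegenerateRangeError(
            f"all values equal ({lo}); cannot segment a zero-width range"
        )
    width = (hi - lo) / n_classes
    thresholds = tuple(lo + i * width for i in range(1, n_classes))
    return ClassificationTask(property_name, n_classes, thresholds)


def assign_class(value: float, task: ClassificationTask) -> int:
    """Label = number of thresholds <= value (boundary goes to the higher
    class). Values outside the labeling range clamp to the end classes."""
    return int(np.searchsorted(task.thresholds, value, side="right"))


def labels_for(
    records: Sequence[MoleculeRecord], task: ClassificationTask
) -> list[int]:
    """Class labels of the records' task property."""
    return [assign_class(r.properties[task.property_name], task) for r in records]


@dataclass(frozen=True)
class SplitSpec:
    """A train/test partition of record ids.

    ``kind`` is one of random_fraction, kfold, family_holdout;
    ``excluded_fragments`` names the held-out families (empty otherwise).
    """

    train_ids: frozenset[str]
    test_ids: frozenset[str]
    kind: str
    excluded_fragments: frozenset[str] = frozenset()
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "train_ids", frozenset(self.train_ids))
        object.__setattr__(self, "test_ids", frozenset(self.test_ids))
        object.__setattr__(
            self, "excluded_fragments", frozenset(self.excluded_fragments)
        )
        if self.train_ids & self.test_ids:
            raise ValueError("train and test ids overlap")

    def select(
        self, records: Sequence[MoleculeRecord]
    ) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
        train = [r for r in records if r.id in self.train_ids]
        test = [r for r in records if r.id in self.test_ids]
        return train, test


def split_random(
    records: Sequence[MoleculeRecord], test_fraction: float, seed: int = 0
) -> SplitSpec:
    """Random split with |test| = round(test_fraction * n)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    ids = [r.id for r in records]
    n_test = round(test_fraction * len(ids))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    test = frozenset(ids[i] for i in perm[:n_test])
    train = frozenset(ids[i] for i in perm[n_test:])
    return SplitSpec(train, test, "random_fraction", seed=seed)


def learning_curve_subsets(
    records: Sequence[MoleculeRecord],
    fractions: Sequence[float],
    seed: int = 0,
    holdout_fraction: float = 0.2,
) -> list[SplitSpec]:
    """Nested training subsets sharing one fixed hold-out.

    A ``holdout_fraction`` hold-out is reserved first; each requested
    fraction f (of the *full* dataset size, f <= 1 - holdout_fraction)
    takes the first round(f * n) elements of one shuffled ordering of the
    remaining pool, so smaller subsets are contained in larger ones and
    every curve point is evaluated on the same hold-out.
    """
    pool_fraction = 1.0 - holdout_fraction
    for f in fractions:
        if not 0 < f <= pool_fraction + 1e-12:
            raise ValueError(
                f"fraction {f} outside (0, {pool_fraction}]: would overlap the hold-out"
            )
    if not fractions:
        return []
    ids = [r.id for r in records]
    n = len(ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = round(holdout_fraction * n)
    test = frozenset(ids[i] for i in perm[:n_test])
    pool = [ids[i] for i in perm[n_test:]]
    specs = []
    for f in fractions:
        n_train = min(round(f * n), len(pool))
        specs.append(
            SplitSpec(frozenset(pool[:n_train]), test, "random_fraction", seed=seed)
        )
    return specs


def split_family_holdout(
    records: Sequence[MoleculeRecord],
    fragments: Iterable[str],
    fragment_library: Mapping[str, Fragment] | None = None,
) -> SplitSpec:
    """Hold out every molecule containing any named fragment.

    Membership is decided by substructure matching of the registered
    fragment (any-match rule: containing one excluded fragment suffices),
    so the train set provably contains no occurrence of any of them.
    """
    library = fragment_library if fragment_library is not None else load_fragment_library()
    names = frozenset(fragments)
    unknown = names - set(library)
    if unknown:
        raise ValueError(f"unknown fragment name(s): {sorted(unknown)}")
    queries = [library[n].query for n in names]
    test, train = [], []
    for r in records:
        mol = mol_from_smiles(r.smiles)
        if any(mol.HasSubstructMatch(q) for q in queries):
            test.append(r.id)
        else:
            train.append(r.id)
    return SplitSpec(
        frozenset(train), frozenset(test), "family_holdout", excluded_fragments=names
    )


def stratified_kfold(
    records: Sequence[MoleculeRecord],
    labels: Sequence[int],
    k: int,
    seed: int = 0,
) -> list[SplitSpec]:
    """Stratified k-fold partition; fold i is the test set of spec i.

    Per-fold class counts differ from perfect proportionality by at most
    one. Raises :class:`StratificationError` when any class has fewer than
    k members.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(records) != len(labels):
        raise ValueError("records and labels must have equal length")
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {int(counts.min())} members; need >= k={k}"
        )
    ids = np.array([r.id for r in records])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    specs = []
    for train_idx, test_idx in skf.split(np.zeros(len(ids)), labels):
        specs.append(
            SplitSpec(
                frozenset(ids[train_idx]), frozenset(ids[test_idx]), "kfold", seed=seed
            )
        )
    return specs


def write_split_csv(spec: SplitSpec, destination, fold: int | None = None) -> None:
    """Serialize a split as a two-column CSV (id, role)."""
    role_test = "test" if fold is None else f"fold_{fold}"

    def _write(fh):
        writer = csv.writer(fh)
        writer.writerow(["id", "role"])
        for i in sorted(spec.train_ids):
            writer.writerow([i, "train"])
        for i in sorted(spec.test_ids):
            writer.writerow([i, role_test])

    if hasattr(destination, "write"):
        _write(destination)
    else:
        with open(destination, "w", newline="", encoding="utf-8") as fh:
            _write(fh)


def read_split_csv(source) -> SplitSpec:
    """Read a split written by :func:`write_split_csv`."""
    if hasattr(source, "read"):
        rows = list(csv.reader(source.read().splitlines()))
    else:
        with open(source, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
    train, test = set(), set()
    for rid, role in rows[1:]:
        (train if role == "train" else test).add(rid)
    return SplitSpec(frozenset(train), frozenset(test), "random_fraction")
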