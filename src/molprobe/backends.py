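"""Classifier backends behind one prompt-completion contract.

A backend is anything with ``fit(pairs)`` and ``complete(prompt) -> str``:
it is trained on prompt-completion pairs and completes an arbitrary text
prompt with a raw string. Two reference implementations are provided:

* :class:`NGramBackend` - a token n-gram linear classifier over the
  atom-level SMILES tokenization. It is a deterministic, desk-scale
  surrogate for a fine-tuned autoregressive language model: like such a
  model it consumes raw text (including ``<missing>`` tokens and invalid
  SMILES) and returns a free-form string, but it trains in seconds.
* :class:`DescriptorSVMBackend` - the classical QSAR baseline: the full
  RDKit descriptor set, univariate top-k feature selection, [0, 1]
  scaling, and a support-vector classifier. Unlike the n-gram surrogate it
  parses chemistry, so unparseable prompts yield a non-label sentinel
  completion.

Completions are mapped back to class labels by :func:`parse_completion`;
anything that is not a valid label string is the :data:`ERRONEOUS` marker.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.feature_selection import SelectKBest, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .errors import TrainingError
from .smiles import PromptCompletionPair, tokenize


class _Erroneous:
    """Singleton marker for completions that are not a valid class label."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "ERRONEOUS"

    def __reduce__(self):  # preserve singleton across pickling
        return (_Erroneous, ())


ERRONEOUS = _Erroneous()


def parse_completion(raw: str, n_classes: int):
    """Label integer if the stripped completion is "0".."n_classes-1",
    else :data:`ERRONEOUS` (a value, never an exception)."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    s = raw.strip()
    if s in {str(i) for i in range(n_classes)}:
        return int(s)
    return ERRONEOUS


@dataclass(frozen=True)
class PredictionRecord:
    """One prompt, its raw completion, and the parsed label (or ERRONEOUS)."""

    input_text: str
    raw_completion: str
    parsed_label: object


@runtime_checkable
class BackendContract(Protocol):
    """Structural contract every classifier backend satisfies."""

    metadata: dict

    def fit(self, pairs: Sequence[PromptCompletionPair]) -> "BackendContract": ...

    def complete(self, prompt: str) -> str: ...


def predict_records(
    backend: BackendContract, prompts: Iterable[str], n_classes: int
) -> list[PredictionRecord]:
    """Complete every prompt and parse the completions."""
    out = []
    for p in prompts:
        raw = backend.complete(p)
        out.append(PredictionRecord(p, raw, parse_completion(raw, n_classes)))
    return out


class NGramBackend:
    """Token n-gram surrogate classifier.

    Prompts are tokenized at the atom level (leniently, so arbitrary
    perturbed text is accepted) and featurized as counts of token n-grams
    of orders ``n_range[0]..n_range[1]``; a multinomial logistic regression
    maps counts to completion strings. n-grams unseen in training are
    ignored.

    With ``gibberish_threshold`` set, prompts in which at least that
    fraction of tokens never occurred in training are answered with the
    non-label string "?" instead of a class label, emulating the erroneous
    free-text responses a language model gives to unfamiliar input.
    """

    NON_LABEL = "?"

    def __init__(
        self,
        n_range: tuple[int, int] = (1, 3),
        C: float = 1.0,
        seed: int = 0,
        gibberish_threshold: float | None = None,
    ):
        self.n_range = n_range
        self.C = C
        self.seed = seed
        self.gibberish_threshold = gibberish_threshold
        self._vectorizer = None
        self._clf = None
        self._token_vocab: set[str] = set()

    @property
    def metadata(self) -> dict:
        return {
            "name": "ngram",
            "seed": self.seed,
            "hyperparameters": {
                "n_range": self.n_range,
                "C": self.C,
                "gibberish_threshold": self.gibberish_threshold,
            },
        }

    def _analyze(self, text: str) -> list[str]:
        tokens = tokenize(text, strict=False).tokens
        lo, hi = self.n_range
        grams = []
        for n in range(lo, hi + 1):
            grams.extend(
                "\x1f".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1)
            )
        return grams

    def fit(self, pairs: Sequence[PromptCompletionPair]) -> "NGramBackend":
        if not pairs:
            raise TrainingError("cannot fit on an empty pair list")
        prompts = [p.prompt for p in pairs]
        completions = [p.completion for p in pairs]
        self._vectorizer = CountVectorizer(analyzer=self._analyze, lowercase=False)
        X = self._vectorizer.fit_transform(prompts)
        self._token_vocab = {
            t for prompt in prompts for t in tokenize(prompt, strict=False).tokens
        }
        self._classes = sorted(set(completions))
        if len(self._classes) == 1:
            self._clf = None  # degenerate single-class data
            self._only_class = self._classes[0]
        else:
            self._clf = LogisticRegression(
                C=self.C, max_iter=2000, random_state=self.seed
            )
            self._clf.fit(X, completions)
        return self

    def complete(self, prompt: str) -> str:
        if self._vectorizer is None:
            raise TrainingError("backend is not fitted")
        if self.gibberish_threshold is not None:
            tokens = tokenize(prompt, strict=False).tokens
            if tokens:
                unseen = sum(1 for t in tokens if t not in self._token_vocab)
                if unseen / len(tokens) >= self.gibberish_threshold:
                    return self.NON_LABEL
        if self._clf is None:
            return self._only_class
        X = self._vectorizer.transform([prompt])
        return str(self._clf.predict(X)[0])


def _descriptor_row(mol: Chem.Mol) -> dict[str, float]:
    """The full RDKit descriptor set; failed descriptors become NaN."""
    try:
        row = Descriptors.CalcMolDescriptors(mol)
    except Exception:
        return {}
    clean = {}
    for k, v in row.items():
        try:
            clean[k] = float(v)
        except (TypeError, ValueError):
            clean[k] = float("nan")
    return clean


class DescriptorSVMBackend:
    """Molecular-descriptor + SVM baseline.

    fit: computes the full RDKit descriptor set per training molecule,
    drops molecules for which more than ``max_missing_fraction`` of
    descriptors failed, drops descriptors with any remaining missing
    value, keeps the ``k_best`` best by univariate ANOVA F-score, rescales
    each to [0, 1] on the training data, and trains an SVC.

    complete: parses the prompt as SMILES; unparseable prompts get the
    non-label sentinel "invalid" (ERRONEOUS downstream). A selected
    descriptor that fails at prediction time is imputed at the training
    minimum of that descriptor.
    """

    NON_LABEL = "invalid"

    def __init__(
        self,
        k_best: int = 20,
        C: float = 1.0,
        kernel: str = "rbf",
        seed: int = 0,
        max_missing_fraction: float = 0.10,
    ):
        self.k_best = k_best
        self.C = C
        self.kernel = kernel
        self.seed = seed
        self.max_missing_fraction = max_missing_fraction
        self._features: list[str] | None = None
        self._scaler = None
        self._clf = None

    @property
    def metadata(self) -> dict:
        return {
            "name": "descriptor_svm",
            "seed": self.seed,
            "hyperparameters": {
                "k_best": self.k_best,
                "C": self.C,
                "kernel": self.kernel,
                "max_missing_fraction": self.max_missing_fraction,
            },
        }

    def fit(self, pairs: Sequence[PromptCompletionPair]) -> "DescriptorSVMBackend":
        if not pairs:
            raise TrainingError("cannot fit on an empty pair list")
        rows, labels = [], []
        for pair in pairs:
            mol = Chem.MolFromSmiles(pair.prompt)
            if mol is None:
                continue
            rows.append(_descriptor_row(mol))
            labels.append(pair.completion)
        frame = pd.DataFrame(rows)
        if frame.empty:
            raise TrainingError("no training prompt parsed as SMILES")
        # drop molecules with too many failed descriptors, then descriptors
        # with any missing value, so the matrix is complete
        keep = frame.isna().mean(axis=1) <= self.max_missing_fraction
        frame = frame.loc[keep]
        labels = [l for l, k in zip(labels, keep) if k]
        if frame.empty:
            raise TrainingError("all molecules dropped by the missing-descriptor rule")
        frame = frame.dropna(axis=1)
        # constant descriptors carry no signal and break the F-score
        frame = frame.loc[:, frame.nunique() > 1]
        k = min(self.k_best, frame.shape[1])
        if len(set(labels)) < 2:
            self._features = list(frame.columns[:k])
            self._only_class = labels[0]
            self._clf = None
            self._scaler = MinMaxScaler().fit(frame[self._features].to_numpy())
            self._train_min = frame[self._features].min().to_numpy()
            return self
        selector = SelectKBest(f_classif, k=k).fit(frame.to_numpy(), labels)
        self._features = list(frame.columns[selector.get_support()])
        X = frame[self._features].to_numpy()
        self._scaler = MinMaxScaler().fit(X)
        self._train_min = frame[self._features].min().to_numpy()
        self._clf = SVC(C=self.C, kernel=self.kernel, random_state=self.seed)
        self._clf.fit(self._scaler.transform(X), labels)
        return self

    def complete(self, prompt: str) -> str:
        if self._features is None:
            raise TrainingError("backend is not fitted")
        mol = Chem.MolFromSmiles(prompt)
        if mol is None:
            return self.NON_LABEL
        row = _descriptor_row(mol)
        x = np.array(
            [row.get(f, float("nan")) for f in self._features], dtype=float
        )
        bad = ~np.isfinite(x)
        x[bad] = self._train_min[bad]
        if self._clf is None:
            return self._only_class
        return str(self._clf.predict(self._scaler.transform(x[None, :]))[0])


STATE_FORMAT_VERSION = 1


def save_backend(backend, destination) -> None:
    """Serialize a fitted backend to a single versioned file."""
    payload = {"format_version": STATE_FORMAT_VERSION, "backend": backend}
    if hasattr(destination, "write"):
        pickle.dump(payload, destination)
    else:
        with open(destination, "wb") as fh:
            pickle.dump(payload, fh)


def load_backend(source):
    """Load a backend written by :func:`save_backend`."""
    if hasattr(source, "read"):
        payload = pickle.load(source)
    else:
        with open(source, "rb") as fh:
            payload = pickle.load(fh)
    if payload.get("format_version") != STATE_FORMAT_VERSION:
        raise ValueError(
            f"unsupported backend state version: {payload.get('format_version')}"
        )
    return payload["backend"]
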