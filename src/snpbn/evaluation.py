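"""Train/test evaluation of disease prediction and external validation."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import json

import numpy as np
import pandas as pd

from .bn import CPTSet, predict_disease
from .data import MISSING, GenotypeDataset


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion matrix and derived metrics for a binary disease classifier.

    ``confusion[i, j]`` counts subjects predicted as class i with actual
    class j, rows/columns ordered (case, control).
    """

    confusion: np.ndarray
    threshold: float

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.n)

    def precision(self, cls: int = 1) -> float:
        i = 0 if cls == 1 else 1  # row 0 = predicted case
        denom = self.confusion[i].sum()
        return float(self.confusion[i, i] / denom) if denom else float("nan")

    def recall(self, cls: int = 1) -> float:
        i = 0 if cls == 1 else 1
        denom = self.confusion[:, i].sum()
        return float(self.confusion[i, i] / denom) if denom else float("nan")

    def f1(self, cls: int = 1) -> float:
        p, r = self.precision(cls), self.recall(cls)
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "confusion": self.confusion.tolist(),
            "threshold": self.threshold,
            "accuracy": self.accuracy,
            "per_class": {
                name: {
                    "precision": self.precision(cls),
                    "recall": self.recall(cls),
                    "f1": self.f1(cls),
                }
                for name, cls in (("disease", 1), ("disease-free", 0))
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_tsv(self, path: str | Path) -> None:
        """Report shaped like a standard model-performance table: one row per
        class with precision/recall/F1 and an accuracy footer."""
        rows = [
            {
                "class": name,
                "precision": f"{self.precision(cls):.4f}",
                "recall": f"{self.recall(cls):.4f}",
                "f1": f"{self.f1(cls):.4f}",
            }
            for name, cls in (("disease-free", 0), ("disease", 1))
        ]
        rows.append({"class": "accuracy", "precision": "", "recall": "",
                     "f1": f"{self.accuracy:.4f}"})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def confusion_from_predictions(
    predicted: np.ndarray, actual: np.ndarray
) -> np.ndarray:
    conf = np.zeros((2, 2), dtype=np.int64)
    for p, a in zip(predicted, actual):
        conf[0 if p == 1 else 1, 0 if a == 1 else 1] += 1
    return conf


def _sample_probabilities(
    cpts: CPTSet, test: GenotypeDataset, loci: Sequence[str]
) -> np.ndarray:
    cols = {l: test.locus_index(l) for l in loci}
    probs = np.empty(test.n_subjects)
    for i in range(test.n_subjects):
        evidence = {
            l: int(test.genotypes[i, j])
            for l, j in cols.items()
            if test.genotypes[i, j] != MISSING
        }
        probs[i] = predict_disease(cpts, evidence)
    return probs


def evaluate(
    cpts: CPTSet,
    test: GenotypeDataset,
    loci: Sequence[str] | None = None,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Classify each test subject by thresholding P(disease | genotypes).

    Subjects with missing genotypes are scored on their observed loci only
    (reduced evidence). The test set must be disjoint from training; the
    splitter guarantees this.
    """
    if test.n_subjects == 0:
        raise ValueError("empty test set")
    ids = list(loci) if loci is not None else [
        n for n in cpts.nodes if n != "disease"
    ]
    probs = _sample_probabilities(cpts, test, ids)
    predicted = (probs >= threshold).astype(int)
    return EvaluationReport(
        confusion_from_predictions(predicted, test.phenotype), threshold
    )


def external_validate(
    cpts: CPTSet,
    samples: GenotypeDataset,
    loci: Sequence[str] | None = None,
    threshold: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Per-sample disease probabilities and the fraction of correct calls at
    the threshold — the external-cohort validation protocol."""
    if samples.n_subjects == 0:
        raise ValueError("empty validation set")
    ids = list(loci) if loci is not None else [
        n for n in cpts.nodes if n != "disease"
    ]
    probs = _sample_probabilities(cpts, samples, ids)
    calls = (probs >= threshold).astype(int)
    fraction = float((calls == samples.phenotype).mean())
    return probs, fraction
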