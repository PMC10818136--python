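"""Metrics and split protocols for drug-target interaction evaluation.

Five metrics: AUROC (Mann-Whitney concordance, ties get half credit), AUPR
(step-wise precision-recall integration), MCC, F1 and balanced accuracy (the
mean of sensitivity and specificity). Thresholded metrics default to 0.5.

Four split protocols:

* ``new_target`` — targets are partitioned into k folds; a pair's fold is its
  target's, so test-fold targets never occur in training pairs.
* ``new_drug`` — symmetric for drugs.
* ``pairwise`` — pairs themselves are partitioned.
* cold start — a fraction of pairs is sampled as the test set and *every*
  pair sharing a drug or a protein with a test pair is removed from training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)

__all__ = [
    "PairRecord",
    "MetricReport",
    "compute_metrics",
    "split",
    "cold_start_split",
    "sample_negatives",
]


@dataclass
class PairRecord:
    drug_id: str
    target_id: str
    label: int
    fold: int | None = None

    def key(self) -> tuple[str, str]:
        return (self.drug_id, self.target_id)


@dataclass
class MetricReport:
    auroc: float
    aupr: float
    mcc: float
    f1: float
    b_acc: float
    n_pos: int
    n_neg: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("auroc", "aupr", "mcc", "f1", "b_acc", "n_pos", "n_neg")}


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricReport:
    """All five metrics from continuous scores and binary labels.

    With a single class present, AUROC and AUPR are undefined (NaN); the
    thresholded metrics are still computed.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos and n_neg:
        auroc = float(roc_auc_score(labels, scores))
        aupr = float(average_precision_score(labels, scores))
    else:
        auroc = aupr = float("nan")
    pred = (scores >= threshold).astype(int)
    mcc = float(matthews_corrcoef(labels, pred)) if len(set(pred) | set(labels)) > 1 else 0.0
    f1 = float(f1_score(labels, pred, zero_division=0))
    b_acc = float(balanced_accuracy_score(labels, pred)) if n_pos and n_neg else float("nan")
    return MetricReport(auroc=auroc, aupr=aupr, mcc=mcc, f1=f1, b_acc=b_acc,
                        n_pos=n_pos, n_neg=n_neg)


def split(records: list[PairRecord], mode: str, k: int = 5, seed: int = 0) -> np.ndarray:
    """Assign a fold in 0..k-1 to every record; returns the fold array and
    writes it onto the records.

    ``new_target`` partitions targets, ``new_drug`` partitions drugs,
    ``pairwise`` partitions the pairs directly. Entity folds are balanced
    (sizes differ by at most one) and deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    if mode in ("new_target", "new_drug"):
        key = (lambda r: r.target_id) if mode == "new_target" else (lambda r: r.drug_id)
        entities = sorted({key(r) for r in records})
        if len(entities) < k:
            raise ValueError(f"{mode} split needs >= {k} distinct entities, got {len(entities)}")
        order = rng.permutation(len(entities))
        fold_of = {entities[idx]: int(pos % k) for pos, idx in enumerate(order)}
        folds = np.array([fold_of[key(r)] for r in records])
    elif mode == "pairwise":
        if len(records) < k:
            raise ValueError(f"pairwise split needs >= {k} pairs")
        order = rng.permutation(len(records))
        folds = np.empty(len(records), dtype=int)
        folds[order] = np.arange(len(records)) % k
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    for r, f in zip(records, folds):
        r.fold = int(f)
    return folds


def cold_start_split(records: list[PairRecord], fraction: float = 0.10,
                     seed: int = 0) -> tuple[list[PairRecord], list[PairRecord]]:
    """Cold-start protocol: sample ``fraction`` of pairs for testing, then
    drop from training every pair whose drug OR target occurs in a test pair.

    Returns (train, test). ``fraction=0`` yields an empty test set (warned).
    Raises if the cascade empties the training set.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_test = int(round(fraction * len(records)))
    if n_test == 0:
        import warnings

        warnings.warn("cold-start fraction selects no test pairs; test set is empty")
        return list(records), []
    test_idx = set(rng.choice(len(records), size=n_test, replace=False).tolist())
    test = [records[i] for i in sorted(test_idx)]
    test_drugs = {r.drug_id for r in test}
    test_targets = {r.target_id for r in test}
    train = [r for i, r in enumerate(records)
             if i not in test_idx and r.drug_id not in test_drugs and r.target_id not in test_targets]
    if not train:
        raise ValueError("cold-start removal emptied the training set; use a smaller fraction")
    return train, test


def sample_negatives(positives: list[tuple[str, str]], drug_ids: list[str],
                     target_ids: list[str], ratio: float = 1.0, seed: int = 0) -> list[tuple[str, str]]:
    """Sample non-interacting pairs uniformly from the complement of the
    positive set, ``ratio`` negatives per positive."""
    rng = np.random.default_rng(seed)
    pos = set(positives)
    n_wanted = int(round(ratio * len(positives)))
    capacity = len(drug_ids) * len(target_ids) - len(pos)
    if n_wanted > capacity:
        raise ValueError(f"cannot sample {n_wanted} negatives from {capacity} available pairs")
    out: list[tuple[str, str]] = []
    seen = set(pos)
    while len(out) < n_wanted:
        d = drug_ids[int(rng.integers(len(drug_ids)))]
        t = target_ids[int(rng.integers(len(target_ids)))]
        if (d, t) not in seen:
            seen.add((d, t))
            out.append((d, t))
    return out
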