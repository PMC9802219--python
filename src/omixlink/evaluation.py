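"""Evaluation of predicted links against ground truth.

Definitions
-----------
*Top-n precision*: among tested links (retained results that have a ground
truth entry), the fraction whose true GCF appears within the first n ranked
labels.  *Annotation rate*: tested links over all ground-truth spectra —
results dropped by the co-occurrence threshold count as "not tested", so the
threshold lowers the annotation rate, not the precision denominator.
*Recall*: true positives over true positives plus links without any returned
result (spectra the linker produced nothing for); threshold-filtered links
are not false negatives.  *Randomness baseline*: mean top-n precision after
randomly permuting which ranked prediction each spectrum receives — the
precision a label-blind assignment would achieve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .linker import LinkResult

__all__ = [
    "EvalReport",
    "read_truth",
    "topn_precision",
    "recall",
    "randomness_baseline",
    "evaluate",
]


@dataclass
class EvalReport:
    """Summary metrics for one evaluation run."""

    n: int
    tested: int
    correct: int
    precision: float
    annotation_rate: float
    recall: float = float("nan")
    randomness: float = float("nan")

    def to_text(self) -> str:
        lines = [
            f"top-{self.n} evaluation",
            f"  tested links     : {self.tested}",
            f"  correct links    : {self.correct}",
            f"  precision        : {self.precision:.3f}",
            f"  annotation rate  : {self.annotation_rate:.3f}",
        ]
        if not math.isnan(self.recall):
            lines.append(f"  recall           : {self.recall:.3f}")
        if not math.isnan(self.randomness):
            lines.append(f"  randomness       : {self.randomness:.3f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def read_truth(path) -> dict[str, str]:
    """Read ``truth.tsv`` (spectrum_id, true_gcf_label) into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("spectrum_id", "true_gcf_label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["spectrum_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate spectrum_id entries")
    return dict(zip(df["spectrum_id"], df["true_gcf_label"]))


def topn_precision(
    results: Sequence[LinkResult], truth: Mapping[str, str], n: int
) -> EvalReport:
    """Top-n precision and annotation rate against ground truth.

    ``tested`` counts retained results whose spectrum has a truth entry;
    ``correct`` those whose true label occurs within the first n ranked GCFs.
    With zero tested links the precision is NaN (with a warning).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tested = 0
    correct = 0
    for r in results:
        true_label = truth.get(r.spectrum_id)
        if true_label is None or not r.retained:
            continue
        tested += 1
        if true_label in r.ranked_gcfs[:n]:
            correct += 1
    if tested == 0:
        warnings.warn("no tested links; precision undefined (NaN)")
        precision = float("nan")
    else:
        precision = correct / tested
    annotation_rate = tested / len(truth) if truth else float("nan")
    return EvalReport(
        n=n, tested=tested, correct=correct, precision=precision, annotation_rate=annotation_rate
    )


def recall(results: Sequence[LinkResult], truth: Mapping[str, str], n: int = 3) -> float:
    """True positives over true positives plus result-less truth spectra.

    A truth spectrum with no link result at all is a false negative; one whose
    result was dropped by the co-occurrence threshold is merely "not tested"
    and affects the annotation rate instead.  Empty truth yields NaN.
    """
    if not truth:
        warnings.warn("empty truth table; recall undefined (NaN)")
        return float("nan")
    by_id = {r.spectrum_id: r for r in results}
    tp = 0
    missing = 0
    for sid, true_label in truth.items():
        r = by_id.get(sid)
        if r is None:
            missing += 1
        elif r.retained and true_label in r.ranked_gcfs[:n]:
            tp += 1
    if tp + missing == 0:
        warnings.warn("no true positives and no missing links; recall undefined (NaN)")
        return float("nan")
    return tp / (tp + missing)


def randomness_baseline(
    results: Sequence[LinkResult],
    truth: Mapping[str, str],
    n: int,
    seed: int,
    reps: int = 100,
) -> float:
    """Shuffled-assignment precision baseline.

    The result payloads (ranked GCFs and retention flags) are randomly
    permuted across the spectrum ids, top-n precision is recomputed, and the
    mean over ``reps`` permutations is returned.  With many distinct families
    this baseline is near 0; a high value signals that precision could be an
    artifact of label imbalance.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    results = list(results)
    values = []
    for _ in range(reps):
        perm = rng.permutation(len(results))
        shuffled = [
            LinkResult(
                spectrum_id=results[i].spectrum_id,
                neighbors=results[j].neighbors,
                retained=results[j].retained,
            )
            for i, j in enumerate(perm)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = topn_precision(shuffled, truth, n)
        values.append(0.0 if math.isnan(report.precision) else report.precision)
    return float(np.mean(values))


def evaluate(
    results: Sequence[LinkResult],
    truth: Mapping[str, str],
    n: int = 3,
    seed: int | None = None,
    reps: int = 100,
) -> EvalReport:
    """Full report: precision, annotation rate, recall, optional randomness."""
    report = topn_precision(results, truth, n)
    report.recall = recall(results, truth, n)
    if seed is not None:
        report.randomness = randomness_baseline(results, truth, n, seed=seed, reps=reps)
    return report
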