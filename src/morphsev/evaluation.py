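"""Performance metrics, permutation testing, paired comparisons, decoding.

Metrics are computed on predictions concatenated across outer folds, with the
severe class as positive: recall equals severe-class accuracy, balanced
accuracy is the mean of the two class accuracies, and F1 (the harmonic mean of
precision and recall) is the headline score; it is defined as 0 when the model
makes no positive predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SEVERE = 1  # positive class coding
NONSEVERE = 0


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Precision, recall (= severe accuracy), class accuracies, balanced, F1."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    nonsevere_acc = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    balanced = 0.5 * (recall + nonsevere_acc)
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "severe_accuracy": recall,
        "nonsevere_accuracy": nonsevere_acc,
        "balanced_accuracy": balanced,
        "f1": f1,
    }


def aggregate_metrics(per_repeat: Sequence[Mapping[str, float]]) -> pd.DataFrame:
    """Median and range of each metric across repeats (one row per metric)."""
    df = pd.DataFrame(per_repeat)
    return pd.DataFrame(
        {"median": df.median(), "min": df.min(), "max": df.max()}
    )


def permutation_test(
    runner: Callable[[np.ndarray], float],
    y: np.ndarray,
    m: int = 500,
    seed: int = 0,
) -> tuple[np.ndarray, float, float]:
    """Permutation test of a scalar score against shuffled labels.

    ``runner`` maps a label assignment to a score (e.g. rebuilds models and
    returns the concatenated-fold F1).  Labels only are permuted; the runner
    is responsible for rebuilding any label-dependent structure (e.g.
    stratified partitions follow the permuted categories).  The p-value
    includes the observed result in the null distribution:
    p = (#{null >= observed} + 1) / (m + 1), so p is never below 1/(m+1).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    observed = float(runner(y))
    null = np.empty(m)
    for i in range(m):
        null[i] = runner(rng.permutation(y))
    p = (np.sum(null >= observed) + 1) / (m + 1)
    return null, observed, float(p)


@dataclass
class PairedComparison:
    t: float
    df: int
    p: float
    cohens_d: float
    degenerate: bool = False


def paired_comparison(
    scores_a: np.ndarray, scores_b: np.ndarray
) -> PairedComparison:
    """Paired t-test on per-repeat scores sharing one partition plan.

    Cohen's d is mean(diff)/sd(diff).  Zero-variance nonzero differences make
    t and d infinite; the result is flagged degenerate.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need equal-length paired score vectors")
    diff = a - b
    n = len(diff)
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return PairedComparison(0.0, n - 1, 1.0, 0.0)
        sign = np.sign(diff.mean())
        return PairedComparison(
            float(sign * np.inf), n - 1, 0.0, float(sign * np.inf), degenerate=True
        )
    t, p = stats.ttest_rel(a, b)
    d = diff.mean() / sd
    return PairedComparison(float(t), n - 1, float(p), float(d))


def decode_topics(
    exemplar_map: np.ndarray,
    topic_maps: Mapping[str, np.ndarray],
    lesion_mask: np.ndarray | None = None,
    r_threshold: float = 0.2,
    alpha: float = 1e-4,
) -> pd.DataFrame:
    """Correlation-threshold decoding of a saliency map against topic maps.

    Pearson r is computed between the (flattened) saliency map and each topic
    map after removing voxels inside the lesion.  A topic is retained iff
    r > ``r_threshold`` and its Bonferroni-corrected p-value (p * n_topics)
    is below ``alpha``.  p-values use the t approximation with n equal to the
    number of included voxels; voxelwise spatial autocorrelation is not
    modelled.
    """
    sal = np.asarray(exemplar_map, dtype=float).ravel()
    keep = np.ones(sal.shape, dtype=bool)
    if lesion_mask is not None:
        keep &= ~np.asarray(lesion_mask).astype(bool).ravel()
    n_topics = len(topic_maps)
    rows = []
    for name, tmap in topic_maps.items():
        t = np.asarray(tmap, dtype=float).ravel()
        if t.shape != sal.shape:
            raise ValueError(f"topic {name!r} shape mismatch")
        a, b = sal[keep], t[keep]
        if a.std() == 0 or b.std() == 0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(a, b)
        p_bonf = min(1.0, p * n_topics)
        rows.append(
            {
                "topic": name,
                "r": float(r),
                "p": float(p),
                "p_bonferroni": float(p_bonf),
                "retained": bool(r > r_threshold and p_bonf < alpha),
            }
        )
    return pd.DataFrame(rows)
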