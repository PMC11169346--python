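"""Preallocated repeated nested stratified cross-validation plans.

Every model in the pipeline (CNN, SVMs, fusion stages) consumes the *same*
plan object, which makes performance comparisons across repeats genuinely
paired.  Stratification uses the four granular aphasia categories rather than
the binary target, so folds sample similar distributions of raw WAB-AQ scores.

Defaults: 20 repeats, 6 outer folds (test), 8 inner folds (tuning), and a
stratified 70/30 train/validation resplit of each outer training set for CNN
retraining.  At N=231 this yields outer test folds of 38-39 subjects, inner
held-out folds of 24-25, and validation sets of 58.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np


@dataclass
class PartitionConfig:
    n_repeats: int = 20
    n_outer: int = 6
    n_inner: int = 8
    val_frac: float = 0.3
    seed: int = 0


@dataclass
class PartitionPlan:
    """Immutable fold assignments shared by all models.

    outer_assignment : (n_repeats, n_subjects) int array, outer fold id.
    inner_assignment : (n_repeats, n_outer, n_subjects) int array; inner fold
        id for subjects in the outer training set, -1 for test subjects.
    val_flag : (n_repeats, n_outer, n_subjects) int array; for the 70/30
        retraining resplit of each outer training set: 1 train, 0 validation,
        -1 not in the outer training set.
    """

    config: PartitionConfig
    category4: np.ndarray
    outer_assignment: np.ndarray
    inner_assignment: np.ndarray
    val_flag: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.outer_assignment.shape[1]

    def outer_split(self, repeat: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_ids, test_ids) for one outer fold of one repeat."""
        a = self.outer_assignment[repeat]
        return np.where(a != fold)[0], np.where(a == fold)[0]

    def inner_split(
        self, repeat: int, outer_fold: int, inner_fold: int
    ) -> tuple[np.ndarray, np.ndarray]:
        a = self.inner_assignment[repeat, outer_fold]
        train = np.where((a != inner_fold) & (a >= 0))[0]
        held = np.where(a == inner_fold)[0]
        return train, held

    def val_split(self, repeat: int, outer_fold: int) -> tuple[np.ndarray, np.ndarray]:
        f = self.val_flag[repeat, outer_fold]
        return np.where(f == 1)[0], np.where(f == 0)[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": vars(self.config),
                "category4": self.category4.tolist(),
                "outer_assignment": self.outer_assignment.tolist(),
                "inner_assignment": self.inner_assignment.tolist(),
                "val_flag": self.val_flag.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PartitionPlan":
        d = json.loads(text)
        return cls(
            PartitionConfig(**d["config"]),
            np.asarray(d["category4"]),
            np.asarray(d["outer_assignment"], dtype=np.int64),
            np.asarray(d["inner_assignment"], dtype=np.int64),
            np.asarray(d["val_flag"], dtype=np.int64),
        )

    def hash(self) -> str:
        """Content hash used to assert that all models share one plan."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _stratified_folds(
    strata: np.ndarray, ids: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign ``ids`` to folds, stratified with <=1 imbalance per stratum.

    Within each stratum the members are shuffled and dealt so every fold gets
    floor(n_s / n_folds) or one more; the "+1" remainders go to the folds with
    the smallest running totals, keeping overall fold sizes within 1 of each
    other as well.
    """
    assignment = np.full(len(ids), -1, dtype=np.int64)
    totals = np.zeros(n_folds, dtype=np.int64)
    labels = strata[ids]
    uniq, counts = np.unique(labels, return_counts=True)
    order = np.argsort(-counts)  # largest strata first
    for u in uniq[order]:
        members = np.where(labels == u)[0]
        members = members[rng.permutation(len(members))]
        base, extra = divmod(len(members), n_folds)
        per_fold = np.full(n_folds, base, dtype=np.int64)
        if extra:
            # folds with smallest totals receive the remainder; random ties
            rank = np.lexsort((rng.permutation(n_folds), totals))
            per_fold[rank[:extra]] += 1
        pos = 0
        for f in range(n_folds):
            assignment[members[pos : pos + per_fold[f]]] = f
            pos += per_fold[f]
        totals += per_fold
    return assignment


def build_nested_partitions(
    category4_labels: np.ndarray | list, config: PartitionConfig | None = None
) -> PartitionPlan:
    """Build the full repeated nested stratified plan.

    Deterministic given ``config.seed``; repeat r uses seed ``seed + r`` so
    repeats are distinct but reproducible.  A stratum smaller than the fold
    count simply spreads its members over distinct folds (no subject dropped).
    """
    config = config or PartitionConfig()
    strata = np.asarray(category4_labels)
    n = len(strata)
    if config.n_outer > n:
        raise ValueError("more outer folds than subjects")
    R, O = config.n_repeats, config.n_outer
    outer = np.zeros((R, n), dtype=np.int64)
    inner = np.full((R, O, n), -1, dtype=np.int64)
    val = np.full((R, O, n), -1, dtype=np.int64)
    all_ids = np.arange(n)
    for r in range(R):
        rng = np.random.default_rng(config.seed + r)
        outer[r] = _stratified_folds(strata, all_ids, O, rng)
        for f in range(O):
            train_ids = np.where(outer[r] != f)[0]
            inner[r, f, train_ids] = _stratified_folds(
                strata, train_ids, config.n_inner, rng
            )
            # singleton strata cannot be split; they stay in the training side
            labels_f = strata[train_ids]
            uniq_f, counts_f = np.unique(labels_f, return_counts=True)
            singleton = np.isin(labels_f, uniq_f[counts_f < 2])
            splittable = train_ids[~singleton]
            tr, va = resplit_for_validation(
                splittable, strata[splittable], config.val_frac, rng=rng
            )
            tr = np.sort(np.concatenate([tr, train_ids[singleton]]))
            val[r, f, tr] = 1
            val[r, f, va] = 0
    return PartitionPlan(config, strata, outer, inner, val)


def resplit_for_validation(
    ids: np.ndarray,
    labels: np.ndarray,
    frac: float = 0.3,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single stratified split with |validation| = round(frac * n).

    Per-stratum validation counts are set by largest remainder on the exact
    proportional shares, so every stratum with >= 2 members contributes at
    least its proportional share (and at least one subject when feasible).
    """
    if not (0.0 < frac < 1.0):
        raise ValueError("frac must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    ids = np.asarray(ids)
    labels = np.asarray(labels)
    n = len(ids)
    n_val = int(round(frac * n))
    uniq, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every stratum needs at least 2 members to split")
    shares = counts * n_val / n
    take = np.floor(shares).astype(int)
    rem = n_val - take.sum()
    if rem > 0:
        frac_part = shares - np.floor(shares)
        order = np.lexsort((rng.permutation(len(uniq)), -frac_part))
        take[order[:rem]] += 1
    # never empty a stratum's training side, never take a whole stratum
    take = np.minimum(take, counts - 1)
    val_ids = []
    for u, t in zip(uniq, take):
        members = ids[labels == u]
        members = members[rng.permutation(len(members))]
        val_ids.extend(members[:t])
    val_ids = np.sort(np.asarray(val_ids, dtype=ids.dtype))
    train_ids = np.setdiff1d(ids, val_ids)
    return train_ids, val_ids
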