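"""Sample alignment across omics layers, train/val/test splits, and CV folds.

A single integer seed drives all randomness so that split plans, fold plans
and downstream training are reproducible run to run. Categorical tasks are
stratified by class in both splits and folds; quantitative tasks use plain
random partitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .encoding import EncodedLayer
from .io import LabelTable, ValidationError


@dataclass
class MultiOmicsDataset:
    """Aligned encoded layers (1-3) plus labels over a shared ordered cohort."""

    layers: list[EncodedLayer]
    labels: LabelTable
    seed: int = 0
    dropped: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= len(self.layers) <= 3:
            raise ValidationError(f"need 1-3 omics layers, got {len(self.layers)}")
        ids = self.labels.sample_ids
        for lay in self.layers:
            if lay.sample_ids != ids:
                raise ValidationError(
                    f"layer {lay.omics_type} sample order does not match labels"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.labels.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def task(self) -> str:
        return self.labels.task

    def tensors(self) -> list[np.ndarray]:
        return [lay.tensor for lay in self.layers]

    def input_shapes(self) -> list[tuple[int, int]]:
        return [(lay.n_features, lay.n_channels) for lay in self.layers]

    def subset(self, ids: list[str]) -> "MultiOmicsDataset":
        return MultiOmicsDataset([lay.subset(ids) for lay in self.layers],
                                 self.labels.subset(ids), seed=self.seed)

    def y_codes(self) -> np.ndarray:
        """Integer class codes (categorical, classes in sorted order) or floats."""
        if self.task == "categorical":
            classes = self.labels.classes
            lut = {c: i for i, c in enumerate(classes)}
            return np.asarray([lut[str(v)] for v in self.labels.values], dtype=int)
        return np.asarray(self.labels.values, dtype=float)


@dataclass
class SplitPlan:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    fractions: tuple[float, float, float]
    seed: int

    def __post_init__(self) -> None:
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValidationError("split partitions overlap")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"train": self.train_ids, "val": self.val_ids,
                       "test": self.test_ids, "fractions": list(self.fractions),
                       "seed": self.seed}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(d["train"], d["val"], d["test"], tuple(d["fractions"]), d["seed"])


@dataclass
class FoldPlan:
    k: int
    assignments: dict[str, int]
    seed: int
    stratified: bool

    def fold_ids(self, fold: int) -> tuple[list[str], list[str]]:
        """(train_ids, test_ids) for one fold, in cohort order."""
        test = [s for s, f in self.assignments.items() if f == fold]
        train = [s for s, f in self.assignments.items() if f != fold]
        return train, test

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"k": self.k, "assignments": self.assignments,
                       "seed": self.seed, "stratified": self.stratified}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FoldPlan":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(d["k"], d["assignments"], d["seed"], d["stratified"])


def align_samples(layers: list[EncodedLayer], labels: LabelTable,
                  seed: int = 0) -> MultiOmicsDataset:
    """Inner-join layers and labels on sample ID (exact string match).

    Samples missing from any layer or from the labels are dropped; the
    returned dataset records per-source dropped IDs in ``dataset.dropped``.
    Sample order follows the label table restricted to the intersection.
    """
    if not layers:
        raise ValidationError("need at least one encoded layer")
    common = set(labels.sample_ids)
    for lay in layers:
        common &= set(lay.sample_ids)
    if not common:
        raise ValidationError("no sample ID shared by all layers and the label table")
    ordered = [s for s in labels.sample_ids if s in common]
    dropped = {"labels": [s for s in labels.sample_ids if s not in common]}
    for lay in layers:
        dropped[lay.omics_type] = [s for s in lay.sample_ids if s not in common]
    ds = MultiOmicsDataset([lay.subset(ordered) for lay in layers],
                           labels.subset(ordered), seed=seed)
    ds.dropped = dropped
    return ds


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    """Integer partition sizes summing to ``total``, proportional to fractions."""
    raw = total * fractions
    base = np.floor(raw).astype(int)
    rem = raw - base
    for i in np.argsort(-rem)[: total - base.sum()]:
        base[i] += 1
    return base


def split_dataset(d: MultiOmicsDataset, fractions=(0.6, 0.2, 0.2),
                  seed: int = 0) -> SplitPlan:
    """Partition samples into train/val/test with exact integer sizes.

    Sizes follow largest-remainder rounding of ``n * fractions`` so a
    100-sample cohort at (0.6, 0.2, 0.2) yields exactly 60/20/20.
    Categorical tasks are stratified: per-class quotas are allocated by
    largest remainder subject to the global partition sizes.
    """
    fr = np.asarray(fractions, dtype=float)
    if len(fr) != 3 or np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValidationError(f"fractions must be 3 positive values summing to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    ids = np.asarray(d.sample_ids, dtype=object)
    n = len(ids)
    targets = _largest_remainder(n, fr)

    if d.task == "categorical":
        y = np.asarray([str(v) for v in d.labels.values], dtype=object)
        groups = [ids[y == c] for c in sorted(set(y))]
        for g in groups:
            if len(g) < 3:
                raise ValidationError(
                    f"a class has only {len(g)} samples; cannot place it in all 3 partitions"
                )
    else:
        groups = [ids]

    parts: list[list[str]] = [[], [], []]
    # per-group quotas: floor(n_g * frac), then distribute the leftover units
    # to cells with the largest fractional remainder, subject to exact row
    # (group size) and column (global partition size) totals
    raw = np.array([[len(g) * fr[p] for p in range(3)] for g in groups])
    quotas = np.floor(raw).astype(int)
    rem = raw - quotas
    row_deficit = np.array([len(g) for g in groups]) - quotas.sum(axis=1)
    col_deficit = targets - quotas.sum(axis=0)
    while row_deficit.sum() > 0:
        open_cells = [(gi, p) for gi in range(len(groups)) for p in range(3)
                      if row_deficit[gi] > 0 and col_deficit[p] > 0]
        gi, p = max(open_cells, key=lambda c: (rem[c], -c[0], -c[1]))
        quotas[gi, p] += 1
        rem[gi, p] = -1.0  # at most one top-up per cell preference pass
        row_deficit[gi] -= 1
        col_deficit[p] -= 1

    for g, q in zip(groups, quotas):
        perm = rng.permutation(len(g))
        shuffled = list(g[perm])
        ofs = 0
        for p in range(3):
            parts[p].extend(shuffled[ofs:ofs + q[p]])
            ofs += q[p]
    order = {s: i for i, s in enumerate(d.sample_ids)}
    parts = [sorted(p, key=order.__getitem__) for p in parts]
    return SplitPlan(parts[0], parts[1], parts[2], tuple(map(float, fr)), seed)


def make_cv_folds(d: MultiOmicsDataset, k: int = 5, seed: int = 0) -> FoldPlan:
    """Assign every sample to one of ``k`` folds, sizes within 1 of each other."""
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    n = d.n_samples
    if k > n:
        raise ValidationError(f"k={k} exceeds the {n} available samples")
    ids = np.asarray(d.sample_ids, dtype=object)
    stratified = d.task == "categorical"
    if stratified:
        y = np.asarray([str(v) for v in d.labels.values], dtype=object)
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        iterator = splitter.split(np.zeros(n), y)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        iterator = splitter.split(np.zeros(n))
    assignments: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(iterator):
        for i in test_idx:
            assignments[str(ids[i])] = fold
    # keep cohort order in the mapping for deterministic serialization
    assignments = {s: assignments[s] for s in d.sample_ids}
    return FoldPlan(k, assignments, seed, stratified)
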