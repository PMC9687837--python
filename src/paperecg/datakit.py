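"""Manifest handling, stratified 70:20:10 splitting, and k-fold partitioning.

Manifests are plain :class:`pandas.DataFrame` objects with columns
``image_id, path, class`` (plus optional ``seed``, ``split``, ``fold``),
serialized as JSON-lines. The split rule is per-class: with ``n_c`` records
of class ``c``, training receives ``floor(0.70 * n_c)``, validation
``floor(0.20 * n_c)``, and the remainder goes to testing — per-class
flooring, not global rounding, because allocations are decided class by
class. Assignment within a class is a seeded shuffle, so membership is
reproducible and counts never depend on input order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError


@dataclass(frozen=True)
class SplitSpec:
    """70:20:10 split ratios with per-class floor/floor/remainder rounding."""

    train: float = 0.70
    val: float = 0.20
    test: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ConfigurationError("split ratios must sum to 1")


def load_manifest(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(json.loads(line))
    return pd.DataFrame(rows)


def save_manifest(manifest: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for row in manifest.to_dict(orient="records"):
            fh.write(json.dumps(row) + "\n")


def split_counts(n: int, spec: SplitSpec = SplitSpec()) -> tuple[int, int, int]:
    """(train, val, test) sizes for one class of ``n`` records."""
    n_train = int(np.floor(spec.train * n))
    n_val = int(np.floor(spec.val * n))
    return n_train, n_val, n - n_train - n_val


def stratified_split(manifest: pd.DataFrame, spec: SplitSpec = SplitSpec()) -> pd.DataFrame:
    """Assign a ``split`` label (train/val/test) per record, stratified by class."""
    if "class" not in manifest.columns:
        raise InputError("manifest has no 'class' column")
    out = manifest.copy()
    out["split"] = ""
    rng = np.random.default_rng(spec.seed)
    for label in sorted(out["class"].unique()):
        idx = out.index[out["class"] == label].to_numpy()
        perm = idx[rng.permutation(len(idx))]
        n_train, n_val, _ = split_counts(len(idx), spec)
        out.loc[perm[:n_train], "split"] = "train"
        out.loc[perm[n_train:n_train + n_val], "split"] = "val"
        out.loc[perm[n_train + n_val:], "split"] = "test"
    return out


def kfold_partition(manifest: pd.DataFrame, k: int, seed: int = 0) -> pd.DataFrame:
    """Assign a ``fold`` label per record, stratified by class.

    For ``k >= 2`` records of each class are shuffled and dealt round-robin,
    so per-class fold sizes differ by at most one. ``k = 1`` is interpreted
    as a single seeded holdout: the 10% test portion of a 70:20:10
    stratified split becomes fold 0 and the rest is the training pool
    (fold -1).
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if "class" not in manifest.columns:
        raise InputError("manifest has no 'class' column")
    out = manifest.copy()
    if k == 1:
        split = stratified_split(out, SplitSpec(seed=seed))
        out["fold"] = np.where(split["split"] == "test", 0, -1)
        return out
    out["fold"] = -1
    rng = np.random.default_rng(seed)
    for label in sorted(out["class"].unique()):
        idx = out.index[out["class"] == label].to_numpy()
        if k > len(idx):
            warnings.warn(
                f"k={k} exceeds class {label!r} size {len(idx)}; "
                "some folds get no records of this class"
            )
        perm = idx[rng.permutation(len(idx))]
        out.loc[perm, "fold"] = np.arange(len(perm)) % k
    return out


def summarize(manifest: pd.DataFrame) -> pd.DataFrame:
    """Counts by class x split (or overall), with a grand total row."""
    if manifest.empty:
        return pd.DataFrame({"total": []})
    if "split" in manifest.columns:
        table = manifest.pivot_table(
            index="class", columns="split", values="image_id",
            aggfunc="count", fill_value=0,
        )
    else:
        table = manifest.groupby("class").size().to_frame("count")
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table
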