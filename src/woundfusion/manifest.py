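"""Dataset model: manifests, class subsets, deterministic splits, CV folds.

A manifest is an ordered list of records, each pairing an image file with
a class label (BG background, N normal skin, D diabetic, P pressure,
S surgical, V venous), an optional body-map location ID and a wound-group
ID (images of the same wound share a group).

Splitting uses a per-class floor rule: with fractions (f_tr, f_val, f_te)
and n records of a class, training receives floor(f_tr*n), validation
floor(f_val*n) and test the remainder. Assignment within a class is a
seed-deterministic shuffle. This allocation reproduces the published
per-class subset counts of the AZH and Medetec wound datasets exactly for
both the 70/15/15 and 60/15/25 partitions. The group-aware mode instead
packs whole groups greedily, keeping images of the same wound in one
subset at the cost of possibly deviating from the exact floor counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

CLASS_SYMBOLS = ("BG", "N", "D", "P", "S", "V")
WOUND_CLASSES = ("D", "P", "S", "V")


class ManifestError(ValueError):
    pass


@dataclass(frozen=True)
class SampleRecord:
    image_ref: str
    label: str
    location_id: int | None = None
    group_id: str = ""

    def __post_init__(self):
        if not self.image_ref:
            raise ManifestError("image_ref must be non-empty")


@dataclass
class Manifest:
    records: list[SampleRecord]
    classes: tuple[str, ...] = CLASS_SYMBOLS

    def __post_init__(self):
        for rec in self.records:
            if rec.label not in self.classes:
                raise ManifestError(
                    f"label {rec.label!r} not in class vocabulary {list(self.classes)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for rec in self.records:
            counts[rec.label] += 1
        return counts

    def label_indices(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[r.label] for r in self.records], dtype=int)


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float]
    seed: int = 0
    group_aware: bool = False

    def __post_init__(self):
        if any(f < 0 for f in self.fractions):
            raise ManifestError("split fractions must be non-negative")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ManifestError(f"split fractions must sum to 1, got {sum(self.fractions)}")


@dataclass
class DatasetSplit:
    train: Manifest
    val: Manifest
    test: Manifest
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# I/O

_COLUMNS = ["image", "label", "location_id", "group_id"]


def read_manifest(path: str | Path, classes: tuple[str, ...] = CLASS_SYMBOLS) -> Manifest:
    """Read a manifest CSV (``image,label,location_id,group_id``)."""
    df = pd.read_csv(path, dtype={"image": str, "label": str, "group_id": str}, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing column(s) {missing}")
    bad = sorted(set(df["label"]) - set(classes))
    if bad:
        raise ManifestError(
            f"{path}: unknown label symbol(s) {bad}; allowed symbols are {list(classes)}"
        )
    records = []
    for row in df.itertuples(index=False):
        loc = row.location_id
        loc_id = None if (loc == "" or pd.isna(loc)) else int(float(loc))
        records.append(SampleRecord(row.image, row.label, loc_id, row.group_id))
    return Manifest(records, classes)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    rows = [
        {
            "image": r.image_ref,
            "label": r.label,
            "location_id": "" if r.location_id is None else r.location_id,
            "group_id": r.group_id,
        }
        for r in manifest.records
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Class subsets

def select_classes(manifest: Manifest, subset: list[str] | tuple[str, ...]) -> Manifest:
    """Keep only records of ``subset`` classes; vocabulary reset to ``subset``."""
    subset = tuple(subset)
    unknown = sorted(set(subset) - set(manifest.classes))
    if unknown:
        raise ManifestError(f"unknown class(es) in subset: {unknown}")
    if len(subset) < 2:
        raise ManifestError("class subset must contain at least 2 classes")
    kept = [r for r in manifest.records if r.label in subset]
    return Manifest(kept, subset)


# ---------------------------------------------------------------------------
# Splitting

def floor_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Per-class subset sizes: floor(train), floor(val), remainder to test.

    The tiny epsilon guards against binary floating-point products like
    0.7*100 landing a hair below the integer they represent.
    """
    n_train = int(np.floor(fractions[0] * n + 1e-9))
    n_val = int(np.floor(fractions[1] * n + 1e-9))
    return n_train, n_val, n - n_train - n_val


def split_dataset(manifest: Manifest, spec: SplitSpec) -> DatasetSplit:
    """Deterministic per-class split of a manifest.

    Classes are processed in vocabulary order; within each class the
    records are shuffled with a generator seeded from ``spec.seed`` and
    dealt train/val/test by the floor rule. With ``group_aware`` whole
    groups are packed greedily toward the target counts instead, so no
    wound leaks across subsets (achieved counts are reported in ``meta``).
    """
    nonzero = sum(1 for f in spec.fractions if f > 0)
    rng = np.random.default_rng(spec.seed)
    parts: dict[str, list[SampleRecord]] = {"train": [], "val": [], "test": []}
    per_class_counts: dict[str, dict[str, int]] = {}

    for cls in manifest.classes:
        cls_records = [r for r in manifest.records if r.label == cls]
        n = len(cls_records)
        if n == 0:
            continue
        if n < nonzero:
            raise ManifestError(
                f"class {cls} has only {n} record(s) for {nonzero} non-empty subsets; "
                "merge it with another class or drop it"
            )
        targets = floor_counts(n, spec.fractions)
        if spec.group_aware:
            if any(not r.group_id for r in cls_records):
                raise ManifestError(f"group_aware split requires group_id on every record (class {cls})")
            assigned = _pack_groups(cls_records, targets, rng)
        else:
            order = rng.permutation(n)
            shuffled = [cls_records[i] for i in order]
            assigned = {
                "train": shuffled[: targets[0]],
                "val": shuffled[targets[0] : targets[0] + targets[1]],
                "test": shuffled[targets[0] + targets[1] :],
            }
        for key in parts:
            parts[key].extend(assigned[key])
        per_class_counts[cls] = {k: len(v) for k, v in assigned.items()}

    meta = {
        "seed": spec.seed,
        "fractions": list(spec.fractions),
        "group_aware": spec.group_aware,
        "per_class_counts": per_class_counts,
    }
    return DatasetSplit(
        Manifest(parts["train"], manifest.classes),
        Manifest(parts["val"], manifest.classes),
        Manifest(parts["test"], manifest.classes),
        meta,
    )


def _pack_groups(records: list[SampleRecord], targets: tuple[int, int, int], rng) -> dict:
    """Greedy packing of whole groups, minimizing deviation from targets."""
    groups: dict[str, list[SampleRecord]] = {}
    for r in records:
        groups.setdefault(r.group_id, []).append(r)
    names = sorted(groups)
    order = rng.permutation(len(names))
    # largest groups first for tighter packing, seeded order breaks ties
    ranked = sorted((names[i] for i in order), key=lambda g: -len(groups[g]))
    keys = ("train", "val", "test")
    assigned: dict[str, list[SampleRecord]] = {k: [] for k in keys}
    filled = [0, 0, 0]
    for g in ranked:
        deficits = [targets[j] - filled[j] for j in range(3)]
        j = int(np.argmax(deficits))
        assigned[keys[j]].extend(groups[g])
        filled[j] += len(groups[g])
    return assigned


def write_split(split: DatasetSplit, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("train", "val", "test"):
        write_manifest(getattr(split, name), out / f"{name}.csv")
    (out / "split.json").write_text(json.dumps(split.meta, indent=2))


# ---------------------------------------------------------------------------
# Cross-validation

def make_cv_folds(manifest: Manifest, k: int, seed: int = 0) -> list[tuple[Manifest, Manifest]]:
    """Stratified k-fold partition: k (train, test) manifest pairs.

    Test folds are pairwise disjoint and union to the manifest; with k=5
    each pair is an 80-20 split per class (up to remainders).
    """
    if k < 2:
        raise ManifestError("k must be at least 2")
    counts = manifest.class_counts()
    small = {c: n for c, n in counts.items() if 0 < n < k}
    if small:
        raise ManifestError(f"class(es) with fewer than k={k} records: {small}")
    y = manifest.label_indices()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    folds = []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        folds.append(
            (
                Manifest([manifest.records[i] for i in train_idx], manifest.classes),
                Manifest([manifest.records[i] for i in test_idx], manifest.classes),
            )
        )
    return folds
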