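"""Balanced labelled feature sets and stratified train/validation/test splits.

Every ground-truth (mask-positive) pixel across the image corpus is
featurized with label C1; an equal number of negative pixels is sampled
uniformly without replacement from the remaining pixels of the cropped
regions, labelled C0, so the full set F_T is exactly class-balanced.
The set is then split 70/20/10 per class with a seeded shuffle, which keeps
the balance exact inside each split.

Feature tables are pandas DataFrames with columns f1..f14 plus the debug
columns label, x, y, source; the debug columns travel with the splits but
are never fed to a model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, GaussianWindow, extract_features, gaussian_window
from .imageprep import GreyImage

__all__ = ["LabelledSet", "DataSplit", "collect_features", "split"]

META_COLUMNS = ["label", "x", "y", "source"]


@dataclass(frozen=True)
class LabelledSet:
    """A balanced feature table; label 1 = hippocampal (C1), 0 = background (C0)."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in FEATURE_COLUMNS + META_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        keys = self.table[["source", "x", "y"]]
        if keys.duplicated().any():
            raise ValueError("duplicate (source, x, y) entries in feature set")

    @property
    def n_c1(self) -> int:
        return int((self.table["label"] == 1).sum())

    @property
    def n_c0(self) -> int:
        return int((self.table["label"] == 0).sum())

    def __len__(self) -> int:
        return len(self.table)

    def X(self, n_features: int = 14) -> np.ndarray:
        """Model inputs only (first n_features columns); debug columns excluded."""
        return self.table[FEATURE_COLUMNS[:n_features]].to_numpy(dtype=np.float64)

    def y(self) -> np.ndarray:
        return self.table["label"].to_numpy(dtype=np.int64)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabelledSet":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class DataSplit:
    """Stratified D_TN / D_VL / D_TS partition of a labelled set."""

    train: LabelledSet
    validation: LabelledSet
    test: LabelledSet
    seed: int
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, part in [
            ("train", self.train),
            ("validation", self.validation),
            ("test", self.test),
        ]:
            part.to_csv(out / f"{name}.csv")
        manifest = {
            "seed": self.seed,
            "fractions": list(self.fractions),
            "counts": {
                "train": len(self.train),
                "validation": len(self.validation),
                "test": len(self.test),
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, out_dir: str | Path) -> "DataSplit":
        out = Path(out_dir)
        manifest = json.loads((out / "manifest.json").read_text())
        return cls(
            train=LabelledSet.from_csv(out / "train.csv"),
            validation=LabelledSet.from_csv(out / "validation.csv"),
            test=LabelledSet.from_csv(out / "test.csv"),
            seed=manifest["seed"],
            fractions=tuple(manifest["fractions"]),
        )


def collect_features(
    images: list[tuple[GreyImage, GreyImage, np.ndarray, str]],
    seed: int,
    G: GaussianWindow | None = None,
    per_image_balance: bool = False,
) -> LabelledSet:
    """Build the balanced set F_T = F_H + F_O from (I_HE, I_NV, mask, source) tuples.

    All mask-positive pixels are featurized with label C1. An equal total
    number of mask-negative pixels is drawn uniformly without replacement —
    by default pooled across all images jointly; with ``per_image_balance``
    each image contributes as many negatives as it has positives.
    """
    G = G or gaussian_window()
    rng = np.random.default_rng(seed)
    frames: list[pd.DataFrame] = []
    neg_pools: list[tuple[int, np.ndarray, np.ndarray]] = []  # (image idx, xs, ys)
    n_pos_total = 0
    pos_per_image: list[int] = []

    for i, (ihe, inv, mask, source) in enumerate(images):
        mask = np.asarray(mask).astype(bool)
        if mask.shape != ihe.pixels.shape:
            raise ValueError(f"mask shape {mask.shape} != image shape for {source!r}")
        ys, xs = np.nonzero(mask)
        pos_per_image.append(len(xs))
        n_pos_total += len(xs)
        if len(xs):
            F = extract_features(ihe, inv, xs, ys, G=G)
            frames.append(_frame(F, 1, xs, ys, source))
        nys, nxs = np.nonzero(~mask)
        neg_pools.append((i, nxs, nys))

    if n_pos_total == 0:
        raise ValueError("no positive pixels in any mask")

    # negative sampling, uniform without replacement
    if per_image_balance:
        picks = []
        for (i, nxs, nys), n_want in zip(neg_pools, pos_per_image):
            if len(nxs) < n_want:
                raise ValueError(
                    f"image {images[i][3]!r} has {len(nxs)} negatives < {n_want} needed"
                )
            sel = rng.choice(len(nxs), size=n_want, replace=False)
            picks.append((i, nxs[sel], nys[sel]))
    else:
        sizes = np.array([len(nxs) for _, nxs, _ in neg_pools])
        total_neg = int(sizes.sum())
        if total_neg < n_pos_total:
            raise ValueError(f"only {total_neg} negative pixels for {n_pos_total} positives")
        flat = rng.choice(total_neg, size=n_pos_total, replace=False)
        flat.sort()
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        picks = []
        for k, (i, nxs, nys) in enumerate(neg_pools):
            local = flat[(flat >= bounds[k]) & (flat < bounds[k + 1])] - bounds[k]
            if len(local):
                picks.append((i, nxs[local], nys[local]))

    for i, xs, ys in picks:
        ihe, inv, _, source = images[i]
        F = extract_features(ihe, inv, xs, ys, G=G)
        frames.append(_frame(F, 0, xs, ys, source))

    table = pd.concat(frames, ignore_index=True)
    return LabelledSet(table)


def _frame(F: np.ndarray, label: int, xs, ys, source: str) -> pd.DataFrame:
    df = pd.DataFrame(F, columns=FEATURE_COLUMNS)
    df["label"] = label
    df["x"] = np.asarray(xs, dtype=np.int64)
    df["y"] = np.asarray(ys, dtype=np.int64)
    df["source"] = source
    return df


def split(
    data: LabelledSet,
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> DataSplit:
    """Stratified seeded split: per class floor(0.7 n) / floor(0.2 n) / remainder."""
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    parts: dict[str, list[pd.DataFrame]] = {"train": [], "validation": [], "test": []}
    for label in (1, 0):
        cls_rows = data.table.index[data.table["label"] == label].to_numpy()
        n = len(cls_rows)
        if n < 10:
            raise ValueError(f"need >= 10 features per class, class {label} has {n}")
        order = rng.permutation(n)
        n_tn = int(np.floor(fractions[0] * n))
        n_vl = int(np.floor(fractions[1] * n))
        parts["train"].append(data.table.loc[cls_rows[order[:n_tn]]])
        parts["validation"].append(data.table.loc[cls_rows[order[n_tn : n_tn + n_vl]]])
        parts["test"].append(data.table.loc[cls_rows[order[n_tn + n_vl :]]])
    sets = {
        k: LabelledSet(pd.concat(v, ignore_index=True)) for k, v in parts.items()
    }
    return DataSplit(
        train=sets["train"],
        validation=sets["validation"],
        test=sets["test"],
        seed=seed,
        fractions=tuple(fractions),
    )
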