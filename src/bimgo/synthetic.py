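"""Synthetic labeled tabular data with known informative-feature ground truth.

Emulates the structure of UCI-style binary-labeled medical tables so the
feature-selection engine can be validated without downloads: a handful of
informative columns carry a Gaussian class-conditional mean shift, optional
redundant columns are noisy positive mixtures of the informative ones, the
rest is pure standard-normal noise, and missing cells can be sprinkled in
uniformly. Because the signal is a mean shift, "informative" is unambiguous
ground truth for recall-style recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .binary_fs import FeatureDataset

import pandas as pd

__all__ = ["SyntheticSpec", "generate", "write_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    ``effect_size`` is the class-mean separation of each informative column in
    units of its (unit) noise SD: class 0 sits at -effect_size/2, class 1 at
    +effect_size/2. Redundant columns mix the informative block with uniform
    (0.5, 1.5) weights plus SD-0.1 noise. ``class_balance`` is the fraction of
    positive (label 1) instances.
    """

    n_instances: int = 300
    n_features: int = 50
    n_informative: int = 5
    effect_size: float = 2.0
    n_redundant: int = 0
    class_balance: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValueError("informative + redundant exceeds n_features")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must be in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_instances < 4:
            raise ValueError("need at least 4 instances")


def generate(spec: SyntheticSpec) -> tuple[FeatureDataset, np.ndarray]:
    """Draw one dataset; returns it with the informative column indices.

    Fully deterministic in ``spec.seed``. Labels use exact class counts (the
    positive count is round(n * class_balance), clamped so both classes keep
    at least two members) in a seeded shuffle. Missing cells are inserted
    uniformly at ``missing_rate`` and median-imputed, with the sites recorded
    in the dataset's ``missing_mask``.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_instances, spec.n_features
    n_pos = int(round(n * spec.class_balance))
    n_pos = min(max(n_pos, 2), n - 2)
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    matrix = rng.standard_normal((n, p))
    shift = np.where(labels == 1, spec.effect_size / 2.0, -spec.effect_size / 2.0)
    informative = np.arange(spec.n_informative)
    matrix[:, informative] += shift[:, None]
    if spec.n_redundant:
        red = np.arange(spec.n_informative, spec.n_informative + spec.n_redundant)
        weights = rng.uniform(0.5, 1.5, size=(spec.n_informative, spec.n_redundant))
        matrix[:, red] = (
            matrix[:, informative] @ weights + 0.1 * rng.standard_normal((n, spec.n_redundant))
        )

    mask = np.zeros((n, p), dtype=bool)
    if spec.missing_rate > 0.0:
        mask = rng.random((n, p)) < spec.missing_rate
        # keep every column partially observed so the median is defined
        full = mask.all(axis=0)
        mask[0, full] = False
        holes = matrix.copy()
        holes[mask] = np.nan
        med = np.nanmedian(holes, axis=0)
        matrix = np.where(mask, med[None, :], matrix)

    dataset = FeatureDataset(
        matrix=matrix,
        labels=labels,
        feature_names=[f"x{j}" for j in range(p)],
        missing_mask=mask,
        positive_class=1,
    )
    return dataset, informative


def write_fixture(
    dataset: FeatureDataset,
    path: Union[str, Path],
    dialect: str = "csv",
) -> Path:
    """Serialize a dataset so ``load_dataset`` round-trips it.

    Imputed cells (per ``missing_mask``) are written back out as missing —
    empty fields in CSV, ``?`` in ARFF — so a reload re-imputes to the same
    matrix. The label column is named ``label``.
    """
    path = Path(path)
    n, p = dataset.matrix.shape
    if dialect == "csv":
        df = pd.DataFrame(dataset.matrix, columns=dataset.feature_names)
        df = df.astype(object)
        df[dataset.missing_mask] = np.nan
        df["label"] = dataset.labels
        df.to_csv(path, index=False)
    elif dialect == "arff":
        with open(path, "w") as fh:
            fh.write("@RELATION synthetic\n\n")
            for name in dataset.feature_names:
                fh.write(f"@ATTRIBUTE {name} NUMERIC\n")
            classes = sorted({str(c) for c in np.unique(dataset.labels)})
            fh.write(f"@ATTRIBUTE label {{{','.join(classes)}}}\n\n@DATA\n")
            for i in range(n):
                cells = [
                    "?" if dataset.missing_mask[i, j] else repr(float(dataset.matrix[i, j]))
                    for j in range(p)
                ]
                cells.append(str(dataset.labels[i]))
                fh.write(",".join(cells) + "\n")
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    return path
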