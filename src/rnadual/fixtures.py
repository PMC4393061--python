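"""Synthetic feature data and label fixtures.

The verified/unclassified status of individual topologies lives in an
external curated database and is not redistributed here, so every
stage that needs labels is exercised with synthetic stand-ins:

* :func:`make_gaussian_classes` draws isotropic Gaussian point clouds
  at a controlled mean separation — the geometry the one-class
  algorithm assumes (a compact positive class, possibly a second class
  some standard deviations away);
* :func:`make_label_fixture` marks a seeded random subset of a catalog
  as "verified", mimicking the *count* of verified structures without
  claiming their identities.

All outputs carry a ``synthetic_labels`` flag so downstream reports
cannot be mistaken for database-derived conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enumeration import DualGraphCatalog
from .features import FeatureMatrix

__all__ = ["FixtureSpec", "make_gaussian_classes", "make_label_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic labeled feature matrix.

    ``separation`` is the shift between consecutive class means in
    every feature, in units of the isotropic noise scale ``sigma`` —
    i.e. classes are ``separation`` standard deviations apart per
    descriptor, the same per-descriptor scale on which the package
    standardizes real descriptor panels.
    """

    n_classes: int = 2
    per_class: int = 100
    dimensions: int = 20
    separation: float = 6.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1 or self.per_class < 1 or self.dimensions < 1:
            raise ValueError("counts must be positive")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


def make_gaussian_classes(spec: FixtureSpec) -> tuple[FeatureMatrix, pd.Series]:
    """Isotropic Gaussian classes at the specified separation.

    Consecutive class means differ by ``separation * sigma`` in every
    feature, with a random sign pattern per feature so classes do not
    all lie along the all-ones diagonal.  Returns a FeatureMatrix (ids
    ``c<k>_<i>``) and a label Series mapping id to class index; both
    seed-reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    direction = rng.integers(0, 2, size=spec.dimensions) * 2 - 1
    rows, ids, labels = [], [], []
    for k in range(spec.n_classes):
        mean = direction * (k * spec.separation * spec.sigma)
        pts = rng.normal(loc=mean, scale=spec.sigma, size=(spec.per_class, spec.dimensions))
        rows.append(pts)
        ids += [f"c{k}_{i}" for i in range(spec.per_class)]
        labels += [k] * spec.per_class
    values = pd.DataFrame(
        np.vstack(rows), index=ids,
        columns=[f"f{j}" for j in range(spec.dimensions)],
    )
    label_series = pd.Series(labels, index=ids, name="class")
    label_series.attrs["synthetic_labels"] = True
    return FeatureMatrix(values=values), label_series


def make_label_fixture(catalog: DualGraphCatalog, n_verified: int, seed: int) -> pd.Series:
    """Seeded random "verified"/"unclassified" labeling of a catalog.

    A stand-in for a curated verified set: the split size can mirror
    the real database counts, but the member identities are synthetic.
    """
    if not 0 <= n_verified <= len(catalog):
        raise ValueError(
            f"n_verified={n_verified} out of range for catalog of {len(catalog)}"
        )
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(len(catalog), size=n_verified, replace=False).tolist())
    labels = pd.Series(
        ["verified" if i in chosen else "unclassified" for i in range(len(catalog))],
        index=list(catalog.ids),
        name="class",
    )
    labels.attrs["synthetic_labels"] = True
    return labels
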