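"""Feature matrices, reference-class normalization, and screening.

Descriptor values computed on the enumerated topologies are compared
against a *reference class*: the subset of graphs verified as real RNA
structures.  Each descriptor is standardized against the reference
class,

    I_normalized = (I_observed - mean_ref) / stdev_ref,

so that the reference class has mean 0 and standard deviation 1 per
descriptor and every other graph is expressed in reference standard
deviations.  A descriptor whose reference values are constant carries
no information on this scale and is dropped with a warning.

Screening asks whether the non-reference graphs even leave the central
band of the reference distribution: a descriptor for which all
candidate values fall between the reference's 10th and 90th percentiles
cannot discriminate and is a poor input to any classifier; the
rank-based ROC AUC of a single descriptor makes the same point on a
[0, 1] scale (0.5 = uninformative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "FeatureMatrix",
    "NormalizationStats",
    "normalize",
    "percentile_band",
    "single_descriptor_auc",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Graphs-by-descriptors value table with missing-cell flags.

    ``values`` is a float DataFrame (rows = graph ids, columns =
    descriptor names); missing cells are NaN and additionally flagged
    in the boolean ``missing`` mask so that a true NaN value can never
    be confused with an uncomputed one.  ``reference_ids`` designates
    the verified (RNA) class.
    """

    values: pd.DataFrame
    missing: pd.DataFrame = None  # type: ignore[assignment]
    reference_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.missing is None:
            object.__setattr__(self, "missing", self.values.isna())
        if self.values.index.has_duplicates:
            raise ValueError("duplicate graph ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate descriptor names")
        unknown = set(self.reference_ids) - set(self.values.index)
        if unknown:
            raise ValueError(f"reference ids not in matrix: {sorted(unknown)}")

    @property
    def graph_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    def reference_values(self) -> pd.DataFrame:
        return self.values.loc[list(self.reference_ids)]

    def nonreference_ids(self) -> list[str]:
        ref = set(self.reference_ids)
        return [g for g in self.values.index if g not in ref]

    def with_reference(self, reference_ids) -> "FeatureMatrix":
        return replace(self, reference_ids=tuple(reference_ids))


@dataclass(frozen=True)
class NormalizationStats:
    """Per-descriptor reference mean/stdev used in the standardization."""

    mean: pd.Series
    stdev: pd.Series
    ddof: int
    excluded: tuple[str, ...] = ()  # constant-over-reference descriptors


def normalize(fm: FeatureMatrix, *, ddof: int = 1) -> tuple[FeatureMatrix, NormalizationStats]:
    """Standardize every descriptor against the reference class.

    ``ddof=1`` (sample standard deviation) is the default; ``ddof=0``
    selects the population convention.  Descriptors with zero reference
    standard deviation are excluded from the output with a warning —
    they cannot be scaled and are non-informative for screening.
    """
    if not fm.reference_ids:
        raise ValueError("reference class is empty; designate reference_ids first")
    ref = fm.reference_values()
    mean = ref.mean()
    stdev = ref.std(ddof=ddof)
    constant = [c for c in fm.values.columns if not stdev[c] > 0]
    if constant:
        warnings.warn(
            "descriptors constant over the reference class excluded from "
            f"normalization: {constant}",
            UserWarning,
            stacklevel=2,
        )
    keep = [c for c in fm.values.columns if c not in set(constant)]
    normed = (fm.values[keep] - mean[keep]) / stdev[keep]
    stats = NormalizationStats(
        mean=mean[keep], stdev=stdev[keep], ddof=ddof, excluded=tuple(constant)
    )
    out = FeatureMatrix(
        values=normed,
        missing=fm.missing[keep],
        reference_ids=fm.reference_ids,
    )
    return out, stats


def percentile_band(
    fm: FeatureMatrix, lower: float = 0.1, upper: float = 0.9
) -> pd.DataFrame:
    """Reference percentile band and the candidates that escape it.

    For each descriptor, the [lower, upper] percentile interval of the
    reference-class values (linear interpolation between order
    statistics) and the count/fraction of non-reference graphs falling
    strictly outside it.  A fraction of 0 marks a non-discriminating
    descriptor: every candidate looks like the reference class.
    """
    if lower >= upper:
        raise ValueError(f"lower percentile {lower} must be < upper {upper}")
    ref = fm.reference_values()
    other = fm.values.loc[fm.nonreference_ids()]
    rows = []
    for name in fm.descriptor_names:
        rv = ref[name].dropna().to_numpy()
        lo, hi = np.percentile(rv, [100 * lower, 100 * upper])
        ov = other[name].dropna().to_numpy()
        outside = int(np.sum((ov < lo) | (ov > hi)))
        rows.append(
            {
                "descriptor": name,
                "band_low": lo,
                "band_high": hi,
                "n_candidates": len(ov),
                "n_outside": outside,
                "fraction_outside": outside / len(ov) if len(ov) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("descriptor")


def single_descriptor_auc(fm: FeatureMatrix, descriptor: str, labels: pd.Series) -> float:
    """Rank-based ROC AUC of one descriptor as a two-group separator.

    ``labels`` maps graph id to 0/1 (or boolean); ties are handled by
    midranks.  0.5 means the descriptor carries no ordering information
    about the groups.
    """
    y = labels.reindex(fm.values.index).astype(int)
    if y.nunique() < 2:
        raise ValueError("need both label groups to compute an AUC")
    scores = fm.values[descriptor]
    ok = scores.notna()
    return float(roc_auc_score(y[ok], scores[ok]))
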