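"""Expression-level filtering and normalization.

Entry criteria for all downstream statistics: features are kept when
their median raw count across *all* samples is strictly above the
threshold (default 50), libraries are scaled by median-of-ratios size
factors, and CPM is provided for presentation-level summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

__all__ = ["SizeFactors", "FilterReport", "filter_by_median", "size_factors", "normalize", "cpm"]


@dataclass
class FilterReport:
    kept: list[str]
    dropped: list[str]
    threshold: float

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


class SizeFactors(pd.Series):
    """Per-sample positive scaling factors (a thin Series subclass)."""

    @property
    def _constructor(self):
        return SizeFactors


def filter_by_median(raw: CountMatrix, threshold: float = 50) -> tuple[CountMatrix, FilterReport]:
    """Keep features whose median raw count over all samples is > threshold.

    The bound is strict: a feature sitting exactly at the threshold is
    dropped.
    """
    if raw.kind != "raw":
        raise ValueError(f"median filter expects raw counts, got kind {raw.kind!r}")
    medians = raw.values.median(axis=1)
    keep = medians > threshold
    kept = CountMatrix(values=raw.values.loc[keep], kind="raw")
    report = FilterReport(
        kept=list(raw.values.index[keep]),
        dropped=list(raw.values.index[~keep]),
        threshold=threshold,
    )
    return kept, report


def size_factors(raw: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    The per-feature reference is the geometric mean across samples,
    computed only over features with all-positive counts; each sample's
    factor is the median of its count/reference ratios.
    """
    if raw.kind != "raw":
        raise ValueError("size factors are computed on raw counts")
    arr = raw.values.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "filter to well-expressed features before computing size factors"
        )
    sub = arr[allpos]
    log_ref = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    gm = float(np.exp(np.mean(np.log(factors))))
    if not 0.5 <= gm <= 2.0:
        warnings.warn(
            f"geometric mean of size factors is {gm:.3g}; libraries look unbalanced",
            stacklevel=2,
        )
    return SizeFactors(factors, index=raw.values.columns, name="size_factor")


def normalize(raw: CountMatrix, sf: SizeFactors) -> CountMatrix:
    """Divide each sample column by its size factor."""
    if list(sf.index) != list(raw.values.columns):
        sf = sf.reindex(raw.values.columns)
        if sf.isna().any():
            raise ValueError("size factors missing for some samples")
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    return CountMatrix(values=raw.values / sf, kind="normalized")


def cpm(counts: CountMatrix) -> CountMatrix:
    """Counts per million: value * 1e6 / column sum.

    Library sizes are the column totals of the matrix passed in, so the
    caller chooses whether CPM reflects pre- or post-filter totals.
    """
    totals = counts.values.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library size for samples: {bad[:5]}")
    return CountMatrix(values=counts.values * 1e6 / totals, kind="cpm")
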