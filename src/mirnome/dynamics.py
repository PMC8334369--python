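"""Nine-pattern gestational expression dynamics taxonomy.

Each miRNA gets an ordered pair of Up/Down/NoChange calls — one for the
first-to-second-trimester transition and one for second-trimester-to-term
— and pattern composition is cross-tabulated by genomic cluster.
"""

from __future__ import annotations

import itertools

import pandas as pd

from .io_formats import FeatureAnnotation
from .stats_core import TestResult, chi2_independence
from .diffexpr import classify_direction

DIRECTIONS = ("Down", "Up", "NoChange")


def pattern_label(first: str, second: str) -> str:
    return f"{first}-{second}"
PATTERNS = [pattern_label(a, b) for a, b in itertools.product(DIRECTIONS, DIRECTIONS)]
CATEGORIES = ("All", "C19MC", "C14MC", "miR371_373", "other")

__all__ = ["PATTERNS", "assign_pattern", "summarize_patterns", "compare_target_counts"]


def assign_pattern(
    de_t1_t2: pd.DataFrame, de_t2_term: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Label each miRNA with its (first transition, second transition) pattern.

    Both DE tables must cover the same feature set; features missing from
    either are an error, not silently dropped.
    """
    only_first = sorted(set(de_t1_t2.index) - set(de_t2_term.index))
    only_second = sorted(set(de_t2_term.index) - set(de_t1_t2.index))
    if only_first or only_second:
        raise ValueError(
            "DE tables cover different features; "
            f"only in first: {only_first[:5]}, only in second: {only_second[:5]}"
        )
    first = classify_direction(de_t1_t2, alpha=alpha)
    second = classify_direction(de_t2_term, alpha=alpha).reindex(first.index)
    out = pd.DataFrame(
        {
            "first_transition": first,
            "second_transition": second,
            "pattern": [pattern_label(a, b) for a, b in zip(first, second)],
        }
    )
    out.index.name = "feature_id"
    return out


def summarize_patterns(
    patterns: pd.DataFrame, annotation: FeatureAnnotation
) -> pd.DataFrame:
    """Cross-tabulate patterns against cluster categories with percentages.

    Returns one row per pattern, and an ``<category>_n`` / ``<category>_pct``
    column pair per category (All, C19MC, C14MC, miR371_373, other).
    Percentages in each category column sum to 100 (empty categories stay
    all-zero).
    """
    clusters = annotation.table["cluster"].reindex(patterns.index)
    if clusters.isna().any():
        missing = sorted(patterns.index[clusters.isna()])
        raise ValueError(f"annotation missing for features: {missing[:5]}")
    out = pd.DataFrame(index=pd.Index(PATTERNS, name="pattern"))
    for cat in CATEGORIES:
        mask = slice(None) if cat == "All" else (clusters == cat).to_numpy()
        sub = patterns.loc[mask, "pattern"] if cat != "All" else patterns["pattern"]
        counts = sub.value_counts().reindex(PATTERNS, fill_value=0)
        total = int(counts.sum())
        out[f"{cat}_n"] = counts
        out[f"{cat}_pct"] = 100.0 * counts / total if total else 0.0
    return out


def compare_target_counts(
    n_up_targets: int,
    n_down_targets: int,
    n_up_targets2: int,
    n_down_targets2: int,
) -> TestResult:
    """Chi-square independence test on the 2x2 table of target-gene counts
    for up- vs down-regulated miRNAs in the two transitions."""
    return chi2_independence(
        [[n_up_targets, n_down_targets], [n_up_targets2, n_down_targets2]]
    )
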