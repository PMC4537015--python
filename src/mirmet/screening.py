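"""Differential-expression screening of dCq profiles.

The screen compares two sample groups per miRNA with the Mann-Whitney rank
test, controls the false discovery rate with Benjamini-Hochberg, and then
applies two candidate-selection filters designed for qPCR panels with
detection dropout:

* missingness-asymmetry filter -- drop a significant miRNA that is
  undetected in some samples of *both* groups, unless the undetected count
  in one group is at least ``ratio`` (default 2) times the other's;
* quartile-separation filter -- keep a miRNA only when the first quartile
  of one group exceeds the third quartile of the other, i.e. the bulks of
  the two dCq distributions do not overlap.

Direction codes follow the dCq scale: a *larger* median dCq in group A
means the miRNA is *less* expressed there (``lower_in_group_a``).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qpcr import DeltaCqMatrix

LOWER_IN_A = "lower_in_group_a"
HIGHER_IN_A = "higher_in_group_a"

#: Exact Mann-Whitney null is used up to this combined sample size (no ties).
EXACT_MAX_N = 20

SCREEN_COLUMNS = [
    "mirna_id",
    "p_raw",
    "p_adj",
    "direction",
    "median_a",
    "median_b",
    "q1_a",
    "q3_a",
    "q1_b",
    "q3_b",
    "n_undetected_a",
    "n_undetected_b",
    "passes_missingness",
    "passes_quartile",
    "significant",
]


def rank_test(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two dCq samples.

    Uses the exact null distribution when the combined sample size is at
    most 20 and there are no ties, otherwise the normal approximation with
    tie and continuity corrections.  Returns ``(U, p)`` with U counted for
    the first sample.  Two identical groups give p = 1 (z = 0 under the
    continuity-corrected approximation).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0:
        # Every value tied: no evidence either way.
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= EXACT_MAX_N and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def missingness_filter(n_undetected_a: int, n_undetected_b: int, ratio: float = 2.0) -> bool:
    """Keep a miRNA unless it is undetected in some samples of both groups
    without a clear asymmetry.

    Returns True (keep) when at least one group has no undetected samples,
    or when the larger undetected count is at least ``ratio`` times the
    smaller; False (exclude) otherwise.
    """
    if n_undetected_a < 0 or n_undetected_b < 0:
        raise ValueError("undetected counts must be non-negative")
    lo, hi = sorted((n_undetected_a, n_undetected_b))
    if lo == 0:
        return True
    return hi >= ratio * lo


def quartile_separation_filter(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "linear",
) -> bool:
    """True when Q1 of one group strictly exceeds Q3 of the other.

    Quartiles use linear interpolation between order statistics (numpy's
    default, the "type 7" convention) unless another ``method`` accepted by
    :func:`numpy.percentile` is given.  The convention matters: PASS/FAIL
    can flip between estimators for small groups, so it is fixed here.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 4 or b.size < 4:
        raise ValueError("each group needs at least 4 values for quartiles")
    q1a, q3a = np.percentile(a, [25, 75], method=method)
    q1b, q3b = np.percentile(b, [25, 75], method=method)
    return bool(q1a > q3b or q1b > q3a)


def direction_from_medians(median_a: float, median_b: float) -> str:
    """Direction code from group median dCq values.

    Higher dCq = lower expression, so ``median_a > median_b`` reads
    "lower in group A".  An exact tie is reported as ``higher_in_group_a``
    by convention (it cannot occur for a significant record).
    """
    return LOWER_IN_A if median_a > median_b else HIGHER_IN_A


def _vectorised_asymptotic_p(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Mann-Whitney p, normal approximation with tie and
    continuity corrections; rows with zero spread get p = 1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.mannwhitneyu(
            A, B, alternative="two-sided", method="asymptotic", use_continuity=True, axis=-1
        )
        p = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    flat = np.ptp(np.concatenate([A, B], axis=1), axis=1) == 0
    p[flat | ~np.isfinite(p)] = 1.0
    return p


def screen(
    delta_cq: DeltaCqMatrix,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    apply_filters: bool = True,
    group_col: str = "group",
    group_a: str | None = None,
    missingness_ratio: float = 2.0,
    quartile_method: str = "linear",
) -> pd.DataFrame:
    """Screen every miRNA for differential expression between two groups.

    ``metadata`` (indexed by sample id) must define exactly two groups among
    the matrix samples; ``group_a`` picks which one is "group A" (default:
    first group in metadata order).  Returns one record per miRNA with raw
    and BH-adjusted p, direction, group medians/quartiles, undetected
    counts and the two filter flags, sorted by adjusted p then id.
    Filter flags are evaluated only for significant records (NA elsewhere);
    imputed (ceiling) values take part in both the test and the quartiles.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    samples = [s for s in delta_cq.sample_ids if s in metadata.index]
    groups = metadata.loc[samples, group_col]
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, found {levels}")
    if group_a is None:
        group_a = levels[0]
    elif group_a not in levels:
        raise ValueError(f"group_a {group_a!r} not among {levels}")
    group_b = next(g for g in levels if g != group_a)
    cols_a = [s for s in samples if groups[s] == group_a]
    cols_b = [s for s in samples if groups[s] == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")

    A = delta_cq.values[cols_a].to_numpy(dtype=float)
    B = delta_cq.values[cols_b].to_numpy(dtype=float)
    n_total = A.shape[1] + B.shape[1]

    if n_total > EXACT_MAX_N:
        p_raw = _vectorised_asymptotic_p(A, B)
    else:
        p_raw = np.array([rank_test(A[i], B[i])[1] for i in range(A.shape[0])])

    p_adj = adjust_bh(p_raw)
    med_a = np.median(A, axis=1)
    med_b = np.median(B, axis=1)
    q1a, q3a = np.percentile(A, [25, 75], axis=1, method=quartile_method)
    q1b, q3b = np.percentile(B, [25, 75], axis=1, method=quartile_method)
    und_a = (~delta_cq.detected[cols_a]).sum(axis=1).to_numpy()
    und_b = (~delta_cq.detected[cols_b]).sum(axis=1).to_numpy()
    significant = p_adj < alpha

    records = pd.DataFrame(
        {
            "mirna_id": delta_cq.mirna_ids,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": [direction_from_medians(x, y) for x, y in zip(med_a, med_b)],
            "median_a": med_a,
            "median_b": med_b,
            "q1_a": q1a,
            "q3_a": q3a,
            "q1_b": q1b,
            "q3_b": q3b,
            "n_undetected_a": und_a,
            "n_undetected_b": und_b,
            "passes_missingness": pd.array([pd.NA] * len(med_a), dtype="boolean"),
            "passes_quartile": pd.array([pd.NA] * len(med_a), dtype="boolean"),
            "significant": significant,
        }
    )
    if apply_filters:
        for i in np.flatnonzero(significant):
            records.loc[i, "passes_missingness"] = missingness_filter(
                int(und_a[i]), int(und_b[i]), ratio=missingness_ratio
            )
            if min(len(cols_a), len(cols_b)) >= 4:
                records.loc[i, "passes_quartile"] = quartile_separation_filter(
                    A[i], B[i], method=quartile_method
                )
    records = records.sort_values(["p_adj", "mirna_id"], kind="mergesort").reset_index(drop=True)
    records.attrs["group_a"] = group_a
    records.attrs["group_b"] = group_b
    records.attrs["alpha"] = alpha
    return records


def selected_candidates(records: pd.DataFrame) -> pd.DataFrame:
    """Subset of screen records that are significant and pass both filters."""
    mask = (
        records["significant"]
        & records["passes_missingness"].fillna(False).astype(bool)
        & records["passes_quartile"].fillna(False).astype(bool)
    )
    return records[mask].reset_index(drop=True)
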