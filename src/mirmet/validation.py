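"""Cross-set confirmation, paired-sample testing and candidate intersection.

A candidate miRNA from the discovery screen is *confirmed* when it is also
significant in an independent validation set (rank test, BH adjustment
across the candidate panel) with the same direction of change.  Paired
metastasis/primary samples from the same patients are analysed with a
one-sample t test on within-pair dCq differences (a rank-based alternative
is available behind a flag).  Named candidate sets can finally be
intersected to nominate the miRNAs consistent across all analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .qpcr import DeltaCqMatrix
from .screening import HIGHER_IN_A, LOWER_IN_A, adjust_bh, rank_test


def confirm_in_validation(
    discovery: pd.DataFrame,
    validation_delta_cq: DeltaCqMatrix,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    group_col: str = "group",
    group_a: str | None = None,
) -> pd.DataFrame:
    """Re-test discovery candidates in an independent sample set.

    ``discovery`` is a screen-record table restricted to the candidate
    panel.  Each candidate is rank-tested on the validation dCq values and
    BH-adjusted *across the panel only*; it is confirmed iff the adjusted p
    is below ``alpha`` and the direction matches discovery.
    """
    candidates = list(discovery["mirna_id"])
    missing = [m for m in candidates if m not in validation_delta_cq.values.index]
    if missing:
        raise KeyError(f"candidates absent from validation matrix: {missing}")

    samples = [s for s in validation_delta_cq.sample_ids if s in metadata.index]
    groups = metadata.loc[samples, group_col]
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, found {levels}")
    if group_a is None:
        group_a = levels[0]
    cols_a = [s for s in samples if groups[s] == group_a]
    cols_b = [s for s in samples if groups[s] != group_a]

    p_raw, directions = [], []
    for m in candidates:
        a = validation_delta_cq.values.loc[m, cols_a].to_numpy(dtype=float)
        b = validation_delta_cq.values.loc[m, cols_b].to_numpy(dtype=float)
        _, p = rank_test(a, b)
        p_raw.append(p)
        directions.append(LOWER_IN_A if np.median(a) > np.median(b) else HIGHER_IN_A)
    p_adj = adjust_bh(p_raw)

    disc_p = discovery.set_index("mirna_id")["p_adj"]
    disc_dir = discovery.set_index("mirna_id")["direction"]
    out = pd.DataFrame(
        {
            "mirna_id": candidates,
            "p_discovery": [disc_p[m] for m in candidates],
            "p_validation_raw": p_raw,
            "p_validation": p_adj,
            "direction_discovery": [disc_dir[m] for m in candidates],
            "direction_validation": directions,
        }
    )
    out["confirmed"] = (
        (out["p_validation"] < alpha)
        & (out["p_discovery"] < alpha)
        & (out["direction_discovery"] == out["direction_validation"])
    )
    return out.sort_values(["p_validation", "mirna_id"], kind="mergesort").reset_index(drop=True)


def paired_test(
    paired_delta_cq: DeltaCqMatrix,
    metadata: pd.DataFrame,
    group_col: str = "group",
    pair_col: str = "pair_id",
    group_a: str | None = None,
    method: str = "t",
) -> pd.DataFrame:
    """Within-pair differential expression across matched sample pairs.

    Differences are dCq(group A member) - dCq(group B member) per pair, so
    a positive mean difference means lower expression in group A.  The
    default test is the two-sided one-sample t; ``method="wilcoxon"``
    switches to the signed-rank test.  Zero-variance differences are
    guarded: all-zero gives p = 1 and no direction; constant non-zero gives
    an infinite t and p = 0.  BH adjustment is applied across miRNAs and
    both raw and adjusted p are reported.
    """
    if method not in ("t", "wilcoxon"):
        raise ValueError("method must be 't' or 'wilcoxon'")
    samples = [s for s in paired_delta_cq.sample_ids if s in metadata.index]
    meta = metadata.loc[samples]
    groups = meta[group_col]
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, found {levels}")
    if group_a is None:
        group_a = levels[0]
    pairs: dict[str, dict[str, str]] = {}
    for s in samples:
        pid = meta.loc[s, pair_col]
        if pid in ("", None) or pd.isna(pid):
            raise ValueError(f"sample {s!r} has no pair id")
        pairs.setdefault(pid, {})[groups[s]] = s
    incomplete = [pid for pid, members in pairs.items() if len(members) != 2]
    if incomplete:
        raise ValueError(f"incomplete pairs: {incomplete}")
    if len(pairs) < 2:
        raise ValueError("need at least 2 complete pairs")

    cols_a = [members[group_a] for members in pairs.values()]
    cols_b = [members[next(g for g in levels if g != group_a)] for members in pairs.values()]
    D = (
        paired_delta_cq.values[cols_a].to_numpy(dtype=float)
        - paired_delta_cq.values[cols_b].to_numpy(dtype=float)
    )

    mean_diff = D.mean(axis=1)
    sd = D.std(axis=1, ddof=1)
    n = D.shape[1]
    stat = np.zeros(len(mean_diff))
    p_raw = np.ones(len(mean_diff))
    for i in range(len(mean_diff)):
        if sd[i] == 0:
            if mean_diff[i] == 0:
                stat[i], p_raw[i] = 0.0, 1.0
            else:
                stat[i] = np.inf * np.sign(mean_diff[i])
                p_raw[i] = 0.0
        elif method == "t":
            res = stats.ttest_1samp(D[i], 0.0)
            stat[i], p_raw[i] = float(res.statistic), float(res.pvalue)
        else:
            res = stats.wilcoxon(D[i], alternative="two-sided")
            stat[i], p_raw[i] = float(res.statistic), float(res.pvalue)
    p_adj = adjust_bh(p_raw)
    direction = [
        None if d == 0 else (LOWER_IN_A if d > 0 else HIGHER_IN_A) for d in mean_diff
    ]
    return pd.DataFrame(
        {
            "mirna_id": paired_delta_cq.mirna_ids,
            "mean_paired_difference": mean_diff,
            "statistic": stat,
            "p_paired": p_raw,
            "p_paired_adj": p_adj,
            "direction": direction,
            "n_pairs": n,
        }
    )


@dataclass
class IntersectionReport:
    """Membership of each id in each named set, plus all k-way intersections."""

    membership: pd.DataFrame  # id x set booleans
    intersections: dict[tuple[str, ...], set[str]]

    def intersection(self, *names: str) -> set[str]:
        return self.intersections[tuple(sorted(names))]

    def provenance(self, item: str) -> list[str]:
        row = self.membership.loc[item]
        return list(row.index[row])


def intersect_candidates(sets: Mapping[str, Sequence[str] | set]) -> IntersectionReport:
    """All pairwise and k-way intersections of named miRNA id sets."""
    named = {name: set(ids) for name, ids in sets.items()}
    universe = sorted(set().union(*named.values())) if named else []
    membership = pd.DataFrame(
        {name: [i in ids for i in universe] for name, ids in named.items()},
        index=pd.Index(universe, name="mirna_id"),
        dtype=bool,
    )
    intersections: dict[tuple[str, ...], set[str]] = {}
    names = sorted(named)
    for k in range(2, len(names) + 1):
        for combo in combinations(names, k):
            acc = set(named[combo[0]])
            for name in combo[1:]:
                acc &= named[name]
            intersections[combo] = acc
    return IntersectionReport(membership, intersections)
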