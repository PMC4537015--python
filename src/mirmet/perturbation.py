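"""Inverse-modulation calling on mimic/inhibitor perturbation arrays.

A miRNA mimic over-expresses the miRNA and should push direct and indirect
targets *down*; an inhibitor suppresses it and should push them *up*.  A
probe is "specifically and inversely modified" when its mimic and inhibitor
contrasts (each versus its matched negative control) are sign-opposed
within each cell line, consistent across the two lines, significant under
an empirical-Bayes moderated t, and large enough in both arms.

With one array per condition per line there is no within-probe replication,
so the per-probe variance of the inverse-modulation effect (estimated
across the two cell lines, one residual degree of freedom) is shrunk
toward a scaled inverse-chi-square prior fitted across all probes -- the
moderation that makes a two-line design testable at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

DEFAULT_MIN_ABS_LFC = math.log2(1.5)

CONTRAST_COLUMNS = ["lfc_mimic_line1", "lfc_mimic_line2", "lfc_inhibitor_line1", "lfc_inhibitor_line2"]

REQUIRED_INPUT_COLUMNS = [
    "line1_mimic",
    "line1_mimic_ctrl",
    "line1_inhibitor",
    "line1_inhibitor_ctrl",
    "line2_mimic",
    "line2_mimic_ctrl",
    "line2_inhibitor",
    "line2_inhibitor_ctrl",
]


@dataclass(frozen=True)
class ModerationParams:
    """Scaled inverse-chi-square prior on per-probe variances.

    ``d0`` is the prior degrees of freedom (``math.inf`` when the observed
    variances show no over-dispersion beyond sampling noise, in which case
    every probe is assigned the common prior variance ``s0_sq``).
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_moderation(residual_variances, residual_df: int) -> ModerationParams:
    """Method-of-moments fit of the variance prior from per-probe sample
    variances with a common residual degree of freedom.

    Matches the mean and variance of log sample variances against the
    marginal implied by s^2 ~ s0^2 * F(df, d0).  When the spread of log
    variances does not exceed what sampling alone produces, the prior
    degrees of freedom are infinite and ``s0_sq`` is the mean variance (for
    identical inputs, exactly that value).  Zero variances are excluded
    from the log-moment fit.
    """
    v = np.asarray(residual_variances, dtype=float)
    if v.size < 10:
        raise ValueError("need at least 10 probes to fit the moderation prior")
    if residual_df < 1:
        raise ValueError("residual_df must be >= 1")
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise ValueError("variances must be finite and non-negative")
    if np.all(v == 0):
        raise ValueError("all variances are zero; nothing to moderate")
    if np.ptp(v) == 0:
        return ModerationParams(math.inf, float(v[0]))

    pos = v[v > 0]
    z = np.log(pos)
    emean = float(z.mean())
    evar = float(z.var(ddof=1)) - float(special.polygamma(1, residual_df / 2.0))
    if evar <= 0:
        return ModerationParams(math.inf, float(v.mean()))
    d0 = 2.0 * _trigamma_inverse(evar)
    log_s0 = (
        emean
        - float(special.digamma(residual_df / 2.0))
        + math.log(residual_df / 2.0)
        + float(special.digamma(d0 / 2.0))
        - math.log(d0 / 2.0)
    )
    return ModerationParams(d0, math.exp(log_s0))


def moderated_t(effect, variance, df: int, params: ModerationParams, n_eff: float = 1.0):
    """Moderated t statistic and two-sided p for per-probe effects.

    The posterior variance ``(d0*s0^2 + df*s^2) / (d0 + df)`` replaces the
    sample variance; the statistic is ``effect / sqrt(s_tilde^2 / n_eff)``
    and p comes from a t distribution with ``d0 + df`` degrees of freedom
    (normal when d0 is infinite).  ``d0 = 0`` reproduces the ordinary t.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    effect = np.asarray(effect, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if math.isinf(params.d0):
        s_tilde = np.full_like(variance, params.s0_sq)
        total_df = math.inf
    else:
        s_tilde = (params.d0 * params.s0_sq + df * variance) / (params.d0 + df)
        total_df = params.d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(s_tilde / n_eff)
    t = np.where(np.isnan(t), 0.0, t)
    if math.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    if np.ndim(effect) == 0:
        return float(t), float(p)
    return t, np.asarray(p)


def compute_contrasts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-probe condition-minus-matched-control log fold changes."""
    missing = [c for c in REQUIRED_INPUT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"perturbation table lacks columns: {missing}")
    if table.index.has_duplicates:
        raise ValueError("duplicate probe ids in perturbation table")
    out = pd.DataFrame(index=table.index)
    out["lfc_mimic_line1"] = table["line1_mimic"] - table["line1_mimic_ctrl"]
    out["lfc_mimic_line2"] = table["line2_mimic"] - table["line2_mimic_ctrl"]
    out["lfc_inhibitor_line1"] = table["line1_inhibitor"] - table["line1_inhibitor_ctrl"]
    out["lfc_inhibitor_line2"] = table["line2_inhibitor"] - table["line2_inhibitor_ctrl"]
    return out


def analyze_perturbation(table: pd.DataFrame, params: ModerationParams | None = None) -> pd.DataFrame:
    """Moderated inverse-modulation statistics for every probe.

    The per-probe effect is the inverse-modulation contrast
    ``(inhibitor_lfc - mimic_lfc) / 2`` averaged over the two cell lines;
    its variance across the lines (1 residual df) is moderated with a prior
    fitted across probes (or supplied via ``params``).
    """
    contrasts = compute_contrasts(table)
    d_line1 = (contrasts["lfc_inhibitor_line1"] - contrasts["lfc_mimic_line1"]) / 2.0
    d_line2 = (contrasts["lfc_inhibitor_line2"] - contrasts["lfc_mimic_line2"]) / 2.0
    D = np.column_stack([d_line1, d_line2])
    effect = D.mean(axis=1)
    s2 = D.var(axis=1, ddof=1)
    df = 1
    if params is None:
        params = fit_moderation(s2, df)
    t, p = moderated_t(effect, s2, df, params, n_eff=2.0)
    out = contrasts.copy()
    out["effect"] = effect
    out["t_moderated"] = t
    out["p"] = p
    out.attrs["moderation_d0"] = params.d0
    out.attrs["moderation_s0_sq"] = params.s0_sq
    return out


def call_inverse_modified(
    results: pd.DataFrame,
    alpha: float = 0.05,
    min_abs_lfc: float = DEFAULT_MIN_ABS_LFC,
) -> pd.DataFrame:
    """Flag probes specifically and inversely modified by mimic/inhibitor.

    A probe is flagged iff (i) mimic and inhibitor contrasts are strictly
    sign-opposed within each cell line, (ii) each arm's sign is consistent
    across lines, and (iii) the moderated p is below ``alpha`` with a mean
    absolute log fold change of at least ``min_abs_lfc`` in both arms.
    """
    missing = [c for c in CONTRAST_COLUMNS + ["p"] if c not in results.columns]
    if missing:
        raise ValueError(f"results table lacks columns: {missing}")
    out = results.copy()
    m1, m2 = out["lfc_mimic_line1"], out["lfc_mimic_line2"]
    i1, i2 = out["lfc_inhibitor_line1"], out["lfc_inhibitor_line2"]
    opposed = (np.sign(m1) == -np.sign(i1)) & (np.sign(m2) == -np.sign(i2)) & (m1 != 0) & (m2 != 0)
    consistent = (np.sign(m1) == np.sign(m2)) & (np.sign(i1) == np.sign(i2))
    mean_mimic = (m1 + m2) / 2.0
    mean_inhibitor = (i1 + i2) / 2.0
    big_enough = (mean_mimic.abs() >= min_abs_lfc) & (mean_inhibitor.abs() >= min_abs_lfc)
    out["mean_lfc_mimic"] = mean_mimic
    out["mean_lfc_inhibitor"] = mean_inhibitor
    out["inverse_modified"] = opposed & consistent & (out["p"] < alpha) & big_enough
    return out


def merge_with_de_genes(
    flagged: pd.DataFrame,
    de_genes: pd.DataFrame,
    gene_col: str = "gene_id",
    direction_col: str = "de_direction_in_metastasis",
) -> pd.DataFrame:
    """Merge inverse-modified probes with metastasis-vs-primary DE genes.

    Concordance encodes the suppression logic: a gene *up* in metastatic
    cells (where the miRNA is low) must also go *up* under the inhibitor
    and down under the mimic; a gene *down* in metastatic cells must go
    down under the inhibitor and up under the mimic.  Probe ids are matched
    to gene ids directly; duplicates in either table are rejected.
    """
    if flagged.index.has_duplicates:
        raise ValueError("duplicate probe ids in flagged table")
    if de_genes[gene_col].duplicated().any():
        raise ValueError("duplicate gene ids in DE table")
    bad = set(de_genes[direction_col]) - {"up_in_BM", "down_in_BM"}
    if bad:
        raise ValueError(f"unknown DE directions: {sorted(bad)}")
    merged = de_genes.set_index(gene_col).join(flagged, how="inner")
    up = merged[direction_col] == "up_in_BM"
    inh_up = merged["mean_lfc_inhibitor"] > 0
    mim_down = merged["mean_lfc_mimic"] < 0
    concordant_dir = np.where(up, inh_up & mim_down, (~inh_up) & (~mim_down))
    merged["concordant"] = merged["inverse_modified"].to_numpy(dtype=bool) & concordant_dir
    merged.index.name = gene_col
    return merged.reset_index()
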