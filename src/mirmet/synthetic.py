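"""Synthetic data with planted ground truth for every pipeline stage.

Three generators mirror the three experimental assays the pipeline
consumes:

* :func:`gen_cq_dataset` -- a stem-loop RT-qPCR card run: per-miRNA latent
  baselines (wide between-miRNA spread), a group shift of several cycles
  for planted true positives, replicate noise, and a logistic detection
  dropout in which weakly expressed (high-Cq) wells go undetected and are
  later imputed at the 40-cycle ceiling.  A low, stable U6 reference row is
  always included.
* :func:`gen_perturbation_dataset` -- mimic/inhibitor transfection arrays
  in two cell lines with matched negative controls; planted targets move
  down under the mimic and up under the inhibitor by the same log fold
  change.
* :func:`gen_sequences` -- random-background 3'UTRs with seed sites and
  AU-rich elements planted at recorded positions.

Every generator takes a seed and is byte-for-byte reproducible; truth
tables record exactly what was planted so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .qpcr import CqMatrix, DEFAULT_REFERENCE
from .screening import HIGHER_IN_A, LOWER_IN_A

RNA_ALPHABET = "ACGU"

PERTURBATION_COLUMNS = [
    "line1_mimic",
    "line1_mimic_ctrl",
    "line1_inhibitor",
    "line1_inhibitor_ctrl",
    "line2_mimic",
    "line2_mimic_ctrl",
    "line2_inhibitor",
    "line2_inhibitor_ctrl",
]

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults for the Cq generator.

    The defaults reproduce the discovery-screen design: 670 miRNAs, two
    groups of 12 samples, 20 planted positives shifted by 8 cycles, wide
    per-miRNA baseline heterogeneity (sd 3 cycles around 28), 2 cycles of
    replicate noise, and logistic dropout centred at Cq 35.
    """

    n_mirnas: int = 670
    n_group_a: int = 12
    n_group_b: int = 12
    n_true_positives: int = 20
    effect_delta_cq: float = 8.0
    baseline_cq_mean: float = 28.0
    baseline_cq_sd: float = 3.0
    noise_sd: float = 2.0
    dropout_cq50: float = 35.0
    dropout_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirnas", "n_group_a", "n_group_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_true_positives < 0 or self.n_true_positives > self.n_mirnas:
            raise ValueError("n_true_positives must lie in [0, n_mirnas]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 < self.dropout_cq50 <= 40:
            raise ValueError("dropout_cq50 must lie in (0, 40]")
        if self.dropout_slope < 0:
            raise ValueError("dropout_slope must be non-negative")


def _make_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    mirna_ids = [f"miR-{i:04d}" for i in range(1, config.n_mirnas + 1)]
    positives = rng.choice(config.n_mirnas, size=config.n_true_positives, replace=False)
    is_tp = np.zeros(config.n_mirnas, dtype=bool)
    is_tp[positives] = True
    directions = np.full(config.n_mirnas, None, dtype=object)
    # Planted direction on the expression scale; lower_in_A = +shift on Cq in A.
    directions[positives] = rng.choice([LOWER_IN_A, HIGHER_IN_A], size=config.n_true_positives)
    shift = np.where(is_tp, config.effect_delta_cq, 0.0)
    return pd.DataFrame(
        {
            "mirna_id": mirna_ids,
            "is_true_positive": is_tp,
            "true_direction": directions,
            "planted_shift": shift,
        }
    )


def _latent_group_shift(truth: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-miRNA Cq shift applied to groups A and B (cycles)."""
    shift_a = np.where(
        truth["true_direction"].to_numpy() == LOWER_IN_A, truth["planted_shift"], 0.0
    )
    shift_b = np.where(
        truth["true_direction"].to_numpy() == HIGHER_IN_A, truth["planted_shift"], 0.0
    )
    return shift_a, shift_b


def gen_cq_dataset(
    config: SimConfig,
    set_label: str = "discovery",
    truth: pd.DataFrame | None = None,
    group_a_label: str = "BM",
    group_b_label: str = "primary",
    paired: bool = False,
    sample_prefix: str | None = None,
) -> tuple[CqMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate one Cq dataset plus sample metadata and its truth table.

    Pass ``truth`` to reuse the planted-effect table from another set so
    that discovery, validation and paired sets share the same positives.
    With ``paired=True`` the groups must be equal-sized and metadata gains
    pair ids linking sample i of group A to sample i of group B.  Undetected
    wells are emitted as NaN (impute downstream); the U6 reference is always
    detected.
    """
    rng = np.random.default_rng(config.seed)
    if truth is None:
        truth = _make_truth(config, rng)
    else:
        truth = truth.reset_index(drop=True)
        if len(truth) != config.n_mirnas:
            raise ValueError("truth table size does not match n_mirnas")
    if paired and config.n_group_a != config.n_group_b:
        raise ValueError("paired datasets need equal group sizes")

    prefix = sample_prefix if sample_prefix is not None else set_label
    n_a, n_b = config.n_group_a, config.n_group_b
    sample_ids = [f"{prefix}_A{i+1:02d}" for i in range(n_a)] + [
        f"{prefix}_B{i+1:02d}" for i in range(n_b)
    ]

    baseline = rng.normal(config.baseline_cq_mean, config.baseline_cq_sd, size=config.n_mirnas)
    shift_a, shift_b = _latent_group_shift(truth)
    shift = np.concatenate([np.tile(shift_a[:, None], n_a), np.tile(shift_b[:, None], n_b)], axis=1)
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_mirnas, n_a + n_b))
    latent = baseline[:, None] + shift + noise

    # Logistic dropout: weak wells (high latent Cq) go undetected.
    if config.dropout_slope > 0:
        p_undetected = 1.0 / (1.0 + np.exp(-(latent - config.dropout_cq50) * config.dropout_slope))
    else:
        p_undetected = np.zeros_like(latent)
    # A well that has not amplified by the end of the 40-cycle run cannot be
    # detected, whatever the stochastic dropout draw says.
    undetected = (rng.uniform(size=latent.shape) < p_undetected) | (latent >= 40.0)
    observed = np.clip(latent, 1e-3, None)
    observed[undetected] = np.nan

    u6 = np.clip(rng.normal(20.0, 0.15, size=n_a + n_b), 1e-3, 40.0)
    values = pd.DataFrame(observed, index=truth["mirna_id"].tolist(), columns=sample_ids)
    values.loc[DEFAULT_REFERENCE] = u6
    detected = values.notna()

    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": [group_a_label] * n_a + [group_b_label] * n_b,
            "set": set_label,
            "pair_id": (
                [f"{prefix}_pair{i+1:02d}" for i in range(n_a)] * 2 if paired else [""] * (n_a + n_b)
            ),
            "mycn": rng.choice(["amplified", "not_amplified"], size=n_a + n_b),
        }
    ).set_index("sample_id")
    return CqMatrix(values, detected, DEFAULT_REFERENCE), metadata, truth


def gen_perturbation_dataset(
    n_probes: int = 5000,
    n_targets: int = 50,
    lfc: float = 1.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 2.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Mimic/inhibitor log-intensity table for two cell lines with matched
    negative controls; returns the table and the planted target ids.

    Planted targets shift by -lfc under the mimic and +lfc under the
    inhibitor, consistently in both lines; non-targets shift by 0.
    """
    if n_probes <= 0 or n_targets < 0 or n_targets > n_probes:
        raise ValueError("need 0 <= n_targets <= n_probes and n_probes > 0")
    if lfc <= 0:
        raise ValueError("lfc must be positive")
    rng = np.random.default_rng(seed)
    probe_ids = [f"GENE{i:05d}" for i in range(1, n_probes + 1)]
    target_idx = rng.choice(n_probes, size=n_targets, replace=False)
    is_target = np.zeros(n_probes, dtype=bool)
    is_target[target_idx] = True

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_probes)
    shift = {
        "mimic": np.where(is_target, -lfc, 0.0),
        "inhibitor": np.where(is_target, +lfc, 0.0),
    }
    data = {}
    for col in PERTURBATION_COLUMNS:
        arm = "mimic" if "mimic" in col else "inhibitor"
        delta = np.zeros(n_probes) if col.endswith("_ctrl") else shift[arm]
        noise = rng.normal(0.0, noise_sd, size=n_probes) if noise_sd > 0 else 0.0
        data[col] = baseline + delta + noise
    table = pd.DataFrame(data, index=pd.Index(probe_ids, name="probe_id"))
    targets = [probe_ids[i] for i in sorted(target_idx)]
    return table, targets


@dataclass(frozen=True)
class PlantedSite:
    """A seed site to plant: UTR index (0-based), site type, 1-based start
    (None = random placement)."""

    utr_index: int
    site_type: str
    start: int | None = None


@dataclass(frozen=True)
class PlantedARE:
    """An AU-rich element to plant: UTR index, number of overlapping AUUUA
    pentamers, 1-based start (None = random placement)."""

    utr_index: int
    n_pentamers: int = 1
    start: int | None = None


def _are_run(n_pentamers: int) -> str:
    return "AUUUA" + "UUUA" * (n_pentamers - 1)


def gen_sequences(
    n_utrs: int,
    mirna_sequence: str,
    planted_sites: Sequence[PlantedSite] = (),
    planted_are: Sequence[PlantedARE] = (),
    seed: int = 0,
    utr_length: int = 200,
    utr_ids: Sequence[str] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random-background RNA 3'UTRs with motifs planted at known positions.

    Returns ``{utr_id: sequence}`` plus a truth table listing every planted
    motif with its 1-based start.  Flanking bases next to a planted seed
    site are adjusted so the site scans as exactly the planted type (a
    chance upstream match or downstream A would otherwise upgrade it).
    """
    from .motifs import seed_patterns  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    if utr_ids is None:
        utr_ids = [f"UTR{i:04d}" for i in range(1, n_utrs + 1)]
    elif len(utr_ids) != n_utrs:
        raise ValueError("utr_ids length must equal n_utrs")
    seqs = [list(rng.choice(list(RNA_ALPHABET), size=utr_length)) for _ in range(n_utrs)]
    patterns = seed_patterns(mirna_sequence)
    m8_char = patterns["7mer-m8"][0]  # base whose upstream presence upgrades to m8
    truth_rows = []

    def _place(seq: list[str], motif: str, start_1b: int | None) -> int:
        if len(motif) > len(seq):
            raise ValueError(f"motif of length {len(motif)} longer than UTR of {len(seq)}")
        if start_1b is None:
            start_1b = int(rng.integers(1, len(seq) - len(motif) + 2))
        if not 1 <= start_1b <= len(seq) - len(motif) + 1:
            raise ValueError(f"motif does not fit at position {start_1b}")
        i = start_1b - 1
        seq[i : i + len(motif)] = list(motif)
        return start_1b

    for site in planted_sites:
        if site.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {site.site_type!r}")
        seq = seqs[site.utr_index]
        motif = patterns[site.site_type]
        start = _place(seq, motif, site.start)
        i = start - 1
        # Guard flanks so the planted type is exactly what a scanner finds.
        if site.site_type in ("6mer", "7mer-A1") and i > 0 and seq[i - 1] == m8_char:
            seq[i - 1] = "G" if m8_char != "G" else "C"
        end = i + len(motif)
        if site.site_type in ("6mer", "7mer-m8") and end < len(seq) and seq[end] == "A":
            seq[end] = "G"
        truth_rows.append(
            {
                "utr_id": utr_ids[site.utr_index],
                "kind": "seed_site",
                "site_type": site.site_type,
                "start": start,
                "n_pentamers": pd.NA,
            }
        )

    for are in planted_are:
        if are.n_pentamers < 1:
            raise ValueError("n_pentamers must be >= 1")
        seq = seqs[are.utr_index]
        motif = _are_run(are.n_pentamers)
        start = _place(seq, motif, are.start)
        i = start - 1
        end = i + len(motif)
        # Guard flanks so the run is maximal exactly as planted: a chance
        # UUUA after the run, or AUUU just before it, would extend it.
        if end + 3 < len(seq) and "".join(seq[end : end + 4]) == "UUUA":
            seq[end] = "G"
        if i >= 4 and "".join(seq[i - 4 : i]) == "AUUU":
            seq[i - 4] = "G"
        truth_rows.append(
            {
                "utr_id": utr_ids[are.utr_index],
                "kind": "are",
                "site_type": pd.NA,
                "start": start,
                "n_pentamers": are.n_pentamers,
            }
        )

    utrs = {uid: "".join(s) for uid, s in zip(utr_ids, seqs)}
    truth = pd.DataFrame(truth_rows, columns=["utr_id", "kind", "site_type", "start", "n_pentamers"])
    return utrs, truth


def write_fasta(sequences: dict[str, str], path) -> None:
    """Write ``{id: sequence}`` to FASTA via Biopython."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    seqio_write(records, str(path), "fasta")
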