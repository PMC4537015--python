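"""End-to-end orchestration: screen -> filters -> validation -> paired ->
perturbation merge -> sequence annotation, driven by one YAML config.

Every run writes seven TSV reports plus a JSON manifest recording the
config hash, the seed and per-stage record counts, so identical inputs and
config reproduce identical outputs.  ``demo`` generates a small synthetic
bundle with known truth and runs the full pipeline on it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import motifs, perturbation, qpcr, synthetic, validation
from .screening import screen as run_screen, selected_candidates

logger = logging.getLogger("mirmet")

REPORT_FILES = [
    "screen.tsv",
    "filters.tsv",
    "validation.tsv",
    "paired.tsv",
    "perturbation.tsv",
    "candidates.tsv",
    "annotation.tsv",
]


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run."""

    cq_path: str
    metadata_path: str
    perturbation_path: str
    de_genes_path: str
    utr_fasta: str
    mirna_fasta: str
    alpha: float = 0.05
    missingness_ratio: float = 2.0
    quartile_convention: str = "linear"
    min_abs_lfc: float = perturbation.DEFAULT_MIN_ABS_LFC
    group_a: str | None = "BM"
    imputation_ceiling: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def validate_paths(self) -> None:
        for name in (
            "cq_path",
            "metadata_path",
            "perturbation_path",
            "de_genes_path",
            "utr_fasta",
            "mirna_fasta",
        ):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"config {name}: {p} does not exist")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


def _config_hash(config: RunConfig) -> str:
    """Hash of the analysis parameters; path fields contribute only their
    file names so a bundle moved to another directory hashes identically
    (content differences still show up in the report checksums)."""
    payload = {
        k: (Path(v).name if isinstance(v, str) and k.endswith(("_path", "_fasta")) else v)
        for k, v in asdict(config).items()
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full analysis and write reports plus a manifest.

    Stages: (1) dCq screen with both selection filters on the discovery
    set; (2) confirmation of filter-passing candidates in the validation
    set; (3) paired within-patient test on the paired set; (4) intersection
    of the three candidate sets (paired membership uses raw p, the
    low-power stage); (5) moderated inverse-modulation calling on the
    perturbation table and merge with the metastasis DE genes; (6) seed-
    site and ARE annotation of the merged candidate genes.  Empty candidate
    sets propagate as header-only reports, not errors.
    """
    config.validate_paths()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    logger.addHandler(handler)
    counts: dict[str, int] = {}
    try:
        matrix, metadata = qpcr.read_cq_table(config.cq_path, config.metadata_path)
        imputed = qpcr.impute_undetected(matrix, ceiling=config.imputation_ceiling)
        delta = qpcr.delta_cq(imputed)

        def subset(set_name: str) -> tuple[qpcr.DeltaCqMatrix, pd.DataFrame]:
            meta = metadata[metadata["set"] == set_name]
            cols = [s for s in delta.sample_ids if s in meta.index]
            if not cols:
                raise ValueError(f"no samples for set {set_name!r}")
            return qpcr.DeltaCqMatrix(delta.values[cols], delta.detected[cols], delta.reference_id), meta

        # Stage 1: discovery screen + filters
        disc_delta, disc_meta = subset("discovery")
        records = run_screen(
            disc_delta,
            disc_meta,
            alpha=config.alpha,
            apply_filters=True,
            group_a=config.group_a,
            missingness_ratio=config.missingness_ratio,
            quartile_method=config.quartile_convention,
        )
        _write(records, out_dir / "screen.tsv")
        counts["screen_total"] = len(records)
        counts["screen_significant"] = int(records["significant"].sum())
        filter_pass = selected_candidates(records)
        _write(filter_pass, out_dir / "filters.tsv")
        counts["filter_pass"] = len(filter_pass)
        logger.info("screen: %d significant, %d pass filters", counts["screen_significant"], len(filter_pass))

        # Stage 2: validation-set confirmation
        val_delta, val_meta = subset("validation")
        if len(filter_pass):
            concordance = validation.confirm_in_validation(
                filter_pass, val_delta, val_meta, alpha=config.alpha, group_a=config.group_a
            )
        else:
            concordance = pd.DataFrame(
                columns=[
                    "mirna_id",
                    "p_discovery",
                    "p_validation_raw",
                    "p_validation",
                    "direction_discovery",
                    "direction_validation",
                    "confirmed",
                ]
            )
        _write(concordance, out_dir / "validation.tsv")
        counts["validation_confirmed"] = int(concordance["confirmed"].sum()) if len(concordance) else 0

        # Stage 3: paired within-patient analysis
        pair_delta, pair_meta = subset("paired")
        paired = validation.paired_test(pair_delta, pair_meta, group_a=config.group_a)
        _write(paired, out_dir / "paired.tsv")
        counts["paired_significant_raw"] = int((paired["p_paired"] < config.alpha).sum())

        # Stage 4: candidate intersection and nomination
        confirmed_ids = set(concordance.loc[concordance["confirmed"], "mirna_id"]) if len(concordance) else set()
        paired_ids = set(paired.loc[paired["p_paired"] < config.alpha, "mirna_id"])
        report = validation.intersect_candidates(
            {
                "discovery_pass": set(filter_pass["mirna_id"]),
                "validation_confirmed": confirmed_ids,
                "paired_significant": paired_ids,
            }
        )
        candidates = report.membership.reset_index()
        if len(candidates):
            candidates["nominated"] = (
                candidates["discovery_pass"]
                & candidates["validation_confirmed"]
                & candidates["paired_significant"]
            )
        else:
            candidates["nominated"] = pd.Series(dtype=bool)
        _write(candidates, out_dir / "candidates.tsv")
        counts["nominated"] = int(candidates["nominated"].sum()) if len(candidates) else 0

        # Stage 5: perturbation analysis + DE merge
        ptable = pd.read_csv(config.perturbation_path, sep="\t", index_col="probe_id")
        results = perturbation.analyze_perturbation(ptable)
        flagged = perturbation.call_inverse_modified(
            results, alpha=config.alpha, min_abs_lfc=config.min_abs_lfc
        )
        _write(flagged.reset_index(), out_dir / "perturbation.tsv")
        counts["inverse_modified"] = int(flagged["inverse_modified"].sum())
        de_genes = pd.read_csv(config.de_genes_path, sep="\t")
        merged = perturbation.merge_with_de_genes(flagged, de_genes)
        counts["merged_candidate_genes"] = int(merged["concordant"].sum())

        # Stage 6: sequence annotation of concordant candidate genes
        mirna_seqs = motifs.read_fasta(config.mirna_fasta)
        if len(mirna_seqs) != 1:
            raise ValueError("mirna_fasta must contain exactly one mature miRNA sequence")
        (mirna_seq,) = mirna_seqs.values()
        gene_candidates = merged[merged["concordant"]].reset_index(drop=True)
        annotated = motifs.annotate_candidates(gene_candidates, config.utr_fasta, mirna_seq)
        _write(annotated, out_dir / "annotation.tsv")
        counts["annotated_genes"] = len(annotated)

        manifest = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "alpha": config.alpha,
            "stage_counts": counts,
            "reports": {name: _checksum(out_dir / name) for name in REPORT_FILES},
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception:
        logger.exception("pipeline failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out_dir


@dataclass
class DemoDesign:
    """Scale of the demonstration bundle (kept small so a full run takes
    seconds): 100 miRNAs with 5 planted positives in 8 vs 8 discovery
    samples, a 6 vs 6 validation set, 6 sample pairs, 500 perturbation
    probes with 25 planted targets, and 20 UTRs."""

    n_mirnas: int = 100
    n_discovery: int = 8
    n_validation: int = 6
    n_pairs: int = 6
    n_true_positives: int = 5
    n_probes: int = 500
    n_targets: int = 25
    n_utrs: int = 20


def _random_mirna(rng) -> str:
    return "".join(rng.choice(list(synthetic.RNA_ALPHABET), size=22))


def make_demo_bundle(seed: int, input_dir: Path, design: DemoDesign | None = None) -> tuple[RunConfig, dict]:
    """Write a synthetic input bundle with shared truth and return the run
    config plus the truth tables."""
    import numpy as np

    design = design or DemoDesign()
    input_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    base = synthetic.SimConfig(
        n_mirnas=design.n_mirnas,
        n_group_a=design.n_discovery,
        n_group_b=design.n_discovery,
        n_true_positives=design.n_true_positives,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    disc_cq, disc_meta, truth = synthetic.gen_cq_dataset(base, set_label="discovery")
    val_cfg = synthetic.SimConfig(
        **{
            **asdict(base),
            "n_group_a": design.n_validation,
            "n_group_b": design.n_validation,
            "seed": int(rng.integers(0, 2**31 - 1)),
        }
    )
    val_cq, val_meta, _ = synthetic.gen_cq_dataset(val_cfg, set_label="validation", truth=truth)
    pair_cfg = synthetic.SimConfig(
        **{
            **asdict(base),
            "n_group_a": design.n_pairs,
            "n_group_b": design.n_pairs,
            "seed": int(rng.integers(0, 2**31 - 1)),
        }
    )
    pair_cq, pair_meta, _ = synthetic.gen_cq_dataset(
        pair_cfg, set_label="paired", truth=truth, paired=True
    )

    values = pd.concat([disc_cq.values, val_cq.values, pair_cq.values], axis=1)
    matrix = qpcr.CqMatrix(values, values.notna(), disc_cq.reference_id)
    metadata = pd.concat([disc_meta, val_meta, pair_meta])
    qpcr.write_cq_table(matrix, input_dir / "cq.tsv")
    metadata.reset_index().to_csv(input_dir / "metadata.tsv", sep="\t", index=False)
    truth.to_csv(input_dir / "mirna_truth.tsv", sep="\t", index=False)

    ptable, targets = synthetic.gen_perturbation_dataset(
        n_probes=design.n_probes,
        n_targets=design.n_targets,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    ptable.to_csv(input_dir / "perturbation.tsv", sep="\t")

    # DE table: planted targets are DE in metastasis with the concordant
    # direction (inverse targets of a miRNA that is low in metastasis rise
    # there, i.e. up_in_BM); a handful of non-targets are DE too.
    non_targets = [p for p in ptable.index if p not in set(targets)][: design.n_targets]
    de_genes = pd.DataFrame(
        {
            "gene_id": list(targets) + non_targets,
            "de_direction_in_metastasis": ["up_in_BM"] * len(targets)
            + list(rng.choice(["up_in_BM", "down_in_BM"], size=len(non_targets))),
        }
    )
    de_genes.to_csv(input_dir / "de_genes.tsv", sep="\t", index=False)

    mirna_seq = _random_mirna(rng)
    synthetic.write_fasta({"mir-demo-3p": mirna_seq}, input_dir / "mirna.fa")
    utr_ids = list(targets[: design.n_utrs])
    planted_sites = [
        synthetic.PlantedSite(utr_index=i, site_type="8mer") for i in range(0, len(utr_ids), 2)
    ]
    planted_ares = [
        synthetic.PlantedARE(utr_index=i, n_pentamers=2) for i in range(0, len(utr_ids), 3)
    ]
    utrs, seq_truth = synthetic.gen_sequences(
        n_utrs=len(utr_ids),
        mirna_sequence=mirna_seq,
        planted_sites=planted_sites,
        planted_are=planted_ares,
        seed=int(rng.integers(0, 2**31 - 1)),
        utr_ids=utr_ids,
    )
    synthetic.write_fasta(utrs, input_dir / "utrs.fa")
    seq_truth.to_csv(input_dir / "sequence_truth.tsv", sep="\t", index=False)

    config = RunConfig(
        cq_path=str(input_dir / "cq.tsv"),
        metadata_path=str(input_dir / "metadata.tsv"),
        perturbation_path=str(input_dir / "perturbation.tsv"),
        de_genes_path=str(input_dir / "de_genes.tsv"),
        utr_fasta=str(input_dir / "utrs.fa"),
        mirna_fasta=str(input_dir / "mirna.fa"),
        seed=seed,
    )
    with open(input_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    truths = {"mirna": truth, "targets": targets, "sequences": seq_truth}
    return config, truths


def demo(seed: int, out_dir: str | Path = "mirmet_demo") -> Path:
    """Generate the demo bundle and run the full pipeline on it."""
    out_dir = Path(out_dir)
    config, _ = make_demo_bundle(seed, out_dir / "inputs")
    return run_pipeline(config, out_dir)
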