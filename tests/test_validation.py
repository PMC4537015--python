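"""Cross-set confirmation, paired testing and candidate intersections."""

import numpy as np
import pandas as pd
import pytest

from mirmet import qpcr
from mirmet.screening import HIGHER_IN_A, LOWER_IN_A, screen
from mirmet.synthetic import SimConfig, gen_cq_dataset
from mirmet.validation import confirm_in_validation, intersect_candidates, paired_test


def _delta(config, **kwargs):
    matrix, meta, truth = gen_cq_dataset(config, **kwargs)
    return qpcr.delta_cq(qpcr.impute_undetected(matrix)), meta, truth


@pytest.fixture(scope="module")
def discovery_and_validation():
    cfg = SimConfig(n_mirnas=120, n_true_positives=8, seed=31)
    d_delta, d_meta, truth = _delta(cfg)
    v_cfg = SimConfig(n_mirnas=120, n_group_a=10, n_group_b=10, n_true_positives=8, seed=32)
    v_delta, v_meta, _ = _delta(v_cfg, set_label="validation", truth=truth)
    records = screen(d_delta, d_meta).set_index("mirna_id")
    candidates = records[records["significant"]].reset_index()
    return candidates, v_delta, v_meta, truth


class TestConfirmInValidation:
    def test_consistent_planted_effects_confirmed(self, discovery_and_validation):
        candidates, v_delta, v_meta, truth = discovery_and_validation
        out = confirm_in_validation(candidates, v_delta, v_meta)
        t = truth.set_index("mirna_id")
        planted = [m for m in out["mirna_id"] if t.loc[m, "is_true_positive"]]
        confirmed = set(out.loc[out["confirmed"], "mirna_id"])
        assert planted, "screen recovered no planted candidates"
        assert len(confirmed & set(planted)) >= 0.8 * len(planted)

    def test_effect_only_in_discovery_not_confirmed(self):
        cfg = SimConfig(n_mirnas=100, n_true_positives=6, seed=33)
        d_delta, d_meta, truth = _delta(cfg)
        # validation set with NO planted effects but the same miRNA panel
        null_cfg = SimConfig(n_mirnas=100, n_group_a=10, n_group_b=10, n_true_positives=0, seed=34)
        null_truth = truth.copy()
        null_truth["is_true_positive"] = False
        null_truth["true_direction"] = None
        null_truth["planted_shift"] = 0.0
        v_delta, v_meta, _ = _delta(null_cfg, set_label="validation", truth=null_truth)
        candidates = screen(d_delta, d_meta)
        candidates = candidates[candidates["significant"]].reset_index(drop=True)
        out = confirm_in_validation(candidates, v_delta, v_meta)
        assert not out["confirmed"].any()

    def test_direction_flip_blocks_confirmation(self, discovery_and_validation):
        candidates, v_delta, v_meta, _ = discovery_and_validation
        flipped = candidates.copy()
        flipped["direction"] = flipped["direction"].map(
            {LOWER_IN_A: HIGHER_IN_A, HIGHER_IN_A: LOWER_IN_A}
        )
        out = confirm_in_validation(flipped, v_delta, v_meta)
        assert not out["confirmed"].any()

    def test_candidate_absent_from_validation_matrix(self, discovery_and_validation):
        candidates, v_delta, v_meta, _ = discovery_and_validation
        bad = candidates.copy()
        bad.loc[0, "mirna_id"] = "miR-missing"
        with pytest.raises(KeyError, match="miR-missing"):
            confirm_in_validation(bad, v_delta, v_meta)

    def test_group_relabel_with_direction_flip_is_symmetric(self, discovery_and_validation):
        candidates, v_delta, v_meta, _ = discovery_and_validation
        out_ab = confirm_in_validation(candidates, v_delta, v_meta, group_a="BM")
        flipped = candidates.copy()
        flipped["direction"] = flipped["direction"].map(
            {LOWER_IN_A: HIGHER_IN_A, HIGHER_IN_A: LOWER_IN_A}
        )
        out_ba = confirm_in_validation(flipped, v_delta, v_meta, group_a="primary")
        merged = out_ab.merge(out_ba, on="mirna_id", suffixes=("_ab", "_ba"))
        assert (merged["confirmed_ab"] == merged["confirmed_ba"]).all()
        np.testing.assert_allclose(merged["p_validation_ab"], merged["p_validation_ba"], atol=1e-12)


def _paired_delta(diffs_by_mirna: dict[str, list[float]]):
    """Build a paired dCq matrix with prescribed within-pair differences
    (group B member fixed at dCq 10)."""
    n = len(next(iter(diffs_by_mirna.values())))
    cols_a = [f"pA{i}" for i in range(n)]
    cols_b = [f"pB{i}" for i in range(n)]
    values = {}
    for i in range(n):
        values[cols_a[i]] = [10.0 + diffs_by_mirna[m][i] for m in diffs_by_mirna]
        values[cols_b[i]] = [10.0] * len(diffs_by_mirna)
    vdf = pd.DataFrame(values, index=list(diffs_by_mirna))
    delta = qpcr.DeltaCqMatrix(vdf, vdf.notna())
    meta = pd.DataFrame(
        {
            "sample_id": cols_a + cols_b,
            "group": ["BM"] * n + ["primary"] * n,
            "set": "paired",
            "pair_id": [f"p{i}" for i in range(n)] * 2,
            "mycn": "amplified",
        }
    ).set_index("sample_id")
    return delta, meta


class TestPairedTest:
    def test_all_zero_differences_degenerate(self):
        delta, meta = _paired_delta({"miR-x": [0.0, 0.0, 0.0, 0.0]})
        out = paired_test(delta, meta)
        row = out.iloc[0]
        assert row["p_paired"] == 1.0
        assert row["direction"] is None

    def test_constant_nonzero_differences(self):
        delta, meta = _paired_delta({"miR-x": [2.0, 2.0, 2.0, 2.0]})
        out = paired_test(delta, meta)
        row = out.iloc[0]
        assert np.isinf(row["statistic"]) and row["statistic"] > 0
        assert row["p_paired"] < 1e-12
        assert row["direction"] == LOWER_IN_A  # positive dCq difference

    def test_planted_shift_significant(self):
        rng = np.random.default_rng(35)
        diffs = {"miR-x": list(6.0 + rng.normal(0, 1, size=4))}
        delta, meta = _paired_delta(diffs)
        out = paired_test(delta, meta)
        assert out.iloc[0]["p_paired"] < 0.05

    def test_matches_scipy_on_random_data(self):
        from scipy import stats

        rng = np.random.default_rng(36)
        diffs = {f"miR-{i}": list(rng.normal(1, 2, size=6)) for i in range(5)}
        delta, meta = _paired_delta(diffs)
        out = paired_test(delta, meta).set_index("mirna_id")
        for m, d in diffs.items():
            expected = stats.ttest_1samp(d, 0.0)
            assert out.loc[m, "p_paired"] == pytest.approx(expected.pvalue, abs=1e-12)

    def test_wilcoxon_alternative(self):
        delta, meta = _paired_delta({"miR-x": [2.0, 2.5, 1.5, 3.0, 2.2, 2.8]})
        out = paired_test(delta, meta, method="wilcoxon")
        assert out.iloc[0]["p_paired"] < 0.05

    def test_incomplete_pair_rejected(self):
        delta, meta = _paired_delta({"miR-x": [1.0, 2.0, 3.0]})
        meta = meta.drop(index="pB2")
        delta = qpcr.DeltaCqMatrix(delta.values.drop(columns="pB2"), delta.detected.drop(columns="pB2"))
        with pytest.raises(ValueError, match="incomplete"):
            paired_test(delta, meta)


class TestIntersectCandidates:
    def test_pairwise_intersection(self):
        report = intersect_candidates({"s1": {"A", "B", "C"}, "s2": {"B", "C", "D"}})
        assert report.intersection("s1", "s2") == {"B", "C"}

    def test_disjoint_sets_empty(self):
        report = intersect_candidates({"s1": {"A"}, "s2": {"B"}, "s3": {"C"}})
        assert report.intersection("s1", "s2", "s3") == set()

    def test_provenance_per_id(self):
        report = intersect_candidates({"s1": {"A", "B"}, "s2": {"B"}})
        assert report.provenance("B") == ["s1", "s2"]
        assert report.provenance("A") == ["s1"]

    def test_end_to_end_consistent_planted_mirnas_in_all_sets(self):
        """Planted consistent effects survive discovery, validation and the
        paired analysis and land in the three-way intersection."""
        from mirmet.screening import selected_candidates

        cfg = SimConfig(n_mirnas=150, n_true_positives=6, seed=37)
        d_delta, d_meta, truth = _delta(cfg)
        v_delta, v_meta, _ = _delta(
            SimConfig(n_mirnas=150, n_group_a=10, n_group_b=10, n_true_positives=6, seed=38),
            set_label="validation",
            truth=truth,
        )
        p_delta, p_meta, _ = _delta(
            SimConfig(n_mirnas=150, n_group_a=6, n_group_b=6, n_true_positives=6, seed=39),
            set_label="paired",
            truth=truth,
            paired=True,
        )
        records = screen(d_delta, d_meta)
        passing = selected_candidates(records)
        confirmed = confirm_in_validation(passing, v_delta, v_meta)
        paired = paired_test(p_delta, p_meta)
        report = intersect_candidates(
            {
                "discovery": set(passing["mirna_id"]),
                "validation": set(confirmed.loc[confirmed["confirmed"], "mirna_id"]),
                "paired": set(paired.loc[paired["p_paired"] < 0.05, "mirna_id"]),
            }
        )
        planted = set(truth.loc[truth["is_true_positive"], "mirna_id"])
        nominated = report.intersection("discovery", "validation", "paired")
        assert len(nominated & planted) >= 4
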