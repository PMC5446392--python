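"""Batch-marker discovery, covariate selection, probe filtering, normalization."""

import numpy as np
import pandas as pd
import pytest

from methwas.preprocess import (
    filter_probes,
    greedy_detection_filter,
    normalize_between_samples,
    paired_batch_test,
    select_covariate_markers,
)
from methwas.simulate import CohortConfig, generate_cohort
from methwas.types import BatchMarkerResult

from conftest import make_beta, make_sheet


def _paired_world(diffs, base=0.5):
    """BetaMatrix + sheet realising the given probe x pair difference matrix."""
    diffs = np.asarray(diffs, dtype=float)
    n_probes, n_pairs = diffs.shape
    orig = np.full((n_probes, n_pairs), base)
    rb = orig - diffs
    ids = [f"o{j}" for j in range(n_pairs)] + [f"o{j}_rb" for j in range(n_pairs)]
    beta = make_beta(np.hstack([orig, rb]), sample_ids=ids)
    sheet = make_sheet(
        ids,
        groups=["case"] * n_pairs + ["case"] * n_pairs,
        batches=["B0"] * n_pairs + ["RB"] * n_pairs,
        rebatch_of=[""] * n_pairs + [f"o{j}" for j in range(n_pairs)],
    )
    return beta, sheet


class TestPairedBatchTest:
    def test_identical_pairs_are_not_candidates(self):
        beta, sheet = _paired_world(np.zeros((3, 4)))
        res = paired_batch_test(beta, sheet)
        assert (res.candidate_p == 1.0).all()
        assert res.candidates == []

    def test_label_swap_leaves_p_unchanged(self):
        rng = np.random.default_rng(4)
        diffs = rng.normal(0.05, 0.01, size=(5, 6))
        beta, sheet = _paired_world(diffs)
        res = paired_batch_test(beta, sheet)
        swapped = sheet.copy()
        # swap roles: originals become re-batch copies of the copies
        swapped["rebatch_of"] = [""] * 6 + [""] * 6
        swapped.loc[:5, "rebatch_of"] = [f"o{j}_rb" for j in range(6)]
        swapped.loc[:5, "batch"] = "RB"
        swapped.loc[6:, "batch"] = "B0"
        res2 = paired_batch_test(beta, swapped)
        assert np.allclose(res.candidate_p.to_numpy(), res2.candidate_p.to_numpy())

    def test_planted_batch_probes_recovered(self):
        cfg = CohortConfig(n_probes=4000, n_batch_probes=50, batch_shift=0.15, seed=21)
        beta, sheet, annot, truth = generate_cohort(cfg)
        res = paired_batch_test(beta, sheet)
        recall = len(set(res.candidates) & set(truth.true_batch_probes)) / 50
        assert recall >= 0.9
        false = set(res.candidates) - set(truth.true_batch_probes)
        assert len(false) <= 2

    def test_too_few_pairs_error(self):
        beta, sheet = _paired_world(np.zeros((2, 1)))
        with pytest.raises(ValueError, match="2 re-batch pairs"):
            paired_batch_test(beta, sheet)

    def test_degenerate_zero_variance_nonzero_mean_flagged(self):
        diffs = np.full((1, 4), 0.05)
        beta, sheet = _paired_world(diffs)
        res = paired_batch_test(beta, sheet)
        assert res.degenerate_probes == ["p0"]
        assert res.candidates == []


class TestCovariateSelection:
    def test_single_latent_factor_selects_one(self):
        # differences are scalar multiples of one factor vector plus small noise
        rng = np.random.default_rng(7)
        factor = 1 + 0.2 * rng.normal(size=12)
        loadings = 0.15 * rng.uniform(0.75, 1.25, size=30)
        diffs = np.outer(loadings, factor) + rng.normal(0, 0.004, size=(30, 12))
        beta, sheet = _paired_world(diffs)
        res = paired_batch_test(beta, sheet)
        assert len(res.candidates) >= 25
        sel = select_covariate_markers(res, beta, sheet)
        assert len(sel.selected_covariates) == 1
        assert sel.selection_trace[-1][1] == 0  # nothing left significant

    def test_independent_factors_need_multiple_covariates(self):
        # two orthogonal factor patterns; selection must not stop after one
        rng = np.random.default_rng(8)
        f1 = 1 + 0.15 * rng.normal(size=12)
        f2 = 1 + 0.15 * rng.normal(size=12)
        l1 = 0.15 * rng.uniform(0.9, 1.1, size=15)
        l2 = 0.15 * rng.uniform(0.9, 1.1, size=15)
        diffs = np.vstack([np.outer(l1, f1), np.outer(l2, f2)]) + rng.normal(0, 0.002, size=(30, 12))
        beta, sheet = _paired_world(diffs)
        res = paired_batch_test(beta, sheet)
        assert len(res.candidates) >= 25
        # the adjusted test for a truly independent factor maxes out near
        # nominal significance at 12 pairs, so follow it at the 0.05 level
        sel = select_covariate_markers(res, beta, sheet, adjusted_alpha=0.05)
        assert len(sel.selected_covariates) >= 2

    def test_termination_and_subset_invariants(self):
        rng = np.random.default_rng(9)
        diffs = np.outer(0.12 * np.ones(10), 1 + 0.1 * rng.normal(size=8)) + rng.normal(0, 0.003, (10, 8))
        beta, sheet = _paired_world(diffs)
        res = paired_batch_test(beta, sheet)
        sel = select_covariate_markers(res, beta, sheet)
        assert set(sel.selected_covariates) <= set(sel.candidates)
        assert len(sel.selection_trace) == len(sel.selected_covariates)
        assert len(sel.selected_covariates) <= len(sel.candidates)

    def test_empty_candidates_error(self):
        beta, sheet = _paired_world(np.zeros((2, 4)))
        res = paired_batch_test(beta, sheet)
        with pytest.raises(ValueError):
            select_covariate_markers(res, beta, sheet)


class TestGreedyDetectionFilter:
    def test_clean_matrix_unchanged(self):
        beta = make_beta(np.full((4, 3), 0.5), detection=np.full((4, 3), 0.001))
        out = greedy_detection_filter(beta)
        assert out.values.equals(beta.values)

    def test_single_offending_probe_removed(self):
        det = np.full((5, 4), 0.001)
        det[2, :] = 0.5
        beta = make_beta(np.full((5, 4), 0.5), detection=det)
        out = greedy_detection_filter(beta)
        assert list(out.probe_ids) == ["p0", "p1", "p3", "p4"]
        assert list(out.sample_ids) == ["s0", "s1", "s2", "s3"]

    def test_matches_independent_greedy_oracle(self):
        rng = np.random.default_rng(12)
        det = rng.beta(1, 300, size=(400, 40))
        fail_mask = rng.random((400, 40)) < 0.01
        det[fail_mask] = 0.5
        beta = make_beta(np.full((400, 40), 0.5), detection=det)
        out = greedy_detection_filter(beta, threshold=0.05)
        assert (out.detection_p.to_numpy() <= 0.05).all()

        # independent re-implementation of the worst-fraction greedy rule
        f = det > 0.05
        rows = list(range(400))
        cols = list(range(40))
        removed_rows, removed_cols = [], []
        while f[np.ix_(rows, cols)].any():
            sub = f[np.ix_(rows, cols)]
            pr = sub.mean(axis=1)
            ps = sub.mean(axis=0)
            if pr.max() >= ps.max():
                removed_rows.append(rows.pop(int(pr.argmax())))
            else:
                removed_cols.append(cols.pop(int(ps.argmax())))
        assert out.shape == (len(rows), len(cols))
        kept_probes = {f"p{i}" for i in rows}
        assert set(out.probe_ids) == kept_probes


class TestFilterProbes:
    def test_nothing_to_remove(self):
        beta = make_beta(np.full((6, 4), 0.5), detection=np.full((6, 4), 0.001))
        annot = pd.DataFrame(
            {
                "probe_id": beta.probe_ids,
                "chrom": "chr1",
                "pos": np.arange(1, 7) * 1000,
                "strand": "+",
                "snp_affected": False,
                "sex_chrom": False,
                "cpg_context": True,
                "promoter": False,
                "candidate_region": False,
            }
        )
        out, log = filter_probes(beta, annot, batch=None)
        assert out.shape == beta.shape
        assert sum(log.removed.values()) == 0

    def test_planted_flag_counts(self, small_cohort):
        beta, sheet, annot, truth = small_cohort
        an = annot.copy()
        res = paired_batch_test(beta, sheet)
        out, log = filter_probes(beta, an, res)
        assert log.removed["snp_affected"] == int(an["snp_affected"].sum())
        assert log.removed["sex_chrom"] == int(an["sex_chrom"].sum())
        # set-algebra oracle over the same flags
        flagged = set(an.loc[an["snp_affected"] | an["sex_chrom"] | ~an["cpg_context"], "probe_id"])
        unstable = set(res.candidate_p[res.candidate_p < 0.01].index)
        removed = set(beta.probe_ids) - set(out.probe_ids)
        greedy_removed = set(log.removed_probes.get("detection", []))
        assert removed == (flagged | unstable | greedy_removed) - set(res.selected_covariates)
        assert set(out.probe_ids) <= set(beta.probe_ids)

    def test_missing_annotation_error(self):
        beta = make_beta(np.full((3, 2), 0.5))
        annot = pd.DataFrame(
            {
                "probe_id": ["p0", "p1"],
                "chrom": "chr1",
                "pos": [100, 200],
                "strand": "+",
                "snp_affected": False,
                "sex_chrom": False,
                "cpg_context": True,
                "promoter": False,
                "candidate_region": False,
            }
        )
        with pytest.raises(ValueError, match="missing from annotation"):
            filter_probes(beta, annot, batch=None)


class TestNormalization:
    def test_none_is_identity(self):
        beta = make_beta(np.random.default_rng(0).random((10, 4)))
        out = normalize_between_samples(beta, method="none")
        assert out.values.equals(beta.values)

    def test_quantile_equalises_sorted_profiles(self):
        rng = np.random.default_rng(1)
        a = rng.random(200)
        b = np.clip(a + 0.05, 0, 1)  # shifted copy
        beta = make_beta(np.column_stack([a, b]))
        out = normalize_between_samples(beta, method="quantile")
        v = out.values.to_numpy()
        # oracle: each sample's sorted values equal the mean sorted profile
        mean_profile = np.sort(np.column_stack([a, b]), axis=0).mean(axis=1)
        for j in range(2):
            assert np.allclose(np.sort(v[:, j]), mean_profile)
        # rank order preserved within sample
        assert (np.argsort(v[:, 0]) == np.argsort(a)).all()

    def test_identical_distributions_unchanged(self):
        a = np.linspace(0.1, 0.9, 50)
        beta = make_beta(np.column_stack([a, a[::-1]]))
        out = normalize_between_samples(beta, method="quantile")
        assert np.allclose(out.values.to_numpy(), beta.values.to_numpy())

    def test_single_sample_warns(self):
        beta = make_beta(np.full((5, 1), 0.4))
        with pytest.warns(UserWarning):
            out = normalize_between_samples(beta, method="quantile")
        assert out.values.equals(beta.values)
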