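"""Filtering and normalization: hand-computed oracles for CPM and quantile
assignment, TMM checked against both closed-form toys and edgeR, and the
structural invariants the differential stage assumes."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import chromcal as cc
from chromcal.datamodel import ValidationError
from chromcal.normalize import NormalizationParams, quantile_normalize_within_group

from conftest import toy_count_matrix


class TestCpm:
    def test_direct_arithmetic(self):
        m = toy_count_matrix([[50], [0]], library_sizes=[1_000_000])
        cpm = cc.cpm_transform(m)
        assert cpm.iloc[0, 0] == pytest.approx(50.0)
        assert cpm.iloc[1, 0] == 0.0

    def test_zero_library_size_names_sample(self):
        m = toy_count_matrix([[50], [1]], library_sizes=[1_000_000])
        m.library_sizes["s0"] = 0
        with pytest.raises(ValidationError, match="s0"):
            cc.cpm_transform(m)


class TestFilter:
    def test_ceiling_rule_keeps_single_passing_sample(self):
        # 10 samples, min_fraction 0.10 -> ceil(1.0) = 1 sample suffices
        counts = np.zeros((2, 10), dtype=int)
        counts[0, 0] = 1  # CPM exactly 1 at library 1e6
        counts[1, :] = 0
        m = toy_count_matrix(counts, library_sizes=[1_000_000] * 10)
        kept, removed = cc.filter_low_signal(m)
        assert kept.region_ids == ["r0"]
        assert removed == ["r1"]

    def test_all_zero_region_removed(self, atac_sim):
        matrix, _, _ = atac_sim
        zeroed = matrix.counts.copy()
        zeroed.iloc[0] = 0
        m = cc.RegionCountMatrix(
            regions=matrix.regions,
            counts=zeroed,
            library_sizes=matrix.library_sizes,
        )
        _, removed = cc.filter_low_signal(m)
        assert zeroed.index[0] in removed

    def test_idempotent(self, atac_sim):
        matrix, _, _ = atac_sim
        once, _ = cc.filter_low_signal(matrix)
        twice, removed_again = cc.filter_low_signal(once)
        assert removed_again == []
        assert twice.counts.equals(once.counts)

    def test_empty_result_advises(self):
        m = toy_count_matrix([[1], [1]], library_sizes=[10_000_000_000])
        with pytest.raises(ValidationError, match="cpm_threshold"):
            cc.filter_low_signal(m)


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        counts = np.tile([[10], [200], [3000], [40]], (1, 3))
        m = toy_count_matrix(counts)
        f = cc.tmm_factors(m)
        assert np.allclose(f, 1.0)

    def test_scaled_sample_absorbed_by_library_size(self):
        # B = 3*A elementwise: after library-size scaling all M-values are 0
        a = np.array([12, 345, 67, 890, 123, 4, 56, 78])
        counts = np.column_stack([a, 3 * a])
        m = toy_count_matrix(counts)
        f = cc.tmm_factors(m)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_equal_library_doubling_hand_factor(self):
        # equal library sizes forced, B = 2*A: every M-value is exactly 1, so
        # the trimmed weighted mean is 1 and factors are (2^-0.5, 2^0.5)
        a = np.array([10, 20, 30, 40, 50, 60, 70, 80])
        counts = np.column_stack([a, 2 * a])
        m = toy_count_matrix(counts, library_sizes=[1000, 1000])
        f = cc.tmm_factors(m)
        assert f.iloc[0] == pytest.approx(2 ** -0.5, abs=1e-12)
        assert f.iloc[1] == pytest.approx(2 ** 0.5, abs=1e-12)

    def test_geometric_mean_one(self, atac_sim):
        matrix, _, _ = atac_sim
        f = cc.tmm_factors(matrix)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_scaling_one_sample(self, atac_sim):
        matrix, _, _ = atac_sim
        sub = matrix.subset_regions(matrix.region_ids[:100])
        f1 = cc.tmm_factors(sub)
        scaled = sub.counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 5
        libs2 = sub.library_sizes.copy()
        libs2.iloc[0] = libs2.iloc[0] * 5
        m2 = cc.RegionCountMatrix(
            regions=sub.regions, counts=scaled, library_sizes=libs2
        )
        f2 = cc.tmm_factors(m2)
        # M-values are unchanged (count and library scale together), so the
        # factor absorbs the scaling up to the precision-weight perturbation
        eff1 = sub.library_sizes * f1
        eff2 = m2.library_sizes * f2
        norm1 = sub.counts / eff1.to_numpy()
        norm2 = scaled / eff2.to_numpy()
        assert np.allclose(norm1.to_numpy(), norm2.to_numpy(), rtol=1e-2)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R unavailable")
    def test_matches_edger_reference(self, tmp_path):
        rng = np.random.default_rng(42)
        counts = rng.negative_binomial(5, 0.01, size=(200, 5)).astype(int)
        counts[:, 2] *= 3
        m = toy_count_matrix(counts)
        ours = cc.tmm_factors(m).to_numpy()
        np.savetxt(tmp_path / "c.tsv", counts, fmt="%d", delimiter="\t")
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.table("{tmp_path / "c.tsv"}"));'
            'cat(sprintf("%.12f\\n", calcNormFactors(x, method="TMM")))'
        )
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        theirs = np.array([float(v) for v in res.stdout.split()])
        assert np.allclose(ours, theirs, atol=1e-9)

    def test_no_shared_nonzero_regions_rejected(self):
        m = toy_count_matrix([[5, 0], [0, 7]])
        with pytest.raises(ValidationError):
            cc.tmm_factors(m)


class TestQuantileNormalization:
    def test_hand_example(self):
        vals = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize_within_group(vals, {"a": "g", "b": "g"})
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["b"].tolist() == [2.5, 3.5, 4.5]

    def test_identical_columns_unchanged(self):
        vals = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0]})
        out = quantile_normalize_within_group(vals, {"a": "g", "b": "g"})
        assert np.allclose(out, vals)

    def test_average_mode_gives_ties_mean_of_target_quantiles(self):
        vals = pd.DataFrame({"a": [1.0, 1.0, 9.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize_within_group(
            vals, {"a": "g", "b": "g"}, ties="average"
        )
        target = np.sort(vals.to_numpy(), axis=0).mean(axis=1)  # [1.5, 2.5, 7.5]
        assert out["a"].tolist() == pytest.approx(
            [(target[0] + target[1]) / 2, (target[0] + target[1]) / 2, target[2]]
        )

    def test_default_mode_exact_distributions_despite_ties(self):
        vals = pd.DataFrame({"a": [1.0, 1.0, 1.0, 9.0], "b": [2.0, 4.0, 6.0, 8.0]})
        out = quantile_normalize_within_group(vals, {"a": "g", "b": "g"})
        assert np.array_equal(np.sort(out["a"]), np.sort(out["b"]))
        # tied values assigned in original row order
        assert out["a"].iloc[0] <= out["a"].iloc[1] <= out["a"].iloc[2]

    def test_groups_normalized_separately(self):
        vals = pd.DataFrame(
            {
                "a": [1.0, 2.0, 3.0],
                "b": [4.0, 5.0, 6.0],
                "c": [10.0, 20.0, 30.0],
                "d": [40.0, 50.0, 60.0],
            }
        )
        groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        out = quantile_normalize_within_group(vals, groups)
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["c"].tolist() == [25.0, 35.0, 45.0]

    def test_single_sample_group_passthrough_warns(self):
        vals = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0], "c": [5.0, 6.0]})
        with pytest.warns(UserWarning, match="single sample"):
            out = quantile_normalize_within_group(
                vals, {"a": "g1", "b": "g1", "c": "solo"}
            )
        assert out["c"].tolist() == [5.0, 6.0]


class TestPipeline:
    def test_within_group_distributions_identical(self, normalized_atac):
        normalized, sheet, _, _ = normalized_atac
        groups = sheet.data.set_index("sample_id")["cell_type"]
        for _g, cols in groups.groupby(groups).groups.items():
            block = normalized[list(cols)].to_numpy()
            sorted_cols = np.sort(block, axis=0)
            spread = sorted_cols.max(axis=1) - sorted_cols.min(axis=1)
            assert spread.max() < 1e-9

    def test_rank_order_preserved_before_quantile_step(self, atac_sim):
        matrix, sheet, _ = atac_sim
        filtered, _ = cc.filter_low_signal(matrix)
        params = NormalizationParams()
        factors = cc.tmm_factors(filtered, params)
        eff = filtered.library_sizes * factors
        logcpm = np.log2(
            (filtered.counts + params.prior_count) / eff.to_numpy()[None, :] * 1e6
        )
        for j in range(3):
            rho = spearmanr(
                filtered.counts.iloc[:, j], logcpm.iloc[:, j]
            ).statistic
            assert rho > 0.999

    def test_constant_matrix_gives_constant_rows(self):
        counts = np.tile([[100], [400], [20], [800]], (1, 4))
        m = toy_count_matrix(counts)
        sheet = cc.SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": [f"s{j}" for j in range(4)],
                    "subject_id": [f"p{j}" for j in range(4)],
                    "cell_type": ["n", "n", "nn", "nn"],
                    "diagnosis": ["case", "control", "case", "control"],
                    "sex": ["male", "female", "male", "female"],
                }
            )
        )
        norm, _ = cc.normalize_pipeline(m, sheet)
        assert (norm.max(axis=1) - norm.min(axis=1)).max() < 1e-9
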