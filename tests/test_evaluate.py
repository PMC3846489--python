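import numpy as np
import pandas as pd
import pytest

from hdimpute import (
    ErrorReport,
    SimConfig,
    SplitSpec,
    allelic_error_rate,
    detect_high_error_snps,
    maf_error_profile,
    mask_hd_only,
    simulate_dataset,
    split_by_age,
)
from hdimpute.model import MISSING

from conftest import make_genotypes, make_map, make_pedigree


class TestSplit:
    def _ped(self, n, years=None):
        years = years or [i // 10 for i in range(n)]
        return make_pedigree([(f"a{i:03d}", "0", "0", "M", years[i]) for i in range(n)])

    def test_eighty_twenty(self):
        ped = self._ped(100)
        train, valid = split_by_age(ped, [f"a{i:03d}" for i in range(100)])
        assert len(train) == 80 and len(valid) == 20
        assert set(train) | set(valid) == {f"a{i:03d}" for i in range(100)}
        assert not set(train) & set(valid)

    def test_validation_is_youngest(self):
        ped = self._ped(10, years=[0, 0, 1, 1, 2, 2, 3, 3, 4, 4])
        train, valid = split_by_age(ped, [f"a{i:03d}" for i in range(10)])
        assert valid == ["a008", "a009"]

    def test_floor_rule_on_odd_sizes(self):
        # 788 animals at 20%: floor gives 157; the printed design used 154,
        # so the fraction is overridable
        ped = self._ped(788)
        ids = [f"a{i:03d}" for i in range(788)]
        train, valid = split_by_age(ped, ids)
        assert len(valid) == int(np.floor(0.2 * 788))
        t2, v2 = split_by_age(ped, ids, SplitSpec(validation_fraction=154 / 788))
        assert len(v2) == 154 and len(t2) == 634

    def test_tie_break_by_id(self):
        ped = self._ped(10, years=[1] * 10)
        train, valid = split_by_age(ped, [f"a{i:03d}" for i in range(10)])
        assert valid == ["a008", "a009"]  # largest ids are "youngest"

    def test_missing_birth_year_rejected(self):
        ped = self._ped(5)
        with pytest.raises(ValueError):
            split_by_age(ped, ["a000", "zz"])


class TestMasking:
    def test_all_shared_is_identity(self):
        g = make_genotypes([[0, 1], [2, 0]])
        out = mask_hd_only(g, make_map(2))
        assert np.array_equal(out.calls, g.calls)

    def test_hd_only_columns_blanked(self):
        g = make_genotypes([[0, 1, 2, 1, 0, 1]])
        mmap = make_map(6, shared_every=3)  # markers 0 and 3 shared
        out = mask_hd_only(g, mmap)
        assert (out.calls[0, [0, 3]] != MISSING).all()
        assert (out.calls[0, [1, 2, 4, 5]] == MISSING).all()

    def test_truth_restores_masked(self, small_dataset):
        g = small_dataset.genotypes
        masked = mask_hd_only(g, small_dataset.marker_map)
        restored = masked.copy()
        blanks = restored.calls == MISSING
        restored.calls[blanks] = g.calls[blanks]
        assert np.array_equal(restored.calls, g.calls)


class TestAllelicError:
    def test_worked_example(self):
        truth = make_genotypes([[0, 1, 2]])
        imputed = make_genotypes([[0, 2, 2]])
        rep = allelic_error_rate(imputed, truth, ["m0000", "m0001", "m0002"])
        assert rep.overall_error == pytest.approx(1.0 / 6.0)
        assert rep.n_alleles_compared == 6

    def test_identity_is_zero(self, small_dataset):
        g = small_dataset.genotypes
        rep = allelic_error_rate(g, g, list(g.marker_ids[:50]))
        assert rep.overall_error == 0.0

    def test_complement_heterozygotes_free_homozygotes_full(self):
        het_truth = make_genotypes([[1, 1, 1, 1]])
        het_imp = make_genotypes([[1, 1, 1, 1]])
        rep = allelic_error_rate(het_imp, het_truth, list(het_truth.marker_ids))
        assert rep.overall_error == 0.0
        hom_truth = make_genotypes([[0, 2, 0, 2]])
        hom_imp = make_genotypes([[2, 0, 2, 0]])
        rep2 = allelic_error_rate(hom_imp, hom_truth, list(hom_truth.marker_ids))
        assert rep2.overall_error == 1.0

    def test_overall_is_ratio_not_mean_of_animals(self):
        # animal a0: 1 wrong allele of 2; animal a1: 0 wrong of 4
        truth = make_genotypes([[0, MISSING], [0, 0]])
        imputed = make_genotypes([[1, 0], [0, 0]])
        rep = allelic_error_rate(imputed, truth, ["m0000", "m0001"])
        assert rep.overall_error == pytest.approx(1.0 / 6.0)  # not (0.5 + 0)/2
        assert rep.per_animal_error["a0"] == pytest.approx(0.5)

    def test_truth_missing_excluded(self):
        truth = make_genotypes([[MISSING, 2]])
        imputed = make_genotypes([[0, 2]])
        rep = allelic_error_rate(imputed, truth, ["m0000", "m0001"])
        assert rep.n_alleles_compared == 2

    def test_error_times_n_is_integer(self, small_dataset):
        g = small_dataset.genotypes
        imputed = g.copy()
        rng = np.random.default_rng(0)
        flip = rng.random(imputed.calls.shape) < 0.05
        imputed.calls[flip] = np.clip(imputed.calls[flip] + 1, 0, 2)
        rep = allelic_error_rate(imputed, g, list(g.marker_ids))
        n_wrong = rep.overall_error * rep.n_alleles_compared
        assert abs(n_wrong - round(n_wrong)) < 1e-9

    def test_no_masked_markers_rejected(self):
        g = make_genotypes([[0]])
        with pytest.raises(ValueError):
            allelic_error_rate(g, g, [])


def report_from(errors: dict, overall=0.0):
    return ErrorReport(
        overall_error=overall,
        per_animal_error={},
        per_snp_error=errors,
        n_alleles_compared=2 * len(errors),
    )


class TestHighErrorSnps:
    def test_constant_errors_flag_nothing(self):
        reps = {b: report_from({f"m{j}": 0.01 for j in range(50)}) for b in "ABC"}
        out = detect_high_error_snps(reps, min_breeds=2)
        assert out.empty

    def test_outlier_flagged_in_all_breeds(self):
        rng = np.random.default_rng(1)
        reps = {}
        for b in "ABC":
            errors = {f"m{j}": float(e) for j, e in enumerate(rng.normal(0.01, 0.005, 999).clip(0))}
            errors["bad"] = 0.5
            reps[b] = report_from(errors)
        out = detect_high_error_snps(reps, min_breeds=3)
        assert list(out["snp_name"]) == ["bad"]
        assert out["n_breeds"].iloc[0] == 3

    def test_min_breeds_monotonicity(self):
        rng = np.random.default_rng(2)
        reps = {}
        for k, b in enumerate("ABCDEF"):
            errors = {f"m{j}": float(e) for j, e in enumerate(rng.normal(0.01, 0.005, 500).clip(0))}
            # snp 'x' is bad in 4 of 6 breeds
            errors["x"] = 0.4 if k < 4 else 0.01
            reps[b] = report_from(errors)
        sizes = [len(detect_high_error_snps(reps, min_breeds=mb)) for mb in (6, 4, 3, 2)]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))
        assert len(detect_high_error_snps(reps, min_breeds=4)) >= 1
        assert len(detect_high_error_snps(reps, min_breeds=5)) == 0

    def test_single_snp_breed_rejected(self):
        reps = {"A": report_from({"m": 0.1}), "B": report_from({"m": 0.1})}
        with pytest.raises(ValueError):
            detect_high_error_snps(reps, min_breeds=2)


class TestMafProfile:
    def test_all_zero_errors_single_flat_group(self, small_dataset):
        g = small_dataset.genotypes
        snps = list(g.marker_ids[:100])
        rep = report_from({m: 0.0 for m in snps})
        table = maf_error_profile(rep, g)
        assert set(table["group"]) == {"low"}
        assert (table["mean_error"] == 0).all()

    def test_random_imputation_error_rises_with_maf(self):
        # a marker imputed by drawing each allele from its frequency has
        # expected allelic error 2 p q (p+q=1... doubled binomial overlap);
        # simulate that process and check the high-error group trend
        rng = np.random.default_rng(3)
        n_animals, n_snps = 300, 400
        maf = rng.uniform(0.02, 0.5, n_snps)
        truth = np.array([rng.binomial(2, p, n_animals) for p in maf]).T.astype(np.int8)
        imputed = np.array([rng.binomial(2, p, n_animals) for p in maf]).T.astype(np.int8)
        g_truth = make_genotypes(truth, marker_ids=[f"m{j:04d}" for j in range(n_snps)])
        g_imp = make_genotypes(imputed, marker_ids=[f"m{j:04d}" for j in range(n_snps)])
        rep = allelic_error_rate(g_imp, g_truth, list(g_truth.marker_ids))
        table = maf_error_profile(rep, g_truth, split_at=0.02)
        high = table[table["group"] == "high"].sort_values("maf_bin")
        from scipy.stats import spearmanr

        rho, _ = spearmanr(high["maf_bin"], high["mean_error"])
        assert rho > 0.5

    def test_clean_low_error_group_has_no_maf_trend(self, small_dataset):
        rng = np.random.default_rng(4)
        g = small_dataset.genotypes
        snps = list(g.marker_ids)
        rep = report_from({m: float(e) for m, e in zip(snps, rng.uniform(0, 0.02, len(snps)))})
        table = maf_error_profile(rep, g)
        low = table[table["group"] == "low"].sort_values("maf_bin")
        from scipy.stats import spearmanr

        rho, p = spearmanr(low["maf_bin"], low["mean_error"])
        assert p > 0.05  # no systematic trend on error rates drawn independently of MAF


class TestMultibreed:
    def _breeds(self):
        from hdimpute import simulate_breeds

        cfg = SimConfig(
            n_founders=30, n_chromosomes=1, markers_per_chromosome_hd=300,
            fraction_shared_50k=0.1, chromosome_length_bp=1_000_000, seed=17,
        )
        return simulate_breeds(cfg, ["X", "Y"])

    def test_duplicated_breed_group_equals_single(self):
        from hdimpute import multibreed_evaluate
        from hdimpute.impute import ImputationConfig

        breeds = self._breeds()
        table = multibreed_evaluate(
            {"X": breeds["X"]}, [["X", "X"]], ImputationConfig(seed=5)
        )
        row = table.iloc[0]
        assert row["multi_error"] == pytest.approx(row["single_error"], abs=1e-12)

    def test_pooled_reference_reports_both_breeds(self):
        from hdimpute import multibreed_evaluate
        from hdimpute.impute import ImputationConfig

        breeds = self._breeds()
        table = multibreed_evaluate(breeds, [["X", "Y"]], ImputationConfig(seed=5))
        assert sorted(table["breed"]) == ["X", "Y"]
        assert ((table["single_error"] >= 0) & (table["single_error"] <= 1)).all()
        assert ((table["multi_error"] >= 0) & (table["multi_error"] <= 1)).all()
        # breeds share coalescent ancestry: pooling must not blow up error
        assert (table["multi_error"] < 5 * table["single_error"] + 0.05).all()

    def test_breed_in_two_groups_rejected(self):
        from hdimpute import multibreed_evaluate

        breeds = self._breeds()
        with pytest.raises(ValueError):
            multibreed_evaluate(breeds, [["X"], ["X", "Y"]])
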