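import numpy as np
import pytest

from hdimpute import (
    SimConfig,
    extract_panels,
    gene_drop,
    generate_pedigree,
    inject_artifacts,
    plan_mismapping,
    simulate_dataset,
    simulate_founder_haplotypes,
)
from hdimpute.model import MISSING, UNKNOWN_PARENT


def tiny_cfg(**kw):
    base = dict(
        n_founders=30,
        n_generations=2,
        n_chromosomes=1,
        markers_per_chromosome_hd=200,
        fraction_shared_50k=0.1,
        chromosome_length_bp=700_000,
        seed=3,
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_founders": 0},
            {"n_founders": 1},
            {"markers_per_chromosome_hd": 0},
            {"fraction_shared_50k": 0.0},
            {"fraction_shared_50k": 1.5},
            {"missing_rate": 1.0},
            {"genotype_error_rate": -0.1},
            {"ld_strength": -1.0},
            {"n_mismapped": -1},
        ],
    )
    def test_degenerate_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            tiny_cfg(**kw).validate()


class TestFounderHaplotypes:
    def test_shapes_and_polymorphism(self):
        cfg = tiny_cfg()
        panel, mmap = simulate_founder_haplotypes(cfg)
        assert panel.alleles.shape == (60, 200)
        freqs = panel.alleles.mean(axis=0)
        assert ((freqs > 0) & (freqs < 1)).all()
        assert len(mmap) == 200
        assert (np.diff(mmap.positions_bp) > 0).all()

    def test_two_founders_one_marker(self):
        cfg = tiny_cfg(n_founders=2, n_generations=1, markers_per_chromosome_hd=2, fraction_shared_50k=1.0)
        panel, _ = simulate_founder_haplotypes(cfg)
        assert panel.alleles.shape == (4, 2)
        assert set(np.unique(panel.alleles)) <= {0, 1}

    def test_independent_sites_r2_matches_shuffle_oracle(self):
        # ld_strength 0: mean r2 over distant pairs ~ 1/(2F - 1), same as
        # for explicitly shuffled (independent) columns
        cfg = tiny_cfg(ld_strength=0.0, n_founders=60, markers_per_chromosome_hd=300)
        panel, _ = simulate_founder_haplotypes(cfg)
        X = panel.alleles.astype(float)
        rng = np.random.default_rng(0)

        def mean_r2(M):
            Z = (M - M.mean(0)) / M.std(0)
            C = (Z.T @ Z / len(M)) ** 2
            iu = np.triu_indices_from(C, k=5)  # non-adjacent pairs
            return C[iu].mean()

        shuffled = X.copy()
        for j in range(shuffled.shape[1]):
            rng.shuffle(shuffled[:, j])
        expected = 1.0 / (2 * cfg.n_founders - 1)
        assert mean_r2(X) == pytest.approx(expected, rel=0.25)
        assert mean_r2(shuffled) == pytest.approx(expected, rel=0.25)

    def test_r2_increases_with_ld_strength(self):
        means = []
        for ld in (0.0, 10_000.0, 50_000.0):
            cfg = tiny_cfg(ld_strength=ld, n_founders=60, seed=5)
            panel, mmap = simulate_founder_haplotypes(cfg)
            X = panel.alleles.astype(float)
            Z = (X - X.mean(0)) / X.std(0)
            r = np.array([
                (Z[:, j] @ Z[:, j + 1] / len(Z)) ** 2 for j in range(X.shape[1] - 1)
            ])
            means.append(r.mean())
        assert means[0] < means[1] < means[2]


class TestPedigree:
    def test_single_generation_is_founders_only(self):
        ped = generate_pedigree(tiny_cfg(n_generations=1))
        assert len(ped) == 30
        assert (ped.table["sire_id"] == UNKNOWN_PARENT).all()
        assert (ped.table["dam_id"] == UNKNOWN_PARENT).all()

    def test_progeny_mean_matches_config(self):
        # Holstein-like family size: realized mean within 20% for many sires
        cfg = SimConfig(n_founders=300, n_generations=2, progeny_per_sire_mean=2.30, seed=2)
        ped = generate_pedigree(cfg)
        t = ped.table
        counts = t.loc[t["sire_id"] != UNKNOWN_PARENT].groupby("sire_id").size()
        assert len(counts) >= 100
        assert 2.30 * 0.8 <= counts.mean() <= 2.30 * 1.2

    def test_birth_years_increase_and_acyclic(self):
        ped = generate_pedigree(tiny_cfg(n_generations=3))
        years = ped.birth_years()
        for _, row in ped.table.iterrows():
            for parent in (row["sire_id"], row["dam_id"]):
                if parent != UNKNOWN_PARENT:
                    assert years[parent] < row["birth_year"]
        assert len(ped.topological_order()) == len(ped)  # no cycles


class TestGeneDrop:
    def test_mendelian_consistency_everywhere(self, small_dataset):
        data = small_dataset
        g = data.genotypes
        idx = {a: i for i, a in enumerate(g.animal_ids)}
        for _, row in data.pedigree.table.iterrows():
            if row["sire_id"] == UNKNOWN_PARENT:
                continue
            child = g.calls[idx[row["animal_id"]]]
            for parent in (row["sire_id"], row["dam_id"]):
                p = g.calls[idx[parent]]
                opposing = ((child == 0) & (p == 2)) | ((child == 2) & (p == 0))
                assert not opposing.any()

    def test_genotypes_are_haplotype_sums(self, small_dataset):
        data = small_dataset
        assert np.array_equal(
            data.truth_haplotypes.to_genotypes().calls, data.genotypes.calls
        )

    def test_zero_recombination_copies_parent_haplotypes(self):
        # 10 kb chromosome: Poisson(1e-4) crossovers, offspring gametes are
        # exact copies of single parental haplotypes
        cfg = tiny_cfg(chromosome_length_bp=10_000, markers_per_chromosome_hd=50, ld_strength=1000.0)
        data = simulate_dataset(cfg)
        hap = data.truth_haplotypes
        idx = {a: i for i, a in enumerate(hap.animal_ids)}
        for _, row in data.pedigree.table.iterrows():
            if row["sire_id"] == UNKNOWN_PARENT:
                continue
            child_pat = hap.alleles[2 * idx[row["animal_id"]]]
            si = idx[row["sire_id"]]
            assert (
                np.array_equal(child_pat, hap.alleles[2 * si])
                or np.array_equal(child_pat, hap.alleles[2 * si + 1])
            )

    def test_drift_variance_matches_binomial(self):
        # one generation of random mating: freq change variance ~ p(1-p)/2N
        cfg = SimConfig(
            n_founders=500,
            n_generations=2,
            progeny_per_sire_mean=2.0,
            n_chromosomes=1,
            markers_per_chromosome_hd=150,
            fraction_shared_50k=0.1,
            chromosome_length_bp=600_000,
            ld_strength=0.0,
            seed=11,
        )
        founders, mmap = simulate_founder_haplotypes(cfg)
        ped = generate_pedigree(cfg)
        data = gene_drop(founders, ped, mmap, cfg)
        f_ids = set(founders.animal_ids)
        gen1 = [a for a in data.genotypes.animal_ids if a not in f_ids]
        p0 = founders.alleles.mean(axis=0)
        g1 = data.genotypes.subset(animals=gen1)
        p1 = g1.calls.mean(axis=0) / 2.0
        n1 = g1.n_animals
        ratio = np.mean((p1 - p0) ** 2) / np.mean(p0 * (1 - p0) / (2 * n1))
        # offspring share parents, which inflates variance somewhat above
        # the independent-binomial floor
        assert 0.7 < ratio < 3.0

    def test_missing_founder_haplotypes_rejected(self):
        cfg = tiny_cfg()
        founders, mmap = simulate_founder_haplotypes(cfg)
        ped = generate_pedigree(tiny_cfg(n_founders=40))  # more founders than haplotypes
        with pytest.raises(ValueError, match="founder"):
            gene_drop(founders, ped, mmap, cfg)


class TestArtifacts:
    def test_no_artifacts_is_identity(self, small_dataset):
        cfg = SimConfig(seed=7)
        out = inject_artifacts(small_dataset, cfg)
        assert np.array_equal(out.genotypes.calls, small_dataset.genotypes.calls)
        assert out.mismapped_ids == set()

    def test_missing_fraction_within_binomial_bounds(self, small_dataset):
        cfg = SimConfig(missing_rate=0.1, seed=7)
        out = inject_artifacts(small_dataset, cfg)
        frac = (out.genotypes.calls == MISSING).mean()
        n = out.genotypes.calls.size
        sd = np.sqrt(0.1 * 0.9 / n)
        assert abs(frac - 0.1) < 3 * sd

    def test_error_rate_changes_calls(self, small_dataset):
        cfg = SimConfig(genotype_error_rate=0.05, seed=7)
        out = inject_artifacts(small_dataset, cfg)
        diff = (out.genotypes.calls != small_dataset.genotypes.calls).mean()
        assert 0.03 < diff < 0.07
        # errors are valid codes, never missing
        assert set(np.unique(out.genotypes.calls)) <= {0, 1, 2}

    def test_mismapping_bookkeeping(self, small_dataset):
        cfg = SimConfig(n_mismapped=10, seed=7)
        out = inject_artifacts(small_dataset, cfg)
        assert len(out.mismapped_ids) == 10
        # genotype values travel with the marker id
        for mid in out.mismapped_ids:
            before = small_dataset.genotypes.subset(markers=[mid]).calls
            after = out.genotypes.subset(markers=[mid]).calls
            assert np.array_equal(before, after)
        # positions changed for mismapped markers only
        pos_before = dict(zip(small_dataset.marker_map.marker_ids, small_dataset.marker_map.positions_bp))
        pos_after = dict(zip(out.marker_map.marker_ids, out.marker_map.positions_bp))
        for mid in out.marker_map.marker_ids:
            if mid in out.mismapped_ids:
                assert pos_before[mid] != pos_after[mid]
            else:
                assert pos_before[mid] == pos_after[mid]

    def test_truth_haplotypes_unchanged(self, small_dataset):
        cfg = SimConfig(missing_rate=0.1, genotype_error_rate=0.02, n_mismapped=6, seed=7)
        out = inject_artifacts(small_dataset, cfg)
        sub = out.truth_haplotypes.subset(markers=small_dataset.truth_haplotypes.marker_ids)
        assert np.array_equal(sub.alleles, small_dataset.truth_haplotypes.alleles)

    def test_shared_plan_hits_same_markers(self, small_dataset):
        rng = np.random.default_rng(0)
        plan = plan_mismapping(small_dataset.marker_map, 8, rng, min_displacement_bp=200_000)
        cfg = SimConfig(seed=7)
        out1 = inject_artifacts(small_dataset, cfg, mismap_plan=plan)
        out2 = inject_artifacts(small_dataset, cfg, mismap_plan=plan)
        assert out1.mismapped_ids == out2.mismapped_ids == set(plan)


class TestPanels:
    def test_shared_subset_is_strict_subset(self, small_dataset):
        hd, k50 = extract_panels(small_dataset)
        assert set(k50.marker_ids) < set(hd.marker_ids)
        assert k50.n_markers == len(small_dataset.marker_map.shared_ids())

    def test_full_sharing_yields_identical_panels(self):
        cfg = tiny_cfg(fraction_shared_50k=1.0)
        data = simulate_dataset(cfg)
        hd, k50 = extract_panels(data)
        assert np.array_equal(hd.calls, k50.calls)

    def test_shared_counts(self):
        cfg = tiny_cfg(markers_per_chromosome_hd=1000, fraction_shared_50k=0.05, chromosome_length_bp=3_500_000)
        data = simulate_dataset(cfg)
        assert len(data.marker_map.shared_ids()) == 50

    def test_shared_calls_agree_between_panels(self, small_dataset):
        hd, k50 = extract_panels(small_dataset)
        sub = hd.subset(markers=list(k50.marker_ids))
        assert np.array_equal(sub.calls, k50.calls)


def test_determinism_bit_identical():
    cfg = SimConfig(
        n_founders=20,
        n_chromosomes=1,
        markers_per_chromosome_hd=120,
        chromosome_length_bp=500_000,
        missing_rate=0.05,
        genotype_error_rate=0.01,
        n_mismapped=4,
        seed=42,
    )
    d1 = simulate_dataset(cfg)
    d2 = simulate_dataset(cfg)
    assert np.array_equal(d1.genotypes.calls, d2.genotypes.calls)
    assert np.array_equal(d1.truth_haplotypes.alleles, d2.truth_haplotypes.alleles)
    assert d1.mismapped_ids == d2.mismapped_ids
    assert d1.marker_map.table.equals(d2.marker_map.table)
    assert d1.pedigree.table.equals(d2.pedigree.table)
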