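"""Scan driver, region grouping, trait attribution and pairwise tables."""

import numpy as np
import pandas as pd
import pytest

from pleioscan import plink_io
from pleioscan.postprocess import (
    PleiotropyRegion,
    ScanConfig,
    attribute_traits,
    group_regions,
    pairwise_region_table,
    run_scan,
    summarize_regions,
)
from pleioscan.simulation import SimulationSetting, write_fixture


@pytest.fixture(scope="module")
def effect_fixture(tmp_path_factory):
    """Synthetic dataset with one variant affecting two of three traits
    strongly (5% of variance each at n=5000), pattern-structured missingness
    and covariates."""
    tmp = tmp_path_factory.mktemp("fixture")
    setting = SimulationSetting(
        n=5000, p=3, rho=0.3, h2_trait1=0.05, effect_ratio=1.0,
        affected_traits=(0, 1),
        missing_pattern_spec=[((0, 1), 0.2), ((1, 2), 0.1)],
        seed=2024,
    )
    paths = write_fixture(
        setting, tmp / "fx", n_variants=40, causal_index=7,
        n_covariates=2, geno_missing_rate=0.01,
    )
    return setting, paths


class TestFixtureRoundTrip:
    def test_written_genotypes_read_back_identical(self, tmp_path, rng):
        setting = SimulationSetting(n=100, p=2, seed=9)
        paths = write_fixture(setting, tmp_path / "rt", n_variants=50)
        variants = plink_io.read_bim(paths["bim"])
        samples = plink_io.read_fam(paths["fam"])
        assert len(variants) == 50 and len(samples) == 100
        bed = plink_io.BedFile(paths["bed"], 100, 50)
        dosage = bed.read_block(range(50)).dosage
        assert set(np.unique(dosage)) <= {0.0, 1.0, 2.0}
        # frequencies consistent with the generating law
        assert 0.0 < dosage.mean() / 2.0 < 0.5

    def test_missingness_patterns_recovered_from_files(self, effect_fixture):
        _, paths = effect_fixture
        samples = plink_io.read_fam(paths["fam"])
        pheno = plink_io.read_table(paths["pheno"], samples)
        obs = pheno.notna().to_numpy()
        patterns, counts = np.unique(obs, axis=0, return_counts=True)
        got = {tuple(p.astype(int)): c for p, c in zip(patterns, counts)}
        assert got[(1, 1, 0)] == 1000
        assert got[(0, 1, 1)] == 500
        assert got[(1, 1, 1)] == 3500


class TestScan:
    def test_causal_snp_found_and_effects_recovered(self, effect_fixture):
        """End-to-end: the injected SNP reaches stage-2 genome-wide
        significance, its effect estimates match the truth within 3 SEs, and
        null SNPs stay above the threshold."""
        setting, paths = effect_fixture
        results, skips, log = run_scan(
            paths["bed"], paths["bim"], paths["fam"], paths["pheno"], paths["covar"],
            config=ScanConfig(),
        )
        assert len(results) + len(skips) == 40
        row = results[results["id"] == paths["truth"]["causal_id"]].iloc[0]
        assert row["p_stage2"] < 1e-8
        beta_true = paths["truth"]["beta"]
        for j, t in enumerate(log["trait_names"]):
            assert abs(row[f"beta_{t}"] - beta_true[j]) < 3 * row[f"se_{t}"]
        null_p2 = results.loc[results["id"] != paths["truth"]["causal_id"], "p_stage2"]
        assert (null_p2 > 1e-8).all()

    def test_every_variant_in_results_or_skip_log(self, effect_fixture):
        _, paths = effect_fixture
        results, skips, _ = run_scan(
            paths["bed"], paths["bim"], paths["fam"], paths["pheno"], paths["covar"]
        )
        seen = set(results["id"]) | set(skips["id"])
        assert seen == {f"snp{i + 1}" for i in range(40)}
        assert len(results) + len(skips) == 40

    def test_chunked_scan_identical_to_single_pass(self, effect_fixture):
        _, paths = effect_fixture
        args = (paths["bed"], paths["bim"], paths["fam"], paths["pheno"], paths["covar"])
        res_one, _, _ = run_scan(*args, config=ScanConfig(chunk_size=1000))
        res_chunk, _, _ = run_scan(*args, config=ScanConfig(chunk_size=7))
        pd.testing.assert_frame_equal(res_one, res_chunk)

    def test_null_scan_stage1_calibrated(self, tmp_path):
        """500 null variants: fraction with stage-1 p < 0.05 close to 0.05."""
        setting = SimulationSetting(n=800, p=3, rho=0.2, seed=31)
        paths = write_fixture(setting, tmp_path / "null", n_variants=500)
        results, _, _ = run_scan(
            paths["bed"], paths["bim"], paths["fam"], paths["pheno"]
        )
        frac = (results["p_stage1"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(results))
        assert abs(frac - 0.05) < 3 * se

    def test_allele_flip_leaves_pvalues_invariant(self, tmp_path):
        """Swapping which allele is counted flips the sign of the effects but
        not the inference."""
        setting = SimulationSetting(
            n=1000, p=2, rho=0.2, h2_trait1=0.02, affected_traits=(0,), seed=17
        )
        paths = write_fixture(setting, tmp_path / "flip", n_variants=5)
        res, _, _ = run_scan(paths["bed"], paths["bim"], paths["fam"], paths["pheno"])
        dosage = plink_io.BedFile(paths["bed"], 1000, 5).read_block(range(5)).dosage
        plink_io.write_bed(tmp_path / "flip2.bed", 2.0 - dosage)
        res2, _, _ = run_scan(
            tmp_path / "flip2.bed", paths["bim"], paths["fam"], paths["pheno"]
        )
        np.testing.assert_allclose(
            res2["beta_trait1"].to_numpy(), -res["beta_trait1"].to_numpy(), atol=1e-12
        )
        np.testing.assert_allclose(
            res2["p_stage1"].to_numpy(), res["p_stage1"].to_numpy(), rtol=1e-10
        )

    def test_empty_after_filters(self, tmp_path):
        setting = SimulationSetting(n=200, p=2, seed=18)
        paths = write_fixture(setting, tmp_path / "e", n_variants=3)
        results, skips, _ = run_scan(
            paths["bed"], paths["bim"], paths["fam"], paths["pheno"],
            config=ScanConfig(maf_min=0.6),  # unsatisfiable on purpose
        )
        assert results.empty
        assert len(skips) == 3


def _snps(rows):
    return pd.DataFrame(rows, columns=["chrom", "bp", "id", "p"])


class TestRegions:
    def test_close_snps_merge(self):
        regs = group_regions(
            _snps([("1", 1_000_000, "a", 1e-9), ("1", 1_500_000, "b", 1e-10)])
        )
        assert len(regs) == 1
        assert (regs[0].start_bp, regs[0].end_bp) == (1_000_000, 1_500_000)
        assert regs[0].lead_snp == "b"

    def test_distant_snps_stay_separate(self):
        regs = group_regions(
            _snps([("1", 1_000_000, "a", 1e-9), ("1", 2_500_000, "b", 1e-10)])
        )
        assert len(regs) == 2

    def test_transitive_chain_merges(self):
        regs = group_regions(
            _snps(
                [
                    ("1", 1_000_000, "a", 1e-9),
                    ("1", 1_900_000, "b", 1e-9),
                    ("1", 2_800_000, "c", 1e-12),
                ]
            )
        )
        assert len(regs) == 1
        assert regs[0].n_snps == 3
        assert regs[0].lead_snp == "c"

    def test_matches_single_linkage_oracle(self, rng):
        """Random positions: the merge partition equals brute-force
        single-linkage clustering at the gap threshold."""
        for _ in range(20):
            m = int(rng.integers(2, 40))
            bps = np.sort(rng.integers(1, 30_000_000, m))
            bps = np.unique(bps)
            snps = _snps([("1", int(b), f"s{i}", 1e-9) for i, b in enumerate(bps)])
            regs = group_regions(snps, gap_bp=1_000_000)
            # oracle: union-find over all pairs closer than the gap
            parent = list(range(len(bps)))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(len(bps)):
                for j in range(i + 1, len(bps)):
                    if abs(int(bps[i]) - int(bps[j])) < 1_000_000:
                        parent[find(i)] = find(j)
            n_clusters = len({find(i) for i in range(len(bps))})
            assert len(regs) == n_clusters

    def test_order_invariance_and_idempotence(self, rng):
        rows = [("2", int(b), f"s{i}", 1e-9) for i, b in enumerate([5e6, 1e6, 5.4e6, 9e6])]
        regs1 = group_regions(_snps(rows))
        regs2 = group_regions(_snps(list(reversed(rows))))
        key = lambda r: (r.chrom, r.start_bp, r.end_bp, r.n_snps, r.lead_snp)
        assert sorted(map(key, regs1)) == sorted(map(key, regs2))
        # idempotence: regrouping the region bounds creates no new merges
        again = group_regions(
            _snps([(r.chrom, r.start_bp, r.lead_snp, r.min_p) for r in regs1])
        )
        assert len(again) == len(regs1)

    def test_regions_separated_by_gap(self, rng):
        bps = np.sort(rng.integers(1, 50_000_000, 60))
        regs = group_regions(
            _snps([("3", int(b), f"s{i}", 1e-9) for i, b in enumerate(bps)])
        )
        starts = sorted((r.start_bp, r.end_bp) for r in regs)
        for (s1, e1), (s2, e2) in zip(starts, starts[1:]):
            assert s2 - e1 >= 1_000_000


class TestAttribution:
    def test_marginal_threshold_rule(self):
        mask, forced = attribute_traits(np.array([1e-12, 1e-9, 0.3]), order=2)
        np.testing.assert_array_equal(mask, [True, True, False])
        assert not forced

    def test_forced_when_too_few_pass(self):
        mask, forced = attribute_traits(np.array([1e-4, 0.5, 1e-3]), order=2)
        np.testing.assert_array_equal(mask, [True, False, True])
        assert forced

    def test_simulated_attribution_recovers_affected_pair(self, rng):
        """SNP affecting traits 1 and 3 strongly: the attributed mask is
        {1,3} in at least 95% of replicates."""
        from pleioscan.gls_engine import accumulate_group_stats, gls_fit
        from pleioscan.preprocess import AdjustedPhenotypeMatrix, find_missing_patterns
        from pleioscan.sequential import marginal_pvalues
        from pleioscan.simulation import simulate_dataset

        hits = 0
        n_reps = 200
        for k in range(n_reps):
            setting = SimulationSetting(
                n=2000, p=3, rho=0.2, h2_trait1=0.04, effect_ratio=1.0,
                affected_traits=(0, 2), seed=1000 + k,
            )
            x, Y = simulate_dataset(setting)
            Y -= Y.mean(axis=0)
            adj = AdjustedPhenotypeMatrix(Y, np.ones_like(Y, dtype=bool), list("abc"))
            groups, _ = find_missing_patterns(adj.observed)
            S = Y.T @ Y / (len(Y) - 1)
            x = x - x.mean()
            est = gls_fit(accumulate_group_stats(x, adj, groups), S=S)
            mask, _ = attribute_traits(
                marginal_pvalues(est.beta_hat, est.cov_beta), order=2, trait_alpha=1e-8
            )
            hits += mask[0] and mask[2] and not mask[1]
        assert hits / n_reps >= 0.95


class TestPairwiseTable:
    def _region(self, mask, n_snps=1):
        return PleiotropyRegion(
            chrom="1", start_bp=1, end_bp=2, n_snps=n_snps, lead_snp="s",
            min_p=1e-9, stage=2, trait_mask=np.array(mask, dtype=bool),
        )

    def test_single_full_region(self):
        out = pairwise_region_table([self._region([1, 1, 1])])
        expected = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
        np.testing.assert_array_equal(out["regions"], expected)

    def test_empty_input(self):
        out = pairwise_region_table([])
        assert out["regions"].size == 0

    def test_matches_exhaustive_pair_counting(self, rng):
        p = 4
        regions = [
            self._region(rng.random(p) < 0.5, n_snps=int(rng.integers(1, 10)))
            for _ in range(5)
        ]
        out = pairwise_region_table(regions)
        for a in range(p):
            for b in range(p):
                if a == b:
                    assert out["regions"][a, b] == 0
                    continue
                expect_r = sum(r.trait_mask[a] and r.trait_mask[b] for r in regions)
                expect_s = sum(
                    r.n_snps for r in regions if r.trait_mask[a] and r.trait_mask[b]
                )
                assert out["regions"][a, b] == expect_r
                assert out["snps"][a, b] == expect_s


class TestSummarize:
    def test_end_to_end_region_summary(self, effect_fixture):
        setting, paths = effect_fixture
        results, _, log = run_scan(
            paths["bed"], paths["bim"], paths["fam"], paths["pheno"], paths["covar"]
        )
        regions, table = summarize_regions(results, log["trait_names"], min_order=2)
        assert len(regions) == 1
        assert regions[0].lead_snp == paths["truth"]["causal_id"]
        np.testing.assert_array_equal(regions[0].trait_mask, [True, True, False])
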