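"""Paternal-allele scan, heterozygosity, and the reproductive-mode call."""

import numpy as np
import pytest

from litterscan import (
    ClassifierThresholds,
    GenotypeMatrix,
    LitterSimConfig,
    apply_error,
    classify_mode,
    find_maternal_homozygous_loci,
    offspring_heterozygosity,
    scan_paternal_alleles,
    simulate_fp_litter,
    simulate_litter,
    simulate_ltss_litter,
    simulate_parents,
)
from litterscan.genotypes import ConfigError, SampleMeta
from litterscan.simulate import MOTHER_ID

from conftest import naive_scan, random_matrix


def build(calls, sample_ids=None, locus_ids=None):
    calls = np.asarray(calls, dtype=np.int32)
    n, L = calls.shape[:2]
    return GenotypeMatrix(
        sample_ids or [f"S{i}" for i in range(n)],
        locus_ids or [f"L{j}" for j in range(L)],
        calls,
    )


class TestMaternalHomozygousLoci:
    def test_three_locus_example(self):
        m = build([[[1, 1], [1, 2], [-9, -9]], [[1, 1], [1, 1], [1, 1]]])
        assert find_maternal_homozygous_loci(m, "S0") == ["L0"]

    def test_fully_heterozygous_mother_degenerates(self):
        m = build([[[1, 2], [1, 2]], [[1, 1], [2, 2]]])
        assert find_maternal_homozygous_loci(m, "S0") == []
        with pytest.warns(UserWarning, match="homozygous at no locus"):
            res = scan_paternal_alleles(m, "S0")
        assert res.conservative_count == 0 and res.liberal_count == 0

    def test_missing_mother_id_raises(self):
        m = build([[[1, 1]]])
        with pytest.raises(KeyError):
            find_maternal_homozygous_loci(m, "NOPE")

    def test_hwe_subset_size(self):
        cfg = LitterSimConfig(allele_freq_spec=0.5, n_loci=10_000, seed=21)
        mother, _, _ = simulate_parents(cfg)
        m = build(mother[None, :, :], ["MOM"], [f"L{j}" for j in range(10_000)])
        n_hom = len(find_maternal_homozygous_loci(m, "MOM"))
        # HWE homozygosity p^2 + q^2 = 0.5 at p = 0.5
        assert abs(n_hom / 10_000 - 0.5) < 3 * np.sqrt(0.25 / 10_000)


class TestScan:
    def test_clone_litter_has_zero_counts(self):
        calls = np.ones((4, 6, 2), dtype=np.int32)
        m = build(calls)
        res = scan_paternal_alleles(m, "S0")
        assert res.conservative_count == 0 and res.liberal_count == 0
        assert all(v == 0.0 for v in res.per_offspring_fraction.values())

    def test_counts_nest_within_homozygous_set(self, rng):
        for seed in range(5):
            m = random_matrix(np.random.default_rng(seed), 8, 60, missing_frac=0.1)
            res = scan_paternal_alleles(m, "S0")
            assert (
                res.conservative_count
                <= res.liberal_count
                <= len(res.maternal_homozygous_loci)
            )
            for v in res.per_offspring_fraction.values():
                assert np.isnan(v) or 0.0 <= v <= 1.0

    def test_matches_naive_recomputation(self):
        for seed in range(10):
            m = random_matrix(np.random.default_rng(100 + seed), 7, 50, missing_frac=0.15)
            kids = m.sample_ids[1:]
            res = scan_paternal_alleles(m, "S0", kids)
            hom, flags, conservative, liberal = naive_scan(m, "S0", kids)
            assert res.maternal_homozygous_loci == hom
            for k, sid in enumerate(kids):
                for j, locus in enumerate(hom):
                    want = flags[(sid, locus)]
                    got = int(res.flags[k, j])
                    assert got == (-1 if want is None else want)
            assert res.conservative_loci == conservative
            assert res.liberal_count == len(liberal)

    def test_removing_offspring_never_decreases_conservative(self):
        for seed in range(8):
            m = random_matrix(np.random.default_rng(200 + seed), 6, 40, missing_frac=0.1)
            kids = m.sample_ids[1:]
            full = scan_paternal_alleles(m, "S0", kids).conservative_count
            fewer = scan_paternal_alleles(m, "S0", kids[:-1]).conservative_count
            assert fewer >= full

    def test_missing_policies_differ_as_documented(self):
        # mother hom 1/1; K1 flagged, K2 missing at L0
        m = build(
            [[[1, 1]], [[2, 2]], [[-9, -9]]],
            ["MOM", "K1", "K2"],
        )
        with pytest.warns(UserWarning, match="no evaluable"):
            strict = scan_paternal_alleles(m, "MOM", missing_policy="strict")
        with pytest.warns(UserWarning, match="no evaluable"):
            loose = scan_paternal_alleles(m, "MOM", missing_policy="evaluated_only")
        assert strict.conservative_count == 0
        assert loose.conservative_count == 1
        assert strict.liberal_count == loose.liberal_count == 1

    def test_multiallelic_offspring_allele_counts_as_paternal(self):
        m = build([[[1, 1]], [[1, 3]]])
        res = scan_paternal_alleles(m, "S0")
        assert res.conservative_count == 1

    def test_empty_offspring_rejected(self):
        m = build([[[1, 1]]])
        with pytest.raises(ValueError):
            scan_paternal_alleles(m, "S0", [])


class TestHeterozygosity:
    def test_extremes(self):
        m = build([[[1, 1], [2, 2]], [[1, 2], [1, 2]]])
        het = offspring_heterozygosity(m)
        assert het["S0"] == 0.0 and het["S1"] == 1.0

    def test_all_missing_flagged_not_zero(self):
        m = build([[[-9, -9]]])
        with pytest.warns(UserWarning, match="no non-missing"):
            het = offspring_heterozygosity(m)
        assert np.isnan(het["S0"])

    def test_hwe_expectation(self):
        cfg = LitterSimConfig(allele_freq_spec=0.5, n_loci=10_000, seed=31)
        mother, _, _ = simulate_parents(cfg)
        m = build(mother[None], ["X"], [f"L{j}" for j in range(10_000)])
        het = offspring_heterozygosity(m)["X"]
        assert abs(het - 0.5) < 3 * np.sqrt(0.25 / 10_000)


class TestClassifier:
    def _classify(self, sim, thresholds=None):
        res = scan_paternal_alleles(sim.matrix, MOTHER_ID)
        het = offspring_heterozygosity(sim.matrix)
        return res, classify_mode(res, het, sim.meta, thresholds)

    def test_fp_gametic_duplication_forced(self):
        cfg = LitterSimConfig(
            mode="fp_gametic_duplication", n_sires=None, seed=41,
            dropout_rate=0, miscall_rate=0, missing_rate=0,
        )
        res, call = self._classify(simulate_litter(cfg))
        assert res.conservative_count == 0
        assert call.litter_call == "FP"
        assert set(call.per_offspring_call.values()) == {"parthenogen"}
        assert call.evidence["all_male_offspring"] is True

    def test_ltss_forced(self):
        cfg = LitterSimConfig(mode="ltss", seed=42, dropout_rate=0, miscall_rate=0, missing_rate=0)
        _, call = self._classify(simulate_litter(cfg))
        assert call.litter_call == "LTSS"
        assert set(call.per_offspring_call.values()) == {"sexual"}

    def test_litter_call_iff_any_sexual(self):
        """The litter is LTSS exactly when >=1 offspring is called sexual."""
        for seed in range(6):
            cfg = LitterSimConfig(seed=seed, mode="ltss" if seed % 2 else "fp_terminal_fusion",
                                  n_sires=1 if seed % 2 else None)
            _, call = self._classify(simulate_litter(cfg))
            any_sexual = any(v == "sexual" for v in call.per_offspring_call.values())
            assert (call.litter_call == "LTSS") == any_sexual

    def test_mixed_litter_exact_recovery_at_default_error_rates(self):
        """3 sexual + 2 parthenogen half-litters, default error overlay."""
        base = dict(n_loci=800, seed=51)
        ltss_cfg = LitterSimConfig(mode="ltss", n_offspring=3, **base)
        mother, sires, _ = simulate_parents(ltss_cfg)
        sexual_m, _, _ = simulate_ltss_litter(ltss_cfg, mother, sires)
        fp_cfg = LitterSimConfig(mode="fp_terminal_fusion", n_sires=None, n_offspring=2, **base)
        fp_m, _ = simulate_fp_litter(fp_cfg, mother)

        calls = np.concatenate([sexual_m.calls, fp_m.calls[1:]], axis=0)
        ids = sexual_m.sample_ids + ["P1", "P2"]
        m = GenotypeMatrix(ids, sexual_m.locus_ids, calls)
        m = apply_error(m, LitterSimConfig(seed=52))  # default error rates
        meta = [SampleMeta(MOTHER_ID, "mother", "female")] + [
            SampleMeta(s, "offspring", "male") for s in ids[1:]
        ]
        res = scan_paternal_alleles(m, MOTHER_ID)
        call = classify_mode(res, offspring_heterozygosity(m), meta)
        assert call.per_offspring_call == {
            "O1": "sexual", "O2": "sexual", "O3": "sexual",
            "P1": "parthenogen", "P2": "parthenogen",
        }
        assert call.litter_call == "LTSS"

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            ClassifierThresholds(sexual_min_fraction=0.01, parthenogen_max_fraction=0.05)

    def test_zero_loci_scan_is_ambiguous(self):
        m = build([[[1, 2]], [[1, 2]]], ["MOM", "K1"])
        with pytest.warns(UserWarning):
            res = scan_paternal_alleles(m, "MOM")
        meta = [SampleMeta("MOM", "mother", "female"), SampleMeta("K1", "offspring", "male")]
        call = classify_mode(res, offspring_heterozygosity(m), meta)
        assert call.litter_call == "ambiguous"
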