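from fractions import Fraction

import numpy as np
import pytest

from logicfam import (
    EnumerationConfig,
    enumerate_family,
    family_mse_spectrum,
    optimize,
    score,
)
from logicfam.enumeration import (
    FamilyTooLarge,
    read_family_csv,
    write_family_csv,
)
from logicfam.synth import SynthConfig, generate_instance
from _oracles import brute_force_family


class TestOptimize:
    def test_toy1_optimum_is_the_truth(self, toy1):
        mse_opt, size_opt, witness = optimize(toy1["hg"], toy1["dataset"])
        assert (mse_opt, size_opt) == (0, 3)
        assert witness.mask == toy1["truth"].mask

    def test_all_zero_observations_give_empty_model(self, toy1):
        ds = toy1["dataset"].copy_with(values=np.zeros_like(toy1["dataset"].values))
        mse_opt, size_opt, witness = optimize(toy1["hg"], ds)
        assert (mse_opt, size_opt, witness.mask) == (0, 0, 0)

    def test_matches_brute_force_on_perturbed_data(self, toy1, toy1_noisy):
        _, (mse_bf, size_bf) = brute_force_family(toy1["hg"], toy1_noisy, 0)
        mse_opt, size_opt, _ = optimize(toy1["hg"], toy1_noisy)
        assert (mse_opt, size_opt) == (mse_bf, size_bf)


class TestEnumerate:
    def test_toy1_zero_tolerance_family(self, toy1):
        fam = enumerate_family(toy1["hg"], toy1["dataset"])
        expected, _ = brute_force_family(toy1["hg"], toy1["dataset"], 0)
        assert {m.mask for m in fam} == expected
        assert len(fam) == 1  # the truth is the unique lexicographic optimum

    def test_tolerance_grows_family(self, toy1, toy1_noisy):
        cfg0 = EnumerationConfig(fit_tolerance=0.0, size_bound=10)
        cfg10 = EnumerationConfig(fit_tolerance=0.10, size_bound=10)
        fam0 = enumerate_family(toy1["hg"], toy1_noisy, cfg0)
        fam10 = enumerate_family(toy1["hg"], toy1_noisy, cfg10)
        masks0 = {m.mask for m in fam0}
        masks10 = {m.mask for m in fam10}
        assert masks0 < masks10
        limit = Fraction(11, 10) * fam10.mse_opt
        assert all(s.mse <= limit for s in fam10.scores)

    def test_size_bound_zero_on_zero_data(self, toy1):
        ds = toy1["dataset"].copy_with(values=np.zeros_like(toy1["dataset"].values))
        fam = enumerate_family(toy1["hg"], ds, EnumerationConfig(size_bound=0))
        assert [m.mask for m in fam] == [0]

    def test_safety_cap(self, toy1):
        ds = toy1["dataset"].copy_with(values=np.zeros_like(toy1["dataset"].values))
        cfg = EnumerationConfig(size_bound=100, safety_cap=3)
        with pytest.raises(FamilyTooLarge, match="tighten"):
            enumerate_family(toy1["hg"], ds, cfg)

    def test_canonical_order_and_determinism(self, toy1, toy1_noisy):
        cfg = EnumerationConfig(fit_tolerance=0.10, size_bound=10)
        fam1 = enumerate_family(toy1["hg"], toy1_noisy, cfg)
        fam2 = enumerate_family(toy1["hg"], toy1_noisy, cfg)
        bvs = [m.bitvector() for m in fam1]
        assert bvs == sorted(bvs)
        assert [m.mask for m in fam1] == [m.mask for m in fam2]

    def test_members_rescore_within_bounds(self, toy1, toy1_noisy):
        cfg = EnumerationConfig(fit_tolerance=0.10, size_bound="optimal")
        fam = enumerate_family(toy1["hg"], toy1_noisy, cfg)
        limit = (1 + Fraction(1, 10)) * fam.mse_opt
        for m, s in zip(fam.models, fam.scores):
            rescored = score(m, toy1_noisy, precision=cfg.precision)
            assert rescored == s
            assert rescored.mse <= limit and rescored.size <= fam.size_opt

    @pytest.mark.parametrize("eps", [0.0, 0.02, 0.1])
    def test_oracle_equivalence_on_random_instances(self, eps):
        # the vectorized complete scan agrees with per-model brute force
        for seed in [2, 5, 9]:
            cfg = SynthConfig(
                n_nodes=7, n_stimuli=2, n_inhibitables=1, n_readouts=2,
                edge_prob=0.4, max_gate_size=2, noise_sd=0.05, seed=seed,
            )
            _, hg, _, ds = generate_instance(cfg, max_hyperedges=10)
            expected, (mse_bf, size_bf) = brute_force_family(hg, ds, eps)
            fam = enumerate_family(
                hg, ds, EnumerationConfig(fit_tolerance=eps, size_bound="optimal")
            )
            assert (fam.mse_opt, fam.size_opt) == (mse_bf, size_bf)
            assert {m.mask for m in fam} == expected

    def test_monotone_in_tolerance(self, toy1, toy1_noisy):
        prev = set()
        for eps in (0.0, 0.02, 0.1, 0.5):
            cfg = EnumerationConfig(fit_tolerance=eps, size_bound=10)
            cur = {m.mask for m in enumerate_family(toy1["hg"], toy1_noisy, cfg)}
            assert prev <= cur
            prev = cur


class TestSpectrum:
    def test_single_model_family(self, toy1):
        fam = enumerate_family(toy1["hg"], toy1["dataset"])
        assert family_mse_spectrum(fam) == [(Fraction(0), 1)]

    def test_matches_brute_force_recount(self, toy1, toy1_noisy):
        cfg = EnumerationConfig(fit_tolerance=0.10, size_bound=10)
        fam = enumerate_family(toy1["hg"], toy1_noisy, cfg)
        spectrum = family_mse_spectrum(fam)
        mses = [s.mse for s in fam.scores]
        assert [m for m, _ in spectrum] == sorted(set(mses))
        assert sum(c for _, c in spectrum) == len(fam)
        for m, c in spectrum:
            assert mses.count(m) == c


class TestFamilyIO:
    def test_csv_roundtrip(self, toy1, toy1_noisy, tmp_path):
        cfg = EnumerationConfig(fit_tolerance=0.10, size_bound=10)
        fam = enumerate_family(toy1["hg"], toy1_noisy, cfg)
        f = tmp_path / "family.csv"
        write_family_csv(fam, f)
        back = read_family_csv(f, toy1["hg"])
        assert [m.mask for m in back] == [m.mask for m in fam]
        assert back.scores == fam.scores
        assert (back.mse_opt, back.size_opt) == (fam.mse_opt, fam.size_opt)

    def test_byte_identical_outputs(self, toy1, toy1_noisy, tmp_path):
        cfg = EnumerationConfig(fit_tolerance=0.10, size_bound=10)
        paths = []
        for i in (1, 2):
            fam = enumerate_family(toy1["hg"], toy1_noisy, cfg)
            p = tmp_path / f"family{i}.csv"
            write_family_csv(fam, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]
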