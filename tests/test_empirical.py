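"""Tests for the measured-landscape pipeline and the synthetic fixture."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from traitscape import DistributionSpec, GAUSSIAN, PARETO_CUTOFF, gaussian_calibrated
from traitscape.empirical import (
    LandscapeValidationError,
    MeasuredLandscape,
    deconvolve_logistic,
    deconvolve_trait,
    empirical_bottleneck,
    fit_pareto_tail,
    make_fixture,
    normalize_fitness,
    read_landscape_table,
    sme_spectrum,
    write_landscape_table,
)


def toy_table_K3():
    rows = []
    for bits in itertools.product("01", repeat=3):
        g = "".join(bits)
        rows.append({"genotype": g, "F_blue": 1.0 + g.count("0"), "F_red": 1.0 + g.count("1")})
    return pd.DataFrame(rows)


@pytest.fixture
def toy_path(tmp_path):
    path = tmp_path / "toy.csv"
    toy_table_K3().to_csv(path, index=False)
    return path


def additive_landscape(h, normalized=True):
    """Build a MeasuredLandscape whose E is exactly additive in h."""
    K = len(h)
    codes = np.arange(1 << K)
    E = ((codes[:, None] >> np.arange(K)) & 1).astype(float) @ h
    table = pd.DataFrame(
        {
            "genotype": [format(c, f"0{K}b")[::-1] for c in codes],
            "F_blue": 1.0,
            "F_red": 1.0,
            "E_B": E,
            "E_R": 0.0,
            "E": E,
        },
        index=codes,
    )
    return MeasuredLandscape(K=K, table=table, normalized=normalized)


class TestReader:
    def test_complete_toy_table(self, toy_path):
        land = read_landscape_table(toy_path)
        assert land.K == 3
        assert land.n == 8

    def test_missing_genotype_named(self, tmp_path):
        df = toy_table_K3()
        df = df[df["genotype"] != "111"]
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        with pytest.raises(LandscapeValidationError, match="111"):
            read_landscape_table(p)

    def test_duplicate_rejected(self, tmp_path):
        df = pd.concat([toy_table_K3()] * 1)
        df.loc[len(df)] = {"genotype": "010", "F_blue": 1.0, "F_red": 1.0}
        p = tmp_path / "dup.csv"
        df.to_csv(p, index=False)
        with pytest.raises(LandscapeValidationError, match="010"):
            read_landscape_table(p)

    def test_ragged_and_negative_rejected(self, tmp_path):
        df = toy_table_K3()
        df.loc[0, "genotype"] = "0000"
        p = tmp_path / "ragged.csv"
        df.to_csv(p, index=False)
        with pytest.raises(LandscapeValidationError):
            read_landscape_table(p)
        df = toy_table_K3()
        df.loc[2, "F_red"] = -0.5
        p2 = tmp_path / "neg.csv"
        df.to_csv(p2, index=False)
        with pytest.raises(LandscapeValidationError):
            read_landscape_table(p2)

    def test_tsv_round_trip(self, toy_path, tmp_path):
        land = read_landscape_table(toy_path)
        out = tmp_path / "round.tsv"
        write_landscape_table(land, out)
        back = read_landscape_table(out)
        np.testing.assert_allclose(back.FB, land.FB)


class TestNormalize:
    def test_references_scaled_to_one(self, toy_path):
        land = normalize_fitness(read_landscape_table(toy_path))
        assert land.FB[0] == pytest.approx(1.0)
        assert land.FR[-1] == pytest.approx(1.0)

    def test_idempotent(self, toy_path):
        once = normalize_fitness(read_landscape_table(toy_path))
        twice = normalize_fitness(once)
        np.testing.assert_allclose(twice.FB, once.FB)
        np.testing.assert_allclose(twice.FR, once.FR)

    def test_zero_reference_rejected(self, toy_path):
        land = read_landscape_table(toy_path)
        land.table.loc[0, "F_blue"] = 0.0
        with pytest.raises(LandscapeValidationError):
            normalize_fitness(land)


class TestDeconvolution:
    def test_power_law_values(self, toy_path):
        land = deconvolve_trait(normalize_fitness(read_landscape_table(toy_path)), 0.44)
        fb = land.FB
        np.testing.assert_allclose(land.table["E_B"], fb**0.44)
        assert 0.5**0.44 == pytest.approx(0.7371, abs=2e-4)
        np.testing.assert_allclose(land.E, land.table["E_B"] - land.table["E_R"])

    def test_requires_normalization(self, toy_path):
        with pytest.raises(LandscapeValidationError):
            deconvolve_trait(read_landscape_table(toy_path))

    def test_invalid_exponent(self, toy_path):
        land = normalize_fitness(read_landscape_table(toy_path))
        with pytest.raises(ValueError):
            deconvolve_trait(land, exponent=0.0)


class TestSmeSpectrum:
    def test_count_and_symmetry(self):
        h = np.random.default_rng(0).normal(0, 1, 5)
        land = additive_landscape(h)
        spectrum = sme_spectrum(land)
        assert spectrum.size == 5 * 2**5
        np.testing.assert_allclose(np.sort(spectrum), -np.sort(-spectrum)[::-1])

    def test_additive_background_independence(self):
        """On an additive landscape every ΔE_i equals ±h_i on all backgrounds."""
        h = np.random.default_rng(1).normal(0, 1, 6)
        land = additive_landscape(h)
        spectrum = sme_spectrum(land).reshape(6, 2**6)
        spread = np.abs(np.abs(spectrum) - np.abs(h)[:, None]).max()
        assert spread < 1e-10


class TestParetoFit:
    def test_parameter_recovery(self):
        spec = DistributionSpec(PARETO_CUTOFF, alpha=0.7, xm=0.1, cutoff=2.0)
        draws = np.abs(spec.sample(100_000, np.random.default_rng(2)))
        fit = fit_pareto_tail(draws, xm=0.1, cutoff=2.0)
        assert abs(fit.alpha_hat - 0.7) < 3 * fit.stderr_alpha
        assert fit.n_tail >= 30

    def test_hill_estimator_cross_check(self):
        """Untruncated MLE equals the Hill estimator (independent closed form)."""
        rng = np.random.default_rng(3)
        alpha = 1.3
        draws = 0.1 * (1 - rng.random(20_000)) ** (-1 / alpha)  # pure Pareto, xm=0.1
        fit = fit_pareto_tail(draws, xm=0.1)
        hill = draws.size / np.log(draws / 0.1).sum()
        assert fit.alpha_hat == pytest.approx(hill, rel=1e-3)
        assert abs(fit.alpha_hat - alpha) < 2 * fit.stderr_alpha

    def test_too_few_tail_points(self):
        with pytest.raises(ValueError):
            fit_pareto_tail(np.full(100, 0.05), xm=0.1)


class TestEmpiricalBottleneck:
    def test_constructed_deep_valley(self):
        """All orders but one hit a dead state; EC is that path's bottleneck."""
        h = np.array([1.0, -2.0, 1.2])
        land = additive_landscape(h)
        # endpoints: E(000)=0 -> not a valid two-phenotype landscape; shift
        t = land.table.copy()
        t["E"] = t["E"] + 0.9  # E(000)=0.9 > 0; E(111)=0.9+0.2=1.1 > 0 -> invalid
        with pytest.raises(LandscapeValidationError):
            empirical_bottleneck(MeasuredLandscape(K=3, table=t, normalized=True))

        # hand-built valid landscape with a single viable chain
        E = np.array([1.0, 0.8, 0.05, 0.6, 0.01, 0.02, -0.7, -1.1])
        t2 = land.table.copy()
        t2["E"] = E
        res = empirical_bottleneck(MeasuredLandscape(K=3, table=t2, normalized=True))
        # only the order 0,1,2 (states 1, 3 -> 0.8, 0.6) stays alive; bottleneck 0.6
        assert res.EC == pytest.approx(0.6)
        assert res.n_paths_at_EC == 1

    def test_capped_landscape(self):
        E = np.array([0.5, 2.0, 1.5, -0.4])
        t = additive_landscape(np.zeros(2)).table.copy()
        t["E"] = E
        res = empirical_bottleneck(MeasuredLandscape(K=2, table=t, normalized=True))
        assert res.EC == pytest.approx(0.4)
        assert res.topology == "capped_no_jumper"

    def test_brute_force_agreement_small_K(self):
        rng = np.random.default_rng(4)
        from test_pathspace import brute_force_EC

        for _ in range(10):
            K = int(rng.integers(2, 6))
            E = rng.normal(0, 1, 1 << K)
            E[0] = abs(E[0]) + 0.5
            E[-1] = -abs(E[-1]) - 0.5
            t = additive_landscape(np.zeros(K)).table.copy()
            t["E"] = E
            res = empirical_bottleneck(MeasuredLandscape(K=K, table=t, normalized=True))
            Eminref = min(E[0], abs(E[-1]))
            assert res.EC == pytest.approx(brute_force_EC(E, K, Eminref), abs=1e-14)


@pytest.fixture(scope="module")
def fixture_K6(tmp_path_factory):
    path = tmp_path_factory.mktemp("fixture") / "fix.tsv"
    fx = make_fixture(K=6, config=gaussian_calibrated(), noise_cv=0.0, seed=3, path=path)
    return fx, path


class TestFixture:
    def test_passes_reader_validation(self, fixture_K6):
        fx, path = fixture_K6
        land = read_landscape_table(path)
        assert land.K == 6
        assert land.n == 64

    def test_noiseless_rank_round_trip(self, fixture_K6):
        """Power-law deconvolution recovers the generating trait order exactly."""
        fx, path = fixture_K6
        land = deconvolve_trait(normalize_fitness(read_landscape_table(path)), 0.44)
        rho = stats.spearmanr(land.E, fx.subcube.E).statistic
        assert rho == pytest.approx(1.0)

    def test_noiseless_exact_inverse_recovers_EC(self, fixture_K6):
        """The logistic inverse recovers E up to the factor 2, hence the same
        bottleneck state and EC (scaled by 2)."""
        fx, path = fixture_K6
        land = deconvolve_logistic(read_landscape_table(path), fx.fitness_params)
        res = empirical_bottleneck(land)
        assert res.EC == pytest.approx(2 * fx.pathspace.EC, rel=1e-9)
        assert res.jumpers == fx.pathspace.jumpers

    def test_noisy_fixture_keeps_single_jumper_mostly(self):
        """Mild measurement noise usually preserves the bottleneck topology."""
        hits = 0
        for seed in range(8):
            fx = make_fixture(K=6, config=gaussian_calibrated(), noise_cv=0.1, seed=seed)
            land = deconvolve_logistic(fx.landscape, fx.fitness_params)
            res = empirical_bottleneck(land)
            hits += res.single_jumper
        assert hits >= 4

    def test_invalid_arguments(self):
        cfg = gaussian_calibrated()
        with pytest.raises(ValueError):
            make_fixture(K=20, config=cfg)
        with pytest.raises(ValueError):
            make_fixture(K=6, config=cfg, noise_cv=-0.1)
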