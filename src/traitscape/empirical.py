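"""Analysis of measured two-phenotype combinatorial landscapes.

This module mirrors, on real or synthetic data, the pipeline used on the
Poelwijk-style fluorescent-protein dataset: a complete 2^K genotype table
with a blue and a red fitness per variant (all-zeros = blue reference,
all-ones = red reference) is normalized to its reference values,
deconvolved into underlying traits (power-law inverse, exponent 0.44 by
default), reduced to the single combined trait E = EB - ER, and analyzed
for its single-mutation-effect (SME) spectrum, Pareto tail, and
path-bottleneck topology.

A synthetic fixture generator replaces the experimental download: it maps
a calibrated-model subcube through the finite-beta sigmoidal fitness
functions, applies multiplicative lognormal measurement noise, and writes
the same delimited table format the reader ingests, so the full pipeline
is testable without external data.  Real tables (e.g. the published
2^13-variant dataset) can be fed through the same reader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._seeding import as_seed_sequence, child
from .ensemble import ModelConfig
from .landscape import BLUE, RED, FitnessParams, fitness
from .pathspace import (
    PathSpaceResult,
    SubcubeLandscape,
    SubcubeTooLarge,
    analyze_subcube,
    enumerate_subcube,
)
from .sme_pool import sample_pool
from .tuning import TuningFailure, build_reference_pair

__all__ = [
    "MeasuredLandscape",
    "ParetoFit",
    "LandscapeValidationError",
    "FixtureResult",
    "read_landscape_table",
    "write_landscape_table",
    "normalize_fitness",
    "deconvolve_trait",
    "deconvolve_logistic",
    "sme_spectrum",
    "fit_pareto_tail",
    "empirical_bottleneck",
    "make_fixture",
]

COLUMNS = ("genotype", "F_blue", "F_red")


class LandscapeValidationError(ValueError):
    pass


@dataclass(frozen=True)
class MeasuredLandscape:
    """A complete 2^K two-color landscape table.

    ``table`` is indexed by the integer code of the genotype (character i
    of the bitstring = site i = bit i), sorted ascending, with columns
    ``genotype``, ``F_blue``, ``F_red`` and, after deconvolution, ``E_B``,
    ``E_R`` and ``E``.  Code 0 is the blue reference (all zeros), code
    2^K - 1 the red reference (all ones).
    """

    K: int
    table: pd.DataFrame
    normalized: bool = False

    @property
    def n(self) -> int:
        return 1 << self.K

    @property
    def FB(self) -> np.ndarray:
        return self.table["F_blue"].to_numpy(dtype=float)

    @property
    def FR(self) -> np.ndarray:
        return self.table["F_red"].to_numpy(dtype=float)

    @property
    def E(self) -> np.ndarray:
        if "E" not in self.table:
            raise LandscapeValidationError("trait E not derived yet; deconvolve first")
        return self.table["E"].to_numpy(dtype=float)

    @property
    def EBref(self) -> float:
        return float(self.E[0])

    @property
    def ERref(self) -> float:
        return float(self.E[-1])


@dataclass(frozen=True)
class ParetoFit:
    """Truncated Pareto tail fit of the |SME| spectrum."""

    alpha_hat: float
    xm: float
    cutoff: float
    n_tail: int
    stderr_alpha: float


def _code(bitstring: str) -> int:
    # character i of the string is site i, stored in bit i
    return int(bitstring[::-1], 2)


def _bitstring(code: int, K: int) -> str:
    return format(code, f"0{K}b")[::-1]


def read_landscape_table(path) -> MeasuredLandscape:
    """Load and validate a delimited ``genotype, F_blue, F_red`` table.

    The file may be comma- or tab-separated.  Validation checks that the
    genotypes are equal-length bitstrings forming the complete 2^K
    hypercube, with no duplicates and non-negative fitness values; errors
    name the offending rows.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={"genotype": str})
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise LandscapeValidationError(f"missing required columns: {missing_cols}")
    geno = df["genotype"].astype(str)
    bad = geno[~geno.str.fullmatch("[01]+")]
    if len(bad):
        raise LandscapeValidationError(f"non-bitstring genotypes: {list(bad.head(5))}")
    K = len(geno.iloc[0])
    ragged = geno[geno.str.len() != K]
    if len(ragged):
        raise LandscapeValidationError(
            f"ragged bitstrings (expected length {K}): {list(ragged.head(5))}"
        )
    dup = geno[geno.duplicated()]
    if len(dup):
        raise LandscapeValidationError(f"duplicated genotypes: {sorted(set(dup))[:5]}")
    codes = geno.map(_code)
    expected = set(range(1 << K))
    found = set(codes)
    if found != expected:
        missing = sorted(expected - found)
        names = [_bitstring(c, K) for c in missing[:5]]
        raise LandscapeValidationError(
            f"incomplete hypercube: {len(missing)} of {1 << K} genotypes missing, "
            f"e.g. {names}"
        )
    for col in ("F_blue", "F_red"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise LandscapeValidationError(f"non-numeric values in {col}")
        neg = geno[vals < 0]
        if len(neg):
            raise LandscapeValidationError(f"negative {col} at genotypes {list(neg.head(5))}")
        df[col] = vals
    out = df.loc[:, list(COLUMNS)].copy()
    out.index = codes.to_numpy()
    out = out.sort_index()
    return MeasuredLandscape(K=K, table=out)


def write_landscape_table(land: MeasuredLandscape, path, sep: str = "\t") -> None:
    """Write the standard ``genotype, F_blue, F_red`` table."""
    land.table.loc[:, list(COLUMNS)].to_csv(path, sep=sep, index=False)


def normalize_fitness(land: MeasuredLandscape) -> MeasuredLandscape:
    """Divide each color by its reference value: FB(a_B) = FR(a_R) = 1.

    Idempotent; raises if either reference fitness is zero.
    """
    fb0 = float(land.FB[0])
    fr1 = float(land.FR[-1])
    if fb0 <= 0 or fr1 <= 0:
        raise LandscapeValidationError(
            f"reference fitness must be positive to normalize (FB(a_B)={fb0}, FR(a_R)={fr1})"
        )
    table = land.table.copy()
    table["F_blue"] = table["F_blue"] / fb0
    table["F_red"] = table["F_red"] / fr1
    return MeasuredLandscape(K=land.K, table=table, normalized=True)


def _with_traits(land: MeasuredLandscape, EB: np.ndarray, ER: np.ndarray) -> MeasuredLandscape:
    table = land.table.copy()
    table["E_B"] = EB
    table["E_R"] = ER
    table["E"] = EB - ER
    return MeasuredLandscape(K=land.K, table=table, normalized=land.normalized)


def deconvolve_trait(land: MeasuredLandscape, exponent: float = 0.44) -> MeasuredLandscape:
    """Power-law deconvolution: EB = FB^exponent, ER = FR^exponent, E = EB - ER.

    Requires a normalized landscape.  0.44 is the exponent used for both
    phenotypes in the original analysis of the fluorescent-protein data;
    it is a convention, not a fit performed here.
    """
    if exponent <= 0:
        raise ValueError(f"exponent must be positive, got {exponent}")
    if not land.normalized:
        raise LandscapeValidationError("normalize the landscape before deconvolving")
    return _with_traits(land, land.FB ** exponent, land.FR ** exponent)


def deconvolve_logistic(land: MeasuredLandscape, params: FitnessParams) -> MeasuredLandscape:
    """Exact inverse of the model's sigmoids (for synthetic round trips).

    With EB = Eth - log(phi0/FB - 1)/beta and the mirrored expression for
    ER, a noiseless fixture generated at trait E recovers EB = E and
    ER = -E exactly, so the combined trait comes back as 2E.  Applies to
    *unnormalized* fixtures; fitness is clipped away from {0, phi0} to
    keep the logits finite.
    """
    eps = 1e-300
    fb = np.clip(land.FB / params.phi0, eps, 1 - 1e-16)
    fr = np.clip(land.FR / params.phi0, eps, 1 - 1e-16)
    EB = params.Eth - np.log(1.0 / fb - 1.0) / params.beta
    ER = params.Eth - np.log(1.0 / fr - 1.0) / params.beta
    return _with_traits(land, EB, ER)


def sme_spectrum(land: MeasuredLandscape) -> np.ndarray:
    """All K * 2^K signed single-mutation effects ΔE_i(a).

    For every background ``a`` and site ``i``, the trait change of
    flipping site i: E(a with site i flipped) - E(a).  The multiset
    contains each mutation together with its reverse, so it is symmetric
    about zero by construction.
    """
    E = land.E
    codes = np.arange(land.n)
    return np.concatenate([E[codes ^ (1 << i)] - E for i in range(land.K)])


def fit_pareto_tail(values, xm: float, cutoff: float = math.inf) -> ParetoFit:
    """Maximum-likelihood Pareto exponent for the tail above ``xm``.

    Fits the conditional density ``f(x) ∝ x^-(alpha+1)`` on
    ``(xm, cutoff]`` to the absolute effects exceeding ``xm``; requires at
    least 30 tail points.  The standard error comes from the observed
    information (numerical second derivative of the log-likelihood).
    """
    if xm <= 0:
        raise ValueError(f"xm must be positive, got {xm}")
    x = np.abs(np.asarray(values, dtype=float))
    tail = x[(x > xm) & (x <= cutoff)]
    n = tail.size
    if n < 30:
        raise ValueError(f"only {n} values in ({xm}, {cutoff}]; need at least 30 for a tail fit")
    S = float(np.log(tail / xm).sum())
    log_ratio = math.log(cutoff / xm) if math.isfinite(cutoff) else math.inf

    def nll(a: float) -> float:
        # f(x) = a x^-(a+1) / (xm^-a - cutoff^-a), x in (xm, cutoff]
        if math.isfinite(log_ratio):
            log_norm = -a * math.log(xm) + math.log1p(-math.exp(-a * log_ratio))
        else:
            log_norm = -a * math.log(xm)
        return -(n * math.log(a) - n * log_norm - (a + 1.0) * (S + n * math.log(xm)))

    res = minimize_scalar(nll, bounds=(1e-8, 100.0), method="bounded")
    a_hat = float(res.x)
    h = 1e-4 * max(1.0, a_hat)
    info = (nll(a_hat + h) - 2.0 * nll(a_hat) + nll(a_hat - h)) / h**2
    stderr = float(1.0 / math.sqrt(info)) if info > 0 else float("nan")
    return ParetoFit(alpha_hat=a_hat, xm=xm, cutoff=cutoff, n_tail=n, stderr_alpha=stderr)


def empirical_bottleneck(land: MeasuredLandscape, max_K: int = 14) -> PathSpaceResult:
    """Bottleneck analysis of the full 2^K hypercube.

    Reuses the maximin path machinery with the all-zeros corner as the
    blue endpoint (E > 0) and the all-ones corner as the red endpoint
    (E < 0).
    """
    if land.K > max_K:
        raise SubcubeTooLarge(f"K={land.K} exceeds max_K={max_K}")
    E = land.E
    if not (E[0] > 0 and E[-1] < 0):
        raise LandscapeValidationError(
            f"expected E(all-zeros) > 0 > E(all-ones); got {E[0]:.3g} and {E[-1]:.3g}"
        )
    sub = SubcubeLandscape(
        M=land.K,
        diff_sites=np.arange(land.K),
        E=E.copy(),
        EBref=float(E[0]),
        ERref=float(E[-1]),
    )
    return analyze_subcube(sub)


@dataclass(frozen=True)
class FixtureResult:
    """A synthetic landscape plus the model instance that generated it."""

    landscape: MeasuredLandscape
    subcube: SubcubeLandscape
    fitness_params: FitnessParams
    pathspace: PathSpaceResult


def make_fixture(
    K: int,
    config: ModelConfig,
    noise_cv: float = 0.1,
    seed=0,
    path: Optional[Path] = None,
    beta: float = 10.0,
    max_tries: int = 20000,
) -> FixtureResult:
    """Generate a synthetic 2^K landscape emulating the measured dataset.

    Calibrated-model instances are drawn until one separates its
    references by exactly M = K mutations; its subcube traits are mapped
    through the finite-sharpness sigmoids (``beta``, threshold
    ``config.ET``) and multiplied by lognormal noise with coefficient of
    variation ``noise_cv`` (mean 1), mimicking fluorescence measurement
    error while preserving non-negativity.  The blue reference lands on
    the all-zeros bitstring by the subcube's mask convention.
    """
    if K > config.max_M_paths:
        raise ValueError(f"K={K} exceeds config.max_M_paths={config.max_M_paths}")
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be non-negative, got {noise_cv}")
    master = as_seed_sequence(seed)
    params = config.tuning_params()
    sub = None
    for i in range(max_tries):
        ss = child(master, i)
        pool = sample_pool(config.spec, config.L, child(ss, 0))
        try:
            pair = build_reference_pair(pool, params, child(ss, 1))
        except TuningFailure:
            continue
        if pair.M == K:
            sub = enumerate_subcube(pool, pair, max_M=K)
            break
    if sub is None:
        raise RuntimeError(f"no instance with M={K} found in {max_tries} tries")
    fparams = FitnessParams(Eth=config.ET, beta=beta, phi0=1.0)
    FB = fitness(sub.E, BLUE, fparams)
    FR = fitness(sub.E, RED, fparams)
    if noise_cv > 0:
        gen = np.random.default_rng(child(master, max_tries))  # disjoint from search streams
        sigma = math.sqrt(math.log1p(noise_cv**2))
        FB = FB * gen.lognormal(-0.5 * sigma**2, sigma, FB.size)
        FR = FR * gen.lognormal(-0.5 * sigma**2, sigma, FR.size)
    codes = np.arange(1 << K)
    table = pd.DataFrame(
        {
            "genotype": [_bitstring(c, K) for c in codes],
            "F_blue": FB,
            "F_red": FR,
        },
        index=codes,
    )
    land = MeasuredLandscape(K=K, table=table)
    if path is not None:
        write_landscape_table(land, path)
    return FixtureResult(
        landscape=land,
        subcube=sub,
        fitness_params=fparams,
        pathspace=analyze_subcube(sub),
    )
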