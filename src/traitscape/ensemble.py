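"""Instance ensembles at fixed parameters and their summary statistics.

An *instance* is one realization of the random model: a zero-sum SME pool,
a tuned blue/red reference pair and — when the pair is close enough
(2 <= M <= ``max_M_paths``) — the subcube landscape of its intermediates
with the full bottleneck analysis.  Ensembles of independent instances
give the distributions that characterize the landscape topology: the
mutation count M, the overshoot EBref/ET, the number of greedy steps, the
spectrum of selected SMEs, EC/Emaxref, the jumper position j/M, and the
number of surviving paths.

Two named presets fix the calibrated operating points:
``gaussian_calibrated`` (L=500, p=0.26, ET=2.0, unit-variance Gaussian)
and ``pareto_calibrated`` (L=500, p=0.25, ET=1.1, Pareto cutoff with
alpha=0.7, xm=0.1, cutoff 2).

The desk-scale default is 2000 instances (the reference analyses used
20000); standard errors scale as 1/sqrt(n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
import pandas as pd

from ._seeding import as_seed_sequence, child
from .pathspace import PathSpaceResult, SubcubeLandscape, analyze_subcube, enumerate_subcube
from .sme_pool import DistributionSpec, GAUSSIAN, PARETO_CUTOFF, SMEPool, sample_pool
from .tuning import ReferencePair, TuningFailure, TuningParams, build_reference_pair

__all__ = [
    "ModelConfig",
    "Instance",
    "EnsembleSummary",
    "gaussian_calibrated",
    "pareto_calibrated",
    "PRESETS",
    "generate_instance",
    "run_ensemble",
    "jumper_position_profile",
]


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of one ensemble run."""

    L: int
    spec: DistributionSpec
    p: float
    ET: float
    max_M_paths: int = 14
    n_instances: int = 2000
    seed: int = 0
    compute_paths: bool = True  # False: tuning statistics only (faster)

    def tuning_params(self) -> TuningParams:
        return TuningParams(p=self.p, ET=self.ET)


def gaussian_calibrated(**overrides) -> ModelConfig:
    """Calibrated Gaussian operating point: L=500, p=0.26, ET=2.0."""
    cfg = ModelConfig(L=500, spec=DistributionSpec(GAUSSIAN), p=0.26, ET=2.0)
    return replace(cfg, **overrides) if overrides else cfg


def pareto_calibrated(**overrides) -> ModelConfig:
    """Calibrated Pareto-cutoff operating point: L=500, p=0.25, ET=1.1."""
    cfg = ModelConfig(
        L=500,
        spec=DistributionSpec(PARETO_CUTOFF, alpha=0.7, xm=0.1, cutoff=2.0),
        p=0.25,
        ET=1.1,
    )
    return replace(cfg, **overrides) if overrides else cfg


PRESETS = {
    "gaussian_calibrated": gaussian_calibrated,
    "pareto_calibrated": pareto_calibrated,
}


@dataclass(frozen=True)
class Instance:
    """One realization: pool, reference pair, and (optionally) path analysis.

    ``subcube``/``result`` are present iff 2 <= M <= max_M_paths and path
    analysis was requested; M=1 pairs (never observed at calibrated
    parameters) and pairs beyond the size limit carry None.
    """

    pool: SMEPool
    pair: ReferencePair
    subcube: Optional[SubcubeLandscape]
    result: Optional[PathSpaceResult]
    seed: object = field(compare=False, default=None)


def generate_instance(config: ModelConfig, instance_seed) -> Instance:
    """Generate one instance, fully reproducible from (config, seed).

    Substreams: ``child(instance_seed, 0)`` samples the pool and
    ``child(instance_seed, 1)`` drives the tuning (which itself splits
    into blue/red substreams).
    """
    ss = as_seed_sequence(instance_seed)
    pool = sample_pool(config.spec, config.L, child(ss, 0))
    pair = build_reference_pair(pool, config.tuning_params(), child(ss, 1))
    subcube = result = None
    if config.compute_paths and 2 <= pair.M <= config.max_M_paths:
        subcube = enumerate_subcube(pool, pair, config.max_M_paths)
        result = analyze_subcube(subcube)
    return Instance(pool=pool, pair=pair, subcube=subcube, result=result, seed=ss)


@dataclass
class EnsembleSummary:
    """Per-instance table plus pooled quantities for one ensemble.

    ``table`` has one row per successfully tuned instance with columns
    M, EBref, ERef, Eminref, Emaxref, n_greedy (both colors pooled in
    n_greedy_blue/n_greedy_red), and — where path-analyzed — EC, j,
    single_jumper, proxy_single, n_paths, log_n_paths, topology.
    ``selected_smes`` pools the M selected effects of every instance.
    """

    config: ModelConfig
    table: pd.DataFrame
    selected_smes: np.ndarray
    n_generated: int
    n_tuning_failures: int

    @property
    def n_path_analyzed(self) -> int:
        return int(self.table["analyzed"].sum())

    # -- scalar summaries ------------------------------------------------
    def mean(self, column: str, mask=None):
        """Mean and standard error of a column, optionally masked."""
        x = self.table[column]
        if mask is not None:
            x = x[mask]
        x = x.dropna().to_numpy(dtype=float)
        if x.size == 0:
            return float("nan"), float("nan")
        sem = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")
        return float(x.mean()), sem

    @property
    def mean_M(self) -> float:
        return self.mean("M")[0]

    @property
    def frac_proxy_single(self) -> float:
        t = self.table[self.table["analyzed"]]
        return float(t["proxy_single"].mean()) if len(t) else float("nan")

    def histogram(self, column: str, bins, mask=None):
        """Fixed-bin histogram (counts, edges) of a column."""
        x = self.table[column]
        if mask is not None:
            x = x[mask]
        return np.histogram(x.dropna().to_numpy(dtype=float), bins=bins)

    def to_dict(self) -> dict:
        ana = self.table[self.table["analyzed"]]
        mean_M, sem_M = self.mean("M")
        out = {
            "n_generated": self.n_generated,
            "n_tuning_failures": self.n_tuning_failures,
            "n_path_analyzed": self.n_path_analyzed,
            "mean_M": mean_M,
            "sem_M": sem_M,
            "mean_EBref_over_ET": self.mean("EBref_over_ET")[0],
            "frac_proxy_single": self.frac_proxy_single,
        }
        if len(ana):
            restricted = ana[ana["proxy_single"]]
            out["mean_EC_over_Emaxref_restricted"] = (
                float(restricted["EC_over_Emaxref"].mean()) if len(restricted) else float("nan")
            )
            out["frac_EC_below_Eminref"] = float((ana["EC"] < ana["Eminref"]).mean())
        return out


def run_ensemble(config: ModelConfig) -> EnsembleSummary:
    """Map :func:`generate_instance` over independent substreams and pool.

    Instance i runs on ``child(config.seed, i)``; aggregation is
    order-independent.  Tuning failures are counted and the instance
    dropped (not resampled into the same slot).  A warning is raised when
    failures exceed 1% of the requested instances.
    """
    rows: List[dict] = []
    smes: List[np.ndarray] = []
    failures = 0
    master = as_seed_sequence(config.seed)
    for i in range(config.n_instances):
        try:
            inst = generate_instance(config, child(master, i))
        except TuningFailure:
            failures += 1
            continue
        pair, res = inst.pair, inst.result
        row = {
            "instance": i,
            "M": pair.M,
            "EBref": pair.EBref,
            "ERref": pair.ERref,
            "Eminref": pair.Eminref,
            "Emaxref": pair.Emaxref,
            "EBref_over_ET": pair.EBref / config.ET,
            "n_greedy_blue": pair.blue.n_greedy,
            "n_greedy_red": pair.red.n_greedy,
            "analyzed": res is not None,
            "EC": res.EC if res else np.nan,
            "EC_over_Emaxref": res.EC / pair.Emaxref if res else np.nan,
            "j": res.j if res and res.j is not None else np.nan,
            "single_jumper": bool(res.single_jumper) if res else False,
            "proxy_single": bool(res.proxy_single) if res else False,
            "n_paths": res.n_paths_at_EC if res else np.nan,
            "log_n_paths": res.log_n_paths if res else np.nan,
            "topology": res.topology if res else "",
        }
        rows.append(row)
        smes.append(pair.selected_smes)
    if failures > 0.01 * config.n_instances:
        warnings.warn(
            f"{failures}/{config.n_instances} instances failed to tune; "
            "the parameter point may be pathological",
            stacklevel=2,
        )
    table = pd.DataFrame(rows)
    selected = np.concatenate(smes) if smes else np.empty(0)
    return EnsembleSummary(
        config=config,
        table=table,
        selected_smes=selected,
        n_generated=len(rows),
        n_tuning_failures=failures,
    )


def jumper_position_profile(summary: EnsembleSummary, M_value: int, min_count: int = 200):
    """Normalized histogram of the jumper position j at fixed M.

    Restricted to instances with a unique jumper; requires at least
    ``min_count`` such instances for a stable profile.

    Returns
    -------
    (probs, positions):
        ``probs[k]`` is the probability of j = positions[k], positions
        running over 1..M-1; probs sums to 1.
    """
    t = summary.table
    sel = t[(t["M"] == M_value) & t["single_jumper"]]
    if len(sel) < min_count:
        raise ValueError(
            f"only {len(sel)} instances with M={M_value} and a unique jumper; "
            f"need at least {min_count}"
        )
    positions = np.arange(1, M_value)
    counts = np.array([(sel["j"] == j).sum() for j in positions], dtype=float)
    return counts / counts.sum(), positions
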