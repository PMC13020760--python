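"""Stochastic greedy/random construction of the two reference variants.

Both references start from the all-zero ancestor.  At each step, with
probability ``p`` a *greedy* mutation is introduced (the unused site whose
effect moves the trait furthest toward the color's target: largest ``h``
for blue, smallest for red), otherwise a *random* step mutates a uniformly
chosen unused site.  The walk stops the first time the trait crosses the
color's tuning target (``E > ET`` for blue, ``E < -ET`` for red).  The two
colors are tuned independently, on independent substreams of the instance
seed, so each trace is individually reproducible.

The procedure caricatures directed evolution toward a new function: a few
strongly beneficial substitutions on top of incidental near-neutral ones.
It makes no claim of population-genetic realism (no fixation dynamics, no
selection coefficients) — it is only a generator of reference genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from ._seeding import as_seed_sequence, child
from .landscape import BLUE, RED, genotype_to_string
from .sme_pool import SMEPool

GREEDY = "greedy"
RANDOM = "random"

__all__ = [
    "GREEDY",
    "RANDOM",
    "TuningFailure",
    "TuningParams",
    "ReferenceTrace",
    "ReferencePair",
    "greedy_site",
    "tune_reference",
    "build_reference_pair",
]


class TuningFailure(RuntimeError):
    """All L sites were mutated without the trait crossing the target."""


@dataclass(frozen=True)
class TuningParams:
    """Greedy-step probability ``p`` and tuning target ``ET > 0``."""

    p: float
    ET: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if not self.ET > 0:
            raise ValueError(f"ET must be positive, got {self.ET}")


@dataclass(frozen=True)
class ReferenceTrace:
    """One tuned reference variant together with its full mutation trace."""

    genotype: np.ndarray
    color: str
    Eref: float
    steps: Tuple[Tuple[int, str], ...]  # (site index, "greedy" | "random")

    @property
    def n_greedy(self) -> int:
        return sum(1 for _, kind in self.steps if kind == GREEDY)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def to_dict(self) -> dict:
        return {
            "genotype": genotype_to_string(self.genotype),
            "color": self.color,
            "Eref": self.Eref,
            "steps": [[int(i), k] for i, k in self.steps],
            "n_greedy": self.n_greedy,
        }


@dataclass(frozen=True)
class ReferencePair:
    """The tuned blue/red pair and the subcube of sites separating them.

    ``diff_sites`` are the M sites whose bits differ between the two
    genotypes; ``selected_smes`` are the pool effects at those sites — the
    mutations that define the space of intermediates (the effects "fixed"
    by the tuning).  ``shared_sites`` (mutated in *both* references) are
    carried as an auxiliary report: they shift both endpoints by the same
    amount and play no role in the path analysis.
    """

    blue: ReferenceTrace
    red: ReferenceTrace
    diff_sites: np.ndarray
    selected_smes: np.ndarray
    shared_sites: np.ndarray

    @property
    def M(self) -> int:
        return int(self.diff_sites.size)

    @property
    def EBref(self) -> float:
        return self.blue.Eref

    @property
    def ERref(self) -> float:
        return self.red.Eref

    @property
    def Eminref(self) -> float:
        return min(self.EBref, abs(self.ERref))

    @property
    def Emaxref(self) -> float:
        return max(self.EBref, abs(self.ERref))

    def to_dict(self) -> dict:
        return {
            "blue": self.blue.to_dict(),
            "red": self.red.to_dict(),
            "M": self.M,
            "diff_sites": [int(i) for i in self.diff_sites],
            "selected_smes": [float(h) for h in self.selected_smes],
            "shared_sites": [int(i) for i in self.shared_sites],
            "Eminref": self.Eminref,
            "Emaxref": self.Emaxref,
        }


def greedy_site(pool: SMEPool, occupied: Sequence[int], color: str) -> int:
    """The unused site with maximal impact toward the color's target.

    Blue takes the argmax of ``h`` over unoccupied sites, red the argmin;
    ties (a zero-probability event for continuous P(h)) are broken by the
    lowest site index.
    """
    occ = set(int(i) for i in occupied)
    free = np.array([i for i in range(pool.L) if i not in occ], dtype=int)
    if free.size == 0:
        raise TuningFailure("no unoccupied site left for a greedy step")
    hf = pool.h[free]
    pick = int(np.argmax(hf)) if color == BLUE else int(np.argmin(hf))
    return int(free[pick])


def tune_reference(pool: SMEPool, color: str, params: TuningParams, seed) -> ReferenceTrace:
    """Run the greedy/random walk for one color until its target is crossed.

    Raises :class:`TuningFailure` if all ``L`` sites are mutated without
    crossing; callers (the ensemble driver) count and resample.
    """
    if color not in (BLUE, RED):
        raise ValueError(f"color must be 'blue' or 'red', got {color!r}")
    generator = np.random.default_rng(as_seed_sequence(seed))
    h = pool.h
    L = pool.L
    # stable argsort => among exact ties the lowest index comes first
    order = np.argsort(-h, kind="stable") if color == BLUE else np.argsort(h, kind="stable")
    occupied = np.zeros(L, dtype=bool)
    genotype = np.zeros(L, dtype=np.uint8)
    steps: List[Tuple[int, str]] = []
    E = 0.0
    ptr = 0  # next-best greedy candidate in `order`
    n_occ = 0
    for _ in range(L):
        if generator.random() < params.p:
            while occupied[order[ptr]]:
                ptr += 1
            site = int(order[ptr])
            kind = GREEDY
        else:
            if 2 * n_occ < L:
                site = int(generator.integers(L))
                while occupied[site]:
                    site = int(generator.integers(L))
            else:
                site = int(generator.choice(np.flatnonzero(~occupied)))
            kind = RANDOM
        occupied[site] = True
        genotype[site] = 1
        n_occ += 1
        E += h[site]
        steps.append((site, kind))
        if (color == BLUE and E > params.ET) or (color == RED and E < -params.ET):
            genotype.setflags(write=False)
            return ReferenceTrace(genotype=genotype, color=color, Eref=E, steps=tuple(steps))
    raise TuningFailure(
        f"all {L} sites mutated without crossing the {color} target ET={params.ET}"
    )


def build_reference_pair(pool: SMEPool, params: TuningParams, seed) -> ReferencePair:
    """Tune the blue and red references on independent substreams.

    Substream derivation: ``child(seed, 0)`` drives the blue trace and
    ``child(seed, 1)`` the red trace.
    """
    ss = as_seed_sequence(seed)
    blue = tune_reference(pool, BLUE, params, child(ss, 0))
    red = tune_reference(pool, RED, params, child(ss, 1))
    diff = np.flatnonzero(blue.genotype != red.genotype)
    shared = np.flatnonzero((blue.genotype == 1) & (red.genotype == 1))
    return ReferencePair(
        blue=blue,
        red=red,
        diff_sites=diff,
        selected_smes=pool.h[diff].copy(),
        shared_sites=shared,
    )
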