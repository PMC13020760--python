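"""Genotypes, the additive underlying trait, and the two-color fitness map.

A genotype is a binary vector ``a`` of length ``L`` (site ``i`` mutated iff
``a_i = 1``).  Its underlying trait is purely additive,

    E(a) = sum_i h_i a_i ,

and all epistasis in fitness is *global*: it arises solely from the
nonlinear, sigmoidal map from trait to fitness, one sigmoid per phenotype
("blue" rises for E above +Eth, "red" rises for E below -Eth).  In the
sharp-sigmoid limit (beta >> 1) fitness becomes a step function at +/-Eth,
and a genotype is functional blue if E > Eth, functional red if E < -Eth,
and nonfunctional in between; all path-space analyses in this package work
directly on the trait in that limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .sme_pool import SMEPool

BLUE = "blue"
RED = "red"
NONFUNCTIONAL = "nonfunctional"
_COLORS = (BLUE, RED)

__all__ = [
    "BLUE",
    "RED",
    "NONFUNCTIONAL",
    "FitnessParams",
    "trait",
    "fitness",
    "phenotype_class",
    "genotype_from_string",
    "genotype_to_string",
]


@dataclass(frozen=True)
class FitnessParams:
    """Parameters of the two sigmoidal fitness functions.

    ``phi0`` is the plateau (fixed to 1 without loss of generality),
    ``beta`` the sharpness of the transition (the model is studied in the
    beta >> 1 limit; 50 is the working default), and ``Eth`` the
    functionality threshold on the trait axis.
    """

    Eth: float
    beta: float = 50.0
    phi0: float = 1.0

    def __post_init__(self) -> None:
        if not self.phi0 > 0:
            raise ValueError(f"phi0 must be positive, got {self.phi0}")
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.Eth < 0:
            raise ValueError(f"Eth must be non-negative, got {self.Eth}")


def trait(a, pool: SMEPool) -> float:
    """Additive trait ``E(a) = sum_i h_i a_i`` of genotype ``a``."""
    a = np.asarray(a)
    if a.shape != (pool.L,):
        raise ValueError(f"genotype has shape {a.shape}, pool has L={pool.L}")
    return float(a @ pool.h)


def fitness(E, color: str, params: FitnessParams):
    """Sigmoidal fitness of a trait value for one of the two phenotypes.

    blue:  phi0 / (1 + exp(beta (Eth - E)))  — increasing in E
    red:   phi0 / (1 + exp(beta (Eth + E)))  — decreasing in E

    Vectorized over ``E``; the logistic is evaluated through
    :func:`scipy.special.expit`, which saturates instead of overflowing.
    """
    E = np.asarray(E, dtype=float)
    if color == BLUE:
        out = params.phi0 * expit(params.beta * (E - params.Eth))
    elif color == RED:
        out = params.phi0 * expit(-params.beta * (E + params.Eth))
    else:
        raise ValueError(f"color must be one of {_COLORS}, got {color!r}")
    return out if out.ndim else float(out)


def phenotype_class(E: float, Eth: float) -> str:
    """Classify a trait value: blue iff ``E > Eth``, red iff ``E < -Eth``.

    Strict inequalities; the boundary ``|E| = Eth`` counts as
    nonfunctional, consistent with the strict path-viability condition.
    """
    if Eth < 0:
        raise ValueError(f"Eth must be non-negative, got {Eth}")
    if E > Eth:
        return BLUE
    if E < -Eth:
        return RED
    return NONFUNCTIONAL


def genotype_from_string(s: str) -> np.ndarray:
    """Parse a bitstring ("0110...") into a genotype array."""
    if not s or any(c not in "01" for c in s):
        raise ValueError(f"genotype string must be a non-empty bitstring, got {s!r}")
    return np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")


def genotype_to_string(a) -> str:
    """Render a genotype array as a bitstring, site order = index order."""
    return "".join("1" if b else "0" for b in np.asarray(a))
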