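"""A-priori distributions of single-mutation effects (SMEs) and zero-sum pools.

The additive trait of a genotype is a sum of per-site effects ``h_i`` drawn
i.i.d. from a symmetric input distribution ``P(h)``.  Two families are
supported:

``gaussian``
    A centred Gaussian, scale ``sigma`` (default 1; the overall scale of
    ``P(h)`` can be absorbed into the fitness threshold and sharpness, so
    unit variance loses no generality).

``pareto_cutoff``
    A symmetric density that is flat on ``|h| < xm`` and decays as a Pareto
    power law ``(xm/|h|)^(alpha+1)`` out to a hard cutoff, beyond which it
    vanishes.  This mimics the fat-tailed SME spectra seen in measured
    combinatorial landscapes of fluorescent-protein variants.

After drawing the ``L`` effects, the pool is recentred so that the effects
sum exactly to zero: the fully mutated genotype then carries the same trait
as the unmutated ancestor, and the two tuned reference variants sit on
opposite sides of zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import stats

from ._seeding import as_seed_sequence

GAUSSIAN = "gaussian"
PARETO_CUTOFF = "pareto_cutoff"
_KINDS = (GAUSSIAN, PARETO_CUTOFF)

__all__ = [
    "GAUSSIAN",
    "PARETO_CUTOFF",
    "DistributionSpec",
    "SMEPool",
    "density",
    "sample_pool",
]


@dataclass(frozen=True)
class DistributionSpec:
    """Specification of the a-priori SME distribution ``P(h)``.

    Parameters
    ----------
    kind:
        ``"gaussian"`` or ``"pareto_cutoff"``.
    alpha:
        Pareto tail exponent (tail decays as ``|h|^-(alpha+1)``).
    xm:
        Shoulder of the Pareto density: flat for ``|h| < xm``.
    cutoff:
        Hard truncation; the density is zero for ``|h| > cutoff``.
    sigma:
        Gaussian scale (standard deviation).
    """

    kind: str
    alpha: float = 0.7
    xm: float = 0.1
    cutoff: float = 2.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}; expected one of {_KINDS}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not (0 < self.xm < self.cutoff):
            raise ValueError(f"need 0 < xm < cutoff, got xm={self.xm}, cutoff={self.cutoff}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    # -- normalization ---------------------------------------------------
    @property
    def pareto_norm(self) -> float:
        """Normalization constant ``A`` of the cut-off Pareto density.

        Solves ``2 [A xm + A (xm/alpha)(1 - (xm/cutoff)^alpha)] = 1``:
        the flat shoulder plus the truncated power-law tail integrate to 1.
        """
        a, xm, c = self.alpha, self.xm, self.cutoff
        return a / (2.0 * xm * (a + 1.0 - (xm / c) ** a))

    # -- density ---------------------------------------------------------
    def density(self, x) -> np.ndarray:
        """Normalized density ``P(h)`` evaluated at ``x`` (vectorized)."""
        x = np.asarray(x, dtype=float)
        if self.kind == GAUSSIAN:
            out = stats.norm.pdf(x, loc=0.0, scale=self.sigma)
        else:
            A = self.pareto_norm
            ax = np.abs(x)
            out = np.where(
                ax < self.xm,
                A,
                np.where(ax <= self.cutoff, A * (self.xm / np.maximum(ax, self.xm)) ** (self.alpha + 1.0), 0.0),
            )
        return out if out.ndim else float(out)

    # -- sampling --------------------------------------------------------
    def sample(self, size: int, generator: np.random.Generator) -> np.ndarray:
        """Draw ``size`` i.i.d. values from ``P(h)``.

        The cut-off Pareto is sampled by inverse CDF on the piecewise
        density (closed form), which is exact and deterministic under
        seeding; no rejection is involved.
        """
        if self.kind == GAUSSIAN:
            return generator.normal(0.0, self.sigma, size)
        A = self.pareto_norm
        xm, a, c = self.xm, self.alpha, self.cutoff
        u = generator.random(size)
        signs = np.where(generator.random(size) < 0.5, -1.0, 1.0)
        u0 = 2.0 * A * xm  # mass of the flat shoulder
        shoulder = u < u0
        mag = np.empty(size)
        mag[shoulder] = u[shoulder] / (2.0 * A)
        # tail: invert 2A (xm/a) (1 - (xm/t)^a) = u - u0
        w = 1.0 - a * (u[~shoulder] - u0) / (2.0 * A * xm)
        mag[~shoulder] = xm * w ** (-1.0 / a)
        np.clip(mag, 0.0, c, out=mag)  # guard fp round-off at u -> 1
        return signs * mag

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        if self.kind == GAUSSIAN:
            return {"kind": self.kind, "sigma": self.sigma}
        return {"kind": self.kind, "alpha": self.alpha, "xm": self.xm, "cutoff": self.cutoff}

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        return cls(**d)


def density(spec: DistributionSpec, x):
    """Normalized density ``P(h)``; symmetric in ``x`` by construction."""
    return spec.density(x)


@dataclass(frozen=True)
class SMEPool:
    """A zero-sum pool of ``L`` single-mutation effects.

    The shift to zero sum is applied exactly once, to the full pool of raw
    draws; it is never re-applied after subsetting (the selected effects of
    a reference pair are plain pool values).
    """

    h: np.ndarray
    spec: DistributionSpec
    seed: Union[int, np.random.SeedSequence, None] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        if h.ndim != 1 or h.size < 2:
            raise ValueError(f"pool must hold at least 2 effects, got shape {h.shape}")
        if abs(float(h.sum())) > 1e-12 * h.size:
            raise ValueError(f"pool is not zero-sum: sum(h)={h.sum():.3e} for L={h.size}")
        h = h.copy()
        h.setflags(write=False)
        object.__setattr__(self, "h", h)

    @property
    def L(self) -> int:
        return int(self.h.size)


def sample_pool(spec: DistributionSpec, L: int, seed) -> SMEPool:
    """Draw ``L`` i.i.d. effects from ``spec`` and recentre them to zero sum.

    Parameters
    ----------
    spec:
        The a-priori SME distribution.
    L:
        Pool size (number of mutable sites); must be at least 2.
    seed:
        Integer or :class:`numpy.random.SeedSequence` driving the draws.
    """
    if L < 2:
        raise ValueError(f"L must be >= 2, got {L}")
    generator = np.random.default_rng(as_seed_sequence(seed))
    raw = spec.sample(L, generator)
    h = raw - raw.mean()
    # remove the tiny fp residue of the mean shift so the invariant is exact
    h -= h.sum() / L
    return SMEPool(h=h, spec=spec, seed=seed)
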