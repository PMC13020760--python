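"""Directed mutational paths between the references and the bottleneck EC.

The 2^M intermediates between the two references form a Boolean lattice
(subsets of the M differing sites; the empty set is the blue reference,
the full set the red one).  A *directed path* introduces each of the M
mutations exactly once — no back-mutations — so there are M! of them.
A path survives at functionality threshold t when every one of its M-1
intermediate states keeps |E| >= t (the endpoints are always retained).

The connectivity threshold EC is the largest t at which at least one path
survives: the maximin over paths of the minimum intermediate |E|.  Because
the references themselves must stay in the viable set, EC is capped at
Eminref = min(EBref, |ERref|).  Both EC and the number of surviving paths
are computed by dynamic programming over the subset lattice in increasing
subset-size order, in O(M 2^M) — never by enumerating the M! orders.

A *jumper* is an intermediate with |E| = EC lying on a surviving path;
when the cap is inactive, raising the threshold past EC removes it and
disconnects the two phenotypes, which is the functional bottleneck.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Tuple

import numpy as np

from .sme_pool import SMEPool
from .tuning import ReferencePair

SINGLE_JUMP_SINGLE_LANDING = "single_jump_single_landing"
SINGLE_JUMP_MULTI_LANDING = "single_jump_multi_landing"
CAPPED_NO_JUMPER = "capped_no_jumper"

#: Largest M for which surviving-path counts fit exactly in int64 (20! < 2^63).
_MAX_M_EXACT = 20

__all__ = [
    "SubcubeLandscape",
    "PathSpaceResult",
    "SubcubeTooLarge",
    "enumerate_subcube",
    "compute_EC",
    "count_paths",
    "find_jumpers",
    "single_jumper_proxy",
    "analyze_subcube",
    "surviving_graph",
    "write_dot",
]


class SubcubeTooLarge(ValueError):
    """M exceeds the path-analysis size limit; the instance is skipped."""


@dataclass(frozen=True)
class SubcubeLandscape:
    """Trait values on the 2^M subcube spanned by the differing sites.

    States are integer bitmasks over ``diff_sites`` (bit j set = site
    ``diff_sites[j]`` flipped from its blue-reference value to its
    red-reference value); mask 0 is the blue reference, the full mask the
    red reference.  ``E[mask]`` is the trait of that state.
    """

    M: int
    diff_sites: np.ndarray
    E: np.ndarray
    EBref: float
    ERref: float

    def __post_init__(self) -> None:
        if self.E.shape != (1 << self.M,):
            raise ValueError(f"E must have 2^M = {1 << self.M} entries, got {self.E.shape}")

    @property
    def full_mask(self) -> int:
        return (1 << self.M) - 1

    @property
    def Eminref(self) -> float:
        return min(self.EBref, abs(self.ERref))

    @property
    def Emaxref(self) -> float:
        return max(self.EBref, abs(self.ERref))


@dataclass(frozen=True)
class PathSpaceResult:
    """Bottleneck summary of one subcube landscape."""

    EC: float
    Eminref: float
    Emaxref: float
    jumpers: Tuple[int, ...]
    j: Optional[int]  # mutations from the blue reference; None when capped
    single_jumper: bool
    proxy_single: bool
    n_paths_at_EC: int
    log_n_paths: float
    topology: str


# ---------------------------------------------------------------------------
# subset-lattice scaffolding, cached per M
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _lattice(M: int):
    """Masks grouped by popcount and, per mask, its popcount predecessors.

    Returns ``(layers, preds)`` where ``layers[k]`` is the array of masks
    with k bits set and ``preds[k]`` has shape (len(layers[k]), k) listing
    each mask with one set bit removed.
    """
    n = 1 << M
    pc = np.zeros(n, dtype=np.int64)
    for b in range(M):
        pc += (np.arange(n) >> b) & 1
    layers: List[np.ndarray] = [np.flatnonzero(pc == k) for k in range(M + 1)]
    preds: List[np.ndarray] = [np.empty((0, 0), dtype=np.int64)]
    for k in range(1, M + 1):
        mk = layers[k]
        pk = np.empty((mk.size, k), dtype=np.int64)
        for row, mask in enumerate(mk):
            m = int(mask)
            col = 0
            while m:
                bit = m & -m
                pk[row, col] = mask ^ bit
                m ^= bit
                col += 1
        preds.append(pk)
    return layers, preds


def enumerate_subcube(pool: SMEPool, pair: ReferencePair, max_M: int = 14) -> SubcubeLandscape:
    """Trait values of all 2^M intermediates, built incrementally.

    Each state's trait is the blue reference trait plus the sum of the
    per-site trait changes of the flipped bits (``+h_i`` when the blue bit
    is 0, ``-h_i`` when it is 1); this agrees exactly with direct dot
    products because it is the same finite sum, reassociated.
    """
    M = pair.M
    if M > max_M:
        raise SubcubeTooLarge(f"M={M} exceeds max_M={max_M}; instance skipped from path analysis")
    delta = pool.h[pair.diff_sites] * np.where(pair.blue.genotype[pair.diff_sites] == 0, 1.0, -1.0)
    n = 1 << M
    bits = ((np.arange(n)[:, None] >> np.arange(M)[None, :]) & 1).astype(float)
    E = pair.EBref + bits @ delta
    E.setflags(write=False)
    return SubcubeLandscape(M=M, diff_sites=pair.diff_sites, E=E, EBref=pair.EBref, ERref=pair.ERref)


# ---------------------------------------------------------------------------
# bottleneck threshold and path counts
# ---------------------------------------------------------------------------


def compute_EC(sub: SubcubeLandscape) -> float:
    """Maximin bottleneck threshold, capped at ``Eminref``.

    DP over subset size: ``best[s] = min(max_pred best, |E(s)|)`` with the
    endpoints excluded from the min (their |E| does not constrain paths).
    ``best[full]`` is then the maximum over the M! directed paths of the
    path's minimum intermediate |E|; for M = 1 there are no intermediates
    and EC equals Eminref by the cap.
    """
    M = sub.M
    absE = np.abs(sub.E)
    layers, preds = _lattice(M)
    best = np.empty(1 << M)
    best[0] = np.inf
    for k in range(1, M + 1):
        mk, pk = layers[k], preds[k]
        inner = best[pk].max(axis=1)
        if k < M:
            best[mk] = np.minimum(inner, absE[mk])
        else:
            best[mk] = inner  # the red endpoint is not an intermediate
    return float(min(best[sub.full_mask], sub.Eminref))


def _forward_counts(viable: np.ndarray, M: int) -> np.ndarray:
    """Number of viable directed paths from mask 0 to each mask (int64)."""
    layers, preds = _lattice(M)
    cnt = np.zeros(1 << M, dtype=np.int64)
    cnt[0] = 1 if viable[0] else 0
    for k in range(1, M + 1):
        mk, pk = layers[k], preds[k]
        cnt[mk] = np.where(viable[mk], cnt[pk].sum(axis=1), 0)
    return cnt


def _viability(sub: SubcubeLandscape, threshold: float) -> np.ndarray:
    """Closed viability |E| >= threshold, endpoints always viable."""
    v = np.abs(sub.E) >= threshold
    v[0] = True
    v[sub.full_mask] = True
    return v


def count_paths(sub: SubcubeLandscape, threshold: float) -> int:
    """Directed paths whose M-1 intermediates all keep ``|E| >= threshold``.

    The condition is closed (>=), so at ``threshold = EC`` the jumper
    itself is retained and at least one path survives.  Counts are exact:
    they stay below M! which fits in int64 for M <= 20.
    """
    if sub.M > _MAX_M_EXACT:
        raise SubcubeTooLarge(f"exact int64 path counts require M <= {_MAX_M_EXACT}")
    return int(_forward_counts(_viability(sub, threshold), sub.M)[sub.full_mask])


def single_jumper_proxy(EC: float, Eminref: float) -> bool:
    """Numerical proxy for a single jumper: strict ``EC < 0.9 Eminref``."""
    if not Eminref > 0:
        raise ValueError(f"Eminref must be positive, got {Eminref}")
    return EC < 0.9 * Eminref


def find_jumpers(
    sub: SubcubeLandscape, EC: float, rel_tol: float = 1e-12
) -> Tuple[Tuple[int, ...], Optional[int], bool, str]:
    """Jumper states at the bottleneck and the resulting topology class.

    A jumper is an intermediate with |E| equal to EC (relative tolerance
    ``rel_tol``) lying on at least one surviving path at threshold EC.
    ``j`` is the jumper's distance from the blue reference (the minimum if
    several).  When the cap is active (EC >= Eminref) there is no jumper
    and the topology is ``capped_no_jumper``; otherwise the class records
    whether the (first) jumper touches one or several opposite-phenotype
    states by single mutations.
    """
    M = sub.M
    full = sub.full_mask
    if EC >= sub.Eminref * (1.0 - rel_tol):
        return (), None, False, CAPPED_NO_JUMPER
    viable = _viability(sub, EC)
    fwd = _forward_counts(viable, M)
    # paths mask -> full are forward paths on the bit-complemented cube
    viable_rev = viable[full ^ np.arange(1 << M)]
    bwd = _forward_counts(viable_rev, M)[full ^ np.arange(1 << M)]
    on_path = (fwd > 0) & (bwd > 0)
    absE = np.abs(sub.E)
    tol = rel_tol * max(EC, 1e-300)
    is_jumper = on_path & (np.abs(absE - EC) <= tol)
    is_jumper[0] = False
    is_jumper[full] = False
    jumpers = tuple(int(m) for m in np.flatnonzero(is_jumper))
    if not jumpers:
        # should not happen for EC below the cap; report defensively
        return (), None, False, CAPPED_NO_JUMPER
    popcount = [bin(m).count("1") for m in jumpers]
    j = int(min(popcount))
    first = jumpers[int(np.argmin(popcount))]
    sign0 = np.sign(sub.E[first])
    landings = 0
    for b in range(M):
        nb = first ^ (1 << b)
        if on_path[nb] and np.sign(sub.E[nb]) != sign0:
            landings += 1
    topology = SINGLE_JUMP_SINGLE_LANDING if landings <= 1 else SINGLE_JUMP_MULTI_LANDING
    return jumpers, j, len(jumpers) == 1, topology


def analyze_subcube(sub: SubcubeLandscape) -> PathSpaceResult:
    """Full bottleneck analysis: EC, jumpers, proxy, and path counts."""
    EC = compute_EC(sub)
    jumpers, j, single, topology = find_jumpers(sub, EC)
    n_paths = count_paths(sub, EC)
    return PathSpaceResult(
        EC=EC,
        Eminref=sub.Eminref,
        Emaxref=sub.Emaxref,
        jumpers=jumpers,
        j=j,
        single_jumper=single,
        proxy_single=single_jumper_proxy(EC, sub.Eminref),
        n_paths_at_EC=n_paths,
        log_n_paths=float(np.log(n_paths)) if n_paths > 0 else float("-inf"),
        topology=topology,
    )


# ---------------------------------------------------------------------------
# surviving-path graph export
# ---------------------------------------------------------------------------


def surviving_graph(sub: SubcubeLandscape, EC: float):
    """Graph of viable states at threshold EC, edges = single mutations.

    Nodes carry the trait value, phenotype sign, layer (mutations from the
    blue reference) and an on-surviving-path flag; suitable for GraphML
    export via :func:`networkx.write_graphml` or DOT via :func:`write_dot`.
    """
    import networkx as nx

    M = sub.M
    full = sub.full_mask
    viable = _viability(sub, EC)
    fwd = _forward_counts(viable, M)
    viable_rev = viable[full ^ np.arange(1 << M)]
    bwd = _forward_counts(viable_rev, M)[full ^ np.arange(1 << M)]
    on_path = (fwd > 0) & (bwd > 0)
    G = nx.Graph(EC=float(EC))
    for mask in np.flatnonzero(viable):
        mask = int(mask)
        E = float(sub.E[mask])
        G.add_node(
            format(mask, f"0{M}b")[::-1],  # bit i of the mask = char i
            E=E,
            sign=int(np.sign(E)),
            layer=bin(mask).count("1"),
            on_path=bool(on_path[mask]),
        )
    for mask in np.flatnonzero(viable):
        mask = int(mask)
        for b in range(M):
            nb = mask | (1 << b)
            if nb != mask and viable[nb]:
                G.add_edge(format(mask, f"0{M}b")[::-1], format(nb, f"0{M}b")[::-1])
    return G


def write_dot(G, path) -> None:
    """Minimal DOT export (no pydot/pygraphviz dependency)."""
    with open(path, "w") as fh:
        fh.write("graph surviving_paths {\n")
        for node, data in G.nodes(data=True):
            color = {1: "blue", -1: "red"}.get(data.get("sign"), "gray")
            fh.write(
                f'  "{node}" [color={color}, label="{node}\\nE={data.get("E", 0):.3g}"];\n'
            )
        for u, v in G.edges():
            fh.write(f'  "{u}" -- "{v}";\n')
        fh.write("}\n")
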