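"""Exhaustive enumeration of pairing states on small systems.

For toy systems whose feasible-pair count is small, every valid pairing
state can be listed, giving exact partition functions, free-energy
landscapes over any order-parameter binning, melting curves, and mean
first-passage times of the kinetic Monte Carlo chain.  These exact results
are the ground truth against which the stochastic sampling and forward
flux sampling modules are validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Hashable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order
from scipy.sparse.linalg import spsolve
from scipy.special import logsumexp

from hpk.energy import EnergyParams, R_KCAL
from hpk.pairing import PairSystem
from hpk.sequences import StrandPairDesign

__all__ = [
    "StateSpace",
    "ExactThermo",
    "TractabilityError",
    "enumerate_states",
    "exact_landscape",
    "exact_melting_curve",
    "exact_mfpt",
    "bin_inter_intra",
    "bin_single_strand",
]

MAX_FEASIBLE_PAIRS = 24
MAX_SOLVE_STATES = 100_000
DENSE_SOLVE_STATES = 2_000


class TractabilityError(RuntimeError):
    """System too large for exact enumeration; message carries an estimate."""


def bin_inter_intra(counts: tuple[int, int, int, int]) -> tuple[int, int]:
    """Duplex order parameter: (inter-strand pairs, total intra-strand pairs)."""
    return (counts[0], counts[1])


def bin_single_strand(counts: tuple[int, int, int, int]) -> tuple[int, int]:
    """Single-strand order parameter: (other intra pairs, intended-stem pairs)."""
    return (counts[3], counts[2])


@dataclass
class StateSpace:
    """All valid pairing states of a system, with energies and adjacency."""

    system: PairSystem
    params: EnergyParams
    masks: list[int]
    index: dict[int, int]
    dH: np.ndarray          # kcal/mol per state
    dS: np.ndarray          # kcal/(mol K) per state
    g_kt: np.ndarray        # free energy in kBT at params.temperature_C
    counts: np.ndarray      # (n_states, 4): n_inter, n_intra, n_stem, n_other
    adjacency: list[tuple[int, int]]

    @property
    def size(self) -> int:
        return len(self.masks)

    def boltzmann(self, temperature_K: float | None = None) -> np.ndarray:
        """Exact per-state probabilities at the given (or configured) temperature."""
        if temperature_K is None:
            g = self.g_kt
        else:
            g = (self.dH - temperature_K * self.dS) / (R_KCAL * temperature_K)
        logw = -g
        return np.exp(logw - logsumexp(logw))


@dataclass
class ExactThermo:
    """Exact partition function and binned free-energy landscape."""

    log_Z: float
    probabilities: np.ndarray
    dG_bins: dict[Hashable, float]      # kBT relative to the reference bin
    bin_probabilities: dict[Hashable, float]
    reference_bin: Hashable = None
    se_bins: dict = field(default_factory=dict)  # zeros; kept for API parity


def enumerate_states(design: StrandPairDesign, params: EnergyParams) -> StateSpace:
    """Enumerate every valid pairing state by depth-first pair extension.

    Refuses systems with more than ``MAX_FEASIBLE_PAIRS`` feasible pairs,
    reporting the 2^m upper bound on the subset count.
    """
    system = PairSystem(design)
    m = system.n_pairs
    if m > MAX_FEASIBLE_PAIRS:
        raise TractabilityError(
            f"{m} feasible pairs exceeds the bound of {MAX_FEASIBLE_PAIRS}; "
            f"up to 2^{m} = {2**m:.3g} subsets would need checking"
        )
    base_masks = system.base_masks
    masks: list[int] = []

    def extend(start: int, mask: int, occ: int) -> None:
        masks.append(mask)
        for k in range(start, m):
            bm = base_masks[k]
            if not occ & bm:
                extend(k + 1, mask | (1 << k), occ | bm)

    extend(0, 0, 0)
    index = {mk: i for i, mk in enumerate(masks)}

    ev = system.evaluator(params)
    n = len(masks)
    dH = np.empty(n)
    dS = np.empty(n)
    counts = np.empty((n, 4), dtype=np.int64)
    for i, mk in enumerate(masks):
        dH[i], dS[i] = ev.dHdS(mk)
        counts[i] = system.counts(mk)
    t = params.temperature_K
    g_kt = (dH - t * dS) / (R_KCAL * t)

    adjacency = []
    for i, mk in enumerate(masks):
        for k in range(m):
            bit = 1 << k
            if mk & bit:
                # each edge is generated exactly once: only the superset
                # state iterates over the removable pair
                j = index[mk ^ bit]
                adjacency.append((min(i, j), max(i, j)))
    return StateSpace(system, params, masks, index, dH, dS, g_kt, counts, adjacency)


def exact_landscape(space: StateSpace,
                    params: EnergyParams | None = None,
                    binning: Callable = bin_inter_intra,
                    reference_bin: Hashable = None) -> ExactThermo:
    """Exact free-energy landscape over an order-parameter binning.

    dG(bin) = -ln sum_{s in bin} e^{-G_s} + ln sum_{s in ref} e^{-G_s}, in kBT.
    The default reference is the bin containing the empty state.
    """
    t = None if params is None else params.temperature_K
    p = space.boltzmann(t)
    log_z = float(logsumexp(-space.g_kt)) if t is None else float(
        logsumexp(-(space.dH - t * space.dS) / (R_KCAL * t)))
    keys = [binning(tuple(c)) for c in space.counts]
    if reference_bin is None:
        reference_bin = keys[space.index[0]]
    bin_p: dict[Hashable, float] = {}
    for k, pi in zip(keys, p):
        bin_p[k] = bin_p.get(k, 0.0) + float(pi)
    if reference_bin not in bin_p or bin_p[reference_bin] <= 0:
        raise ValueError(f"reference bin {reference_bin!r} is empty")
    ref = bin_p[reference_bin]
    dg = {k: -np.log(v / ref) for k, v in bin_p.items()}
    return ExactThermo(log_Z=log_z, probabilities=p, dG_bins=dg,
                       bin_probabilities=bin_p, reference_bin=reference_bin,
                       se_bins={k: 0.0 for k in dg})


def exact_melting_curve(space: StateSpace, params: EnergyParams,
                        temperatures_C: np.ndarray,
                        predicate: Callable[[tuple], bool]) -> tuple[np.ndarray, np.ndarray]:
    """Exact equilibrium yield of predicate states at each temperature.

    Free energies are recomputed from the per-state DH/DS at every
    temperature, so there is no reweighting error.  Returns (T_C, yield).
    """
    temperatures_C = np.asarray(temperatures_C, dtype=float)
    sel = np.array([bool(predicate(tuple(c))) for c in space.counts])
    out = np.empty_like(temperatures_C)
    for i, tc in enumerate(temperatures_C):
        p = space.boltzmann(tc + 273.15)
        out[i] = float(p[sel].sum())
    return temperatures_C, out


def rate_matrix(space: StateSpace, rate_model) -> csr_matrix:
    """CTMC generator-off-diagonal rates on the enumerated adjacency."""
    n = space.size
    rows, cols, vals = [], [], []
    for i, j in space.adjacency:
        rows.append(i); cols.append(j)
        vals.append(rate_model.edge_rate(space.g_kt[i], space.g_kt[j]))
        rows.append(j); cols.append(i)
        vals.append(rate_model.edge_rate(space.g_kt[j], space.g_kt[i]))
    return csr_matrix((vals, (rows, cols)), shape=(n, n))


def exact_mfpt(space: StateSpace, rate_model,
               source: Callable[[tuple], bool],
               absorbing: Callable[[tuple], bool]) -> float:
    """Mean first-passage time from equilibrium-within-source to absorption.

    Solves the linear first-passage system of the continuous-time chain;
    dense below ``DENSE_SOLVE_STATES`` states, sparse up to the refusal
    bound of ``MAX_SOLVE_STATES``.
    """
    n = space.size
    if n > MAX_SOLVE_STATES:
        raise TractabilityError(f"{n} states exceeds the solve bound {MAX_SOLVE_STATES}")
    absorbing_sel = np.array([bool(absorbing(tuple(c))) for c in space.counts])
    source_sel = np.array([bool(source(tuple(c))) for c in space.counts])
    if not absorbing_sel.any():
        raise ValueError("absorbing set is empty")
    if not source_sel.any():
        raise ValueError("source set is empty")

    rates = rate_matrix(space, rate_model)
    # reachability: rates are positive both ways on each edge, so undirected
    order = breadth_first_order(rates, int(np.flatnonzero(absorbing_sel)[0]),
                                directed=False, return_predecessors=False)
    reach = np.zeros(n, dtype=bool)
    reach[order] = True
    reach[absorbing_sel] = True
    if not reach[source_sel].all():
        raise ValueError("absorbing set unreachable from part of the source set")

    transient = np.flatnonzero(~absorbing_sel)
    tidx = {int(s): k for k, s in enumerate(transient)}
    nt = len(transient)
    q = rates[transient][:, transient]
    out_rate = np.asarray(rates[transient].sum(axis=1)).ravel()
    if nt <= DENSE_SOLVE_STATES:
        a = q.toarray() - np.diag(out_rate)
        tau_t = np.linalg.solve(a, -np.ones(nt))
    else:
        from scipy.sparse import diags
        a = (q - diags(out_rate)).tocsc()
        tau_t = spsolve(a, -np.ones(nt))
    tau = np.zeros(n)
    for s, k in tidx.items():
        tau[s] = tau_t[k]

    pi = space.boltzmann()
    w = np.where(source_sel, pi, 0.0)
    return float(np.dot(w, tau) / w.sum())
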