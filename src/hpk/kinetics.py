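"""Kinetic Monte Carlo dynamics and forward flux sampling for hybridization.

Dynamics: a continuous-time Markov chain over single-pair add/remove moves
with Metropolis-form rates k0 min(1, e^{-dG}).  Because in-box state free
energies already include the duplex-initiation and box-to-standard-state
terms, the 0 -> 1 inter-pair (association) moves automatically carry the
box-concentration scaling, and detailed balance with respect to the
landscape module's Boltzmann weights holds edge-exactly.  k0 = 1 sets the
reduced time unit; only relative rates are physically meaningful here.

Rates of rare transitions (hybridization, and on toys also melting) are
estimated with direct forward flux sampling over interfaces on the number
of inter-strand base pairs: the flux through the first interface is the
basin-equilibrium average of the instantaneous boundary-crossing propensity
(banking first-contact configurations in proportion to their rate, i.e. the
exact flux-weighted ensemble), and each subsequent interface contributes a
conditional crossing probability estimated by shooting continuations from
the banked ensemble.  k+ = flux x prod(p_i) = r+ x P+ by construction,
mirroring the decomposition into the first-contact rate r+ (0 -> 1) and the
success probability P+ (1 -> full duplex).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from hpk.energy import EnergyParams
from hpk.oracle import StateSpace
from hpk.pairing import PairingState, PairSystem, decompose_linear, _bits
from hpk.sampling import get_evaluator, get_system
from hpk.sequences import StrandPairDesign

__all__ = [
    "RateModel",
    "Move",
    "Trajectory",
    "FFSResult",
    "AttachmentStats",
    "PathwayRecord",
    "propensities",
    "gillespie_run",
    "ffs_hybridization",
    "ffs_melting",
    "infer_relative_rates",
    "attachment_statistics",
    "classify_pathways",
    "check_detailed_balance",
]


@dataclass(frozen=True)
class RateModel:
    """Metropolis-rate CTMC: rate(a -> b) = k0 min(1, e^{-(G_b - G_a)})."""

    k0: float = 1.0

    def edge_rate(self, g_from_kt: float, g_to_kt: float) -> float:
        return self.k0 * min(1.0, math.exp(-(g_to_kt - g_from_kt)))


@dataclass(frozen=True)
class Move:
    pair_index: int
    add: bool


@dataclass
class Trajectory:
    times: list
    masks: list
    truncated: bool = False

    @property
    def final_mask(self) -> int:
        return self.masks[-1]


def propensities(state: PairingState | int, design: StrandPairDesign,
                 params: EnergyParams, rate_model: RateModel) -> list[tuple[Move, float]]:
    """All single-pair moves from a state with their CTMC rates.

    Enumeration order follows the feasible-pair index, so the list is
    deterministic.  Every edge satisfies the detailed-balance ratio
    rate(a->b)/rate(b->a) = e^{-(G_b - G_a)} to machine precision.
    """
    system = get_system(design)
    ev = get_evaluator(system, params)
    mask = state if isinstance(state, int) else system.state_to_mask(state)
    occ = system.occupancy(mask)
    g = ev.g_kt(mask)
    out = []
    for k in range(system.n_pairs):
        bit = 1 << k
        if mask & bit:
            out.append((Move(k, False), rate_model.edge_rate(g, ev.g_kt(mask ^ bit))))
        elif not occ & system.base_masks[k]:
            out.append((Move(k, True), rate_model.edge_rate(g, ev.g_kt(mask | bit))))
    return out


def check_detailed_balance(design: StrandPairDesign, params: EnergyParams,
                           rate_model: RateModel, mask: int) -> float:
    """Max |ln(rate_ab/rate_ba) + (G_b - G_a)| over all edges out of a state."""
    system = get_system(design)
    ev = get_evaluator(system, params)
    worst = 0.0
    for mv, r_ab in propensities(mask, design, params, rate_model):
        bit = 1 << mv.pair_index
        other = mask | bit if mv.add else mask ^ bit
        r_ba = rate_model.edge_rate(ev.g_kt(other), ev.g_kt(mask))
        lhs = math.log(r_ab / r_ba)
        rhs = -(ev.g_kt(other) - ev.g_kt(mask))
        worst = max(worst, abs(lhs - rhs))
    return worst


def gillespie_run(design: StrandPairDesign, params: EnergyParams,
                  rate_model: RateModel, start: PairingState | int,
                  stop: Callable[[tuple], bool] | None = None,
                  max_time: float = math.inf, seed: int = 0,
                  max_steps: int = 10_000_000,
                  record: bool = True) -> Trajectory:
    """Exact stochastic simulation of the pairing-state CTMC.

    Uses the uniformized formulation: a uniform proposal over the fixed
    move list with Metropolis acceptance and exponential waiting times at
    the total proposal rate, which realizes exactly the same process law
    as a direct Gillespie simulation of the per-move rates.  The
    trajectory records every state change with its time; a run cut off by
    ``max_time`` or ``max_steps`` is flagged truncated.
    """
    system = get_system(design)
    ev = get_evaluator(system, params)
    mask = start if isinstance(start, int) else system.state_to_mask(start)
    rng = np.random.default_rng(seed)
    m = system.n_pairs
    if m == 0:
        return Trajectory([0.0], [mask], truncated=False)
    total_rate = m * rate_model.k0
    occ = system.occupancy(mask)
    g = ev.g_kt(mask)
    t = 0.0
    times, masks = [0.0], [mask]
    truncated = False
    chunk = 4096
    ks = us = es = None
    ptr = chunk
    for _step in range(max_steps):
        if stop is not None and stop(system.counts(mask)):
            break
        if ptr >= chunk:
            ks = rng.integers(0, m, size=chunk)
            us = rng.random(chunk)
            es = rng.exponential(1.0 / total_rate, size=chunk)
            ptr = 0
        t += es[ptr]
        if t > max_time:
            t = max_time
            truncated = True
            break
        k = int(ks[ptr])
        u = us[ptr]
        ptr += 1
        bit = 1 << k
        bm = system.base_masks[k]
        if mask & bit:
            new_mask = mask ^ bit
        elif not occ & bm:
            new_mask = mask | bit
        else:
            continue
        new_g = ev.g_kt(new_mask)
        if u < math.exp(min(0.0, -(new_g - g))):
            mask, g = new_mask, new_g
            occ = (occ | bm) if mask & bit else (occ & ~bm)
            if record:
                times.append(t)
                masks.append(mask)
    else:
        truncated = True
    if not record or times[-1] != t:
        times.append(t)
        masks.append(mask)
    return Trajectory(times, masks, truncated)


# ---- forward flux sampling ----

@dataclass
class BankedConfig:
    mask: int
    site: int               # P-strand index of the first-contact pair
    aligned: bool           # first pair in the full-duplex register
    stems_full: tuple       # per strand: all intended stem pairs present at association
    stems_any: tuple        # per strand: >= 1 intended stem pair present
    ancestor: int           # index into the lambda_0 bank
    time: float = 0.0
    fourway: bool = False
    kissing: bool = False
    max_inter_intra: tuple = (0, 0)


@dataclass
class PathwayRecord:
    """Classification of one successful association trajectory.

    By microscopic reversibility the same records, read in reverse,
    describe the ensemble of melting trajectories.
    """

    site: int
    aligned: bool
    stems_full: tuple
    stems_any: tuple
    fourway: bool
    kissing: bool
    max_inter_intra: tuple
    time: float


@dataclass
class FFSResult:
    interfaces: list
    flux: float
    flux_se: float
    p: np.ndarray
    p_se: np.ndarray
    k_plus: float
    k_plus_se: float
    trials: list
    successes: list
    seed: int
    direction: str = "forward"
    bank0: list = field(default_factory=list)
    stage_site_stats: list = field(default_factory=list)
    records: list = field(default_factory=list)
    first_contact_records: list = field(default_factory=list)
    truncated_trials: int = 0
    n_basin_samples: int = 0

    @property
    def r_plus(self) -> float:
        return self.flux

    @property
    def P_plus(self) -> float:
        p = 1.0
        for x in self.p:
            p *= float(x)
        return p

    @property
    def r_plus_se(self) -> float:
        return self.flux_se

    @property
    def P_plus_se(self) -> float:
        rel = sum((s / p) ** 2 for p, s in zip(self.p, self.p_se) if p > 0)
        return self.P_plus * math.sqrt(rel)


class InterfaceStarvation(RuntimeError):
    """No successful crossings at an interface; suggests refining the ladder."""


def _strand_stem_flags(system: PairSystem, mask: int) -> tuple[tuple, tuple]:
    full, any_ = [], []
    for sid in system.strand_ids:
        stem_bits = 0
        for k in range(system.n_pairs):
            if (system.stem_mask >> k) & 1 and system.pairs[k].endpoint_a[0] == sid:
                stem_bits |= 1 << k
        if stem_bits == 0:
            full.append(False)
            any_.append(False)
        else:
            present = (mask & stem_bits).bit_count()
            full.append(present == stem_bits.bit_count())
            any_.append(present >= 1)
    return tuple(full), tuple(any_)


def _topology_flags(system: PairSystem, mask: int) -> tuple[bool, bool]:
    """(four-way junction, kissing) flags for one state."""
    lp = [system.linear_pairs[k] for k in _bits(mask)]
    fd = decompose_linear(lp, system.n_bases, system.nicks,
                          bool(mask & system.inter_mask))
    inter_set = {system.linear_pairs[k] for k in _bits(mask & system.inter_mask)}
    n_inter_helices = sum(1 for h in fd.helices if h[0] in inter_set)
    stems_full, _ = _strand_stem_flags(system, mask)
    fourway = n_inter_helices >= 2 and all(stems_full)
    kissing = bool(inter_set) and all(stems_full) and fd.n_crossings > 0
    return fourway, kissing


def _basin_sample(system: PairSystem, ev, rng, basin_keep: Callable[[int], bool],
                  start_mask: int, n_samples: int, thin: int) -> list[int]:
    """Metropolis chain confined to a basin, recording state masks.

    This samples the basin's *equilibrium* ensemble (it feeds the FFS flux
    estimate), so besides single-pair moves it uses the helix-toggle moves
    that decorrelate hairpin formation; the shooting dynamics elsewhere
    remain strictly single-pair.
    """
    mask = start_mask
    occ = system.occupancy(mask)
    g = ev.g_kt(mask)
    m = system.n_pairs
    out = []
    if m == 0:
        return [mask] * n_samples
    runs = system.run_moves
    run_bases = system.run_base_masks
    n_moves = m + len(runs)
    # burn-in matters here: the chain starts from a bare state whose
    # association propensity is atypically high, and the bank is
    # flux-weighted, so unequilibrated early samples would bias the
    # first-contact ensemble
    burn = max(n_samples * thin // 4, 5 * thin)
    steps = burn + n_samples * thin
    ks = rng.integers(0, n_moves, size=steps)
    us = rng.random(steps)
    for i in range(steps):
        mid = int(ks[i])
        if mid < m:
            mv_mask = 1 << mid
            mv_base = system.base_masks[mid]
        else:
            mv_mask = runs[mid - m]
            mv_base = run_bases[mid - m]
        present = mask & mv_mask
        if present == mv_mask:
            new_mask = mask ^ mv_mask
            adding = False
        elif present == 0 and not occ & mv_base:
            new_mask = mask | mv_mask
            adding = True
        else:
            new_mask = None
        if new_mask is not None and basin_keep(new_mask):
            new_g = ev.g_kt(new_mask)
            if us[i] < math.exp(min(0.0, -(new_g - g))):
                mask, g = new_mask, new_g
                occ = (occ | mv_base) if adding else (occ & ~mv_base)
        if i >= burn and (i + 1 - burn) % thin == 0:
            out.append(mask)
    return out


def _ffs(design: StrandPairDesign, params: EnergyParams, rate_model: RateModel,
         interfaces: Sequence[int], seed: int, n_trials: int,
         n_basin_samples: int, basin_thin: int | None,
         direction: str, max_steps_per_trial: int) -> FFSResult:
    system = get_system(design)
    ev = get_evaluator(system, params)
    rng = np.random.default_rng(seed)
    inter_mask = system.inter_mask
    n_full = system.n_full_duplex
    if n_full == 0:
        raise ValueError("FFS needs a two-strand design with aligned duplex pairs")

    if direction == "forward":
        def op(mask: int) -> int:
            return (mask & inter_mask).bit_count()
        basin_start = 0
    else:
        def op(mask: int) -> int:
            return n_full - (mask & inter_mask).bit_count()
        basin_start = _full_duplex_mask(system)

    interfaces = sorted(set(int(x) for x in interfaces))
    if interfaces[0] != 1:
        raise ValueError("the first interface must sit at order parameter 1")
    if any(b <= a for a, b in zip(interfaces, interfaces[1:])):
        raise ValueError("interfaces must be strictly increasing")

    if basin_thin is None:
        basin_thin = 2 * max(system.n_pairs, 1)

    # stage 0: basin equilibrium; flux = <sum of boundary-crossing rates>
    basin_states = _basin_sample(system, ev, rng, lambda mk: op(mk) == 0,
                                 basin_start, n_basin_samples, basin_thin)
    k_out = np.zeros(len(basin_states))
    boundary_moves: list[list[tuple[int, float]]] = []
    for i, mk in enumerate(basin_states):
        occ = system.occupancy(mk)
        g = ev.g_kt(mk)
        moves = []
        for k in _bits(inter_mask):
            bit = 1 << k
            if direction == "forward":
                if (mk & bit) or (occ & system.base_masks[k]):
                    continue
                new = mk | bit
            else:
                if not mk & bit:
                    continue
                new = mk ^ bit
            if op(new) != 1:
                continue
            r = rate_model.edge_rate(g, ev.g_kt(new))
            moves.append((new, r))
        boundary_moves.append(moves)
        k_out[i] = sum(r for _n, r in moves)
    flux = float(k_out.mean())
    if flux <= 0:
        raise InterfaceStarvation("no boundary-crossing moves found from the basin")
    nb = max(len(k_out) // N_FLUX_BLOCKS, 1)
    blocks = [k_out[j: j + nb].mean() for j in range(0, len(k_out), nb)]
    flux_se = float(np.std(blocks, ddof=1) / math.sqrt(len(blocks))) \
        if len(blocks) >= 2 else flux

    # bank the lambda_0 ensemble proportionally to crossing rate
    p_state = k_out / k_out.sum()
    bank0: list[BankedConfig] = []
    picks = rng.choice(len(basin_states), size=n_trials, p=p_state)
    for idx in picks:
        moves = boundary_moves[int(idx)]
        rs = np.array([r for _n, r in moves])
        j = int(rng.choice(len(moves), p=rs / rs.sum()))
        new_mask = moves[j][0]
        changed = new_mask ^ basin_states[int(idx)]
        k = changed.bit_length() - 1
        bp = system.pairs[k]
        site = bp.endpoint_a[1] if bp.endpoint_a[0] == "P" else bp.endpoint_b[1]
        aligned = bool((system.aligned_mask >> k) & 1)
        stems_full, stems_any = _strand_stem_flags(system, basin_states[int(idx)])
        fw, ki = _topology_flags(system, new_mask)
        bank0.append(BankedConfig(new_mask, site, aligned, stems_full, stems_any,
                                  ancestor=len(bank0), fourway=fw, kissing=ki,
                                  max_inter_intra=_ii(system, new_mask)))

    # staged shooting
    bank = bank0
    trials_per_stage, succ_per_stage = [], []
    p_list, p_se_list = [], []
    stage_site_stats = []
    truncated = 0
    for stage in range(len(interfaces) - 1):
        lam_next = interfaces[stage + 1]
        succ = 0
        resolved = 0
        new_bank: list[BankedConfig] = []
        site_stats: dict[int, list] = {}
        # if every trial of a stage is censored or fails, the stage is
        # retried with a relaxed step cap (fewer trials): starvation here
        # usually means the censoring window was shorter than the blocked
        # intermediates' resolution time, not that the interface is wrong
        for attempt in range(3):
            cap = max_steps_per_trial * 5 ** attempt
            n_t = max(n_trials // (2 ** attempt), 20)
            succ = resolved = 0
            new_bank = []
            site_stats = {}
            for t in range(n_t):
                cfg = bank[t % len(bank)]
                res, end_mask, dt, trunc = _shoot(system, ev, rng, rate_model,
                                                  op, cfg.mask, lam_next, cap)
                if trunc:
                    # a trial stuck in a metastable intermediate (typically a
                    # hairpin-blocked partial duplex) is unresolved within the
                    # step budget: it is reported and excluded from the
                    # conditional-probability estimate rather than silently
                    # counted as a failure
                    truncated += 1
                    continue
                resolved += 1
                anc = bank0[cfg.ancestor]
                st = site_stats.setdefault(
                    anc.site if anc.aligned else -anc.site - 1, [0, 0])
                st[0] += 1
                if res:
                    succ += 1
                    st[1] += 1
                    fw, ki = _topology_flags(system, end_mask)
                    new_bank.append(BankedConfig(
                        end_mask, cfg.site, cfg.aligned, cfg.stems_full,
                        cfg.stems_any, ancestor=cfg.ancestor,
                        time=cfg.time + dt,
                        fourway=cfg.fourway or fw, kissing=cfg.kissing or ki,
                        max_inter_intra=max(cfg.max_inter_intra,
                                            _ii(system, end_mask))))
            if succ > 0:
                break
        trials_per_stage.append(resolved)
        succ_per_stage.append(succ)
        stage_site_stats.append(site_stats)
        if succ == 0:
            raise InterfaceStarvation(
                f"no successes crossing interface {lam_next} "
                f"(stage {stage}); refine the interface ladder")
        p_hat = succ / resolved
        p_list.append(p_hat)
        p_se_list.append(math.sqrt(p_hat * (1 - p_hat) / resolved))
        bank = new_bank

    p_arr = np.array(p_list)
    p_se = np.array(p_se_list)
    k_plus = flux
    for x in p_arr:
        k_plus *= float(x)
    rel = (flux_se / flux) ** 2 + sum(
        (s / p) ** 2 for p, s in zip(p_arr, p_se) if p > 0)
    records = [PathwayRecord(c.site, c.aligned, c.stems_full, c.stems_any,
                             c.fourway, c.kissing, c.max_inter_intra, c.time)
               for c in bank]
    first_contact_records = [
        PathwayRecord(c.site, c.aligned, c.stems_full, c.stems_any,
                      c.fourway, c.kissing, c.max_inter_intra, c.time)
        for c in bank0]
    return FFSResult(list(interfaces), flux, flux_se, p_arr, p_se,
                     k_plus, k_plus * math.sqrt(rel),
                     trials_per_stage, succ_per_stage, seed, direction,
                     bank0=bank0, stage_site_stats=stage_site_stats,
                     records=records, truncated_trials=truncated,
                     first_contact_records=first_contact_records,
                     n_basin_samples=len(basin_states))


N_FLUX_BLOCKS = 8


def _ii(system: PairSystem, mask: int) -> tuple[int, int]:
    c = system.counts(mask)
    return (c[0], c[1])


def _full_duplex_mask(system: PairSystem) -> int:
    return system.aligned_mask


def _shoot(system, ev, rng, rate_model, op, mask, lam_next, max_steps):
    """One KMC continuation: returns (reached_next, end_mask, elapsed, truncated)."""
    m = system.n_pairs
    occ = system.occupancy(mask)
    g = ev.g_kt(mask)
    total_rate = m * rate_model.k0
    t = 0.0
    chunk = 2048
    ptr = chunk
    ks = us = es = None
    for _ in range(max_steps):
        if ptr >= chunk:
            ks = rng.integers(0, m, size=chunk)
            us = rng.random(chunk)
            es = rng.exponential(1.0 / total_rate, size=chunk)
            ptr = 0
        t += es[ptr]
        k = int(ks[ptr])
        u = us[ptr]
        ptr += 1
        bit = 1 << k
        bm = system.base_masks[k]
        if mask & bit:
            new_mask = mask ^ bit
        elif not occ & bm:
            new_mask = mask | bit
        else:
            continue
        new_g = ev.g_kt(new_mask)
        if u < math.exp(min(0.0, -(new_g - g))):
            mask, g = new_mask, new_g
            occ = (occ | bm) if mask & bit else (occ & ~bm)
            o = op(mask)
            if o >= lam_next:
                return True, mask, t, 0
            if o == 0:
                return False, mask, t, 0
    return False, mask, t, 1


def default_interfaces(n_full: int) -> list[int]:
    base = [1, 2, 4, 6, 9, 12, 16, 20]
    return sorted({x for x in base if x < n_full} | {n_full})


def ffs_hybridization(design: StrandPairDesign, params: EnergyParams,
                      rate_model: RateModel | None = None,
                      interfaces: Sequence[int] | None = None,
                      n_trials: int = 400, seed: int = 0,
                      n_basin_samples: int = 800,
                      basin_thin: int | None = None,
                      max_steps_per_trial: int = 50_000) -> FFSResult:
    """Hybridization rate k+ by direct FFS over n_inter interfaces.

    The unbound basin A is every state with zero inter-strand pairs (any
    intra structure allowed); the target B is the full duplex.  Returns
    the flux through the first interface (r+), the per-interface crossing
    probabilities whose product is P+, and k+ = r+ P+ exactly, together
    with the banked first-contact ensemble used for attachment statistics
    and the pathway records of the successful continuations.
    """
    rate_model = rate_model or RateModel()
    system = get_system(design)
    if interfaces is None:
        interfaces = default_interfaces(system.n_full_duplex)
    return _ffs(design, params, rate_model, interfaces, seed, n_trials,
                n_basin_samples, basin_thin, "forward", max_steps_per_trial)


def ffs_melting(design: StrandPairDesign, params: EnergyParams,
                rate_model: RateModel | None = None,
                interfaces: Sequence[int] | None = None,
                n_trials: int = 400, seed: int = 0,
                n_basin_samples: int = 800,
                basin_thin: int | None = None,
                max_steps_per_trial: int = 50_000) -> FFSResult:
    """Melting rate k- by FFS run in the dissociation direction.

    The basin is the full duplex; interfaces count *broken* duplex pairs,
    and success is complete strand separation (zero inter-strand pairs).
    Feasible on toy systems; used to verify the detailed-balance relation
    between k+, k- and dG0.
    """
    rate_model = rate_model or RateModel()
    system = get_system(design)
    if interfaces is None:
        interfaces = list(range(1, system.n_full_duplex + 1))
    return _ffs(design, params, rate_model, interfaces, seed, n_trials,
                n_basin_samples, basin_thin, "reverse", max_steps_per_trial)


def infer_relative_rates(results: dict[str, FFSResult],
                         reference: str) -> "pd.DataFrame":
    """Ratios k0+/k+, r0+/r+, P0+/P+ for each system against a reference.

    Standard errors are propagated on the log scale; the reference row is
    exactly one in every column.
    """
    import pandas as pd

    if reference not in results:
        raise KeyError(f"reference system {reference!r} missing from results")
    ref = results[reference]
    rows = []
    for name, r in results.items():
        def ratio(a, a_se, b, b_se):
            v = a / b
            return v, v * math.sqrt((a_se / a) ** 2 + (b_se / b) ** 2)
        k, k_se = ratio(ref.k_plus, ref.k_plus_se, r.k_plus, r.k_plus_se)
        rp, rp_se = ratio(ref.r_plus, ref.r_plus_se, r.r_plus, r.r_plus_se)
        pp, pp_se = ratio(ref.P_plus, ref.P_plus_se, r.P_plus, r.P_plus_se)
        if name == reference:
            k, rp, pp = 1.0, 1.0, 1.0
            k_se = rp_se = pp_se = 0.0
        rows.append({"system": name, "k_plus_ratio": k, "k_plus_ratio_se": k_se,
                     "r_plus_ratio": rp, "r_plus_ratio_se": rp_se,
                     "P_plus_ratio": pp, "P_plus_ratio_se": pp_se})
    return pd.DataFrame(rows).set_index("system")


@dataclass
class AttachmentStats:
    """First-contact frequencies and success probabilities per P-strand site."""

    frequency: dict          # (site, aligned) -> fraction of first contacts
    success: dict            # (site, aligned) -> probability of reaching full duplex
    interface_success: list  # success probability from each interface onward
    dissociation_from_6bp: float | None


def attachment_statistics(result: FFSResult) -> AttachmentStats:
    """Site-resolved attachment statistics from a forward FFS run.

    Frequencies are over the flux-weighted first-contact ensemble; the
    success probability of a site class is the product over stages of its
    conditional crossing probabilities (fractional credit over the
    continuations of each banked configuration).
    """
    if result.direction != "forward" or not result.bank0:
        raise ValueError("attachment statistics need a forward FFS result with a bank")
    n0 = len(result.bank0)
    freq: dict = {}
    for c in result.bank0:
        key = (c.site, c.aligned)
        freq[key] = freq.get(key, 0.0) + 1.0 / n0

    succ: dict = {}
    for key in freq:
        site, aligned = key
        skey = site if aligned else -site - 1
        p = 1.0
        for st in result.stage_site_stats:
            if skey not in st or st[skey][0] == 0:
                p = 0.0
                break
            p *= st[skey][1] / st[skey][0]
        succ[key] = p

    iface_succ = []
    for i in range(len(result.p)):
        v = 1.0
        for x in result.p[i:]:
            v *= float(x)
        iface_succ.append(v)
    diss6 = None
    if 6 in result.interfaces:
        idx = result.interfaces.index(6)
        v = 1.0
        for x in result.p[idx:]:
            v *= float(x)
        diss6 = 1.0 - v
    return AttachmentStats(freq, succ, iface_succ, diss6)


def classify_pathways(records: Sequence[PathwayRecord]) -> dict:
    """Fractions of association pathway classes over successful trajectories.

    "Intact" uses all-intended-stem-pairs-present as the headline
    criterion; the >= 1-stem-pair variant is reported alongside.  By
    microscopic reversibility the same fractions describe the melting
    trajectory ensemble read in reverse.
    """
    n = len(records)
    if n == 0:
        return {"n": 0}
    both_full = sum(1 for r in records if all(r.stems_full)) / n
    one_full = sum(1 for r in records
                   if any(r.stems_full) and not all(r.stems_full)) / n
    none_full = sum(1 for r in records if not any(r.stems_full)) / n
    at_least_one_full = sum(1 for r in records if any(r.stems_full)) / n
    both_any = sum(1 for r in records if all(r.stems_any)) / n
    at_least_one_any = sum(1 for r in records if any(r.stems_any)) / n
    return {
        "n": n,
        "both_stems_intact": both_full,
        "one_stem_intact": one_full,
        "no_stem_intact": none_full,
        "at_least_one_stem_intact": at_least_one_full,
        "both_stems_any_pair": both_any,
        "at_least_one_stem_any_pair": at_least_one_any,
        "fourway_junction": sum(1 for r in records if r.fourway) / n,
        "kissing": sum(1 for r in records if r.kissing) / n,
    }
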