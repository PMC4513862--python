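"""Canonical-ensemble Monte Carlo with umbrella biasing and reweighting.

The sampler is a Metropolis chain over single-pair add/remove moves: a
feasible pair is drawn uniformly; if present it is proposed for removal,
if absent and both bases are free it is proposed for addition, and the
move is accepted with min(1, w'/w * exp(-dG)) where w are fixed umbrella
bias weights per order-parameter bin.  Barriers along the inter-strand
base-pair coordinate are crossed with overlapping umbrella windows whose
bias weights are learned in a Wang-Landau pre-pass and then frozen for
production (so the production chain satisfies detailed balance exactly).
Window histograms are unbiased, stitched by least-squares matching of
log-frequencies on overlap bins, and referenced to a declared bin.
Single-histogram temperature reweighting extrapolates sampled ensembles
to nearby temperatures using per-sample enthalpies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Hashable, Sequence

import numpy as np

from hpk.energy import EnergyParams, R_KCAL
from hpk.oracle import bin_inter_intra, bin_single_strand
from hpk.pairing import PairSystem, StateEnergy
from hpk.sequences import StrandPairDesign

__all__ = [
    "UmbrellaWindow",
    "WindowHistogram",
    "Landscape2D",
    "MeltCurve",
    "mc_run",
    "stitch_windows",
    "reweight_temperature",
    "hairpin_yield_curve",
    "single_strand_landscape",
    "duplex_landscapes",
    "duplex_dg0_keq",
    "get_system",
    "get_evaluator",
]

CENSOR_DG_KT = 10.0
REWEIGHT_TRUST_C = 5.0
MIN_ESS = 200.0
N_BLOCKS = 8
N_REPLICAS = 4
BIAS_RANGE_KT = 16.0
MAX_INTRA_BIAS = 10
MAX_INTRA_DUPLEX = 12

_system_cache: dict[str, PairSystem] = {}
_evaluator_cache: dict[tuple, StateEnergy] = {}


def get_system(design: StrandPairDesign) -> PairSystem:
    key = design.to_json()
    sys_ = _system_cache.get(key)
    if sys_ is None:
        sys_ = _system_cache[key] = PairSystem(design)
    return sys_


def get_evaluator(system: PairSystem, params: EnergyParams) -> StateEnergy:
    key = (id(system), params.temperature_C, params.box_volume_m3,
           params.pseudoknot_penalty_kT, params.hairpin_closing_dH,
           params.hairpin_closing_dS, params.lonely_pair_dH,
           params.lonely_pair_dS)
    ev = _evaluator_cache.get(key)
    if ev is None:
        ev = _evaluator_cache[key] = StateEnergy(system, params)
    return ev


@dataclass
class UmbrellaWindow:
    """An order-parameter window with fixed per-bin bias weights.

    ``x_range``/``y_range`` are inclusive bounds on the two binning axes
    (None = unrestricted); ``bias`` maps bin keys to strictly positive
    weights (missing bins default to 1).
    """

    x_range: tuple[int, int] | None = None
    y_range: tuple[int, int] | None = None
    bias: dict = field(default_factory=dict)
    seed: int = 0
    # bounds on x + y, e.g. to cap total intra pairs for single strands
    sum_range: tuple[int, int] | None = None
    # maps a bin key to the key the bias table is indexed by (default:
    # identity); biasing on a coarser coordinate such as x + y makes the
    # adaptive pre-pass converge on a handful of bins
    bias_key: Callable | None = None
    _min_log_w: float | None = field(default=None, repr=False, compare=False)

    def contains(self, key: tuple[int, int]) -> bool:
        x, y = key
        if self.x_range is not None and not self.x_range[0] <= x <= self.x_range[1]:
            return False
        if self.y_range is not None and not self.y_range[0] <= y <= self.y_range[1]:
            return False
        if self.sum_range is not None and not self.sum_range[0] <= x + y <= self.sum_range[1]:
            return False
        return True

    def log_w(self, key: tuple[int, int]) -> float:
        if self.bias_key is not None:
            key = self.bias_key(key)
        w = self.bias.get(key)
        if w is None:
            # bins the bias pre-pass never reached get the least attractive
            # learned weight, so the production chain is not sucked into
            # unexplored (extremely high free energy) corners
            if not self.bias:
                return 0.0
            if self._min_log_w is None:
                self._min_log_w = math.log(min(self.bias.values()))
            return self._min_log_w
        if w <= 0:
            raise ValueError(f"bias weight for bin {key} must be strictly positive")
        return math.log(w)


@dataclass
class WindowHistogram:
    """Samples and unbiased per-bin log-frequencies from one window run."""

    window: UmbrellaWindow
    counts: dict                      # bin -> raw sample count
    log_p: dict                       # bin -> unbiased log-frequency (unnormalized)
    se: dict                          # bin -> SE of log_p (block estimate)
    samples_bin: np.ndarray           # (n, 2) int bins
    samples_dH: np.ndarray            # (n,) kcal/mol per sample
    samples_logw: np.ndarray          # (n,) bias log-weight of the sample's bin
    acceptance_rate: float
    n_steps: int
    seed: int
    temperature_C: float
    ess: float | None = None
    low_ess: bool = False


@dataclass
class Landscape2D:
    """Binned free-energy landscape (kBT, relative to ``reference_bin``)."""

    bins: dict                        # bin -> dG in kBT
    se: dict                          # bin -> standard error
    n_samples: dict                   # bin -> raw sample count
    reference_bin: tuple
    stitch_residual: float = 0.0
    censor_threshold: float = CENSOR_DG_KT

    @property
    def censored(self) -> set:
        return {k for k, g in self.bins.items() if g >= self.censor_threshold}

    def resolved(self) -> dict:
        return {k: g for k, g in self.bins.items() if k not in self.censored}

    def marginal_x(self) -> "Landscape2D":
        """1D landscape over the first axis: G(x) = -ln sum_y e^{-G(x, y)}."""
        acc: dict[int, list] = {}
        for (x, _y), g in self.bins.items():
            acc.setdefault(x, []).append(((x, _y), g))
        bins, se, ns = {}, {}, {}
        for x, items in acc.items():
            ws = np.array([math.exp(-g) for _k, g in items])
            bins[(x,)] = -math.log(ws.sum())
            p = ws / ws.sum()
            se[(x,)] = float(np.sqrt(np.sum((p * np.array(
                [self.se.get(k, 0.0) for k, _g in items])) ** 2)))
            ns[(x,)] = sum(self.n_samples.get(k, 0) for k, _g in items)
        ref = min(bins)  # shift so the x of the reference bin is zero
        rx = (self.reference_bin[0],)
        shift = bins.get(rx, bins[ref])
        bins = {k: g - shift for k, g in bins.items()}
        return Landscape2D(bins, se, ns, rx, self.stitch_residual,
                           self.censor_threshold)


@dataclass
class MeltCurve:
    """Yield-versus-temperature curve with an interpolated melting point."""

    temperatures_C: np.ndarray
    yields: np.ndarray
    se: np.ndarray
    tm_C: float | None = None


# ---- core Metropolis chain ----

def _allowed_pair_indices(system: PairSystem, forbid_intra: bool) -> np.ndarray:
    if not forbid_intra:
        return np.arange(system.n_pairs)
    return np.array([k for k in range(system.n_pairs)
                     if (system.inter_mask >> k) & 1], dtype=np.int64)


def mc_run(design: StrandPairDesign, params: EnergyParams,
           window: UmbrellaWindow | None = None,
           n_steps: int = 100_000, seed: int = 0,
           binning: Callable = bin_inter_intra,
           forbid_intra: bool = False,
           init_state_mask: int = 0,
           thin: int = 1,
           burn_in: int | None = None) -> WindowHistogram:
    """Metropolis sampling restricted to an umbrella window.

    The first ``burn_in`` steps (default one fifth of ``n_steps``) are
    discarded so the seeded initial state does not bias the histogram.
    Returns the per-bin histogram with unbiased log-frequencies and
    standard errors (sequential block estimates), plus the raw samples
    (bin, enthalpy) needed for temperature reweighting.
    """
    system = get_system(design)
    ev = get_evaluator(system, params)
    if window is None:
        window = UmbrellaWindow()
    rng = np.random.default_rng(seed)
    allowed = _allowed_pair_indices(system, forbid_intra)
    if len(allowed) == 0:
        n_rec = n_steps // thin
        key = binning(system.counts(init_state_mask))
        return _finalize_histogram(
            window, {key: n_rec}, np.full((n_rec, 2), key, dtype=np.int64),
            np.full(n_rec, ev.dHdS(init_state_mask)[0]),
            np.zeros(n_rec), 0.0, n_steps, seed, params.temperature_C)

    mask = init_state_mask
    occ = system.occupancy(mask)
    g = ev.g_kt(mask)
    key = binning(system.counts(mask))
    if not window.contains(key):
        raise ValueError(f"initial state bin {key} lies outside the window")
    logw = window.log_w(key)
    dh = ev.dHdS(mask)[0]
    runs = [] if forbid_intra else system.run_moves
    run_bases = system.run_base_masks
    n_pair_moves = len(allowed)
    n_moves = n_pair_moves + len(runs)

    if burn_in is None:
        burn_in = n_steps // 5
    total = burn_in + n_steps
    n_rec = n_steps // thin
    samples_bin = np.empty((n_rec, 2), dtype=np.int64)
    samples_dh = np.empty(n_rec)
    samples_logw = np.empty(n_rec)
    counts: dict[Hashable, int] = {}
    accepted = 0
    rec = 0

    chunk = 8192
    done = 0
    explored = 0
    while done < total:
        m = min(chunk, total - done)
        ids = rng.integers(0, n_moves, size=m)
        us = rng.random(m)
        for mid, u in zip(ids, us):
            mid = int(mid)
            if mid < n_pair_moves:
                k = int(allowed[mid])
                mv_mask = 1 << k
                mv_base = system.base_masks[k]
            else:
                mv_mask = runs[mid - n_pair_moves]
                mv_base = run_bases[mid - n_pair_moves]
            present = mask & mv_mask
            if present == mv_mask:
                new_mask = mask ^ mv_mask
                adding = False
            elif present == 0 and not occ & mv_base:
                new_mask = mask | mv_mask
                adding = True
            else:
                new_mask = None  # partially blocked: null proposal
            if new_mask is not None:
                new_key = binning(system.counts(new_mask))
                if window.contains(new_key):
                    new_g = ev.g_kt(new_mask)
                    new_logw = window.log_w(new_key)
                    if u < math.exp(min(0.0, (new_logw - logw) - (new_g - g))):
                        mask, g, key, logw = new_mask, new_g, new_key, new_logw
                        occ = (occ | mv_base) if adding else (occ & ~mv_base)
                        dh = ev.dHdS(mask)[0]
                        accepted += 1
            done += 1
            if done > burn_in and (done - burn_in) % thin == 0 and rec < n_rec:
                samples_bin[rec] = key
                samples_dh[rec] = dh
                samples_logw[rec] = logw
                counts[key] = counts.get(key, 0) + 1
                rec += 1
        explored += m
        if not counts and explored > 200_000:
            raise RuntimeError("window contains no reachable recorded states")

    return _finalize_histogram(window, counts, samples_bin[:rec],
                               samples_dh[:rec], samples_logw[:rec],
                               accepted / max(total, 1), n_steps, seed,
                               params.temperature_C)


def _finalize_histogram(window, counts, samples_bin, samples_dh, samples_logw,
                        acc_rate, n_steps, seed, temperature_C) -> WindowHistogram:
    log_p, se = _unbiased_logp(counts, samples_bin, samples_logw)
    return WindowHistogram(window, counts, log_p, se, samples_bin, samples_dh,
                           samples_logw, acc_rate, n_steps, seed, temperature_C)


def _unbiased_logp(counts: dict, samples_bin: np.ndarray,
                   samples_logw: np.ndarray,
                   weights: np.ndarray | None = None) -> tuple[dict, dict]:
    """Unbiased log-frequency per bin and block-based standard errors."""
    n = len(samples_bin)
    if n == 0:
        return {}, {}
    if weights is None:
        weights = np.ones(n)
    keys = [tuple(b) for b in samples_bin]
    w_un = weights * np.exp(-samples_logw)  # divide out the umbrella bias
    tot: dict[Hashable, float] = {}
    for k, w in zip(keys, w_un):
        tot[k] = tot.get(k, 0.0) + w
    z = sum(tot.values())
    log_p = {k: math.log(v / z) for k, v in tot.items()}

    # sequential block estimates of the log-frequency scatter
    edges = np.linspace(0, n, N_BLOCKS + 1).astype(int)
    block_logp: dict[Hashable, list] = {k: [] for k in tot}
    for b0, b1 in zip(edges[:-1], edges[1:]):
        bt: dict[Hashable, float] = {}
        for k, w in zip(keys[b0:b1], w_un[b0:b1]):
            bt[k] = bt.get(k, 0.0) + w
        bz = sum(bt.values())
        if bz <= 0:
            continue
        for k, v in bt.items():
            block_logp[k].append(math.log(v / bz))
    se = {}
    for k, vals in block_logp.items():
        cnt = counts.get(k, 1)
        multinom = math.sqrt(max(1.0 - math.exp(log_p[k]), 1e-12) / cnt)
        if len(vals) >= 2:
            blk = float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
            se[k] = max(blk, multinom)
        else:
            se[k] = max(2.0 * multinom, 1.0)  # effectively unresolved
    return log_p, se


def merge_replicas(hists: Sequence[WindowHistogram]) -> WindowHistogram:
    """Combine independent production replicas of one window.

    The merged log-frequency is the replica mean and its SE the replica
    scatter, which honestly reflects chain autocorrelation; bins missing
    from some replicas keep the single-estimate fallback SE.
    """
    if len(hists) == 1:
        return hists[0]
    keys = set()
    for h in hists:
        keys |= set(h.log_p)
    log_p, se, counts = {}, {}, {}
    for k in keys:
        vals = [h.log_p[k] for h in hists if k in h.log_p]
        counts[k] = sum(h.counts.get(k, 0) for h in hists)
        log_p[k] = float(np.mean(vals))
        if len(vals) >= 2:
            scatter = float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
            floor = min(h.se[k] for h in hists if k in h.se) / math.sqrt(len(vals))
            se[k] = max(scatter, floor)
        else:
            se[k] = max(h.se[k] for h in hists if k in h.se)
    merged = WindowHistogram(
        hists[0].window, counts, log_p, se,
        np.concatenate([h.samples_bin for h in hists]),
        np.concatenate([h.samples_dH for h in hists]),
        np.concatenate([h.samples_logw for h in hists]),
        float(np.mean([h.acceptance_rate for h in hists])),
        sum(h.n_steps for h in hists), hists[0].seed, hists[0].temperature_C)
    return merged


# ---- Wang-Landau bias learning ----

def learn_bias(design: StrandPairDesign, params: EnergyParams,
               window: UmbrellaWindow, seed: int = 0,
               binning: Callable = bin_inter_intra,
               forbid_intra: bool = False,
               init_state_mask: int = 0,
               n_steps_per_stage: int = 30_000,
               f_schedule: Sequence[float] = (1.0, 0.5, 0.2, 0.05),
               flatten_axis: int | None = 0,
               initial_logw: dict | None = None,
               bias_range: float | None = None) -> dict:
    """Adaptive pre-pass estimating per-bin weights that flatten the window.

    Two-phase scheme: stages with f > 0 apply Wang-Landau-style additive
    updates on every visit, which push the chain over barriers and rough in
    the weights; stages with f = 0 sample with *fixed* weights and then
    flatten against the stage histogram (multicanonical recursion), whose
    update noise shrinks with stage length.  The returned weights are used
    as fixed umbrella biases in production, so any residual imperfection
    costs only variance, never correctness.
    """
    system = get_system(design)
    ev = get_evaluator(system, params)
    rng = np.random.default_rng(seed)
    allowed = _allowed_pair_indices(system, forbid_intra)
    logw: dict[Hashable, float] = dict(initial_logw or {})
    bk = window.bias_key or (lambda key: key)

    mask = init_state_mask
    occ = system.occupancy(mask)
    g = ev.g_kt(mask)
    key = bk(binning(system.counts(mask)))
    if not window.contains(binning(system.counts(mask))):
        raise ValueError(f"initial state bin {key} lies outside the window")
    if len(allowed) == 0:
        return {key: 1.0}

    runs = [] if forbid_intra else system.run_moves
    run_bases = system.run_base_masks
    n_pair_moves = len(allowed)
    n_moves = n_pair_moves + len(runs)

    for f in f_schedule:
        stage_counts: dict[Hashable, int] = {}
        ids = rng.integers(0, n_moves, size=n_steps_per_stage)
        us = rng.random(n_steps_per_stage)
        for mid, u in zip(ids, us):
            mid = int(mid)
            if mid < n_pair_moves:
                mv_mask = 1 << int(allowed[mid])
                mv_base = system.base_masks[int(allowed[mid])]
            else:
                mv_mask = runs[mid - n_pair_moves]
                mv_base = run_bases[mid - n_pair_moves]
            present = mask & mv_mask
            if present == mv_mask:
                new_mask = mask ^ mv_mask
                adding = False
            elif present == 0 and not occ & mv_base:
                new_mask = mask | mv_mask
                adding = True
            else:
                if f:
                    logw[key] = logw.get(key, 0.0) - f
                stage_counts[key] = stage_counts.get(key, 0) + 1
                continue
            new_bin = binning(system.counts(new_mask))
            if window.contains(new_bin):
                new_key = bk(new_bin)
                new_g = ev.g_kt(new_mask)
                d = (logw.get(new_key, 0.0) - logw.get(key, 0.0)) - (new_g - g)
                if u < math.exp(min(0.0, d)):
                    mask, g, key = new_mask, new_g, new_key
                    occ = (occ | mv_base) if adding else (occ & ~mv_base)
            if f:
                logw[key] = logw.get(key, 0.0) - f
            stage_counts[key] = stage_counts.get(key, 0) + 1
        if not f:
            mean_c = float(np.mean(list(stage_counts.values())))
            for k2, c in stage_counts.items():
                logw[k2] = logw.get(k2, 0.0) - math.log(c / mean_c)

    # Cap the learned bias: bins far above the landscape floor are censored
    # in the output, and flattening into them would waste the production
    # run.  When ``flatten_axis`` names a barrier coordinate, the cap is
    # applied within each column of that axis (the axis itself is flattened
    # in full so the chain can traverse the barrier); otherwise the cap is
    # global, measured from the window's most stable bin.
    if bias_range is None:
        bias_range = BIAS_RANGE_KT
    if flatten_axis is None or not isinstance(next(iter(logw)), tuple):
        bottom = min(logw.values())
        capped = {k: min(v, bottom + bias_range) for k, v in logw.items()}
    else:
        colmin: dict[int, float] = {}
        for k, v in logw.items():
            colmin[k[flatten_axis]] = min(colmin.get(k[flatten_axis], math.inf), v)
        capped = {k: min(v, colmin[k[flatten_axis]] + bias_range)
                  for k, v in logw.items()}
    top = max(capped.values())
    return {k: math.exp(v - top) for k, v in capped.items()}


# ---- window stitching ----

def stitch_windows(histograms: Sequence[WindowHistogram],
                   reference_bin: tuple = (0, 0),
                   allow_disconnected: bool = False) -> Landscape2D:
    """Least-squares stitching of overlapping window histograms.

    Window offsets are solved from log-frequency differences on shared
    bins (inverse-variance weighted); a single global shift then fixes
    dG(reference) = 0.  The RMS mismatch on overlaps after stitching is
    reported as ``stitch_residual``.
    """
    nw = len(histograms)
    resolved = [set(h.log_p) for h in histograms]

    # connectivity of the window-overlap graph
    comp = list(range(nw))

    def find(a):
        while comp[a] != a:
            comp[a] = comp[comp[a]]
            a = comp[a]
        return a

    overlaps = []
    for a in range(nw):
        for b in range(a + 1, nw):
            shared = resolved[a] & resolved[b]
            if shared:
                overlaps.append((a, b, shared))
                comp[find(a)] = find(b)
    roots = {find(a) for a in range(nw)}
    if len(roots) > 1:
        groups: dict = {}
        for a in range(nw):
            groups.setdefault(find(a), []).append(a)
        if not allow_disconnected:
            raise ValueError(
                f"window graph is disconnected; components: {sorted(groups.values())}")
        # keep only the component reachable from the window containing the
        # reference bin; the remainder of the landscape stays unresolved
        ref_w = next((w for w in range(nw) if reference_bin in resolved[w]), None)
        if ref_w is None:
            raise ValueError(f"reference bin {reference_bin} was never sampled")
        keep = set(groups[find(ref_w)])
        histograms = [h for w, h in enumerate(histograms) if w in keep]
        return stitch_windows(histograms, reference_bin, allow_disconnected=False)

    # weighted least squares for offsets c_w (c_0 = 0)
    c = np.zeros(nw)
    if nw > 1:
        rows, rhs, wts = [], [], []
        for a, b, shared in overlaps:
            for k in shared:
                r = np.zeros(nw)
                r[a], r[b] = 1.0, -1.0
                rows.append(r)
                rhs.append(histograms[b].log_p[k] - histograms[a].log_p[k])
                wts.append(1.0 / (histograms[a].se[k] ** 2 +
                                  histograms[b].se[k] ** 2 + 1e-12))
        anchor = np.zeros(nw)
        anchor[0] = 1.0
        rows.append(anchor)
        rhs.append(0.0)
        wts.append(1e6)
        a_mat = np.array(rows) * np.sqrt(np.array(wts))[:, None]
        b_vec = np.array(rhs) * np.sqrt(np.array(wts))
        c, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
        cov = np.linalg.pinv(a_mat.T @ a_mat)
        c_var = np.clip(np.diag(cov), 0.0, None)
    else:
        c_var = np.zeros(nw)

    # combine bins across windows; offset uncertainty enters in quadrature
    acc: dict[Hashable, list] = {}
    for w, h in enumerate(histograms):
        for k, lp in h.log_p.items():
            se_w = math.sqrt(h.se[k] ** 2 + c_var[w])
            acc.setdefault(k, []).append((lp + c[w], se_w, h.counts.get(k, 0)))
    log_p, se, ns = {}, {}, {}
    for k, items in acc.items():
        ws = np.array([1.0 / (s ** 2 + 1e-12) for _l, s, _n in items])
        ls = np.array([l for l, _s, _n in items])
        log_p[k] = float(np.dot(ws, ls) / ws.sum())
        se[k] = float(1.0 / math.sqrt(ws.sum()))
        ns[k] = sum(n for _l, _s, n in items)

    residuals = []
    for a, b, shared in overlaps:
        for k in shared:
            residuals.append((histograms[a].log_p[k] + c[a]) -
                             (histograms[b].log_p[k] + c[b]))
    residual = float(np.sqrt(np.mean(np.square(residuals)))) if residuals else 0.0

    if reference_bin not in log_p:
        raise ValueError(f"reference bin {reference_bin} was never sampled")

    # hop distance of each window from the one holding the reference bin:
    # sequential stitching drifts like a random walk, so the empirical
    # mismatch enters each bin's error scaled by sqrt(hops)
    ref_w = next(w for w in range(nw) if reference_bin in resolved[w])
    hops = {ref_w: 0}
    frontier = [ref_w]
    while frontier:
        nxt = []
        for a, b, _sh in overlaps:
            for u, v in ((a, b), (b, a)):
                if u in hops and v not in hops and u in frontier:
                    hops[v] = hops[u] + 1
                    nxt.append(v)
        frontier = nxt
    bin_hops: dict[Hashable, int] = {}
    for w, h in enumerate(histograms):
        for k in h.log_p:
            bin_hops[k] = min(bin_hops.get(k, 1 << 20), hops.get(w, 1))

    ref_lp, ref_se = log_p[reference_bin], se[reference_bin]
    bins = {k: -(lp - ref_lp) for k, lp in log_p.items()}
    # the observed cross-window mismatch is an empirical error floor: the
    # replica scatter alone understates slowly-relaxing systematic error
    se_out = {k: math.sqrt(se[k] ** 2 + ref_se ** 2
                           + (residual ** 2) * max(bin_hops.get(k, 1), 1))
              if k != reference_bin else 0.0 for k in se}
    return Landscape2D(bins, se_out, ns, reference_bin, residual)


# ---- temperature reweighting ----

def reweight_temperature(histogram: WindowHistogram, params: EnergyParams,
                         t_prime_C: float) -> WindowHistogram:
    """Single-histogram reweighting of a sampled window to a nearby temperature.

    Each sample is reweighted by exp[-dH (1/kT' - 1/kT)]; the entropic terms
    of the nearest-neighbor decomposition cancel.  The effective sample size
    is reported, with a low-ESS warning flag below ``MIN_ESS``.
    """
    t0 = histogram.temperature_C + 273.15
    t1 = t_prime_C + 273.15
    if abs(t_prime_C - histogram.temperature_C) > REWEIGHT_TRUST_C + 1e-9:
        raise ValueError(
            f"|T' - T| = {abs(t_prime_C - histogram.temperature_C):.1f} C exceeds "
            f"the reweighting trust range of {REWEIGHT_TRUST_C} C")
    dbeta = 1.0 / (R_KCAL * t1) - 1.0 / (R_KCAL * t0)
    lw = -histogram.samples_dH * dbeta
    lw -= lw.max() if len(lw) else 0.0
    w = np.exp(lw)
    ess = float(w.sum() ** 2 / np.square(w).sum()) if len(w) else 0.0
    log_p, se = _unbiased_logp(histogram.counts, histogram.samples_bin,
                               histogram.samples_logw, weights=w)
    out = WindowHistogram(histogram.window, dict(histogram.counts), log_p, se,
                          histogram.samples_bin, histogram.samples_dH,
                          histogram.samples_logw, histogram.acceptance_rate,
                          histogram.n_steps, histogram.seed, t_prime_C,
                          ess=ess, low_ess=ess < MIN_ESS)
    return out


def yield_from_histogram(histogram: WindowHistogram,
                         predicate: Callable[[tuple], bool]) -> tuple[float, float]:
    """Fraction of unbiased weight in predicate bins, with a block SE."""
    log_p = histogram.log_p
    if not log_p:
        return 0.0, 0.0
    ps = {k: math.exp(v) for k, v in log_p.items()}
    z = sum(ps.values())
    y = sum(p for k, p in ps.items() if predicate(k)) / z
    # block SE via per-block yields
    n = len(histogram.samples_bin)
    edges = np.linspace(0, n, N_BLOCKS + 1).astype(int)
    w_un = np.exp(-histogram.samples_logw)
    sel = np.array([predicate(tuple(b)) for b in histogram.samples_bin])
    vals = []
    for b0, b1 in zip(edges[:-1], edges[1:]):
        tot = w_un[b0:b1].sum()
        if tot > 0:
            vals.append(float(w_un[b0:b1][sel[b0:b1]].sum() / tot))
    se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) >= 2 else 1.0
    return y, se


# ---- headline operations ----

def single_strand_log_z(design: StrandPairDesign, params: EnergyParams,
                        n_steps: int = 40_000, seed: int = 0) -> tuple[float, float]:
    """ln of the single-strand configurational partition function.

    z = Z_ss / Z_unstructured = 1 / P(no intra pair); measured from an
    umbrella-biased single-strand run.  Returns (ln z, SE).
    """
    single = design if design.target is None else design.single("P")
    system = get_system(single)
    if system.n_pairs == 0:
        return 0.0, 0.0
    inits = _single_strand_inits(system, get_evaluator(system, params))
    h = None
    for attempt in range(3):
        scale = 2 ** attempt
        win = UmbrellaWindow(sum_range=(0, MAX_INTRA_BIAS),
                             bias_key=lambda k: k[0] + k[1])
        win.bias = learn_bias(single, params, win,
                              seed=seed + 17 + 5555 * attempt,
                              binning=bin_single_strand, flatten_axis=None,
                              f_schedule=(0.0,) * 4,
                              n_steps_per_stage=max(scale * n_steps // 8, 2000))
        reps = [mc_run(single, params, win, max(scale * n_steps // 2, 1),
                       seed + 211 * r + 5555 * attempt,
                       binning=bin_single_strand,
                       init_state_mask=inits[r % len(inits)])
                for r in range(2)]
        h = merge_replicas(reps)
        if (0, 0) in h.log_p:
            break
    if (0, 0) not in h.log_p:
        raise ValueError("unstructured state never sampled; cannot form ln z")
    p0 = math.exp(h.log_p[(0, 0)])
    z = sum(math.exp(v) for v in h.log_p.values())
    ln_z = math.log(z / p0)
    se = h.se.get((0, 0), 1.0)
    return ln_z, se


def intra_column_free_energies(design: StrandPairDesign, params: EnergyParams,
                               n_steps: int = 60_000, seed: int = 0) -> dict:
    """Free energies of the unbound (n_inter = 0) column by strand convolution.

    With no inter-strand pairs the two strands are independent, so the
    combined-intra-count distribution is the convolution of the two
    single-strand ensembles, each sampled with the (well-equilibrated)
    single-strand umbrella machinery.  Returns {n_intra: dG_kT relative to
    the fully unpaired bin}.
    """
    tables = []
    var = 0.0
    for sid in design.strand_ids:
        l2 = single_strand_landscape(design.single(sid), params,
                                     n_steps=n_steps, seed=seed + 31 * ord(sid))
        tot: dict[int, float] = {}
        for (o, st), g in l2.bins.items():
            tot[o + st] = tot.get(o + st, 0.0) + math.exp(-g)
        var += max((se for k, se in l2.se.items()
                    if k not in l2.censored), default=0.0) ** 2
        tables.append(tot)
    if len(tables) == 1:
        tables.append({0: 1.0})
    conv: dict[int, float] = {}
    for a, wa in tables[0].items():
        for b, wb in tables[1].items():
            conv[a + b] = conv.get(a + b, 0.0) + wa * wb
    z0 = conv[0]
    out = {y: -math.log(w / z0) for y, w in conv.items()}
    out["se"] = math.sqrt(var)
    return out


def duplex_dg0_bound_anchor(design: StrandPairDesign, params: EnergyParams,
                            ln_z_probe: tuple[float, float],
                            ln_z_target: tuple[float, float],
                            n_steps: int = 60_000, seed: int = 0,
                            x_floor: int = 15) -> tuple[float, float, float]:
    """Standard-state dG0 anchored at the exactly-known full-duplex energy.

    The bound partition function is dominated by states near the full
    duplex, whose free energy is a closed-form sum of stack and initiation
    terms; a short unbiased chain confined to n_inter >= ``x_floor``
    measures the full duplex's conditional occupancy p_full, giving
    Z_bound = e^{-G_full} / p_full without any umbrella ladder (partially
    bound states below the floor are tens of kBT above the duplex and
    contribute negligibly).  The unbound side is the product of the two
    single-strand partition functions.  dG0 = G_full + ln p_full
    + ln z_P + ln z_T.  Returns (dG0_kT, Keq, SE).
    """
    system = get_system(design)
    ev = get_evaluator(system, params)
    full = system.aligned_mask
    n = system.n_full_duplex
    g_full_std = ev.g_kt(full) - params.ln_box_states
    win = UmbrellaWindow(x_range=(x_floor, n))
    h = mc_run(design, params, win, n_steps, seed, init_state_mask=full)
    key = (n, 0)
    if key not in h.log_p:
        raise ValueError("full duplex never sampled in the bound basin")
    log_p_full = h.log_p[key] - math.log(
        sum(math.exp(v) for v in h.log_p.values()))
    se_pf = h.se.get(key, 0.5)
    dg0 = g_full_std + log_p_full + ln_z_probe[0] + ln_z_target[0]
    se = math.sqrt(se_pf ** 2 + ln_z_probe[1] ** 2 + ln_z_target[1] ** 2)
    return dg0, math.exp(-dg0), se


def duplex_dg0_factorized(design: StrandPairDesign, params: EnergyParams,
                          landscape_no_intra: Landscape2D,
                          ln_z_probe: tuple[float, float],
                          ln_z_target: tuple[float, float]) -> tuple[float, float, float]:
    """Standard-state dG0 via the single-strand factorization.

    With intra structure forbidden the duplex ladder gives Keq0; allowing
    intra structure multiplies the unbound partition function by the two
    single-strand factors z_P z_T while leaving the bound side (dominated
    by the full duplex, which has no free bases) essentially unchanged:
    dG0 = dG0_no_intra + ln z_P + ln z_T.  Returns (dG0_kT, Keq, SE).
    """
    dg0_f, _keq_f, se_f = duplex_dg0_keq(design, params,
                                         landscape=landscape_no_intra)
    dg0 = dg0_f + ln_z_probe[0] + ln_z_target[0]
    se = math.sqrt(se_f ** 2 + ln_z_probe[1] ** 2 + ln_z_target[1] ** 2)
    return dg0, math.exp(-dg0), se


def _intra_predicate(key: tuple[int, int]) -> bool:
    # single-strand binning keys are (n_other_intra, n_intended_stem)
    return key[0] + key[1] >= 1


def hairpin_yield_curve(design: StrandPairDesign, params: EnergyParams,
                        t_range_C: tuple[float, float, float] = (0.0, 100.0, 2.0),
                        n_steps: int = 150_000, seed: int = 0) -> MeltCurve:
    """Hairpin yield (states with >= 1 intra pair) versus temperature.

    Anchor simulations are spaced so that every scan temperature lies
    within the reweighting trust range of an anchor; the melting
    temperature is linearly interpolated at yield 0.5.
    """
    single = design if design.target is None else design.single("P")
    system = get_system(single)
    lo, hi, step = t_range_C
    ts = np.arange(lo, hi + 1e-9, step)
    if system.n_pairs == 0:
        return MeltCurve(ts, np.zeros_like(ts), np.zeros_like(ts), None)
    anchors = np.arange(lo + REWEIGHT_TRUST_C, hi + REWEIGHT_TRUST_C,
                        2 * REWEIGHT_TRUST_C)
    hists = {}
    for i, ta in enumerate(anchors):
        p_a = EnergyParams(temperature_C=float(ta),
                           box_volume_m3=params.box_volume_m3,
                           pseudoknot_penalty_kT=params.pseudoknot_penalty_kT)
        # stem formation/breaking is an activated event, so each anchor is
        # umbrella-biased on the total intra-pair count (a handful of bins,
        # on which the adaptive pre-pass converges quickly) and unbiased
        # afterwards; states beyond MAX_INTRA_BIAS simultaneous intra pairs
        # carry negligible weight and are excluded
        win = UmbrellaWindow(sum_range=(0, MAX_INTRA_BIAS),
                             bias_key=lambda k: k[0] + k[1])
        win.bias = learn_bias(single, p_a, win, seed=seed + 101 * i + 7,
                              binning=bin_single_strand, flatten_axis=None,
                              f_schedule=(0.0, 0.0, 0.0, 0.0),
                              n_steps_per_stage=max(n_steps // 8, 2000))
        inits = _single_strand_inits(system, get_evaluator(system, p_a))
        reps = [mc_run(single, p_a, win, max(n_steps // 2, 1),
                       seed + 101 * i + 211 * r, binning=bin_single_strand,
                       init_state_mask=inits[r % len(inits)])
                for r in range(2)]
        hists[float(ta)] = merge_replicas(reps)
    ys = np.empty_like(ts)
    ses = np.empty_like(ts)
    for i, t in enumerate(ts):
        ta = min(hists, key=lambda a: abs(a - t))
        h = reweight_temperature(hists[ta], params, float(t)) \
            if abs(ta - t) > 1e-9 else hists[ta]
        ys[i], ses[i] = yield_from_histogram(h, _intra_predicate)
    tm = _interp_tm(ts, ys)
    return MeltCurve(ts, ys, ses, tm)


def _single_strand_inits(system: PairSystem, ev) -> list[int]:
    """Decorrelated replica starts: the empty state and the best helix."""
    inits = [0]
    if system.run_moves:
        best = min(system.run_moves, key=ev.g_kt)
        inits.append(best)
    return inits


def _interp_tm(ts: np.ndarray, ys: np.ndarray) -> float | None:
    for i in range(len(ts) - 1):
        y0, y1 = ys[i], ys[i + 1]
        if (y0 - 0.5) * (y1 - 0.5) <= 0 and y0 != y1 and y0 >= 0.5:
            return float(ts[i] + (y0 - 0.5) / (y0 - y1) * (ts[i + 1] - ts[i]))
    return None


def single_strand_landscape(design: StrandPairDesign, params: EnergyParams,
                            n_steps: int = 200_000, seed: int = 0) -> Landscape2D:
    """Free-energy landscape over (other intra pairs, intended-stem pairs)."""
    single = design if design.target is None else design.single("P")
    system = get_system(single)
    if system.n_pairs == 0:
        return Landscape2D({(0, 0): 0.0}, {(0, 0): 0.0}, {(0, 0): n_steps}, (0, 0))
    window = UmbrellaWindow(sum_range=(0, MAX_INTRA_BIAS),
                            bias_key=lambda k: k[0] + k[1])
    window.bias = learn_bias(single, params, window, seed=seed + 7,
                             binning=bin_single_strand, flatten_axis=None,
                             f_schedule=(0.0, 0.0, 0.0, 0.0))
    inits = _single_strand_inits(system, get_evaluator(system, params))
    reps = [mc_run(single, params, window, max(n_steps // N_REPLICAS, 1),
                   seed + 331 * r, binning=bin_single_strand,
                   init_state_mask=inits[r % len(inits)])
            for r in range(N_REPLICAS)]
    return stitch_windows([merge_replicas(reps)], reference_bin=(0, 0))


def default_duplex_windows(n: int) -> list[tuple[int, int]]:
    """Overlapping n_inter window ranges covering 0..n.

    Small systems use nested windows anchored at zero, which keeps every
    window ergodic through the unbound state; longer duplexes use a
    staircase of overlapping restricted windows (the deep duplex well
    would otherwise span too large a free-energy range per window).
    """
    if n <= 12:
        return [(0, e) for e in [*range(2, n, 2), n]]
    wins = []
    for a in range(0, n - 1, 2):
        wins.append((a, min(a + 3, n)))
    if wins[-1][1] < n:
        wins.append((n - 3, n))
    return wins


def duplex_landscapes(design: StrandPairDesign, params: EnergyParams,
                      forbid_intra: bool = False,
                      windows: Sequence[tuple[int, int]] | None = None,
                      n_steps: int = 150_000, wl_steps: int = 20_000,
                      seed: int = 0,
                      allow_disconnected: bool = False,
                      max_intra: int | None = None) -> tuple[Landscape2D, Landscape2D]:
    """Umbrella-sampled 2D landscape over (n_inter, n_intra) and its 1D marginal.

    With ``forbid_intra`` the intra-pair moves are disabled, so the 2D
    landscape is supported on the n_intra = 0 row only (the hairpin-free
    constraint).  Windows tile the inter-strand base-pair axis.
    """
    system = get_system(design)
    if len(design.strand_ids) != 2:
        raise ValueError("duplex landscapes need a two-strand design")
    n = system.n_full_duplex
    if windows is None:
        windows = default_duplex_windows(n)
    hists = []
    guess = _duplex_guess_logw(params)
    nested = all(lo == 0 for lo, _hi in windows)
    sched = (1.0, 0.5, 0.2, 0.05, 0.0, 0.0) if nested else (0.0,) * 8
    if max_intra is None:
        max_intra = MAX_INTRA_DUPLEX
    prev_logw: dict = {}
    for wi, (lo, hi) in enumerate(windows):
        init = _duplex_init_mask(system, lo)
        win = UmbrellaWindow(x_range=(lo, hi), y_range=(0, max_intra))
        # warm start from the analytic zippering profile, overridden by the
        # previous window's learned weights on any bin both windows cover;
        # the guess is shifted onto the previous window's (normalized)
        # scale so the seam between learned and guessed bins is smooth
        shared = [k for k in prev_logw if lo <= k[0] <= hi]
        shift = (float(np.mean([prev_logw[k] - guess(k[0]) for k in shared]))
                 if shared else 0.0)
        start = {(x, y): prev_logw.get((x, y), guess(x) + shift)
                 for x in range(lo, hi + 1)
                 for y in range(max_intra + 1)}
        def run_window(attempt: int) -> list[WindowHistogram]:
            scale = 2 ** attempt
            # retries re-learn from the plain analytic profile: a poisoned
            # warm start would otherwise be inherited by every attempt
            start_a = start if attempt == 0 else {
                k: guess(k[0]) for k in start}
            win.bias = learn_bias(design, params, win,
                                  seed=seed + 13 * wi + 1 + 7777 * attempt,
                                  forbid_intra=forbid_intra,
                                  init_state_mask=init, f_schedule=sched,
                                  n_steps_per_stage=wl_steps * scale,
                                  initial_logw=start_a,
                                  bias_range=None if forbid_intra else 20.0)
            win._min_log_w = None
            return [mc_run(design, params, win,
                           max(scale * n_steps // N_REPLICAS, 1),
                           seed + 13 * wi + 101 * r + 7777 * attempt,
                           forbid_intra=forbid_intra,
                           init_state_mask=_duplex_init_mask(system, lo,
                                                             offset=3 * r))
                    for r in range(N_REPLICAS)]

        # a window must resolve the columns it shares with its neighbours;
        # if a run failed to traverse, retry with a fresh, longer pre-pass
        h = merge_replicas(run_window(0))
        for attempt in (1, 2):
            xs = {k[0] for k in h.log_p}
            col_counts: dict[int, int] = {}
            for k, cnt in h.counts.items():
                col_counts[k[0]] = col_counts.get(k[0], 0) + cnt
            # the first window must resolve the unbound column itself (it
            # anchors the whole landscape) and the last its top column (it
            # alone covers the duplex end, so bare presence is not enough:
            # a handful of late-arriving samples cannot weight the deep
            # states correctly); every window needs its overlaps
            lo_ok = (lo in xs) if wi == 0 else bool(xs & {lo, lo + 1})
            hi_ok = (col_counts.get(hi, 0) >= 1000) \
                if wi == len(windows) - 1 else bool(xs & {hi - 1, hi})
            if lo_ok and hi_ok:
                break
            h = merge_replicas(run_window(attempt))
        prev_logw = {k: math.log(v) for k, v in win.bias.items()}
        hists.append(h)
    if forbid_intra:
        l2 = stitch_windows(hists, reference_bin=(0, 0),
                            allow_disconnected=allow_disconnected)
        return l2, l2.marginal_x()
    # For hairpin-forming systems the fully unpaired bin (0, 0) can be a
    # rarely-visited corner of the unbound basin.  Stitch against the
    # best-sampled unbound bin, then re-anchor to (0, 0) through the exact
    # strand-independence of the n_inter = 0 column.
    col0 = [k for h in hists for k in h.log_p if k[0] == 0]
    if not col0:
        raise ValueError("no unbound (n_inter = 0) bin was sampled")
    counts0: dict = {}
    for h in hists:
        for k, c in h.counts.items():
            if k[0] == 0:
                counts0[k] = counts0.get(k, 0) + c
    anchor = intra_column_free_energies(design, params,
                                        n_steps=max(n_steps // 2, 20_000),
                                        seed=seed + 991)
    covered = {k: c for k, c in counts0.items() if k[1] in anchor}
    if not covered:
        raise ValueError(
            f"anchor table covers none of the sampled unbound bins {sorted(counts0)}")
    ref = max(covered, key=covered.get)
    l2 = stitch_windows(hists, reference_bin=ref,
                        allow_disconnected=allow_disconnected)
    shift = anchor[ref[1]]
    anchor_se = float(anchor.get("se", 0.05))
    bins = {k: g + shift for k, g in l2.bins.items()}
    bins.setdefault((0, 0), 0.0)
    # every bin inherits the anchor-shift uncertainty; the synthetic (0, 0)
    # reference is exact by construction
    se = {k: math.sqrt(v ** 2 + anchor_se ** 2) for k, v in l2.se.items()}
    se[(0, 0)] = 0.0 if (0, 0) not in l2.bins else se.get((0, 0), anchor_se)
    ns = dict(l2.n_samples)
    ns.setdefault((0, 0), 0)
    l2 = Landscape2D(bins, se, ns, (0, 0), l2.stitch_residual,
                     l2.censor_threshold)
    return l2, l2.marginal_x()


def _duplex_guess_logw(params: EnergyParams):
    """Crude analytic zippering profile used to warm-start window biases.

    G(x) ~ (initiation + box penalty) at the first inter pair, then one
    mean stack per additional pair; the adaptive pre-pass refines it.
    """
    gbar = float(np.mean([params.g_kt(*params.stack(st))
                          for st in ("AA", "AT", "TA", "CA", "GT", "CT",
                                     "GA", "CG", "GC", "GG")]))
    barrier = params.ln_box_states + params.g_kt(*params.duplex_init()) \
        + params.g_kt(*params.lonely_pair())

    def guess(x: int) -> float:
        if x == 0:
            return 0.0
        return barrier + (x - 1) * gbar

    return guess


def _duplex_init_mask(system: PairSystem, n_inter: int, offset: int = 0) -> int:
    """A contiguous block of aligned duplex pairs, used to seed a window.

    Different ``offset`` values place the block at different positions
    along the duplex, so independent replicas start from decorrelated
    configurations.
    """
    aligned = [k for k in range(system.n_pairs) if (system.aligned_mask >> k) & 1]
    if n_inter > len(aligned):
        raise ValueError(f"cannot seed a state with {n_inter} aligned pairs")
    if n_inter == 0:
        return 0
    start = offset % (len(aligned) - n_inter + 1)
    mask = 0
    for k in aligned[start:start + n_inter]:
        mask |= 1 << k
    return mask


def duplex_dg0_keq(design: StrandPairDesign, params: EnergyParams,
                   landscape: Landscape2D | None = None,
                   **kwargs) -> tuple[float, float, float]:
    """Standard-state duplex formation free energy and equilibrium constant.

    Keq/c0^-1 = (P_bound / P_unbound) N_A V c0 from the in-box landscape;
    dG0 = -ln Keq in kBT.  Returns (dG0_kT, Keq, SE of dG0).
    """
    if landscape is None:
        landscape, _ = duplex_landscapes(design, params, **kwargs)
    wb = wu = 0.0
    vb = vu = 0.0
    for (x, _y), g in landscape.bins.items():
        w = math.exp(-g)
        s = landscape.se.get((x, _y), 0.0)
        if x >= 1:
            wb += w
            vb += (w * s) ** 2
        else:
            wu += w
            vu += (w * s) ** 2
    if wb == 0 or wu == 0:
        raise ValueError("bound or unbound bins unresolved; cannot form Keq")
    ratio = wb / wu
    keq = ratio * math.exp(params.ln_box_states)
    dg0 = -math.log(keq)
    se = math.sqrt(vb / wb ** 2 + vu / wu ** 2)
    return dg0, keq, se
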