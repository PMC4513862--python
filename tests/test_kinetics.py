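"""Kinetic Monte Carlo dynamics and forward flux sampling."""

import math

import numpy as np
import pytest

from hpk.energy import EnergyParams
from hpk.kinetics import (FFSResult, PathwayRecord, RateModel,
                          attachment_statistics, check_detailed_balance,
                          classify_pathways, ffs_hybridization, ffs_melting,
                          gillespie_run, infer_relative_rates, propensities)
from hpk.oracle import enumerate_states, exact_mfpt
from hpk.pairing import PairingState
from hpk.sampling import get_evaluator, get_system
from hpk.sequences import NucleotideSequence, pair_design


class TestPropensities:
    def test_downhill_move_has_rate_k0(self, toy_plain, params):
        sys_ = get_system(toy_plain)
        aligned = [k for k in range(sys_.n_pairs)
                   if (sys_.aligned_mask >> k) & 1]
        mask = (1 << aligned[0]) | (1 << aligned[1])
        rm = RateModel(k0=1.5)
        moves = propensities(mask, toy_plain, params, rm)
        ev = get_evaluator(sys_, params)
        for mv, rate in moves:
            bit = 1 << mv.pair_index
            new = mask | bit if mv.add else mask ^ bit
            if ev.g_kt(new) < ev.g_kt(mask):
                assert rate == rm.k0

    def test_detailed_balance_edge_exact_on_random_states(self, space_hairpin,
                                                          toy_hairpin, params):
        rng = np.random.default_rng(2)
        rm = RateModel()
        idx = rng.choice(space_hairpin.size, size=50, replace=False)
        for i in idx:
            worst = check_detailed_balance(toy_hairpin, params, rm,
                                           space_hairpin.masks[i])
            assert worst < 1e-12

    def test_total_rate_matches_oracle_adjacency(self, space_plain, toy_plain,
                                                 params):
        rm = RateModel()
        # independent recomputation: sum edge rates out of each state from
        # the enumerated adjacency
        out_rate = {i: 0.0 for i in range(space_plain.size)}
        for i, j in space_plain.adjacency:
            out_rate[i] += rm.edge_rate(space_plain.g_kt[i], space_plain.g_kt[j])
            out_rate[j] += rm.edge_rate(space_plain.g_kt[j], space_plain.g_kt[i])
        rng = np.random.default_rng(4)
        for i in rng.choice(space_plain.size, size=40, replace=False):
            moves = propensities(space_plain.masks[i], toy_plain, params, rm)
            assert sum(r for _m, r in moves) == pytest.approx(out_rate[int(i)])


class TestGillespie:
    def test_two_state_waiting_time(self, params):
        d = pair_design(NucleotideSequence("g", "G"))
        rm = RateModel()
        sys_ = get_system(d)
        ev = get_evaluator(sys_, params)
        k_off = rm.edge_rate(ev.g_kt(1), ev.g_kt(0))  # bound -> unbound
        times = []
        for rep in range(3000):
            traj = gillespie_run(d, params, rm, 1,
                                 stop=lambda c: c[0] == 0, seed=rep)
            times.append(traj.times[-1])
        mean = float(np.mean(times))
        se = float(np.std(times, ddof=1) / math.sqrt(len(times)))
        assert abs(mean - 1.0 / k_off) <= 3 * se

    def test_occupancies_match_boltzmann(self, toy_hairpin, params,
                                         space_hairpin):
        # time-average occupancy of intra-structure classes in long
        # unconstrained runs; stem formation is an activated event under
        # the physical single-pair dynamics, so several long runs are
        # averaged
        rm = RateModel()
        sys_ = space_hairpin.system
        occ: dict[int, float] = {}
        for seed in (77, 78, 79):
            traj = gillespie_run(toy_hairpin, params, rm, 0, seed=seed,
                                 max_steps=1_200_000)
            for t0, t1, mask in zip(traj.times, traj.times[1:], traj.masks):
                if not mask & sys_.inter_mask:  # unbound states only
                    n_intra = (mask & sys_.intra_mask).bit_count()
                    occ[n_intra] = occ.get(n_intra, 0.0) + (t1 - t0)
        z = sum(occ.values())
        pi = space_hairpin.boltzmann()
        ref: dict[int, float] = {}
        for p, c, mask in zip(pi, space_hairpin.counts, space_hairpin.masks):
            if c[0] == 0:
                ref[int(c[1])] = ref.get(int(c[1]), 0.0) + float(p)
        zr = sum(ref.values())
        for k in ref:
            if ref[k] / zr > 0.02:
                assert occ.get(k, 0.0) / z == pytest.approx(ref[k] / zr,
                                                            abs=0.08)

    def test_same_seed_same_trajectory(self, toy_plain, params):
        rm = RateModel()
        a = gillespie_run(toy_plain, params, rm, 0, seed=5, max_steps=5000)
        b = gillespie_run(toy_plain, params, rm, 0, seed=5, max_steps=5000)
        assert a.times == b.times and a.masks == b.masks

    def test_max_time_truncation_flagged(self, toy_plain, params):
        traj = gillespie_run(toy_plain, params, RateModel(), 0,
                             max_time=0.5, seed=1, max_steps=100000)
        assert traj.truncated
        assert traj.times[-1] == 0.5


class TestFFS:
    def test_degenerate_single_interface(self, toy_plain, params):
        res = ffs_hybridization(toy_plain, params, RateModel(),
                                interfaces=[1], n_trials=50, seed=3,
                                n_basin_samples=200)
        assert res.P_plus == 1.0
        assert res.k_plus == res.flux

    def test_k_plus_agrees_with_exact_mfpt(self, toy_hairpin, params,
                                           space_hairpin):
        rm = RateModel()
        n_full = space_hairpin.system.n_full_duplex
        res = ffs_hybridization(toy_hairpin, params, rm,
                                interfaces=[1, 2, 4, n_full],
                                n_trials=600, seed=8, n_basin_samples=600)
        mfpt = exact_mfpt(space_hairpin, rm, lambda c: c[0] == 0,
                          lambda c: c[0] >= n_full)
        k_exact = 1.0 / mfpt
        assert abs(res.k_plus - k_exact) <= 3 * max(res.k_plus_se,
                                                    0.1 * k_exact)

    def test_k_equals_r_times_p_bitexact(self, toy_plain, params):
        res = ffs_hybridization(toy_plain, params, RateModel(),
                                interfaces=[1, 2, 4, 8], n_trials=150,
                                seed=4, n_basin_samples=200)
        prod = res.flux
        for p in res.p:
            prod *= float(p)
        assert res.k_plus == prod
        assert res.k_plus == res.r_plus * res.P_plus or \
            res.k_plus == pytest.approx(res.r_plus * res.P_plus, rel=1e-12)

    def test_se_shrinks_with_trials(self, toy_plain, params):
        small = ffs_hybridization(toy_plain, params, RateModel(),
                                  interfaces=[1, 2, 4, 8], n_trials=100,
                                  seed=6, n_basin_samples=300)
        big = ffs_hybridization(toy_plain, params, RateModel(),
                                interfaces=[1, 2, 4, 8], n_trials=400,
                                seed=6, n_basin_samples=300)
        rel_small = small.P_plus_se / small.P_plus
        rel_big = big.P_plus_se / big.P_plus
        assert rel_big < rel_small
        assert rel_small / rel_big == pytest.approx(2.0, rel=0.5)


class TestThermokineticClosure:
    def test_eq1_closure_on_toy(self, toy_hairpin, params, space_hairpin):
        # forward k+, reverse k-, and the exact bound/unbound ratio satisfy
        # in-box detailed balance within combined errors
        rm = RateModel()
        n_full = space_hairpin.system.n_full_duplex
        fwd = ffs_hybridization(toy_hairpin, params, rm,
                                interfaces=[1, 2, 4, n_full],
                                n_trials=600, seed=15, n_basin_samples=600)
        rev = ffs_melting(toy_hairpin, params, rm, n_trials=600, seed=16,
                          n_basin_samples=600)
        pi = space_hairpin.boltzmann()
        bound = sum(p for p, c in zip(pi, space_hairpin.counts) if c[0] >= 1)
        k_ratio = fwd.k_plus / rev.k_plus
        expect = bound / (1.0 - bound)
        rel_se = math.hypot(fwd.k_plus_se / fwd.k_plus,
                            rev.k_plus_se / rev.k_plus)
        assert abs(math.log(k_ratio / expect)) <= 3 * max(rel_se, 0.1)


class TestRelativeRates:
    def test_reference_row_is_ones(self, toy_plain, params):
        res = ffs_hybridization(toy_plain, params, RateModel(),
                                interfaces=[1, 2, 8], n_trials=80, seed=5,
                                n_basin_samples=150)
        table = infer_relative_rates({"a": res, "b": res}, "a")
        assert table.loc["a", "k_plus_ratio"] == 1.0
        assert table.loc["b", "k_plus_ratio"] == pytest.approx(1.0)

    def test_hand_computed_ratios(self):
        def fake(k, r):
            res = FFSResult(interfaces=[1, 2], flux=r, flux_se=0.0,
                            p=np.array([k / r]), p_se=np.array([0.0]),
                            k_plus=k, k_plus_se=0.0, trials=[10],
                            successes=[5], seed=0)
            return res
        table = infer_relative_rates({"ref": fake(2.0, 4.0),
                                      "x": fake(0.5, 2.0)}, "ref")
        assert table.loc["x", "k_plus_ratio"] == pytest.approx(4.0)
        assert table.loc["x", "r_plus_ratio"] == pytest.approx(2.0)
        assert table.loc["x", "P_plus_ratio"] == pytest.approx(2.0)

    def test_missing_reference_raises(self):
        with pytest.raises(KeyError):
            infer_relative_rates({}, "nope")


class TestAttachmentStatistics:
    def test_frequencies_sum_to_one(self, toy_plain, params):
        res = ffs_hybridization(toy_plain, params, RateModel(),
                                interfaces=[1, 2, 8], n_trials=200, seed=7,
                                n_basin_samples=300)
        stats = attachment_statistics(res)
        assert sum(stats.frequency.values()) == pytest.approx(1.0)
        assert all(0.0 <= v <= 1.0 for v in stats.success.values())

    def test_first_contact_matches_exact_flux_weights(self, toy_hairpin,
                                                      params, space_hairpin):
        # exact flux-weighted first-contact distribution over P-strand sites
        rm = RateModel()
        sys_ = space_hairpin.system
        ev = get_evaluator(sys_, params)
        pi = space_hairpin.boltzmann()
        exact = {}
        total = 0.0
        for p, mask, c in zip(pi, space_hairpin.masks, space_hairpin.counts):
            if c[0] != 0:
                continue
            occ = sys_.occupancy(mask)
            for k in range(sys_.n_pairs):
                bit = 1 << k
                if not (sys_.inter_mask >> k) & 1 or occ & sys_.base_masks[k]:
                    continue
                rate = p * rm.edge_rate(ev.g_kt(mask), ev.g_kt(mask | bit))
                bp = sys_.pairs[k]
                site = bp.endpoint_a[1] if bp.endpoint_a[0] == "P" \
                    else bp.endpoint_b[1]
                aligned = bool((sys_.aligned_mask >> k) & 1)
                exact[(site, aligned)] = exact.get((site, aligned), 0.0) + rate
                total += rate
        exact = {k: v / total for k, v in exact.items()}
        res = ffs_hybridization(toy_hairpin, params, rm, interfaces=[1, 8],
                                n_trials=4000, seed=9, n_basin_samples=1500)
        stats = attachment_statistics(res)
        for key, p_exact in exact.items():
            se = math.sqrt(p_exact * (1 - p_exact) / 4000)
            assert abs(stats.frequency.get(key, 0.0) - p_exact) <= \
                4 * max(se, 0.005)


class TestClassifyPathways:
    def test_hand_built_records(self):
        recs = [
            PathwayRecord(0, True, (True, True), (True, True), False, False,
                          (1, 4), 0.0),
            PathwayRecord(1, False, (False, False), (False, False), False,
                          True, (2, 0), 0.0),
        ]
        out = classify_pathways(recs)
        assert out["both_stems_intact"] == 0.5
        assert out["no_stem_intact"] == 0.5
        assert out["kissing"] == 0.5

    def test_no_intra_trajectory_is_no_hairpin_class(self):
        recs = [PathwayRecord(3, True, (False, False), (False, False),
                              False, False, (5, 0), 1.0)]
        out = classify_pathways(recs)
        assert out["no_stem_intact"] == 1.0

    def test_toy_intact_fraction_matches_flux_weights(self, toy_hairpin,
                                                      params, space_hairpin):
        # fraction of first contacts with the probe stem fully formed,
        # computed exactly from the flux-weighted basin ensemble
        rm = RateModel()
        sys_ = space_hairpin.system
        ev = get_evaluator(sys_, params)
        pi = space_hairpin.boltzmann()
        stem_bits = sys_.stem_mask & sys_.intra_mask
        p_bits = 0
        for k in range(sys_.n_pairs):
            if (stem_bits >> k) & 1 and sys_.pairs[k].endpoint_a[0] == "P":
                p_bits |= 1 << k
        num = den = 0.0
        for p, mask, c in zip(pi, space_hairpin.masks, space_hairpin.counts):
            if c[0] != 0:
                continue
            occ = sys_.occupancy(mask)
            k_out = sum(rm.edge_rate(ev.g_kt(mask), ev.g_kt(mask | (1 << k)))
                        for k in range(sys_.n_pairs)
                        if (sys_.inter_mask >> k) & 1
                        and not occ & sys_.base_masks[k])
            den += p * k_out
            if (mask & p_bits) == p_bits:
                num += p * k_out
        expect = num / den
        res = ffs_hybridization(toy_hairpin, params, rm, interfaces=[1, 8],
                                n_trials=3000, seed=19, n_basin_samples=1500)
        frac = sum(1 for c in res.bank0 if c.stems_full[0]) / len(res.bank0)
        se = math.sqrt(expect * (1 - expect) / len(res.bank0))
        assert abs(frac - expect) <= 4 * max(se, 0.01)
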