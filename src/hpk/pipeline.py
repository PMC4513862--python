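"""End-to-end pipeline: thermodynamics, kinetics, and the relative-rate table.

For each requested probe/target system the pipeline computes hairpin melting
curves, constrained and unconstrained duplex landscapes, the standard-state
duplex formation free energy, FFS hybridization rates with their
first-contact/success decomposition, attachment-site statistics and pathway
classifications; it then assembles the relative-rate table (including the
detailed-balance-inferred melting rates) against a declared reference
system.  All stage seeds derive deterministically from the master seed, and
every artifact is written with a manifest so a rerun with the same
configuration reproduces the numbers exactly.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from hpk.energy import EnergyParams
from hpk.kinetics import (RateModel, attachment_statistics, classify_pathways,
                          ffs_hybridization)
from hpk.rates import build_rate_table, naive_slowdown
from hpk.sampling import (duplex_dg0_bound_anchor, duplex_landscapes,
                          get_system, hairpin_yield_curve,
                          single_strand_log_z)
from hpk.sequences import (NucleotideSequence, StrandPairDesign,
                           complementary_runs, pair_design, table1_fixtures)

__all__ = ["infer_intended_stem", "build_system_design", "default_config",
           "parse_config", "run_pipeline"]


def infer_intended_stem(seq: NucleotideSequence, params: EnergyParams,
                        min_len: int = 3) -> tuple[tuple[int, int], ...]:
    """The lowest-free-energy single hairpin helix of a strand.

    The designed stems of the experimental strands are not annotated in
    machine-readable form, so they are recovered as the most stable
    contiguous self-complementary run (stacks + loop closure) under the
    energy model; runs shorter than ``min_len`` or with dG >= 0 at the
    working temperature yield an empty stem (unstructured strand).
    """
    best = None
    best_g = 0.0
    for i, j, length in complementary_runs(seq.bases, min_len=min_len):
        dh = ds = 0.0
        for k in range(length - 1):
            h, s = params.stack(seq.bases[i + k] + seq.bases[i + k + 1])
            dh += h
            ds += s
        loop = (j - length + 1) - (i + length - 1) - 1
        h, s = params.hairpin_loop(loop)
        dh += h
        ds += s
        if length >= 3:
            h, s = params.hairpin_closing()
            dh += h
            ds += s
        g = params.g_kt(dh, ds)
        if g < best_g:
            best_g = g
            best = tuple((i + k, j - k) for k in range(length))
    return best if best is not None else ()


def build_system_design(label: str, params: EnergyParams) -> StrandPairDesign:
    """A Table-1 duplex system ('P0T0', 'P3T3', 'P4T4') with inferred stems."""
    fx = table1_fixtures()
    p_label = label[:2]
    probe = fx[p_label]
    target = fx["T" + p_label[1]]
    design = pair_design(
        probe,
        intended_stem_p=infer_intended_stem(probe, params),
        intended_stem_t=infer_intended_stem(target, params),
        label=label,
    )
    # keep the fixture's own target name
    return StrandPairDesign(design.probe, target, design.intended_stem,
                            design.design_params)


def default_config() -> dict:
    """Desk-scale budgets for the three experimental systems at 20 C."""
    return {
        "systems": ["P0T0", "P3T3", "P4T4"],
        "reference": "P0T0",
        "temperature_C": 20.0,
        "box_volume_m3": 3.96e-23,
        "pseudoknot_penalty_kT": 2.0,
        "seed": 1,
        "yield_steps": 60_000,
        "landscape_steps": 60_000,
        "wl_steps": 12_000,
        "ffs_trials": 300,
        "basin_samples": 500,
        "ffs_max_steps": 20_000,
        "lnz_steps": 250_000,
        "melt_range_C": [0.0, 100.0, 2.0],
    }


def parse_config(path) -> dict:
    """Plain-text key = value configuration (JSON literals on the right)."""
    config = default_config()
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line {ln}: expected 'key = value'")
        key, _, val = line.partition("=")
        key = key.strip()
        val = val.strip()
        try:
            config[key] = json.loads(val)
        except json.JSONDecodeError:
            config[key] = val
    return config


def _curve_dict(curve) -> dict:
    return {
        "temperatures_C": [float(x) for x in curve.temperatures_C],
        "yields": [float(x) for x in curve.yields],
        "se": [float(x) for x in curve.se],
        "tm_C": None if curve.tm_C is None else float(curve.tm_C),
    }


def _landscape_rows(l2) -> list[dict]:
    rows = []
    for key in sorted(l2.bins):
        rows.append({
            "bin": list(key),
            "dG_kT": float(l2.bins[key]),
            "se": float(l2.se.get(key, 0.0)),
            "n_samples": int(l2.n_samples.get(key, 0)),
            "censored": key in l2.censored,
        })
    return rows


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run the full analysis for every configured system; return the bundle.

    On a stage failure the bundle carries a failure manifest for that
    system instead of its results, and the remaining systems still run.
    """
    if not isinstance(config, dict):
        config = parse_config(config)
    cfg = default_config()
    cfg.update(config)
    params = EnergyParams.from_config(cfg)
    seed = int(cfg["seed"])
    bundle: dict = {"config": cfg, "systems": {}, "failures": {}}

    per_system: dict[str, dict] = {}
    for si, label in enumerate(cfg["systems"]):
        sys_seed = seed + 1000 * si
        try:
            per_system[label] = _run_system(label, params, cfg, sys_seed)
        except Exception as exc:  # partial bundle with failure manifest
            bundle["failures"][label] = {"stage": "system", "error": repr(exc)}
    bundle["systems"] = per_system

    ref = cfg["reference"]
    if ref in per_system and not bundle["failures"]:
        k_plus = {s: (d["ffs"]["k_plus"], d["ffs"]["k_plus_se"]) for s, d in per_system.items()}
        r_plus = {s: (d["ffs"]["r_plus"], d["ffs"]["r_plus_se"]) for s, d in per_system.items()}
        p_plus = {s: (d["ffs"]["P_plus"], d["ffs"]["P_plus_se"]) for s, d in per_system.items()}
        dg0 = {s: (d["dG0_kT"], d["dG0_se"]) for s, d in per_system.items()}
        rt = build_rate_table(k_plus, dg0, ref, r_plus=r_plus, P_plus=p_plus)
        bundle["rate_table"] = json.loads(rt.table.to_json(orient="index"))
        bundle["naive_slowdown"] = {
            s: naive_slowdown(dg0[s][0] - dg0[ref][0]) for s in per_system}
        bundle["_rate_table_obj"] = rt

    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _run_system(label: str, params: EnergyParams, cfg: dict, seed: int) -> dict:
    design = build_system_design(label, params)
    out: dict = {"label": label,
                 "probe": design.probe.bases,
                 "target": design.target.bases,
                 "intended_stem": {k: [list(p) for p in v]
                                   for k, v in design.intended_stem.items()}}

    curve = hairpin_yield_curve(design, params, tuple(cfg["melt_range_C"]),
                                n_steps=int(cfg["yield_steps"]), seed=seed + 1)
    out["melt_curve"] = _curve_dict(curve)
    t20 = int(np.argmin(np.abs(curve.temperatures_C - params.temperature_C)))
    out["yield_at_working_T"] = float(curve.yields[t20])

    l2, l1 = duplex_landscapes(design, params, forbid_intra=False,
                               n_steps=int(cfg["landscape_steps"]),
                               wl_steps=int(cfg["wl_steps"]), seed=seed + 2,
                               allow_disconnected=True)
    l2f, l1f = duplex_landscapes(design, params, forbid_intra=True,
                                 n_steps=int(cfg["landscape_steps"]),
                                 wl_steps=int(cfg["wl_steps"]), seed=seed + 3,
                                 allow_disconnected=True)
    # auxiliary low-intra landscape: the same dynamics window-restricted to
    # n_intra <= 2 resolves the n_intra = 0 row even for hairpin-dominated
    # systems, giving a dual-route consistency check against the
    # move-disabled (forbid_intra) ladder
    l2c, _l1c = duplex_landscapes(design, params, forbid_intra=False,
                                  n_steps=int(cfg["landscape_steps"]),
                                  wl_steps=int(cfg["wl_steps"]), seed=seed + 5,
                                  allow_disconnected=True, max_intra=2)
    out["landscape_2d"] = _landscape_rows(l2)
    out["landscape_2d_low_intra"] = _landscape_rows(l2c)
    out["landscape_1d"] = _landscape_rows(l1)
    out["landscape_1d_no_hairpins"] = _landscape_rows(l1f)
    # dG0 via the bound-anchor factorization: the full duplex's free energy
    # is a closed-form sum, a short bound-basin run supplies its conditional
    # occupancy, and the single-strand partition functions supply the
    # stabilization of the unbound state
    ln_z_p = single_strand_log_z(design.single("P"), params,
                                 n_steps=int(cfg["lnz_steps"]), seed=seed + 7)
    ln_z_t = single_strand_log_z(design.single("T"), params,
                                 n_steps=int(cfg["lnz_steps"]), seed=seed + 8)
    dg0, keq, dg0_se = duplex_dg0_bound_anchor(design, params, ln_z_p, ln_z_t,
                                               n_steps=int(cfg["yield_steps"]),
                                               seed=seed + 9)
    out["ln_z_probe"] = ln_z_p[0]
    out["ln_z_target"] = ln_z_t[0]
    out["dG0_kT"] = dg0
    out["Keq"] = keq
    out["dG0_se"] = dg0_se

    ffs = ffs_hybridization(design, params, RateModel(),
                            n_trials=int(cfg["ffs_trials"]), seed=seed + 4,
                            n_basin_samples=int(cfg["basin_samples"]),
                            max_steps_per_trial=int(cfg["ffs_max_steps"]))
    out["ffs"] = {
        "interfaces": ffs.interfaces,
        "flux": ffs.flux, "flux_se": ffs.flux_se,
        "p": [float(x) for x in ffs.p],
        "p_se": [float(x) for x in ffs.p_se],
        "k_plus": ffs.k_plus, "k_plus_se": ffs.k_plus_se,
        "r_plus": ffs.r_plus, "r_plus_se": ffs.r_plus_se,
        "P_plus": ffs.P_plus, "P_plus_se": ffs.P_plus_se,
        "trials": ffs.trials, "successes": ffs.successes,
        "truncated_trials": ffs.truncated_trials,
        "seed": ffs.seed,
    }
    att = attachment_statistics(ffs)
    out["attachment"] = {
        "frequency": {f"{s}:{'aligned' if a else 'mis'}": v
                      for (s, a), v in sorted(att.frequency.items())},
        "success": {f"{s}:{'aligned' if a else 'mis'}": v
                    for (s, a), v in sorted(att.success.items())},
        "interface_success": att.interface_success,
        "dissociation_from_6bp": att.dissociation_from_6bp,
    }
    # first-contact classification is over the unbiased flux-weighted
    # association ensemble; the success-conditioned variant is estimated
    # from resolved trajectories only and inherits the censoring bias of
    # the trial step cap (see the methods note)
    out["pathways"] = classify_pathways(ffs.first_contact_records)
    out["pathways_successful"] = classify_pathways(ffs.records)
    out["_ffs_obj"] = ffs
    out["_landscapes"] = (l2, l1, l1f)
    return out


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    clean = _strip_private(bundle)
    (outdir / "report.json").write_text(
        json.dumps(clean, indent=1, sort_keys=True) + "\n")
    if "_rate_table_obj" in bundle:
        bundle["_rate_table_obj"].to_csv(outdir / "rate_table.csv")
    for label, d in bundle["systems"].items():
        _write_csv(outdir / f"landscape_{label}.csv",
                   ["n_inter", "n_intra", "dG_kT", "se", "n_samples", "censored"],
                   [[r["bin"][0], r["bin"][1], r["dG_kT"], r["se"],
                     r["n_samples"], int(r["censored"])]
                    for r in d["landscape_2d"]])
        mc = d["melt_curve"]
        _write_csv(outdir / f"melt_{label}.csv", ["T_C", "yield", "se"],
                   list(zip(mc["temperatures_C"], mc["yields"], mc["se"])))
    manifest = {"config": bundle["config"],
                "systems": sorted(bundle["systems"]),
                "failures": bundle["failures"]}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")


def _strip_private(obj):
    if isinstance(obj, dict):
        return {k: _strip_private(v) for k, v in obj.items()
                if not str(k).startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_strip_private(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_csv(path: Path, header: list[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(f"{x:.8g}" if isinstance(x, float) else str(x)
                              for x in row) + "\n")
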