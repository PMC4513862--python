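"""Detailed-balance inference of melting rates and Table-style rate reporting.

For a second-order duplex formation reaction the hybridization and melting
rate constants are tied to the standard free-energy change of duplex
formation by k+/k- = exp(-dG0/kBT)/c0 with c0 = 1 M.  Knowing k+ (from FFS)
and dG0 (from the equilibrium landscapes), k- follows without simulating
melting.  In relative form, against a hairpin-free reference system,

    k-/k-0 = (Keq0/Keq) / (k0+/k+),

which is how the headline table is assembled.  The naive-slowdown factor
exp(ddG0/kBT) is the hybridization slowdown one would expect if the entire
change in duplex stability loaded onto k+ alone; the measured k+ ratios fall
far short of it, which is the package's central observation: hairpins act
mostly by accelerating melting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RateTable", "infer_k_minus", "naive_slowdown", "build_rate_table"]

CLOSURE_TOL = 1e-9


def infer_k_minus(k_plus: float, dg0_kt: float, temperature_C: float | None = None,
                  k_plus_se: float = 0.0, dg0_se: float = 0.0) -> tuple[float, float]:
    """Melting rate from k+ and dG0 (kBT, 1 M standard state): k- = k+ c0 e^{dG0}.

    Returns (k_minus, standard error).  The temperature argument is
    accepted for interface symmetry; dG0 must already be expressed in kBT
    at that temperature.
    """
    if k_plus <= 0:
        raise ValueError("k_plus must be positive")
    k_minus = k_plus * math.exp(dg0_kt)  # c0 = 1 in the rate units used here
    rel = math.sqrt((k_plus_se / k_plus) ** 2 + dg0_se ** 2)
    return k_minus, k_minus * rel


def naive_slowdown(ddg_kt: float | None = None, dg_a_kt: float | None = None,
                   dg_b_kt: float | None = None) -> float:
    """Expected k+ slowdown if all single-strand stabilization loaded onto k+.

    Accepts either the difference ddG directly or two per-system
    stabilization values (ddG = dg_b - dg_a).
    """
    if ddg_kt is None:
        if dg_a_kt is None or dg_b_kt is None:
            raise ValueError("provide ddg_kt or both per-system values")
        ddg_kt = dg_b_kt - dg_a_kt
    return math.exp(ddg_kt)


@dataclass
class RateTable:
    """Per-system relative rates against a reference system.

    Columns: k0+/k+ ratio, r0+/r+ and P0+/P+ decomposition ratios,
    Keq0/Keq, inferred k-/k-0, dG0 (kBT), with standard errors.  The
    closure identity (k-/k-0) / [(k0+/k+)^-1 (Keq0/Keq)] = 1 holds by
    construction on every row and is verified at build time.
    """

    table: pd.DataFrame
    reference: str

    def row(self, system: str) -> pd.Series:
        return self.table.loc[system]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, float_format="%.6g")

    def printed(self, sig: int = 3) -> pd.DataFrame:
        """Ratios rounded to ``sig`` significant figures for display."""
        def r3(x):
            if isinstance(x, float) and np.isfinite(x) and x != 0:
                return float(f"{x:.{sig}g}")
            return x
        return self.table.map(r3)


def build_rate_table(k_plus: dict[str, tuple[float, float]],
                     dg0: dict[str, tuple[float, float]],
                     reference: str,
                     r_plus: dict[str, tuple[float, float]] | None = None,
                     P_plus: dict[str, tuple[float, float]] | None = None) -> RateTable:
    """Assemble the relative-rate table from per-system k+ and dG0.

    ``k_plus``/``dg0`` map system label to (value, SE); optional
    ``r_plus``/``P_plus`` add the first-contact/success decomposition.
    All systems must share the temperature and standard state under which
    dG0 was computed.  Raises if the closure identity fails (an internal
    inconsistency) or the reference is missing.
    """
    if reference not in k_plus or reference not in dg0:
        raise KeyError(f"reference system {reference!r} missing")
    k0, k0_se = k_plus[reference]
    g0, g0_se = dg0[reference]
    rows = {}
    for name in k_plus:
        k, k_se = k_plus[name]
        g, g_se = dg0[name]
        k_ratio = k0 / k
        k_ratio_se = k_ratio * math.sqrt((k_se / k) ** 2 + (k0_se / k0) ** 2)
        keq_ratio = math.exp(g - g0)  # Keq0/Keq = e^{dG0_sys - dG0_ref}
        keq_ratio_se = keq_ratio * math.sqrt(g_se ** 2 + g0_se ** 2)
        km_ratio = keq_ratio / k_ratio
        km_ratio_se = km_ratio * math.sqrt(
            (keq_ratio_se / keq_ratio) ** 2 + (k_ratio_se / k_ratio) ** 2)
        closure = km_ratio / (keq_ratio / k_ratio)
        if abs(closure - 1.0) > CLOSURE_TOL:
            raise RuntimeError(f"closure identity violated for {name}: {closure}")
        row = {
            "k_plus_ratio": k_ratio, "k_plus_ratio_se": k_ratio_se,
            "keq_ratio": keq_ratio, "keq_ratio_se": keq_ratio_se,
            "k_minus_ratio": km_ratio, "k_minus_ratio_se": km_ratio_se,
            "dG0_kT": g, "dG0_se": g_se,
        }
        if r_plus is not None and name in r_plus:
            r, r_se = r_plus[name]
            r0, r0_se = r_plus[reference]
            v = r0 / r
            row["r_plus_ratio"] = v
            row["r_plus_ratio_se"] = v * math.sqrt((r_se / r) ** 2 + (r0_se / r0) ** 2)
        if P_plus is not None and name in P_plus:
            p, p_se = P_plus[name]
            p0, p0_se = P_plus[reference]
            v = p0 / p
            row["P_plus_ratio"] = v
            row["P_plus_ratio_se"] = v * math.sqrt((p_se / p) ** 2 + (p0_se / p0) ** 2)
        rows[name] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "system"
    for col in ("k_plus_ratio", "keq_ratio", "k_minus_ratio",
                "r_plus_ratio", "P_plus_ratio"):
        if col in df.columns:
            df.loc[reference, col] = 1.0
            se_col = col + "_se"
            if se_col in df.columns:
                df.loc[reference, se_col] = 0.0
    return RateTable(df, reference)
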