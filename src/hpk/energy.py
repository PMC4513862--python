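"""Nearest-neighbor free-energy parameters for the pairing-state model.

The model assigns each pairing state a free energy built from dinucleotide
stacking DH/DS terms (loaded from a versioned CSV shipped with the package),
purely entropic loop-closure penalties (hairpin, bulge, interior, multibranch),
a bimolecular duplex-initiation term, a configurable pseudoknot penalty per
crossing base pair, and a translational standard-state correction relating the
simulation box volume to the 1 M reference concentration.  Every term is kept
as a (DH, DS) pair so that free energies can be recomputed exactly at any
temperature and so that single-histogram temperature reweighting (which only
needs per-state enthalpies) is well defined.

This is a secondary-structure-level stand-in for a 3D nucleotide model: its
absolute numbers are model-dependent, but it reproduces the qualitative
thermodynamics (hairpin stability orderings, duplex melting) that drive the
kinetic phenomena studied here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

__all__ = ["EnergyParams", "R_KCAL", "AVOGADRO", "STANDARD_CONC"]

# gas constant, kcal / (mol K)
R_KCAL = 1.98720425864083e-3
AVOGADRO = 6.02214076e23
# standard concentration c0 = 1 mol/L
STANDARD_CONC = 1.0
_T37 = 310.15

# Loop-closure free energies at 37 C (kcal/mol), treated as purely entropic;
# values beyond the table extrapolate as dG(30) + 1.75 R T37 ln(l/30).
_HAIRPIN_G37 = {3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.2, 8: 4.3, 9: 4.5,
                10: 4.4, 12: 4.7, 14: 4.9, 16: 5.0, 18: 5.2, 20: 5.3,
                25: 5.6, 30: 5.9}
_BULGE_G37 = {1: 4.0, 2: 2.9, 3: 3.1, 4: 3.2, 5: 3.3, 6: 3.5, 7: 3.7,
              8: 3.8, 9: 3.9, 10: 3.9, 12: 4.3, 14: 4.4, 16: 4.5, 18: 4.6,
              20: 4.7, 25: 4.9, 30: 5.0}
_INTERIOR_G37 = {2: 3.2, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4, 7: 4.6, 8: 4.8,
                 9: 4.9, 10: 4.9, 12: 5.2, 14: 5.4, 16: 5.6, 18: 5.8,
                 20: 5.9, 25: 6.3, 30: 6.6}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _load_stack_table() -> dict[str, tuple[float, float]]:
    text = resources.files("hpk.data").joinpath("nn_stacks.csv").read_text()
    table: dict[str, tuple[float, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("step"):
            continue
        step, dh, ds = line.split(",")
        dh_f, ds_f = float(dh), float(ds) / 1000.0  # cal -> kcal per K
        table[step] = (dh_f, ds_f)
        rc = _COMPLEMENT[step[1]] + _COMPLEMENT[step[0]]
        table.setdefault(rc, (dh_f, ds_f))
    return table


def _loop_g37(table: dict[int, float], length: int) -> float:
    if length <= 0:
        raise ValueError("loop length must be positive")
    keys = sorted(table)
    if length in table:
        return table[length]
    if length > keys[-1]:
        return table[keys[-1]] + 1.75 * R_KCAL * _T37 * math.log(length / keys[-1])
    if length < keys[0]:
        return table[keys[0]]
    lo = max(k for k in keys if k < length)
    hi = min(k for k in keys if k > length)
    w = (length - lo) / (hi - lo)
    return (1 - w) * table[lo] + w * table[hi]


@dataclass
class EnergyParams:
    """Temperature, volume, and energy-function parameters.

    Every term-returning method yields a ``(dH, dS)`` pair in kcal/mol and
    kcal/(mol K); ``g_kt`` converts such a pair to kBT at the configured
    temperature.  ``pseudoknot_penalty_kT`` is charged once per crossing
    pair-pair combination in a state's topology.
    """

    temperature_C: float = 20.0
    box_volume_m3: float = 3.96e-23
    pseudoknot_penalty_kT: float = 2.0
    duplex_init_dH: float = 0.2
    duplex_init_dS: float = -5.7e-3
    # loop-closing terminal stack: the first loop bases stack onto the closing
    # pair of a hairpin helix; omitting it badly underestimates the stability
    # of short designed stems.  Applied once per hairpin loop whose closing
    # pair terminates a stacked helix.
    hairpin_closing_dH: float = -5.0
    hairpin_closing_dS: float = -12.0e-3
    # an isolated (unstacked) base pair: NN tables carry all base-pair
    # enthalpy in stacks, so a bare pair-subset model would make lonely
    # pairs athermal and their population temperature-independent, which is
    # unphysical (melting curves must vanish at high T).  The term below
    # costs a lonely pair ~+1.4 kcal/mol at 37 C, in the spirit of
    # secondary-structure models that penalize or forbid lonely pairs.
    lonely_pair_dH: float = -6.0
    lonely_pair_dS: float = -24.0e-3
    stack_table: dict = field(default_factory=_load_stack_table, repr=False)

    @classmethod
    def from_config(cls, config: dict) -> "EnergyParams":
        kw = {k: config[k] for k in
              ("temperature_C", "box_volume_m3", "pseudoknot_penalty_kT")
              if k in config}
        return cls(**kw)

    @property
    def temperature_K(self) -> float:
        return self.temperature_C + 273.15

    @property
    def rt(self) -> float:
        """kBT in kcal/mol at the configured temperature."""
        return R_KCAL * self.temperature_K

    @property
    def ln_box_states(self) -> float:
        """ln(N_A V c0): ratio of the box volume to the 1 M standard-state volume.

        A bound (inter-paired) state in the box is penalized by this many kBT
        relative to its 1 M standard-state free energy, which makes in-box
        Boltzmann occupancies, Keq, and association/dissociation propensities
        mutually consistent.
        """
        v_liters = self.box_volume_m3 * 1e3
        return math.log(AVOGADRO * v_liters * STANDARD_CONC)

    def g_kt(self, dh: float, ds: float, temperature_K: float | None = None) -> float:
        t = self.temperature_K if temperature_K is None else temperature_K
        return (dh - t * ds) / (R_KCAL * t)

    # ---- individual terms, each as (dH, dS) ----

    def stack(self, step: str) -> tuple[float, float]:
        """Stacking term for a 5'->3' dinucleotide step paired to its complement."""
        return self.stack_table[step]

    def duplex_init(self) -> tuple[float, float]:
        return (self.duplex_init_dH, self.duplex_init_dS)

    def hairpin_loop(self, length: int) -> tuple[float, float]:
        g37 = _loop_g37(_HAIRPIN_G37, max(length, 3))
        return (0.0, -g37 / _T37)

    def hairpin_closing(self) -> tuple[float, float]:
        return (self.hairpin_closing_dH, self.hairpin_closing_dS)

    def lonely_pair(self) -> tuple[float, float]:
        return (self.lonely_pair_dH, self.lonely_pair_dS)

    def bulge(self, length: int) -> tuple[float, float]:
        # length 0 can arise when a gap is fully occupied by crossing arcs;
        # charge it as the smallest tabulated bulge
        g37 = _loop_g37(_BULGE_G37, max(length, 1))
        return (0.0, -g37 / _T37)

    def interior_loop(self, l1: int, l2: int) -> tuple[float, float]:
        if l1 == 0 or l2 == 0:
            return self.bulge(l1 + l2)
        g37 = _loop_g37(_INTERIOR_G37, l1 + l2)
        return (0.0, -g37 / _T37)

    def multiloop(self, branches: int, unpaired: int) -> tuple[float, float]:
        # generic affine multibranch-closure penalty
        g37 = 2.5 + 0.4 * branches + 0.05 * unpaired
        return (0.0, -g37 / _T37)

    def pseudoknot(self, n_crossings: int) -> tuple[float, float]:
        # a fixed kBT cost per crossing pair-pair combination (athermal)
        return (0.0, -R_KCAL * self.pseudoknot_penalty_kT * n_crossings)

    def box_translation(self) -> tuple[float, float]:
        # applied to bound states: + kBT ln(N_A V c0)
        return (0.0, -R_KCAL * self.ln_box_states)
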