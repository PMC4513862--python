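"""Pairing states over one or two strands and their free energies.

A configuration of the system is a set of Watson-Crick base pairs, each pair
either intra-strand (closing a hairpin, minimum 3-nt loop) or inter-strand.
Each base participates in at most one pair.  For energy evaluation the
strands are concatenated 5'->3' (probe first, then target) with a nick
between them; pairs become arcs over this line.  A maximal non-crossing
subset of arcs defines a nested secondary structure whose faces (stacks,
hairpin loops, interior loops/bulges, multibranch loops, and the open
exterior) carry the nearest-neighbor energy terms; arcs that cross the
nested skeleton (pseudoknots, kissing interactions) keep their stacking
energy and are charged a fixed penalty per crossing pair-pair combination.

Free energies are reported in kBT relative to the empty (fully unpaired)
state.  States with at least one inter-strand pair additionally carry the
bimolecular initiation term and the box-to-standard-state translational
correction, so that in-box Boltzmann occupancies and equilibrium constants
are mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from hpk.energy import EnergyParams
from hpk.sequences import MIN_LOOP, StrandPairDesign, _COMPLEMENT

__all__ = [
    "BasePair",
    "PairingState",
    "StateValidationError",
    "StateDiagnostics",
    "FaceDecomposition",
    "PairSystem",
    "StateEnergy",
    "feasible_pairs",
    "validate_state",
    "loop_decomposition",
    "state_free_energy",
]


class StateValidationError(ValueError):
    """A pairing state violates a structural constraint; names the pair."""


def _canon(a: tuple[str, int], b: tuple[str, int]) -> tuple[tuple[str, int], tuple[str, int]]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class BasePair:
    """One Watson-Crick pair between two base endpoints (strand id, 0-based index)."""

    endpoint_a: tuple[str, int]
    endpoint_b: tuple[str, int]

    def __post_init__(self) -> None:
        a, b = _canon(self.endpoint_a, self.endpoint_b)
        object.__setattr__(self, "endpoint_a", a)
        object.__setattr__(self, "endpoint_b", b)
        if a == b:
            raise StateValidationError(f"pair {a}-{b}: endpoints must be distinct")

    @property
    def is_intra(self) -> bool:
        return self.endpoint_a[0] == self.endpoint_b[0]

    @property
    def is_inter(self) -> bool:
        return not self.is_intra


@dataclass(frozen=True)
class PairingState:
    """A set of base pairs; the empty frozenset is the reference (unpaired) state."""

    pairs: frozenset = frozenset()

    @classmethod
    def from_pairs(cls, pairs: Iterable[BasePair]) -> "PairingState":
        return cls(frozenset(pairs))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class StateDiagnostics:
    n_inter: int
    n_intra: int
    n_intended_stem: int
    n_other_intra: int
    pseudoknotted: bool
    n_crossings: int


@dataclass
class FaceDecomposition:
    """Faces of a pairing state's nested skeleton plus its crossing arcs.

    ``helices`` are the maximal stacked segments (each pair belongs to exactly
    one); ``stacks`` lists the dinucleotide steps inside them.  Loop faces
    partition the unpaired bases; faces open at a nick or a strand end are
    exterior and carry no penalty.
    """

    helices: list = field(default_factory=list)          # list[list[(i, j)]]
    stacks: list = field(default_factory=list)           # list[str] dinucleotide steps
    hairpin_loops: list = field(default_factory=list)    # list[(closing pair, length, closed_by_helix)]
    interior_loops: list = field(default_factory=list)   # list[(outer, inner, l1, l2)]
    multiloops: list = field(default_factory=list)       # list[(closing pair, branches, unpaired)]
    exterior_unpaired: int = 0
    crossing_pairs: list = field(default_factory=list)   # arcs excluded from the skeleton
    n_crossings: int = 0                                 # crossing pair-pair combinations
    has_inter: bool = False


class PairSystem:
    """Precomputed geometry of a design: feasible pairs, masks, linearization.

    States are represented internally as integer bitmasks over the feasible
    pair list, which makes occupancy checks, order-parameter counters, and
    energy caching O(1) bit operations.
    """

    def __init__(self, design: StrandPairDesign):
        self.design = design
        self.strand_ids = design.strand_ids
        self.seqs = {sid: design.strand(sid).bases for sid in self.strand_ids}
        self.offsets = {}
        off = 0
        linear = []
        for sid in self.strand_ids:
            self.offsets[sid] = off
            linear.append(self.seqs[sid])
            off += len(self.seqs[sid])
        self.n_bases = off
        self.linear_bases = "".join(linear)
        # nick positions: a boundary sits between linear index b-1 and b
        self.nicks = frozenset(
            self.offsets[sid] for sid in self.strand_ids[1:]
        )
        self.n_probe = len(self.seqs["P"])

        stem_set = set()
        for sid in self.strand_ids:
            for i, j in design.intended_stem.get(sid, ()):
                a, b = sorted((i, j))
                stem_set.add((self.offsets[sid] + a, self.offsets[sid] + b))

        pairs: list[BasePair] = []
        self.linear_pairs: list[tuple[int, int]] = []
        for sa in self.strand_ids:
            for sb in self.strand_ids:
                if sb < sa:
                    continue
                ba, bb = self.seqs[sa], self.seqs[sb]
                for i in range(len(ba)):
                    j0 = i + MIN_LOOP + 1 if sa == sb else 0
                    for j in range(j0, len(bb)):
                        if _COMPLEMENT[ba[i]] == bb[j]:
                            pairs.append(BasePair((sa, i), (sb, j)))
                            self.linear_pairs.append(
                                tuple(sorted((self.offsets[sa] + i, self.offsets[sb] + j)))
                            )
        self.pairs = pairs
        self.n_pairs = len(pairs)
        self.index = {bp: k for k, bp in enumerate(pairs)}

        self.base_masks = []
        self.inter_mask = 0
        self.intra_mask = 0
        self.stem_mask = 0
        for k, (bp, (li, lj)) in enumerate(zip(pairs, self.linear_pairs)):
            self.base_masks.append((1 << li) | (1 << lj))
            bit = 1 << k
            if bp.is_inter:
                self.inter_mask |= bit
            else:
                self.intra_mask |= bit
            if (li, lj) in stem_set:
                self.stem_mask |= bit
        self.full_mask = (1 << self.n_pairs) - 1

        # helix-toggle moves for equilibrium sampling: each maximal
        # intra-strand complementary run of >= 2 pairs, as a pair-index mask
        from hpk.sequences import complementary_runs
        self.run_moves: list[int] = []
        self.run_base_masks: list[int] = []
        for sid in self.strand_ids:
            for i, j, length in complementary_runs(self.seqs[sid], min_len=2):
                rmask = 0
                for k in range(length):
                    idx = self.index.get(BasePair((sid, i + k), (sid, j - k)))
                    if idx is None:
                        rmask = 0
                        break
                    rmask |= 1 << idx
                if rmask:
                    self.run_moves.append(rmask)
                    bmask = 0
                    for k in _bits(rmask):
                        bmask |= self.base_masks[k]
                    self.run_base_masks.append(bmask)
        # number of aligned duplex pairs in the full duplex (i_P + i_T = N - 1)
        self.n_full_duplex = 0
        if len(self.strand_ids) == 2:
            n = self.n_probe
            self.aligned_mask = 0
            for k, bp in enumerate(pairs):
                if bp.is_inter and bp.endpoint_a[1] + bp.endpoint_b[1] == n - 1:
                    self.aligned_mask |= 1 << k
                    self.n_full_duplex += 1
        else:
            self.aligned_mask = 0

    # ---- state representations ----

    def state_to_mask(self, state: PairingState | Iterable[BasePair]) -> int:
        pairs = state.pairs if isinstance(state, PairingState) else state
        mask = 0
        for bp in pairs:
            k = self.index.get(bp)
            if k is None:
                raise StateValidationError(f"pair {bp} is not feasible for this design")
            mask |= 1 << k
        return mask

    def mask_to_state(self, mask: int) -> PairingState:
        return PairingState(frozenset(self.pairs[k] for k in _bits(mask)))

    def mask_is_valid(self, mask: int) -> bool:
        occ = 0
        for k in _bits(mask):
            bm = self.base_masks[k]
            if occ & bm:
                return False
            occ |= bm
        return True

    def occupancy(self, mask: int) -> int:
        occ = 0
        for k in _bits(mask):
            occ |= self.base_masks[k]
        return occ

    def counts(self, mask: int) -> tuple[int, int, int, int]:
        """(n_inter, n_intra, n_intended_stem, n_other_intra) for a state mask."""
        n_inter = (mask & self.inter_mask).bit_count()
        n_intra = (mask & self.intra_mask).bit_count()
        n_stem = (mask & self.stem_mask).bit_count()
        return n_inter, n_intra, n_stem, n_intra - n_stem

    def evaluator(self, params: EnergyParams) -> "StateEnergy":
        return StateEnergy(self, params)


def _bits(mask: int):
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def _crossing(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (i, j), (k, l) = p, q
    return (i < k < j < l) or (k < i < l < j)


def decompose_linear(linear_pairs: Sequence[tuple[int, int]], n_bases: int,
                     nicks: frozenset[int], has_inter: bool) -> FaceDecomposition:
    """Face decomposition of a set of arcs over the concatenated strand line."""
    fd = FaceDecomposition(has_inter=has_inter)
    arcs = sorted(linear_pairs)
    occupied = set()
    for i, j in arcs:
        occupied.add(i)
        occupied.add(j)

    # crossing count over all arcs; greedy maximal non-crossing skeleton
    kept: list[tuple[int, int]] = []
    for m, p in enumerate(arcs):
        for q in arcs[m + 1:]:
            if _crossing(p, q):
                fd.n_crossings += 1
        if any(_crossing(p, q) for q in kept):
            fd.crossing_pairs.append(p)
        else:
            kept.append(p)

    # helices: maximal runs of stacked arcs (over ALL arcs, crossing included)
    arc_set = set(arcs)
    for i, j in arcs:
        inner = (i + 1, j - 1)
        outer_present = (i - 1, j + 1) in arc_set and i - 1 >= 0 and \
            (i not in nicks) and (j + 1 not in nicks)
        if outer_present:
            continue  # not the start of a helix
        helix = [(i, j)]
        a, b = i, j
        while (a + 1, b - 1) in arc_set and (a + 1 not in nicks) and (b not in nicks):
            helix.append((a + 1, b - 1))
            a, b = a + 1, b - 1
        fd.helices.append(helix)

    # de-duplicate: an arc may appear in one helix only; rebuild greedily
    seen: set[tuple[int, int]] = set()
    helices = []
    for h in fd.helices:
        h2 = [p for p in h if p not in seen]
        if h2:
            helices.append(h2)
            seen.update(h2)
    fd.helices = helices
    for h in fd.helices:
        for (i, j), (a, b) in zip(h, h[1:]):
            fd.stacks.append((i, a))  # step from linear position i to i+1

    # nesting forest over the kept arcs
    children: dict[tuple[int, int] | None, list] = {None: []}
    stack: list[tuple[int, int]] = []
    for p in kept:
        while stack and stack[-1][1] < p[0]:
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append(p)
        children.setdefault(p, [])
        stack.append(p)

    def face_gaps(lo: int, hi: int, kids: list) -> tuple[int, bool]:
        """Unoccupied-base count and nick-presence over [lo, hi] minus child spans."""
        segs = []
        pos = lo
        for ci, cj in kids:
            segs.append((pos, ci - 1))
            pos = cj + 1
        segs.append((pos, hi))
        unpaired = sum(
            1 for a, b in segs for x in range(a, b + 1) if x not in occupied
        )
        # a nick between linear positions nk-1 and nk lies in this face's open
        # region iff some segment (a, b) satisfies a <= nk <= b + 1
        nick_here = any(a <= nk <= b + 1 for a, b in segs for nk in nicks)
        return unpaired, nick_here

    for p in kept:
        i, j = p
        kids = children[p]
        unpaired, nick_here = face_gaps(i + 1, j - 1, kids)
        if nick_here:
            continue  # face opens at the nick: exterior-like, no penalty
        if len(kids) == 0:
            # the loop-closing terminal stack needs a well-formed helix end:
            # it is granted only when the closing pair terminates a helix of
            # at least three pairs
            closed_by_helix = (
                (i - 1, j + 1) in arc_set and (i - 2, j + 2) in arc_set
                and i - 2 >= 0
                and i not in nicks and (j + 1) not in nicks
                and (i - 1) not in nicks and (j + 2) not in nicks)
            fd.hairpin_loops.append((p, unpaired, closed_by_helix))
        elif len(kids) == 1:
            ci, cj = kids[0]
            l1 = sum(1 for b in range(i + 1, ci) if b not in occupied)
            l2 = sum(1 for b in range(cj + 1, j) if b not in occupied)
            if l1 == 0 and l2 == 0 and ci == i + 1 and cj == j - 1:
                pass  # stack face; energy carried by the helix terms
            else:
                fd.interior_loops.append((p, kids[0], l1, l2))
        else:
            fd.multiloops.append((p, len(kids) + 1, unpaired))

    ext, _ = face_gaps(0, n_bases - 1, children[None])
    fd.exterior_unpaired = ext
    return fd


class StateEnergy:
    """Cached (dH, dS) and free-energy evaluation for states of one system."""

    CACHE_LIMIT = 4_000_000

    def __init__(self, system: PairSystem, params: EnergyParams):
        self.system = system
        self.params = params
        self._cache: dict[int, tuple[float, float]] = {}

    def dHdS(self, mask: int) -> tuple[float, float]:
        hit = self._cache.get(mask)
        if hit is not None:
            return hit
        sys_, par = self.system, self.params
        lp = [sys_.linear_pairs[k] for k in _bits(mask)]
        has_inter = bool(mask & sys_.inter_mask)
        fd = decompose_linear(lp, sys_.n_bases, sys_.nicks, has_inter)
        dh = ds = 0.0
        bases = sys_.linear_bases
        for (i, _a) in fd.stacks:
            h, s = par.stack(bases[i] + bases[i + 1])
            dh += h
            ds += s
        for helix in fd.helices:
            if len(helix) == 1:
                h, s = par.lonely_pair()
                dh += h
                ds += s
        for _p, length, closed_by_helix in fd.hairpin_loops:
            h, s = par.hairpin_loop(length)
            dh += h
            ds += s
            if closed_by_helix:
                h, s = par.hairpin_closing()
                dh += h
                ds += s
        for _p, _c, l1, l2 in fd.interior_loops:
            h, s = par.interior_loop(l1, l2)
            dh += h
            ds += s
        for _p, branches, unpaired in fd.multiloops:
            h, s = par.multiloop(branches, unpaired)
            dh += h
            ds += s
        if fd.crossing_pairs:
            # charged per crossing pair (arc excluded from the nested
            # skeleton), not per crossing combination: a kissing helix of
            # h pairs then costs h penalties, growing linearly with size
            h, s = par.pseudoknot(len(fd.crossing_pairs))
            dh += h
            ds += s
        if has_inter:
            h, s = par.duplex_init()
            dh += h
            ds += s
            h, s = par.box_translation()
            dh += h
            ds += s
        if len(self._cache) >= self.CACHE_LIMIT:
            self._cache.clear()
        self._cache[mask] = (dh, ds)
        return (dh, ds)

    def g_kt(self, mask: int, temperature_K: float | None = None) -> float:
        dh, ds = self.dHdS(mask)
        return self.params.g_kt(dh, ds, temperature_K)


# ---- public, spec-level operations ----

def feasible_pairs(design: StrandPairDesign) -> list[BasePair]:
    """Every Watson-Crick pairing of two bases allowed by the move set."""
    return list(PairSystem(design).pairs)


def validate_state(state: PairingState, design: StrandPairDesign) -> StateDiagnostics:
    """Check structural constraints and classify the state's topology.

    Raises :class:`StateValidationError` naming the offending pair on a
    violation; otherwise returns counters and the nested/pseudoknotted flag.
    """
    sys_ = PairSystem(design)
    occ = 0
    mask = 0
    for bp in state.pairs:
        (sa, ia), (sb, ib) = bp.endpoint_a, bp.endpoint_b
        for sid, pos in (bp.endpoint_a, bp.endpoint_b):
            if sid not in sys_.seqs:
                raise StateValidationError(f"pair {bp}: unknown strand {sid!r}")
            if not 0 <= pos < len(sys_.seqs[sid]):
                raise StateValidationError(f"pair {bp}: index {pos} out of range")
        if _COMPLEMENT[sys_.seqs[sa][ia]] != sys_.seqs[sb][ib]:
            raise StateValidationError(f"pair {bp}: bases are not Watson-Crick complementary")
        if sa == sb and abs(ia - ib) < MIN_LOOP + 1:
            raise StateValidationError(f"pair {bp}: hairpin loop shorter than {MIN_LOOP} nt")
        k = sys_.index[bp]
        bm = sys_.base_masks[k]
        if occ & bm:
            raise StateValidationError(f"pair {bp}: a base participates in more than one pair")
        occ |= bm
        mask |= 1 << k
    lp = [sys_.linear_pairs[k] for k in _bits(mask)]
    fd = decompose_linear(lp, sys_.n_bases, sys_.nicks, bool(mask & sys_.inter_mask))
    n_inter, n_intra, n_stem, n_other = sys_.counts(mask)
    return StateDiagnostics(n_inter, n_intra, n_stem, n_other,
                            pseudoknotted=fd.n_crossings > 0,
                            n_crossings=fd.n_crossings)


def loop_decomposition(state: PairingState, design: StrandPairDesign) -> FaceDecomposition:
    """Faces (helices/stacks, hairpin, interior/bulge, multibranch, exterior)."""
    sys_ = PairSystem(design)
    mask = sys_.state_to_mask(state)
    lp = [sys_.linear_pairs[k] for k in _bits(mask)]
    return decompose_linear(lp, sys_.n_bases, sys_.nicks, bool(mask & sys_.inter_mask))


def state_free_energy(state: PairingState, design: StrandPairDesign,
                      params: EnergyParams) -> float:
    """Free energy of a state in kBT relative to the empty state (exactly 0)."""
    validate_state(state, design)
    sys_ = PairSystem(design)
    return sys_.evaluator(params).g_kt(sys_.state_to_mask(state))
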