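"""Sequence ingestion, experimental strand fixtures, and synthetic strand designs.

All sequences are stored 5'->3' over the alphabet {A, C, G, T}.  The six
experimental 25-mers (probe strands P0/P3/P4 and their complementary targets
T0/T3/T4) are shipped as fixtures; P0/T0 were designed with negligible
secondary structure while P3/T3 and P4/T4 carry stable 3- and 4-base-pair
hairpins in the single-stranded state.  The generator functions produce
strand pairs with designed hairpin stems of configurable geometry, and tiny
"toy" pairs whose complete pairing state space can be enumerated exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio import SeqIO

__all__ = [
    "NucleotideSequence",
    "StrandPairDesign",
    "AlphabetError",
    "FastaParseError",
    "DesignFailure",
    "read_fasta",
    "reverse_complement",
    "table1_fixtures",
    "generate_designed_pair",
    "generate_toy_system",
    "complementary_runs",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_ALPHABET = frozenset("ACGT")

# Minimum number of unpaired nucleotides a hairpin loop must contain; an
# intra-strand pair (i, j) is only feasible when |i - j| >= MIN_LOOP + 1.
MIN_LOOP = 3


class AlphabetError(ValueError):
    """A sequence contains a symbol outside {A, C, G, T}."""


class FastaParseError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


class DesignFailure(RuntimeError):
    """Sequence design geometry infeasible or rejection-sampling budget exhausted."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence, stored 5'->3'."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise AlphabetError(f"sequence {self.name!r} is empty")
        bad = set(self.bases) - _ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence {self.name!r} contains non-ACGT symbol(s): {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def __getitem__(self, i: int) -> str:
        return self.bases[i]


def reverse_complement(seq: NucleotideSequence | str) -> NucleotideSequence:
    """Antiparallel Watson-Crick complement, returned 5'->3'.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    if isinstance(seq, str):
        seq = NucleotideSequence("seq", seq.upper())
    rc = "".join(_COMPLEMENT[b] for b in reversed(seq.bases))
    return NucleotideSequence(f"rc({seq.name})", rc)


def _is_complement(a: str, b: str) -> bool:
    return _COMPLEMENT[a] == b


def read_fasta(path) -> list[NucleotideSequence]:
    """Read a multi-record FASTA file into a list of sequences.

    Bases are uppercased; orientation is taken as written (5'->3').
    Malformed lines raise :class:`FastaParseError` naming the line;
    non-ACGT symbols raise :class:`AlphabetError`.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    seen_header = False
    for ln, line in enumerate(lines, start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith(">"):
            seen_header = True
            continue
        if not seen_header:
            raise FastaParseError(f"line {ln}: sequence data before any '>' header")
        bad = set(s.upper()) - _ALPHABET
        if bad:
            raise AlphabetError(f"line {ln}: non-ACGT symbol(s) {sorted(bad)}")
    records = list(SeqIO.parse(path, "fasta"))
    return [NucleotideSequence(r.id, str(r.seq).upper()) for r in records]


# Experimental strands, as printed 3'->5' in the source table; reversed into
# the package's 5'->3' convention on access.  Pn and Tn are complementary.
_TABLE1_3TO5 = {
    "P0": "GAGACTTGCCATCGTAGAACTGTTG",
    "P3": "TGACGATCATGTCTGCGTGACTAGA",
    "P4": "ACACGATCATGTCTGCGTGACTAGA",
    "T0": "CAACAGTTCTACGATGGCAAGTCTC",
    "T3": "TCTAGTCACGCAGACATGATCGTCA",
    "T4": "TCTAGTCACGCAGACATGATCGTGT",
}


def table1_fixtures() -> dict[str, NucleotideSequence]:
    """The six experimental 25-mers, keyed P0/P3/P4/T0/T3/T4, stored 5'->3'."""
    return {
        name: NucleotideSequence(name, s[::-1]) for name, s in _TABLE1_3TO5.items()
    }


def complementary_runs(bases: str, min_len: int = 2) -> list[tuple[int, int, int]]:
    """Maximal feasible intra-strand helical runs within one strand.

    Returns (i, j, length) triples: pairs (i, j), (i+1, j-1), ...,
    (i+length-1, j-length+1) are all Watson-Crick complementary and each
    satisfies the minimum-loop separation.  Used both to locate designed
    stems and to screen generated sequences for unintended structure.
    """
    n = len(bases)
    runs = []
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            # only report maximal runs: skip if extendable outward
            if i > 0 and j < n - 1 and _is_complement(bases[i - 1], bases[j + 1]):
                continue
            length = 0
            a, b = i, j
            while a < b and b - a >= MIN_LOOP + 1 and _is_complement(bases[a], bases[b]):
                length += 1
                a += 1
                b -= 1
            if length >= min_len:
                runs.append((i, j, length))
    return runs


@dataclass(frozen=True)
class StrandPairDesign:
    """A probe/target pair with optional designed hairpin stems.

    ``intended_stem`` maps strand id ("P" or "T") to a tuple of intra-strand
    (i, j) index pairs (0-based from the 5' end) that form the designed
    self-complementary stem; empty tuples for unstructured strands.
    """

    probe: NucleotideSequence
    target: NucleotideSequence | None
    intended_stem: dict = field(default_factory=dict)
    design_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.target is not None:
            rc = reverse_complement(self.probe)
            if self.target.bases != rc.bases:
                raise ValueError("target must be the reverse complement of probe")
        for sid, stem in self.intended_stem.items():
            bases = self.strand(sid).bases
            for i, j in stem:
                if not _is_complement(bases[i], bases[j]):
                    raise ValueError(f"intended stem pair ({i},{j}) on {sid} not complementary")
                if abs(j - i) < MIN_LOOP + 1:
                    raise ValueError(f"intended stem pair ({i},{j}) on {sid} violates loop minimum")

    @property
    def strand_ids(self) -> tuple[str, ...]:
        return ("P",) if self.target is None else ("P", "T")

    def strand(self, sid: str) -> NucleotideSequence:
        if sid == "P":
            return self.probe
        if sid == "T" and self.target is not None:
            return self.target
        raise KeyError(sid)

    def single(self, sid: str = "P") -> "StrandPairDesign":
        """The one-strand system for strand ``sid`` (keeps its intended stem)."""
        seq = self.strand(sid)
        stem = {"P": tuple(self.intended_stem.get(sid, ()))}
        return StrandPairDesign(
            NucleotideSequence("P", seq.bases), None, stem,
            dict(self.design_params, parent_strand=sid),
        )

    def to_json(self) -> str:
        d = {
            "probe": {"name": self.probe.name, "bases": self.probe.bases},
            "target": None if self.target is None else {
                "name": self.target.name, "bases": self.target.bases},
            "intended_stem": {k: [list(p) for p in v] for k, v in self.intended_stem.items()},
            "design_params": self.design_params,
        }
        return json.dumps(d, indent=1, sort_keys=True)

    @staticmethod
    def from_json(s: str) -> "StrandPairDesign":
        d = json.loads(s)
        tgt = d["target"]
        return StrandPairDesign(
            NucleotideSequence(d["probe"]["name"], d["probe"]["bases"]),
            None if tgt is None else NucleotideSequence(tgt["name"], tgt["bases"]),
            {k: tuple(tuple(p) for p in v) for k, v in d["intended_stem"].items()},
            d.get("design_params", {}),
        )


def pair_design(probe: NucleotideSequence, name: str = "",
                intended_stem_p: Iterable[tuple[int, int]] = (),
                intended_stem_t: Iterable[tuple[int, int]] = (),
                **design_params) -> StrandPairDesign:
    """Build a probe/target design with target = reverse complement of probe."""
    target = reverse_complement(probe)
    target = NucleotideSequence(name + "_T" if name else f"{probe.name}_rc", target.bases)
    return StrandPairDesign(
        probe, target,
        {"P": tuple(intended_stem_p), "T": tuple(intended_stem_t)},
        design_params,
    )


def _mirror_stem(stem: Iterable[tuple[int, int]], n: int) -> tuple[tuple[int, int], ...]:
    # an intra stem (i,j) on the probe maps to (n-1-j, n-1-i) on its reverse complement
    return tuple(sorted((n - 1 - j, n - 1 - i) for i, j in stem))


_RETRY_BUDGET = 10_000


def _draw_bases(rng: np.random.Generator, n: int, gc_frac: float) -> list[str]:
    p = [(1 - gc_frac) / 2, gc_frac / 2, gc_frac / 2, (1 - gc_frac) / 2]
    return list(rng.choice(list("ACGT"), size=n, p=p))


def generate_designed_pair(stem_len: int, loop_len: int, tail5: int, tail3: int,
                           gc_frac: float = 0.5, seed: int = 0) -> StrandPairDesign:
    """Design a complementary strand pair whose probe carries one hairpin stem.

    The probe layout 5'->3' is  tail5 | stem arm | loop | stem arm' | tail3
    with arm' the reverse complement of the arm, so the two arms can close a
    hairpin of ``stem_len`` base pairs around a ``loop_len``-nt loop.
    Sequences are rejection-sampled until the probe contains no unintended
    complementary run of >= 3 feasible pairs outside the designed stem;
    deterministic given ``seed``.  The target is the reverse complement and
    therefore carries the mirrored stem.
    """
    if stem_len < 0:
        raise DesignFailure("stem_len must be >= 0")
    if stem_len > 0 and loop_len < MIN_LOOP:
        raise DesignFailure(f"loop_len must be >= {MIN_LOOP} when stem_len > 0")
    n = 2 * stem_len + loop_len + tail5 + tail3
    if n <= 0:
        raise DesignFailure("total length must be positive")
    rng = np.random.default_rng(seed)
    stem = tuple(
        (tail5 + k, tail5 + stem_len + loop_len + (stem_len - 1 - k))
        for k in range(stem_len)
    )
    for _ in range(_RETRY_BUDGET):
        bases = _draw_bases(rng, n, gc_frac)
        for k in range(stem_len):  # overwrite arm' with the arm's complement
            i, j = stem[k]
            bases[j] = _COMPLEMENT[bases[i]]
        s = "".join(bases)
        runs = complementary_runs(s, min_len=3)
        stem_set = set(stem)
        unintended = [r for r in runs if not _run_within(r, stem_set)]
        if unintended:
            continue
        if stem_len >= 3 and not any(_run_covers(r, stem_set) for r in runs):
            continue  # designed stem itself broken by the loop-minimum screen
        probe = NucleotideSequence(f"design_s{stem_len}l{loop_len}", s)
        d = pair_design(
            probe,
            intended_stem_p=stem,
            intended_stem_t=_mirror_stem(stem, n),
            stem_len=stem_len, loop_len=loop_len, tail5=tail5, tail3=tail3,
            gc_frac=gc_frac, seed=seed,
        )
        return d
    raise DesignFailure(
        f"no sequence without unintended structure found in {_RETRY_BUDGET} draws"
    )


def _run_pairs(run: tuple[int, int, int]) -> set[tuple[int, int]]:
    i, j, length = run
    return {(i + k, j - k) for k in range(length)}


def _run_within(run, stem_set: set) -> bool:
    return _run_pairs(run) <= stem_set


def _run_covers(run, stem_set: set) -> bool:
    return stem_set <= _run_pairs(run)


def generate_toy_system(n_nt: int, with_hairpin: bool = False, seed: int = 0) -> StrandPairDesign:
    """A complementary pair short enough for exhaustive state enumeration.

    Sequences are rejection-sampled so that the total number of feasible
    base pairs stays within the enumeration oracle's tractability bound.
    ``with_hairpin`` embeds a 2-3 bp self-complementary stem in the probe
    (requires n_nt >= 8); otherwise the probe has no feasible intra pair.
    """
    from hpk.pairing import feasible_pairs  # local import to avoid a cycle

    if not 1 <= n_nt <= 14:
        raise ValueError("n_nt must be between 1 and 14")
    if with_hairpin and n_nt < 8:
        raise ValueError("with_hairpin requires n_nt >= 8 (2 bp stem + 3 nt loop)")
    rng = np.random.default_rng(seed)
    if n_nt == 1:
        return pair_design(NucleotideSequence("toy1", "G"), n_nt=1, seed=seed)
    for _ in range(_RETRY_BUDGET):
        s = "".join(_draw_bases(rng, n_nt, 0.5))
        runs = complementary_runs(s, min_len=2)
        if with_hairpin:
            good = [r for r in runs if 2 <= r[2] <= 3]
            if not good or len(runs) > 1:
                continue
            stem = tuple(sorted(_run_pairs(good[0])))
        else:
            probe_pairs = [
                (i, j) for i in range(n_nt) for j in range(i + MIN_LOOP + 1, n_nt)
                if _is_complement(s[i], s[j])
            ]
            if probe_pairs:
                continue
            stem = ()
        d = pair_design(
            NucleotideSequence(f"toy{n_nt}", s),
            intended_stem_p=stem,
            intended_stem_t=_mirror_stem(stem, n_nt),
            n_nt=n_nt, with_hairpin=with_hairpin, seed=seed,
        )
        if len(feasible_pairs(d)) <= 24:
            return d
    raise DesignFailure(f"no enumerable toy system found for n_nt={n_nt} in budget")
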