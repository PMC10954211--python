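"""Constrained stochastic sequence design for trap blueprints.

A blueprint is a linear description of the single-stranded origami: every
position is either fixed (structural motifs: the 5' GGA transcription
start, the aptamer block, the four lock hairpins, the 3' primer site) or
free, and a partial involution (``pair_map``) records which positions must
end up Watson-Crick (or wobble) paired — secondary-structure stems as well
as the kissing-loop pseudoknot pairs between cognate lock loops.

The solver is a simple mutate-and-repair stochastic search: free
positions are randomised, paired partners are repaired immediately, and
single-position mutations are accepted whenever the violation score (pair
violations + spurious-complementarity windows) does not increase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Blueprint",
    "KeySet",
    "ValidationReport",
    "InfeasibleError",
    "ConvergenceError",
    "design_sequence",
    "validate_sequence",
    "find_spurious_windows",
    "make_keys",
    "derive_keyset",
    "traptamer_blueprint",
    "reverse_complement",
]

RNA_BASES = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}

#: minimal spurious-complementarity screen: no perfect WC window of this
#: many nt between regions that are not designed to pair
SPURIOUS_WINDOW = 8


class InfeasibleError(ValueError):
    """Blueprint constraints cannot all be satisfied simultaneously."""


class ConvergenceError(RuntimeError):
    """Search exhausted max_iter; carries best-found diagnostics."""

    def __init__(self, message: str, best_sequence: str, report: "ValidationReport"):
        super().__init__(message)
        self.best_sequence = best_sequence
        self.report = report


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _is_paired(a: str, b: str, allow_gu: bool) -> bool:
    if (a, b) in _WC_PAIRS:
        return True
    return allow_gu and (a, b) in _WOBBLE_PAIRS


@dataclass(frozen=True)
class Blueprint:
    """Linear design blueprint: length, pairing targets, fixed bases.

    ``pair_map`` is a symmetric partial involution over 0-based positions;
    ``constraints`` maps fixed positions to their base; positions listed
    in ``no_gu`` (the 2 bp flanking each crossover seam) must pair
    strictly Watson-Crick.  ``segments`` names the blueprint regions.
    """

    length: int
    pair_map: dict[int, int]
    constraints: dict[int, str]
    no_gu: frozenset[int] = frozenset()
    segments: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, j in self.pair_map.items():
            if not (0 <= i < self.length and 0 <= j < self.length):
                raise InfeasibleError("pair_map position out of range")
            if i == j:
                raise InfeasibleError(f"position {i} paired with itself")
            if self.pair_map.get(j) != i:
                raise InfeasibleError("pair_map is not symmetric")
        for i, b in self.constraints.items():
            if b not in RNA_BASES:
                raise InfeasibleError(f"invalid constrained base {b!r} at {i}")
        for i, j in self.pair_map.items():
            if i in self.constraints and j in self.constraints:
                a, b = self.constraints[i], self.constraints[j]
                if not _is_paired(a, b, allow_gu=i not in self.no_gu and j not in self.no_gu):
                    raise InfeasibleError(
                        f"constrained bases {a}{b} at pair ({i},{j}) are incompatible"
                    )

    def segment(self, name: str) -> tuple[int, int]:
        return self.segments[name]

    def segment_seq(self, seq: str, name: str) -> str:
        lo, hi = self.segments[name]
        return seq[lo:hi]


@dataclass(frozen=True)
class ValidationReport:
    violated_pairs: tuple[tuple[int, int], ...]
    violated_constraints: tuple[int, ...]
    spurious_windows: tuple[tuple[int, int, int], ...]

    @property
    def n_violations(self) -> int:
        return (len(self.violated_pairs) + len(self.violated_constraints)
                + len(self.spurious_windows))

    @property
    def ok(self) -> bool:
        return self.n_violations == 0


def find_spurious_windows(seq: str, pair_map: dict[int, int],
                          min_len: int = SPURIOUS_WINDOW) -> list[tuple[int, int, int]]:
    """Perfect antiparallel WC windows >= ``min_len`` nt outside the design.

    Returns maximal windows as ``(i, j, length)``: positions ``i..i+len-1``
    pair ``j..j-len+1``.  Windows containing any designed pair are not
    spurious.  Quadratic scan; lengths here are a few hundred nt.
    """
    n = len(seq)
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.int8)
    for k, b in enumerate(RNA_BASES):
        lut[ord(b)] = k
    c = lut[codes]
    wc = np.zeros((4, 4), dtype=bool)
    for a, b in _WC_PAIRS:
        wc[RNA_BASES.index(a), RNA_BASES.index(b)] = True
    m = wc[c[:, None], c[None, :]]
    m &= np.triu(np.ones((n, n), dtype=bool), k=1)
    for i, j in pair_map.items():           # designed pairs break runs
        m[i, j] = False
    run = np.zeros((n, n), dtype=np.int32)
    run[0] = m[0]
    for i in range(1, n):
        run[i, :-1] = m[i, :-1] * (run[i - 1, 1:] + 1)
        run[i, -1] = m[i, -1]
    hits: list[tuple[int, int, int]] = []
    for i, j in zip(*np.nonzero(run >= min_len)):
        w = int(run[i, j])
        if i + 1 < n and j >= 1 and run[i + 1, j - 1] > w:
            continue                        # not maximal
        hits.append((int(i) - w + 1, int(j) + w - 1, w))
    return hits


def validate_sequence(seq: str, bp: Blueprint) -> ValidationReport:
    """Check a sequence against every blueprint requirement."""
    if len(seq) != bp.length:
        raise ValueError(f"sequence length {len(seq)} != blueprint length {bp.length}")
    bad_pairs = []
    for i, j in bp.pair_map.items():
        if i < j and not _is_paired(seq[i], seq[j],
                                    allow_gu=i not in bp.no_gu and j not in bp.no_gu):
            bad_pairs.append((i, j))
    bad_cons = [i for i, b in bp.constraints.items() if seq[i] != b]
    spurious = find_spurious_windows(seq, bp.pair_map)
    return ValidationReport(tuple(sorted(bad_pairs)), tuple(sorted(bad_cons)),
                            tuple(spurious))


def _score(seq: list[str], bp: Blueprint) -> int:
    rep = validate_sequence("".join(seq), bp)
    return rep.n_violations


def design_sequence(bp: Blueprint, seed: int, max_iter: int = 20000) -> str:
    """Solve a blueprint by seeded mutate-and-repair search.

    Free positions are randomised, every designed pair is repaired to a
    Watson-Crick complement, then single-position mutations (with
    immediate partner repair) are accepted while the violation count does
    not increase.  Reproducible for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    seq = [""] * bp.length
    for i in range(bp.length):
        seq[i] = bp.constraints.get(i) or RNA_BASES[rng.integers(4)]
    free = [i for i in range(bp.length) if i not in bp.constraints]
    free_paired = [i for i in free if i in bp.pair_map]
    # initial repair: make every pair complementary, never touching
    # constrained positions (their consistency was checked upstream)
    for i, j in bp.pair_map.items():
        if i < j:
            if j not in bp.constraints:
                seq[j] = _COMPLEMENT[seq[i]]
            elif i not in bp.constraints:
                seq[i] = _COMPLEMENT[seq[j]]
    score = _score(seq, bp)
    best = list(seq)
    best_score = score
    it = 0
    while score > 0 and it < max_iter:
        it += 1
        pos = int(free[rng.integers(len(free))])
        old = seq[pos]
        partner = bp.pair_map.get(pos)
        if partner is not None and partner in bp.constraints:
            seq[pos] = _COMPLEMENT[seq[partner]]
        else:
            seq[pos] = RNA_BASES[rng.integers(4)]
        old_partner = None
        if partner is not None and partner not in bp.constraints:
            old_partner = seq[partner]
            seq[partner] = _COMPLEMENT[seq[pos]]
        new = _score(seq, bp)
        if new <= score:
            score = new
            if new < best_score:
                best, best_score = list(seq), new
        else:
            seq[pos] = old
            if old_partner is not None:
                seq[partner] = old_partner
    if score > 0:
        report = validate_sequence("".join(best), bp)
        raise ConvergenceError(
            f"no feasible sequence after {max_iter} iterations "
            f"({report.n_violations} residual violations)",
            "".join(best), report,
        )
    _ = free_paired
    return "".join(seq)


# ---------------------------------------------------------------------------
# keys and anti-keys
# ---------------------------------------------------------------------------

#: default toehold extension appended to keys (6 nt, weakly structured)
DEFAULT_TOEHOLD = "AUCAUC"


@dataclass(frozen=True)
class KeySet:
    """Key/anti-key strands for the two locks.

    Each anti-key is the full reverse complement of its key, so it can
    capture the key through the external toehold and strip it off the
    opened lock, re-closing the trap.
    """

    key_a: str
    key_b: str
    anti_key_a: str
    anti_key_b: str
    toehold_len: int = 6
    toehold_side: str = "3prime"

    def __post_init__(self) -> None:
        if self.anti_key_a != reverse_complement(self.key_a):
            raise InfeasibleError("anti_key_a must be the reverse complement of key_a")
        if self.anti_key_b != reverse_complement(self.key_b):
            raise InfeasibleError("anti_key_b must be the reverse complement of key_b")
        if self.toehold_side == "none" and self.toehold_len != 0:
            raise InfeasibleError("toehold_side 'none' implies toehold_len 0")


def make_keys(hairpin_seq: str, stem_len: int = 5, loop_len: int = 6,
              toehold_side: str = "none", toehold_len: int = 6,
              toehold_seq: str | None = None) -> tuple[str, str]:
    """Derive the (key, anti-key) pair that opens one lock hairpin.

    The hairpin reads stem-out, loop, stem-back (``2*stem_len + loop_len``
    nt).  The key is the reverse complement of the invasion path
    (outgoing stem + loop), so it first pairs the loop toehold and then
    displaces along the stem into the kissing segment.  An external
    toehold of ``toehold_len`` nt is appended on the requested side
    (``t-key`` = 5prime, ``key-t`` = 3prime); the anti-key is the full
    reverse complement of the extended key.
    """
    if len(hairpin_seq) != 2 * stem_len + loop_len:
        raise ValueError("hairpin sequence length must be 2*stem_len + loop_len")
    if toehold_side not in ("5prime", "3prime", "none"):
        raise ValueError("toehold_side must be 5prime, 3prime or none")
    if toehold_side != "none" and toehold_len < 1:
        raise ValueError("toehold_len must be >= 1 when a toehold side is given")
    invasion = hairpin_seq[: stem_len + loop_len]
    key = reverse_complement(invasion)
    if toehold_side != "none":
        ext = (toehold_seq or (DEFAULT_TOEHOLD * toehold_len))[:toehold_len]
        key = ext + key if toehold_side == "5prime" else key + ext
    return key, reverse_complement(key)


def derive_keyset(solved_seq: str, bp: Blueprint, toehold_side: str = "3prime",
                  toehold_len: int = 6) -> KeySet:
    """Build the full key set from a solved blueprint sequence."""
    hp_a = bp.segment_seq(solved_seq, "lockA_bottom")
    hp_b = bp.segment_seq(solved_seq, "lockB_bottom")
    if toehold_side == "none":
        toehold_len = 0
    key_a, anti_a = make_keys(hp_a, toehold_side=toehold_side, toehold_len=toehold_len)
    key_b, anti_b = make_keys(hp_b, toehold_side=toehold_side, toehold_len=toehold_len)
    return KeySet(key_a, key_b, anti_a, anti_b, toehold_len, toehold_side)


# ---------------------------------------------------------------------------
# bundled blueprint
# ---------------------------------------------------------------------------

# Fixed structural motif sequences.  All are synthetic stand-ins chosen
# for this package (self-consistent stems, palindromic kissing loops so
# cognate loops are mutually complementary); they are not any published
# construct's sequence.  Lock B's stem is GC-richer, i.e. more stable,
# than lock A's, which is why key B opens its lock more slowly.
LOCK_A_STEM = "GCAGC"
LOCK_A_LOOP = "GUGCAC"
LOCK_B_STEM = "GGCGC"
LOCK_B_LOOP = "CAUAUG"
APTAMER_BLOCK = "GGAAGGACGCAACUGAAUGG"   # synthetic aptamer placeholder
PRIMER_SITE = "ACUCAUCACUUCAGC"          # synthetic 3' primer site


def _lock_hairpin(stem: str, loop: str) -> str:
    return stem + loop + reverse_complement(stem)


def traptamer_blueprint(design=None, L: int | None = None, R: int | None = None) -> Blueprint:
    """Bundled blueprint for an L-R trap design (default 14-14).

    Layout (5'->3'): GGA | top helix out | lock B top | top helix back |
    lock A top | seam | left stem | aptamer block | right stem | seam |
    bottom helix out | lock B bottom | bottom helix back | lock A bottom |
    right stem back | left stem back | primer site.  Helix strands pair
    antiparallel; cognate lock loops pair as kissing pseudoknots.
    """
    if design is not None:
        L, R = design.L, design.R
    L = 14 if L is None else L
    R = 14 if R is None else R
    n_helix = 25
    seam = 6
    order = [
        ("start", 3), ("h1_a", n_helix), ("lockB_top", 16), ("h1_b", n_helix),
        ("lockA_top", 16), ("seam1", seam), ("mid_left", L),
        ("aptamer", len(APTAMER_BLOCK)), ("mid_right", R), ("seam2", seam),
        ("h3_a", n_helix), ("lockB_bottom", 16), ("h3_b", n_helix),
        ("lockA_bottom", 16), ("mid_right_b", R), ("mid_left_b", L),
        ("primer", len(PRIMER_SITE)),
    ]
    segments: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, ln in order:
        segments[name] = (pos, pos + ln)
        pos += ln
    length = pos

    pair_map: dict[int, int] = {}

    def pair_antiparallel(seg_a: str, seg_b: str) -> None:
        (a0, a1), (b0, b1) = segments[seg_a], segments[seg_b]
        assert a1 - a0 == b1 - b0
        for k in range(a1 - a0):
            i, j = a0 + k, b1 - 1 - k
            pair_map[i] = j
            pair_map[j] = i

    pair_antiparallel("h1_a", "h1_b")
    pair_antiparallel("h3_a", "h3_b")
    pair_antiparallel("mid_left", "mid_left_b")
    pair_antiparallel("mid_right", "mid_right_b")
    for lock in ("lockA", "lockB"):
        for side in ("top", "bottom"):
            lo, _ = segments[f"{lock}_{side}"]
            for k in range(5):                      # internal 5-bp stem
                i, j = lo + k, lo + 15 - k
                pair_map[i] = j
                pair_map[j] = i
        t0, _ = segments[f"{lock}_top"]
        b0, _ = segments[f"{lock}_bottom"]
        for k in range(6):                          # kissing pseudoknot
            i, j = t0 + 5 + k, b0 + 5 + 5 - k
            pair_map[i] = j
            pair_map[j] = i

    constraints: dict[int, str] = {}

    def constrain(name: str, seq: str) -> None:
        lo, hi = segments[name]
        assert hi - lo == len(seq)
        for k, b in enumerate(seq):
            constraints[lo + k] = b

    constrain("start", "GGA")
    constrain("aptamer", APTAMER_BLOCK)
    constrain("primer", PRIMER_SITE)
    constrain("lockA_top", _lock_hairpin(LOCK_A_STEM, LOCK_A_LOOP))
    constrain("lockA_bottom", _lock_hairpin(LOCK_A_STEM, LOCK_A_LOOP))
    constrain("lockB_top", _lock_hairpin(LOCK_B_STEM, LOCK_B_LOOP))
    constrain("lockB_bottom", _lock_hairpin(LOCK_B_STEM, LOCK_B_LOOP))

    # structural stringency: strict WC for the 2 bp flanking each
    # crossover seam (the ends of every helical segment at a seam)
    no_gu: set[int] = set()
    for name in ("h1_a", "h1_b", "h3_a", "h3_b", "mid_left", "mid_left_b",
                 "mid_right", "mid_right_b"):
        lo, hi = segments[name]
        no_gu.update((lo, lo + 1, hi - 2, hi - 1))

    return Blueprint(length=length, pair_map=pair_map, constraints=constraints,
                     no_gu=frozenset(no_gu), segments=segments)
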