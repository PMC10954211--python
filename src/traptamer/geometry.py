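"""Ideal rigid-body geometry of three-helix RNA origami aptamer traps.

The trap ("Traptamer") is a three-helix RNA origami tile: a fluorogenic
aptamer sits in the middle helix between two flanking stems of L and R
base pairs, the outer helices are held in register by two double-crossover
seams, and two branched kissing loops (bKL locks A and B) bridge the outer
helices.  Because the middle helix length varies with the design while the
outer frame does not, closing both locks requires winding the middle helix
away from its relaxed register: each inserted base pair adds one helical
step of rise (2.9 Å) and twist (360/11 ≈ 32.7°).  This module builds the
relaxed (open, unstrained) coarse model of a design and measures the two
strain observables used for screening: the separation between cognate lock
tips and the signed closing twist.

Conventions
-----------
* Right-handed coordinates, Å units; helix axes along +x; the tile plane
  is the xy-plane; 1-based residue numbering only in PDB output.
* A-form helix: 11 bp/turn, 2.9 Å rise/bp (defaults, configurable).
* Coarse resolution: one node per base pair along the duplex helices
  (a single-pass phosphate-trace cartoon), one node per nucleotide in the
  lock hairpins and in the 6-nt single-stranded seam spacers that absorb
  the design-dependent register mismatch at the two crossover seams.
* Twist sign: positive closing twist = the middle helix must be wound
  further (overtwisted) to bring both locks into closing register.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HelixParams",
    "BKLSpec",
    "AptamerInsert",
    "DesignVariant",
    "IdealModel",
    "StrainReport",
    "InvalidDesignError",
    "StructuralError",
    "accumulated_twist",
    "middle_axial_length",
    "closing_twist",
    "model_closing_twist",
    "build_ideal_model",
    "kl_separation",
    "strain_report",
    "write_model_pdb",
    "wrap_angle",
]


class InvalidDesignError(ValueError):
    """A design description violates a structural precondition."""


class StructuralError(ValueError):
    """A built model is missing a required structural element."""


# Outer-helix length in bp.  25 bp ≡ 3 mod 11 keeps the two lock anchors
# (at bp 1 and 23, exactly two full turns apart) in a common register, so
# both locks see the same closing-twist mismatch.
OUTER_HELIX_BP = 25
_LOCK_ANCHOR_BP = {"A": 1, "B": 23}
#: nt in each single-stranded crossover seam spacer
SEAM_SPACER_NT = 6
#: bonded-distance window for consecutive coarse residues, Å
BOND_WINDOW = (3.0, 8.0)

# hairpin construction constants (Å)
_STEM_ENTRY = 2.5    # radial gap between helix surface and first stem node
_RAIL_HALF_GAP = 1.8  # half the axial separation of the two stem rails
_LOOP_RADIUS = 7.2   # loop arc radius; apex is the lock-tip reference


def wrap_angle(deg: float) -> float:
    """Reduce an angle in degrees to the interval (-180, +180]."""
    a = math.fmod(deg, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class HelixParams:
    """Rigid A-form helix parameters.

    ``twist_per_bp`` must equal ``360 / bp_per_turn``; the default 11 bp
    per turn gives 32.727° twist and 2.9 Å rise per base pair.
    """

    bp_per_turn: int = 11
    twist_per_bp: float = 360.0 / 11.0
    rise_per_bp: float = 2.9
    helix_radius: float = 11.5
    inter_helix_gap: float = 3.0

    def __post_init__(self) -> None:
        if self.bp_per_turn <= 0:
            raise InvalidDesignError("bp_per_turn must be positive")
        if abs(self.twist_per_bp * self.bp_per_turn - 360.0) > 1e-9:
            raise InvalidDesignError(
                "twist_per_bp * bp_per_turn must equal 360 degrees"
            )
        if self.rise_per_bp <= 0:
            raise InvalidDesignError("rise_per_bp must be positive")

    @property
    def axis_spacing(self) -> float:
        """Centre-to-centre distance between adjacent helix axes (Å)."""
        return 2.0 * self.helix_radius + self.inter_helix_gap


@dataclass(frozen=True)
class BKLSpec:
    """A branched-kissing-loop lock: an extended stem capped by a loop.

    The default 5-bp stem with a 6-nt loop is the openable lock motif;
    the loop doubles as the toehold for loop-mediated strand displacement.
    """

    stem_len: int = 5
    loop_len: int = 6
    lock_id: str = "A"

    def __post_init__(self) -> None:
        if self.stem_len < 1:
            raise InvalidDesignError("bKL stem must be at least 1 bp")
        if self.loop_len < 4:
            raise InvalidDesignError("bKL loop must be at least 4 nt")
        if self.lock_id not in ("A", "B"):
            raise InvalidDesignError("lock_id must be 'A' or 'B'")


@dataclass(frozen=True)
class AptamerInsert:
    """Aptamer motif coarse-grained to a rigid pseudo-helical segment.

    ``effective_bp`` is the helical footprint of the folded motif inside
    the middle helix and ``intrinsic_twist_offset`` any extra rotation it
    contributes beyond ``effective_bp`` ideal steps.  The defaults are a
    calibration constant of this package: 14 effective bp with no offset
    places design 14-14 in the overtwist (>60°) regime and 11-11 in the
    undertwist (<-90°) regime, matching the screening behaviour expected
    of those designs.
    """

    name: str = "iSpinach"
    effective_bp: int = 14
    intrinsic_twist_offset: float = 0.0
    intrinsic_length: float = 14 * 2.9

    def __post_init__(self) -> None:
        if self.effective_bp < 0:
            raise InvalidDesignError("effective_bp must be >= 0")
        if self.intrinsic_length < 0:
            raise InvalidDesignError("intrinsic_length must be >= 0")


@dataclass(frozen=True)
class DesignVariant:
    """A trap design named "L-R" after its flanking stem lengths in bp."""

    L: int
    R: int
    insert: AptamerInsert = AptamerInsert()
    lock_a: BKLSpec = BKLSpec(lock_id="A")
    lock_b: BKLSpec = BKLSpec(lock_id="B")

    def __post_init__(self) -> None:
        if self.L < 1 or self.R < 1:
            raise InvalidDesignError("flanking stems need at least 1 bp")
        if self.lock_a.lock_id == self.lock_b.lock_id:
            raise InvalidDesignError("lock_a and lock_b must be distinct locks")

    @property
    def name(self) -> str:
        return f"{self.L}-{self.R}"

    @property
    def middle_bp(self) -> int:
        """Total base-pair steps in the middle helix (stems + insert)."""
        return self.L + self.insert.effective_bp + self.R

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "DesignVariant":
        try:
            left, right = name.split("-")
            return cls(L=int(left), R=int(right), **kwargs)
        except (ValueError, TypeError) as exc:
            raise InvalidDesignError(f"cannot parse design name {name!r}") from exc


@dataclass(frozen=True)
class StrainReport:
    """Per-lock tip separation and the signed twist needed to close."""

    separation_A: float
    separation_B: float
    closing_twist: float
    axial_mismatch: float

    def __post_init__(self) -> None:
        if self.separation_A < 0 or self.separation_B < 0:
            raise StructuralError("separations must be non-negative")
        if not (-180.0 < self.closing_twist <= 180.0):
            raise StructuralError("closing_twist must lie in (-180, 180]")


def accumulated_twist(n_bp: int, params: HelixParams | None = None) -> float:
    """Total helical twist in degrees over ``n_bp`` base-pair steps.

    No modular reduction is applied: one step at 11 bp/turn is 32.727°,
    11 steps are a full 360° turn.
    """
    if n_bp < 0:
        raise InvalidDesignError("n_bp must be >= 0")
    params = params or HelixParams()
    return n_bp * params.twist_per_bp


def middle_axial_length(design: DesignVariant, params: HelixParams | None = None) -> float:
    """Axial end-to-end length of the middle helix (Å) in the relaxed model."""
    params = params or HelixParams()
    n_steps = design.middle_bp - 1 - design.insert.effective_bp
    return n_steps * params.rise_per_bp + design.insert.intrinsic_length


def closing_twist(design: DesignVariant, params: HelixParams | None = None) -> float:
    """Signed twist (deg) the middle helix must add to close both locks.

    The relaxed register carried through the crossover seams leaves the
    two lock anchors of each cognate pair misaligned by the accumulated
    middle-helix twist modulo one turn; positive values mean the helix
    must be wound further (overtwist), negative values unwound.  Both
    locks share the same mismatch because their anchors sit an integer
    number of turns apart on the outer helices.
    """
    params = params or HelixParams()
    total = accumulated_twist(design.middle_bp - 1, params)
    total += design.insert.intrinsic_twist_offset
    # +180°: the two cognate anchors face each other across the tile, so
    # the closing register is half a turn out of phase with the seam one.
    return wrap_angle(total + 180.0)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _rot_x(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _radial(deg: float) -> np.ndarray:
    """Unit vector in the yz-plane at angle ``deg`` from +y."""
    t = math.radians(deg)
    return np.array([0.0, math.cos(t), math.sin(t)])


@dataclass
class _Helix:
    name: str
    x0: float
    y: float
    phase: float          # frame angle of bp 0, degrees
    angles: np.ndarray    # per-bp frame angle, degrees
    xs: np.ndarray        # per-bp axial position, Å

    def frame_position(self, i: int) -> np.ndarray:
        return np.array([self.xs[i], self.y, 0.0])

    def frame_orientation(self, i: int) -> np.ndarray:
        return _rot_x(self.angles[i])

    def node(self, i: int, radius: float) -> np.ndarray:
        return self.frame_position(i) + radius * _radial(self.angles[i])


@dataclass
class IdealModel:
    """Coarse relaxed model: per-bp frames, chain nodes, lock anchors.

    ``frames`` maps helix name -> list of (position, orientation) pairs;
    ``nodes`` are the coarse residue coordinates in chain order and
    ``connectivity`` the chain path over node indices; ``anchors`` maps
    lock id -> anchor/tip geometry for the cognate hairpin pair.
    """

    design: DesignVariant | None
    params: HelixParams
    frames: dict[str, list[tuple[np.ndarray, np.ndarray]]]
    nodes: np.ndarray
    node_labels: list[str]
    connectivity: list[int]
    anchors: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def n_residues(self) -> int:
        return len(self.nodes)

    def bond_lengths(self) -> np.ndarray:
        """Distances between consecutive chain residues."""
        path = self.nodes[self.connectivity]
        return np.linalg.norm(np.diff(path, axis=0), axis=1)


def _hairpin_nodes(anchor_pos: np.ndarray, theta: float, spec: BKLSpec,
                   params: HelixParams) -> tuple[list[np.ndarray], np.ndarray]:
    """Coarse nodes of a branched lock hairpin and its loop-tip point.

    The hairpin leaves the parent helix radially at frame angle ``theta``:
    an outgoing stem rail, a loop arc over the apex, and a returning rail.
    """
    v = _radial(theta)
    xhat = np.array([1.0, 0.0, 0.0])
    r = params.helix_radius
    stem_span = spec.stem_len * params.rise_per_bp
    step = stem_span / max(spec.stem_len - 1, 1)
    base = r + _STEM_ENTRY
    nodes: list[np.ndarray] = []
    for k in range(spec.stem_len):          # outgoing rail
        nodes.append(anchor_pos + (base + k * step) * v + _RAIL_HALF_GAP * xhat)
    centre = anchor_pos + (base + stem_span) * v
    tip = centre + _LOOP_RADIUS * v
    n_gap = spec.loop_len + 1
    for m in range(spec.loop_len):          # loop arc, +x side to -x side
        phi = math.radians((m + 1) * 180.0 / n_gap)
        nodes.append(centre + _LOOP_RADIUS * (math.cos(phi) * xhat + math.sin(phi) * v))
    for k in range(spec.stem_len):          # returning rail
        nodes.append(anchor_pos + (base + (spec.stem_len - 1 - k) * step) * v
                     - _RAIL_HALF_GAP * xhat)
    return nodes, tip


def _seam_spacer(p: np.ndarray, q: np.ndarray, bulge_dir: np.ndarray,
                 n: int = SEAM_SPACER_NT) -> list[np.ndarray]:
    """Single-stranded seam spacer bridging two crossover residues.

    ``n`` nodes are placed on an arc from ``p`` to ``q``; when the end
    points are close the arc bulges along ``bulge_dir`` until every bond
    of the sub-chain clears the lower bonded-distance bound.
    """
    lo = BOND_WINDOW[0] + 0.2
    mid = 0.5 * (p + q)
    u = q - p
    c = float(np.linalg.norm(u))
    u = u / c
    w = bulge_dir - np.dot(bulge_dir, u) * u
    w = w / np.linalg.norm(w)
    # straight-line interpolation when the end points are already far apart
    ts = np.linspace(0.0, 1.0, n + 2)[1:-1]
    straight = p[None, :] + ts[:, None] * (q - p)[None, :]
    if c / (n + 1) >= lo:
        return [pt for pt in straight]
    for h in np.arange(max(c, 1.0), 30.0, 0.25):
        # circular arc through the apex mid + h*w
        k = (h * h - c * c / 4.0) / (2.0 * h)
        centre = mid + k * w
        radius = h - k
        a0 = math.atan2(np.dot(p - centre, w), np.dot(p - centre, u))
        a1 = math.atan2(np.dot(q - centre, w), np.dot(q - centre, u))
        if a1 >= a0:  # take the major arc, over the apex at +w
            a1 -= 2.0 * math.pi
        angles = np.linspace(a0, a1, n + 2)[1:-1]
        pts = centre[None, :] + radius * (
            np.cos(angles)[:, None] * u[None, :] + np.sin(angles)[:, None] * w[None, :]
        )
        chain = np.vstack([p, pts, q])
        if np.linalg.norm(np.diff(chain, axis=0), axis=1).min() >= lo:
            return [pt for pt in pts]
    raise StructuralError("could not route seam spacer")  # pragma: no cover


def build_ideal_model(design: DesignVariant,
                      params: HelixParams | None = None) -> IdealModel:
    """Build the relaxed coarse model of a design.

    Three parallel coplanar helices (top / middle / bottom) joined by two
    crossover seams, lock hairpins A and B branched from the outer
    helices, and the aptamer insert occupying the centre of the middle
    helix.  The register of each outer helix is propagated through its
    seam from the middle helix, so all design-dependent twist mismatch
    shows up at the lock anchors, where :func:`kl_separation` and
    :func:`closing_twist` measure it.
    """
    params = params or HelixParams()
    n_mid = design.middle_bp
    if n_mid < 2:
        raise InvalidDesignError("middle helix must span at least 1 bp between crossovers")
    omega = params.twist_per_bp
    rise = params.rise_per_bp
    d = params.axis_spacing
    n_out = OUTER_HELIX_BP

    # middle helix: stems at ideal rise, insert spanning its intrinsic length
    ins = design.insert
    xs_mid = np.empty(n_mid)
    ang_mid = np.empty(n_mid)
    x = 0.0
    theta = 0.0
    ins_step = (ins.intrinsic_length / ins.effective_bp) if ins.effective_bp else 0.0
    ins_twist = ((ins.effective_bp * omega + ins.intrinsic_twist_offset) / ins.effective_bp
                 if ins.effective_bp else 0.0)
    for i in range(n_mid):
        xs_mid[i] = x
        ang_mid[i] = theta
        in_insert = design.L <= i < design.L + ins.effective_bp
        x += ins_step if in_insert else rise
        theta += ins_twist if in_insert else omega
    middle = _Helix("middle", 0.0, 0.0, 0.0, ang_mid, xs_mid)

    # outer helices: top anchored to the middle's left end, bottom to its
    # right end; seam transfer flips the register by half a turn.
    top = _Helix("top", 0.0, +d, 180.0,
                 180.0 + omega * np.arange(n_out),
                 rise * np.arange(n_out))
    t_end = ang_mid[-1]
    chi3 = t_end + 180.0 - (n_out - 1) * omega
    bottom = _Helix("bottom", 0.0, -d, chi3,
                    chi3 + omega * np.arange(n_out),
                    xs_mid[-1] - rise * (n_out - 1) + rise * np.arange(n_out))

    nodes: list[np.ndarray] = []
    labels: list[str] = []
    anchors: dict[str, dict[str, np.ndarray]] = {}
    r = params.helix_radius

    def add(pos: np.ndarray, label: str) -> None:
        nodes.append(np.asarray(pos, dtype=float))
        labels.append(label)

    def add_hairpin(helix: _Helix, lock: BKLSpec, side: str) -> None:
        b = _LOCK_ANCHOR_BP[lock.lock_id]
        hp, tip = _hairpin_nodes(helix.frame_position(b), helix.angles[b],
                                 lock, params)
        for pos in hp:
            add(pos, f"lock{lock.lock_id}_{side}")
        entry = anchors.setdefault(lock.lock_id, {})
        entry[f"tip_{side}"] = tip
        entry[f"angle_{side}"] = np.float64(helix.angles[b])
        entry[f"anchor_{side}"] = helix.frame_position(b)

    # chain: top helix right-to-left (locks B then A), seam, middle helix
    # left-to-right, seam, bottom helix right-to-left (locks B then A)
    for j in range(n_out - 1, -1, -1):
        add(top.node(j, r), "top")
        if j in (_LOCK_ANCHOR_BP["B"], _LOCK_ANCHOR_BP["A"]):
            lock = design.lock_b if j == _LOCK_ANCHOR_BP["B"] else design.lock_a
            add_hairpin(top, lock, "top")
    seam1 = _seam_spacer(top.node(0, r), middle.node(0, r), np.array([-1.0, 0, 0]))
    for pos in seam1:
        add(pos, "seam1")
    for i in range(n_mid):
        lab = ("insert" if design.L <= i < design.L + ins.effective_bp else "middle")
        add(middle.node(i, r), lab)
    seam2 = _seam_spacer(middle.node(n_mid - 1, r), bottom.node(n_out - 1, r),
                         np.array([1.0, 0, 0]))
    for pos in seam2:
        add(pos, "seam2")
    for j in range(n_out - 1, -1, -1):
        add(bottom.node(j, r), "bottom")
        if j in (_LOCK_ANCHOR_BP["B"], _LOCK_ANCHOR_BP["A"]):
            lock = design.lock_b if j == _LOCK_ANCHOR_BP["B"] else design.lock_a
            add_hairpin(bottom, lock, "bottom")

    frames = {
        h.name: [(h.frame_position(i), h.frame_orientation(i))
                 for i in range(len(h.xs))]
        for h in (top, middle, bottom)
    }
    return IdealModel(
        design=design,
        params=params,
        frames=frames,
        nodes=np.array(nodes),
        node_labels=labels,
        connectivity=list(range(len(nodes))),
        anchors=anchors,
    )


def kl_separation(model: IdealModel) -> tuple[float, float]:
    """Euclidean distance (Å) between cognate lock-tip reference points.

    Returns ``(separation_A, separation_B)`` measured between the loop
    apexes of each cognate hairpin pair in the relaxed model.
    """
    out = []
    for lock_id in ("A", "B"):
        entry = model.anchors.get(lock_id)
        if not entry or "tip_top" not in entry or "tip_bottom" not in entry:
            raise StructuralError(f"model is missing lock {lock_id} anchors")
        out.append(float(np.linalg.norm(entry["tip_top"] - entry["tip_bottom"])))
    return out[0], out[1]


def model_closing_twist(model: IdealModel) -> float:
    """Closing twist measured from the built model's lock anchor angles.

    The cognate tips face each other when the top anchor points at 180°
    and the bottom anchor at 0°; the signed sum of the two deviations is
    the twist the middle helix must supply.  Agrees exactly with
    :func:`closing_twist` computed from the design alone.
    """
    vals = []
    for lock_id in ("A", "B"):
        entry = model.anchors.get(lock_id)
        if not entry:
            raise StructuralError(f"model is missing lock {lock_id} anchors")
        vals.append(wrap_angle(float(entry["angle_top"]) - 180.0
                               + float(entry["angle_bottom"])))
    return vals[0]


def strain_report(design: DesignVariant,
                  params: HelixParams | None = None) -> StrainReport:
    """Build the relaxed model of ``design`` and report its lock strain."""
    params = params or HelixParams()
    model = build_ideal_model(design, params)
    sep_a, sep_b = kl_separation(model)
    axial = (design.middle_bp - OUTER_HELIX_BP) * params.rise_per_bp
    return StrainReport(
        separation_A=sep_a,
        separation_B=sep_b,
        closing_twist=closing_twist(design, params),
        axial_mismatch=axial,
    )


# ---------------------------------------------------------------------------
# PDB output
# ---------------------------------------------------------------------------

def write_model_pdb(model: IdealModel, path) -> None:
    """Write the coarse model as a one-atom-per-residue (P proxy) PDB.

    Single chain, sequential residue numbering from 1, one phosphate
    pseudo-atom per coarse residue.
    """
    from Bio.PDB import PDBIO, StructureBuilder

    if model.n_residues == 0:
        raise StructuralError("cannot write an empty model")
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("trap")
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg("    ")
    for idx in model.connectivity:
        pos = model.nodes[idx]
        builder.init_residue("  N", " ", idx + 1, " ")
        builder.init_atom("P", pos.astype(float), 0.0, 1.0, " ", "P", idx + 1, "P")
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def read_model_coordinates(path) -> np.ndarray:
    """Read back coordinates written by :func:`write_model_pdb`."""
    import warnings

    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("trap", str(path))
    coords = [atom.get_coord() for atom in structure.get_atoms()]
    return np.array(coords, dtype=float)
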