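"""Deterministic kinetics of the trap's key/anti-key machine cycle.

The trap is modelled as a lattice of well-mixed mass-action states:

* each lock is ``closed``, ``loop`` (key bound to the hairpin loop
  toehold) or ``open`` (key fully invaded, kissing interaction broken);
* the aptamer is ``unfolded`` or ``folded`` — folding is gated on the
  lock pattern (AND coupling for the cooperative 14-14 design, OR
  coupling for the longer designs, with a configurable leak when only
  one lock is open);
* the dye binds only the folded aptamer; fluorescence is proportional to
  the dye-bound fraction.

Free keys, anti-keys and dye are tracked in nM alongside the state
fractions; anti-keys strip keys out of open locks (single-step
displacement) and also sequester free keys as inert duplexes.  Timed
addition events (a :class:`Schedule`) drive the machine through its
open/close cycle; integration restarts at each addition.

Rates are first order except key/anti-key/dye binding (second order in
the free species).  Stem invasion scales as ``k_branch *
exp(+dG_stem/RT)``: a less stable branched stem is invaded faster, which
is why lock B (GC-richer stem) opens more slowly than lock A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .sequence_design import LOCK_A_STEM, LOCK_B_STEM, reverse_complement, _WC_PAIRS

__all__ = [
    "KineticParams",
    "Schedule",
    "SimulationError",
    "simulate",
    "stem_free_energy",
    "calibrate",
    "activation_percent",
    "activation_time",
    "deactivation_tau",
    "time_to_baseline",
    "reversibility_schedule",
    "both_keys_schedule",
    "GAS_CONSTANT_KCAL",
]

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal / (mol K)


class SimulationError(RuntimeError):
    """Integration failure or invalid simulation input."""


# ---------------------------------------------------------------------------
# nearest-neighbour stem free energy
# ---------------------------------------------------------------------------

# Minimal Watson-Crick nearest-neighbour stack table (kcal/mol, 37 C),
# keyed by the 5'->3' dinucleotide step on the given strand.  Symmetric
# under reverse complement, so a duplex reads the same from either side.
NN_STACK = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08, "AG": -2.08,
    "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24,
    "GA": -2.35, "UC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}


def stem_free_energy(stem_seq: str, bottom: str | None = None) -> float:
    """Nearest-neighbour stacking free energy (kcal/mol) of a duplex.

    ``stem_seq`` is one strand 5'->3'; ``bottom`` defaults to its reverse
    complement.  A supplied non-complementary bottom strand is rejected.
    An empty duplex is 0 kcal/mol.
    """
    seq = stem_seq.upper().replace("T", "U")
    if bottom is None:
        bottom = reverse_complement(seq)
    else:
        bottom = bottom.upper().replace("T", "U")
        if len(bottom) != len(seq) or any(
            (a, b) not in _WC_PAIRS for a, b in zip(seq, reversed(bottom))
        ):
            raise ValueError("duplex strands are not Watson-Crick complementary")
    if any(b not in "ACGU" for b in seq):
        raise ValueError(f"invalid RNA sequence {stem_seq!r}")
    return float(sum(NN_STACK[seq[i:i + 2]] for i in range(len(seq) - 1)))


# ---------------------------------------------------------------------------
# parameters and schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """Rate constants for the machine cycle.

    Units: /min for first-order constants, /(nM min) for the bimolecular
    ``k_toehold_on``, ``k_dye_on`` and ``k_antikey``; free energies in
    kcal/mol; ``signal_scale_u`` maps the dye-bound fraction to the
    plate-reader's arbitrary fluorescence units.

    The defaults are the frozen output of :func:`calibrate` against the
    shipped activation/deactivation anchors (fractional activation at
    30 min, toehold-dependent maximum activation rates, anti-key
    turn-off time); see the package methods note.
    """

    k_toehold_on: float = 1.9694e-3        # /(nM min), key -> hairpin loop
    k_toehold_off: float = 0.5             # /min
    k_branch: float = 9.6669e7             # /min, invasion attempt baseline
    k_open: float = 10.0                   # /min, kissing disruption
    k_close: float = 1e-3                  # /min, kissing reformation
                                           # (invasion is nearly irreversible)
    k_fold: float = 0.6                    # /min, aptamer maturation
    k_unfold: float = 0.2                  # /min, mechanical unfolding when trapped
    k_dye_on: float = 2.0e-3               # /(nM min)
    k_dye_off: float = 0.1                 # /min
    k_antikey: float = 4.0e-4              # /(nM min), single-step displacement
    dG_stem_a: float = stem_free_energy(LOCK_A_STEM)
    dG_stem_b: float = stem_free_energy(LOCK_B_STEM)
    temperature: float = 298.15            # K
    penalty_key_t: float = 0.33768         # step-1 multiplier, 3' toehold keys
    penalty_t_key: float = 0.30438         # step-2 multiplier, 5' toehold keys
    fold_leak_single: float = 0.22         # folding gate with one lock open (AND)
    kcl_fold_multiplier: float = 1.0       # optional K+ effect on maturation
    signal_scale_u: float = 14456.0        # a.u. per dye-bound fraction
    baseline_au: float = 500.0             # instrument background, a.u.

    def __post_init__(self) -> None:
        for name in ("k_toehold_on", "k_toehold_off", "k_branch", "k_open",
                     "k_close", "k_fold", "k_unfold", "k_dye_on", "k_dye_off",
                     "k_antikey"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def branch_rate(self, lock: str, key_type: str = "plain") -> float:
        """Stem-invasion rate for one lock: baseline * exp(+dG/RT)."""
        dg = self.dG_stem_a if lock == "A" else self.dG_stem_b
        rt = GAS_CONSTANT_KCAL * self.temperature
        rate = self.k_branch * math.exp(dg / rt)
        if key_type == "t_key":
            rate *= self.penalty_t_key
        return min(rate, 1e4)

    def loop_on_rate(self, key_type: str = "plain") -> float:
        rate = self.k_toehold_on
        if key_type == "key_t":
            rate *= self.penalty_key_t
        return rate


SPECIES = ("key_a", "key_b", "antikey_a", "antikey_b", "dye")


@dataclass(frozen=True)
class Schedule:
    """Timed additions (minutes, nM) driving a simulation."""

    events: tuple[tuple[float, str, float], ...]
    horizon: float = 200.0
    output_grid: float = 1.0

    def __post_init__(self) -> None:
        for t, sp, conc in self.events:
            if not (0.0 <= t <= self.horizon):
                raise ValueError(f"event at {t} min is outside the horizon")
            if sp not in SPECIES:
                raise ValueError(f"unknown species {sp!r}")
            if conc < 0:
                raise ValueError("concentrations must be non-negative")


def both_keys_schedule(key_conc: float = 500.0, dye: float = 500.0,
                       t_add: float = 0.0, horizon: float = 200.0,
                       output_grid: float = 1.0) -> Schedule:
    """Dye at t=0 and both keys added together at ``t_add``."""
    events = [(0.0, "dye", dye),
              (t_add, "key_a", key_conc), (t_add, "key_b", key_conc)]
    return Schedule(tuple(events), horizon=horizon, output_grid=output_grid)


def reversibility_schedule(key_conc: float = 500.0, antikey_conc: float = 1000.0,
                  rekey_conc: float = 2000.0, horizon: float = 220.0,
                  output_grid: float = 0.5, with_rekey: bool = True) -> Schedule:
    """The reversibility cycle: keys at 5 min, anti-keys at 85 min, keys
    again at 150 min."""
    events = [(0.0, "dye", 500.0),
              (5.0, "key_a", key_conc), (5.0, "key_b", key_conc),
              (85.0, "antikey_a", antikey_conc), (85.0, "antikey_b", antikey_conc)]
    if with_rekey:
        events += [(150.0, "key_a", rekey_conc), (150.0, "key_b", rekey_conc)]
    return Schedule(tuple(events), horizon=horizon, output_grid=output_grid)


# ---------------------------------------------------------------------------
# the state lattice
# ---------------------------------------------------------------------------

# lock states
_CLOSED, _LOOP, _OPEN = 0, 1, 2
_N_LATTICE = 3 * 3 * 2 * 2       # lock A x lock B x folded x dye-bound


def _sidx(a: int, b: int, f: int, d: int) -> int:
    return ((a * 3 + b) * 2 + f) * 2 + d


def _gate(a: int, b: int, design_rule: str, leak: float) -> float:
    """Folding gate as a function of the lock pattern."""
    open_a, open_b = a == _OPEN, b == _OPEN
    if design_rule == "or":
        return 1.0 if (open_a or open_b) else 0.0
    if open_a and open_b:
        return 1.0
    if open_a or open_b:
        return leak
    return 0.0


def _build_transitions(params: KineticParams, design_rule: str, key_type: str):
    """Enumerate lattice transitions as (src, dst, rate_const, species, species_deltas).

    ``rate_const`` multiplies the free concentration of ``species`` (or 1
    if None); ``species_deltas`` maps free-species index -> stoichiometry
    per transition event (scaled by the trap concentration).
    """
    kon = params.loop_on_rate(key_type)
    koff = params.k_toehold_off
    # series combination of stem invasion (step 2) and kissing
    # disruption (step 3): two sequential barriers out of the loop state
    kfwd = {}
    for lock in "AB":
        kb = params.branch_rate(lock, key_type)
        kfwd[lock] = 1.0 / (1.0 / kb + 1.0 / params.k_open) if kb > 0 else 0.0
    sp = {name: i for i, name in enumerate(SPECIES)}
    trans = []

    def lock_transitions(which: str):
        key = sp[f"key_{which.lower()}"]
        anti = sp[f"antikey_{which.lower()}"]
        moves = [
            (_CLOSED, _LOOP, kon, key, {key: -1}),
            (_LOOP, _CLOSED, koff, None, {key: +1}),
            (_LOOP, _OPEN, kfwd[which], None, {}),
            (_OPEN, _LOOP, params.k_close, None, {}),
            # anti-key strips the key and the kissing interaction reforms;
            # the key leaves as an inert key:anti-key duplex
            (_OPEN, _CLOSED, params.k_antikey, anti, {anti: -1, "duplex": which}),
        ]
        return moves

    # lock A moves
    for s0, s1, rate, species, deltas in lock_transitions("A"):
        for b in range(3):
            for f in range(2):
                for d in range(2):
                    trans.append((_sidx(s0, b, f, d), _sidx(s1, b, f, d),
                                  rate, species, deltas))
    # lock B moves
    for s0, s1, rate, species, deltas in lock_transitions("B"):
        for a in range(3):
            for f in range(2):
                for d in range(2):
                    trans.append((_sidx(a, s0, f, d), _sidx(a, s1, f, d),
                                  rate, species, deltas))
    # folding / unfolding
    for a in range(3):
        for b in range(3):
            g = _gate(a, b, design_rule, params.fold_leak_single)
            kf = params.k_fold * params.kcl_fold_multiplier * g
            ku = params.k_unfold * (1.0 - g)
            if kf > 0:
                trans.append((_sidx(a, b, 0, 0), _sidx(a, b, 1, 0), kf, None, {}))
            if ku > 0:
                trans.append((_sidx(a, b, 1, 0), _sidx(a, b, 0, 0), ku, None, {}))
                # mechanical unfolding ejects a bound dye in the same step
                trans.append((_sidx(a, b, 1, 1), _sidx(a, b, 0, 0),
                              ku, None, {sp["dye"]: +1}))
    # dye binding to the folded aptamer
    for a in range(3):
        for b in range(3):
            trans.append((_sidx(a, b, 1, 0), _sidx(a, b, 1, 1),
                          params.k_dye_on, sp["dye"], {sp["dye"]: -1}))
            trans.append((_sidx(a, b, 1, 1), _sidx(a, b, 1, 0),
                          params.k_dye_off, None, {sp["dye"]: +1}))
    return trans


# free-species vector layout appended to the lattice fractions:
# [key_a, key_b, antikey_a, antikey_b, dye, duplex_a, duplex_b]
_N_FREE = 7
_DUP_A, _DUP_B = 5, 6


def _rhs_factory(params: KineticParams, design_rule: str, key_type: str,
                 trap_conc: float):
    trans = _build_transitions(params, design_rule, key_type)
    src = np.array([t[0] for t in trans])
    dst = np.array([t[1] for t in trans])
    rate = np.array([t[2] for t in trans])
    # species whose concentration multiplies the rate (-1 = none)
    conc_of = np.array([(t[3] if t[3] is not None else -1) for t in trans])
    n_t = len(trans)
    delta = np.zeros((n_t, _N_FREE))
    for k, t in enumerate(trans):
        for key, v in t[4].items():
            if key == "duplex":
                dup = _DUP_A if v == "A" else _DUP_B
                delta[k, dup] += 1.0
            else:
                delta[k, key] += v

    def rhs(_t, y):
        frac = y[:_N_LATTICE]
        free = np.maximum(y[_N_LATTICE:], 0.0)
        mult = np.where(conc_of >= 0, free[np.maximum(conc_of, 0)], 1.0)
        flux = rate * mult * np.maximum(frac[src], 0.0)
        dy = np.zeros_like(y)
        np.add.at(dy, src, -flux)
        np.add.at(dy, dst, flux)
        dy[_N_LATTICE:] += trap_conc * (flux @ delta)
        # free key + free anti-key annihilate into an inert duplex
        for key_i, anti_i, dup_i in ((0, 2, _N_LATTICE + _DUP_A),
                                     (1, 3, _N_LATTICE + _DUP_B)):
            v = params.k_antikey * free[key_i] * free[anti_i]
            dy[_N_LATTICE + key_i] -= v
            dy[_N_LATTICE + anti_i] -= v
            dy[dup_i] += v
        return dy

    return rhs


def simulate(params: KineticParams, schedule: Schedule,
             design_rule: str = "and", key_type: str = "plain",
             trap_conc: float = 100.0, condition: str = "sim",
             return_states: bool = False):
    """Integrate the machine cycle over a schedule of additions.

    Returns a trace DataFrame (``time_min``, ``signal_au``,
    ``replicate``, ``condition``) on the schedule's output grid, with
    ``signal_au = baseline_au + signal_scale_u * dye_bound_fraction``.
    With ``return_states`` the raw state matrix is returned as well.
    """
    if design_rule not in ("and", "or"):
        raise ValueError("design_rule must be 'and' or 'or'")
    if key_type not in ("plain", "t_key", "key_t"):
        raise ValueError("key_type must be plain, t_key or key_t")
    rhs = _rhs_factory(params, design_rule, key_type, trap_conc)
    y = np.zeros(_N_LATTICE + _N_FREE)
    y[_sidx(_CLOSED, _CLOSED, 0, 0)] = 1.0

    grid = np.arange(0.0, schedule.horizon + 1e-9, schedule.output_grid)
    event_times = sorted({t for t, _, _ in schedule.events})
    breakpoints = [t for t in event_times if t > 0] + [schedule.horizon]
    for t, sp_name, conc in schedule.events:
        if t == 0.0:
            y[_N_LATTICE + SPECIES.index(sp_name)] += conc

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    t0 = 0.0
    for t1 in breakpoints:
        if t1 > t0:
            t_eval = grid[(grid >= t0 - 1e-9) & (grid <= t1 + 1e-9)]
            sol = solve_ivp(rhs, (t0, t1), y, method="LSODA",
                            t_eval=t_eval, rtol=1e-8, atol=1e-10)
            if not sol.success:
                raise SimulationError(f"integration failed: {sol.message}")
            if sol.y.size and sol.y.min() < -1e-6:
                raise SimulationError("negative state encountered; tighten tolerances")
            times_out.append(sol.t)
            states_out.append(sol.y.T)
            y = sol.y[:, -1].copy()
        for t, sp_name, conc in schedule.events:
            if abs(t - t1) < 1e-9:
                y[_N_LATTICE + SPECIES.index(sp_name)] += conc
        t0 = t1

    times = np.concatenate(times_out)
    states = np.vstack(states_out)
    keep = np.concatenate([[True], np.diff(times) > 1e-12])
    times, states = times[keep], states[keep]
    bound = states[:, [_sidx(a, b, 1, 1) for a in range(3) for b in range(3)]].sum(axis=1)
    signal = params.baseline_au + params.signal_scale_u * bound
    trace = pd.DataFrame({
        "time_min": times, "signal_au": signal,
        "replicate": 1, "condition": condition,
    })
    if return_states:
        return trace, times, states
    return trace


def activation_percent(trace: pd.DataFrame, params: KineticParams,
                       reference: float | None = None) -> pd.Series:
    """Signal as % of full activation (plateau reference).

    ``reference`` defaults to the trace's final signal, i.e. the plateau
    of a run that has reached completion.
    """
    ref = reference if reference is not None else float(trace["signal_au"].iloc[-1])
    base = params.baseline_au
    if ref <= base:
        raise ValueError("reference does not exceed baseline")
    return 100.0 * (trace["signal_au"] - base) / (ref - base)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

#: parameters calibrate() may adjust, with (lo, hi) bounds
CALIBRATABLE = {
    "k_toehold_on": (1e-5, 1e-1),
    "k_branch": (1e4, 1e10),
    "k_fold": (1e-2, 10.0),
    "k_unfold": (1e-2, 10.0),
    "k_antikey": (1e-6, 1e-1),
    "penalty_key_t": (1e-3, 1.0),
    "penalty_t_key": (1e-3, 1.0),
    "signal_scale_u": (1e2, 1e7),
}


def _observable(name_args: tuple, params: KineticParams) -> float:
    """Evaluate one supported calibration observable."""
    from . import trace_analysis as ta

    name = name_args[0]
    if name == "activation_at":
        _, t_min, key_type = name_args
        tr = simulate(params, both_keys_schedule(horizon=240.0), key_type=key_type)
        act = activation_percent(tr, params)
        return float(np.interp(t_min, tr["time_min"], act))
    if name == "max_rate":
        _, key_type = name_args
        tr = simulate(params, both_keys_schedule(horizon=240.0), key_type=key_type)
        return ta.max_rate(tr)
    if name == "time_off":
        tr = simulate(params, reversibility_schedule(with_rekey=False), key_type="key_t")
        return time_to_baseline(tr, params)
    if name == "time_on":
        tr = simulate(params, both_keys_schedule(horizon=300.0), key_type="key_t")
        return activation_time(tr, params)
    if name == "deactivation_tau":
        tr = simulate(params, reversibility_schedule(with_rekey=False), key_type="key_t")
        return deactivation_tau(tr)
    raise ValueError(f"unsupported observable {name_args!r}")


def activation_time(trace: pd.DataFrame, params: KineticParams,
                    level: float = 90.0) -> float:
    """Minutes until the signal reaches ``level`` % of its plateau."""
    act = activation_percent(trace, params).to_numpy()
    if not (act >= level).any():
        return float("inf")
    return float(trace["time_min"].to_numpy()[np.argmax(act >= level)])


def deactivation_tau(trace: pd.DataFrame, t_antikey: float = 85.0,
                     t_key: float = 5.0) -> float:
    """1/e decay time (min) of the signal after anti-key addition."""
    t = trace["time_min"].to_numpy()
    s = trace["signal_au"].to_numpy()
    base = s[t < t_key].mean() if (t < t_key).any() else s[0]
    peak = s[(t >= t_key) & (t <= t_antikey)].max()
    thresh = base + (peak - base) / math.e
    after = (t > t_antikey) & (s <= thresh)
    if not after.any():
        return float("inf")
    return float(t[after][0] - t_antikey)


def time_to_baseline(trace: pd.DataFrame, params: KineticParams,
                     t_antikey: float = 85.0, t_key: float = 5.0,
                     frac: float = 0.05) -> float:
    """Minutes from anti-key addition until the signal is back within
    ``frac`` of the activated amplitude above the pre-key baseline."""
    t = trace["time_min"].to_numpy()
    s = trace["signal_au"].to_numpy()
    base = s[t < t_key].mean() if (t < t_key).any() else s[0]
    peak = s[(t >= t_key) & (t <= t_antikey)].max()
    thresh = base + frac * (peak - base)
    after = (t > t_antikey) & (s <= thresh)
    if not after.any():
        return float("inf")
    return float(t[after][0] - t_antikey)


def calibrate(targets: list[tuple[tuple, float]],
              start: KineticParams | None = None,
              free: tuple[str, ...] | None = None,
              max_nfev: int = 60) -> KineticParams:
    """Fit selected rate constants to observable targets.

    ``targets`` is a list of ``(observable, value)`` where observable is
    e.g. ``("activation_at", 30, "plain")``, ``("max_rate", "key_t")``,
    ``("time_off",)`` or ``("time_on",)``.  Deterministic (derivative-free
    trust-region least squares in log-parameter space with fixed start).
    Raises with residual diagnostics when no parameter set fits.
    """
    from scipy.optimize import least_squares

    start = start or KineticParams()
    if free is None:
        free = tuple(k for k in CALIBRATABLE)
    for name in free:
        if name not in CALIBRATABLE:
            raise ValueError(f"{name} is not a calibratable parameter")

    def unpack(x) -> KineticParams:
        return replace(start, **{n: float(math.exp(v)) for n, v in zip(free, x)})

    def residuals(x):
        p = unpack(x)
        out = []
        for obs, target in targets:
            try:
                val = _observable(obs, p)
            except (SimulationError, ValueError):
                val = 10.0 * target if target else 10.0
            out.append((val - target) / (abs(target) if target else 1.0))
        return np.array(out)

    x0 = np.log([getattr(start, n) for n in free])
    lb = np.log([CALIBRATABLE[n][0] for n in free])
    ub = np.log([CALIBRATABLE[n][1] for n in free])
    res = least_squares(residuals, x0, bounds=(lb, ub), max_nfev=max_nfev,
                        diff_step=0.05, xtol=1e-4, ftol=1e-6)
    final = residuals(res.x)
    if np.max(np.abs(final)) > 0.25:
        raise SimulationError(
            f"calibration failed to reach targets; residuals {np.round(final, 3)}"
        )
    return unpack(res.x)
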