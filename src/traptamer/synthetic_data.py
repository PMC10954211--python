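"""Plate-reader-like synthetic fixtures for the screening and cycling assays.

The generator emulates the fluorescence experiments used to characterise
the traps: a screening plate (designs x key conditions, plus the
untrapped No-KL control), key titrations and the key/anti-key
reversibility cycle.  Noise-free trace means equal the configured
parameters exactly, so every statistic in :mod:`traptamer.trace_analysis`
can be validated by round trip; multiplicative Gaussian noise with a
configurable CV (default 2%) emulates replicate scatter.

The shipped screening table transcribes only the activation numbers the
screening narrative states for the cooperative (AND) 14-14 design —
52% / 16% single-key activation, 22-fold both-keys response over a low
(<0.2) background — and for the OR-class designs (~90% / ~50% single-key
activation).  Bar heights that are only plotted, never printed, are not
transcribed; background levels are chosen inside their stated class band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import KineticParams, Schedule, simulate

__all__ = [
    "DesignMeans",
    "ScreenConfig",
    "generate_screen",
    "generate_cycle_trace",
    "CONDITIONS",
    "condition_label",
]

#: key conditions per design on the screening plate
CONDITIONS = ("no-keys", "key-A", "key-B", "keys-AB")
#: the shared untrapped control condition
NO_KL = "No-KL"


def condition_label(design: str, condition: str) -> str:
    return f"{design}/{condition}"


@dataclass(frozen=True)
class DesignMeans:
    """Noise-free screening parameters for one design.

    All values are on the No-KL-normalised scale (No-KL plateau = 1.0):
    ``background`` is the pre-key plateau, ``fold_both`` the both-keys
    fold change over no-keys at the evaluation time, and ``act_a`` /
    ``act_b`` the single-key activations relative to the both-keys
    full-activation reference.
    """

    background: float
    fold_both: float
    act_a: float
    act_b: float

    def target_values(self) -> dict[str, float]:
        full = self.background * self.fold_both
        span = full - self.background
        return {
            "no-keys": self.background,
            "key-A": self.background + self.act_a * span,
            "key-B": self.background + self.act_b * span,
            "keys-AB": full,
        }


#: printed screening numbers: AND-class 14-14 and the OR-class designs.
#: "14-14v2" carries the later-experiment regime (lower single-key
#: activation), the regime in which the 30% AND-gate threshold applies.
DEFAULT_DESIGN_MEANS = {
    "14-14": DesignMeans(background=0.10, fold_both=22.0, act_a=0.52, act_b=0.16),
    "14-14v2": DesignMeans(background=0.10, fold_both=22.0, act_a=0.25, act_b=0.10),
    "15-15": DesignMeans(background=0.15, fold_both=10.0, act_a=0.90, act_b=0.50),
    "16-16": DesignMeans(background=0.15, fold_both=10.0, act_a=0.90, act_b=0.50),
    "17-16": DesignMeans(background=0.18, fold_both=8.0, act_a=0.90, act_b=0.50),
}


@dataclass(frozen=True)
class ScreenConfig:
    """Configuration of a synthetic screening plate."""

    design_means: dict[str, DesignMeans] = field(
        default_factory=lambda: dict(DEFAULT_DESIGN_MEANS))
    noise_cv: float = 0.02
    replicates: int = 3
    seed: int = 1
    t_add: float = 30.0         # key-addition time, min
    t_end: float = 90.0         # last time point, min
    dt: float = 2.0             # grid spacing, min
    rise_tau: float = 12.0      # exponential activation time constant, min
    t_eval_offset: float = 50.0  # statistic evaluation time after addition
    scale_au: float = 10000.0   # raw a.u. value of the No-KL plateau

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for name, dm in self.design_means.items():
            if min(dm.background, dm.fold_both, dm.act_a, dm.act_b) < 0:
                raise ValueError(f"negative mean parameter for design {name}")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(0.0, self.t_end + 1e-9, self.dt)

    @property
    def t_eval(self) -> float:
        return self.t_add + self.t_eval_offset


def _mean_curve(cfg: ScreenConfig, start: float, target: float) -> np.ndarray:
    """Plateau at ``start``, then exponential rise hitting ``target``
    exactly at the evaluation time."""
    t = cfg.grid
    rise = np.where(t >= cfg.t_add, 1.0 - np.exp(-(t - cfg.t_add) / cfg.rise_tau), 0.0)
    norm = 1.0 - np.exp(-cfg.t_eval_offset / cfg.rise_tau)
    return start + (target - start) * rise / norm


def generate_screen(cfg: ScreenConfig | None = None,
                    designs: list[str] | None = None) -> pd.DataFrame:
    """Synthetic screening plate as a tidy trace DataFrame.

    One trace per design x condition x replicate plus the shared No-KL
    control; condition labels are ``"<design>/<condition>"``.  Noise-free
    means hit the configured fold-change / activation values exactly at
    the evaluation time (t_add + 50 min); reproducible under the seed.
    """
    cfg = cfg or ScreenConfig()
    designs = designs or list(cfg.design_means)
    for name in designs:
        if name not in cfg.design_means:
            raise ValueError(f"unknown design {name!r}; configured: "
                             f"{sorted(cfg.design_means)}")
    rng = np.random.default_rng(cfg.seed)
    t = cfg.grid
    rows = []

    def emit(label: str, mean_curve: np.ndarray) -> None:
        for rep in range(1, cfg.replicates + 1):
            noise = 1.0 + cfg.noise_cv * rng.standard_normal(len(t))
            rows.append(pd.DataFrame({
                "time_min": t,
                "signal_au": cfg.scale_au * mean_curve * noise,
                "replicate": rep,
                "condition": label,
            }))

    emit(NO_KL, np.ones_like(t))
    for name in designs:
        targets = cfg.design_means[name].target_values()
        bg = cfg.design_means[name].background
        for cond in CONDITIONS:
            emit(condition_label(name, cond), _mean_curve(cfg, bg, targets[cond]))
    return pd.concat(rows, ignore_index=True)


def generate_cycle_trace(params: KineticParams, schedule: Schedule,
                         noise_cv: float = 0.02, seed: int = 1,
                         replicates: int = 3, design_rule: str = "and",
                         key_type: str = "key_t",
                         condition: str = "cycle") -> pd.DataFrame:
    """Simulated machine-cycle trace plus multiplicative replicate noise.

    Wraps :func:`traptamer.kinetics.simulate`; with a no-event schedule
    the result is a flat baseline plus noise, with the reversibility
    schedule it shows the rise / anti-key turn-off / re-activation cycle.
    """
    clean = simulate(params, schedule, design_rule=design_rule, key_type=key_type,
                     condition=condition)
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(1, replicates + 1):
        noisy = clean.copy()
        noisy["signal_au"] = clean["signal_au"] * (
            1.0 + noise_cv * rng.standard_normal(len(clean)))
        noisy["replicate"] = rep
        out.append(noisy)
    return pd.concat(out, ignore_index=True)
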