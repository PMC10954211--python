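"""Mapping geometric strain to predicted trapping regime.

Screening showed that the closing twist of the middle helix predicts a
design's behaviour: designs needing more than ~90° of unwinding are
never trapped (high background, no key response), designs needing more
than ~60° of overwinding are well trapped and key-activatable, and the
band in between behaves variably.  This module applies those thresholds
to the geometry engine's strain reports and tabulates design series.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .geometry import (DesignVariant, HelixParams, StrainReport, strain_report)

__all__ = [
    "RegimeThresholds",
    "TrapRegime",
    "classify_design",
    "screen_series",
    "SCREEN_SERIES",
]

#: the 11-design screening series (L 11..17, R 11..16)
SCREEN_SERIES = ("11-11", "12-12", "13-12", "13-13", "14-13", "14-14",
                "15-14", "15-15", "16-15", "16-16", "17-16")

#: designs known to multimerise, which the strain model does not predict
MULTIMER_PRONE = ("15-14", "16-15")


@dataclass(frozen=True)
class RegimeThresholds:
    """Closing-twist cuts separating the three screening regimes (deg)."""

    undertwist_cut: float = -90.0
    overtwist_cut: float = +60.0

    def __post_init__(self) -> None:
        if not (self.undertwist_cut < 0.0 < self.overtwist_cut):
            raise ValueError("thresholds must satisfy undertwist_cut < 0 < overtwist_cut")


@dataclass(frozen=True)
class TrapRegime:
    """Predicted regime with a short rationale and known-failure caveat."""

    label: str
    rationale: str
    caveat: str = ""


def classify_design(strain: StrainReport,
                    thresholds: RegimeThresholds | None = None,
                    design_name: str = "") -> TrapRegime:
    """Classify a strain report into a trapping regime.

    Pure function of the closing twist and the thresholds: below the
    undertwist cut the aptamer is untrapped (high background, no key
    response); above the overtwist cut it is trapped and key-responsive;
    in between the behaviour is variable.
    """
    th = thresholds or RegimeThresholds()
    tw = strain.closing_twist
    if tw < th.undertwist_cut:
        label = "untrapped"
        why = (f"undertwist of {-tw:.1f} deg exceeds {-th.undertwist_cut:.0f} deg: "
               "aptamer folds despite the locks; high background, no key response")
    elif tw > th.overtwist_cut:
        label = "trapped_responsive"
        why = (f"overtwist of {tw:.1f} deg exceeds {th.overtwist_cut:.0f} deg: "
               "aptamer is trapped and released by keys")
    else:
        label = "variable"
        why = (f"closing twist {tw:.1f} deg sits between the cuts: "
               "variable inhibition, weak key response")
    caveat = ""
    if design_name in MULTIMER_PRONE:
        caveat = ("known to assemble into multimers, a failure mode the "
                  "single-tile strain model does not predict")
    return TrapRegime(label=label, rationale=why, caveat=caveat)


def screen_series(designs: list[DesignVariant] | None = None,
                  params: HelixParams | None = None,
                  thresholds: RegimeThresholds | None = None) -> pd.DataFrame:
    """Strain screen table for a design series (default: the 11-design set).

    One row per design with separations, closing twist and regime label,
    sorted by (L, R).  Duplicate design names are rejected.
    """
    if designs is None:
        designs = [DesignVariant.from_name(n) for n in SCREEN_SERIES]
    if not designs:
        raise ValueError("design list is empty")
    names = [d.name for d in designs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate design names: {dupes}")
    rows = []
    for d in sorted(designs, key=lambda d: (d.L, d.R)):
        sr = strain_report(d, params)
        regime = classify_design(sr, thresholds, design_name=d.name)
        rows.append({
            "name": d.name, "L": d.L, "R": d.R,
            "separation_A": sr.separation_A, "separation_B": sr.separation_B,
            "closing_twist": sr.closing_twist,
            "axial_mismatch": sr.axial_mismatch,
            "regime": regime.label, "caveat": regime.caveat,
        })
    return pd.DataFrame(rows)
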