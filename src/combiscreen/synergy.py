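"""Combination index Q (Jin's method) and interaction classification.

Q compares the observed killing effect of a two-drug combination with the
Bliss independence expectation of the single agents:

    Q = KE(a+b) / (KEa + KEb - KEa * KEb)

Q < 0.85 is called antagonism, 0.85 <= Q <= 1.15 additive, Q > 1.15
synergism. The boundary values belong to "additive": the conventional
thresholds attach strict inequalities to the outer classes only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "CombinationMeasurement",
    "SynergyThresholds",
    "QResult",
    "ANTAGONISM",
    "ADDITIVE",
    "SYNERGISM",
    "q_index",
    "classify_interaction",
    "analyze_grid",
    "grid_from_killing_effects",
]

ANTAGONISM = "antagonism"
ADDITIVE = "additive"
SYNERGISM = "synergism"


@dataclass(frozen=True)
class CombinationMeasurement:
    """Killing effects for one dose pair: each drug alone and combined."""

    dose_a: float
    dose_b: float
    kea: float
    keb: float
    keab: float

    def __post_init__(self) -> None:
        for name in ("kea", "keb", "keab"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a killing-effect fraction in [0, 1], got {v}")


@dataclass(frozen=True)
class SynergyThresholds:
    """Interaction-class cutoffs on Q (boundaries are additive)."""

    antagonism_below: float = 0.85
    synergism_above: float = 1.15

    def __post_init__(self) -> None:
        if not self.antagonism_below < self.synergism_above:
            raise ValueError("antagonism_below must be < synergism_above")


DEFAULT_THRESHOLDS = SynergyThresholds()


@dataclass(frozen=True)
class QResult:
    q: float
    expected_ke: float  # Bliss expectation KEa + KEb - KEa*KEb
    interaction_class: str | None = None


def q_index(m: CombinationMeasurement) -> QResult:
    """Combination index Q for one dose pair (interaction class unset).

    Raises
    ------
    ValueError
        If both single agents are inert (KEa = KEb = 0), which leaves the
        Bliss expectation — Q's denominator — at zero.
    """
    expected = m.kea + m.keb - m.kea * m.keb
    if expected == 0.0:
        raise ValueError("undefined index: both single agents inert (KEa = KEb = 0)")
    return QResult(q=m.keab / expected, expected_ke=expected)


def classify_interaction(q: float, thresholds: SynergyThresholds = DEFAULT_THRESHOLDS) -> str:
    """Classify a Q value as antagonism, additive or synergism."""
    if not math.isfinite(q):
        raise ValueError(f"Q must be finite, got {q}")
    if q < 0:
        raise ValueError(f"Q must be non-negative, got {q}")
    if q < thresholds.antagonism_below:
        return ANTAGONISM
    if q > thresholds.synergism_above:
        return SYNERGISM
    return ADDITIVE


def analyze_grid(
    measurements,
    thresholds: SynergyThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Score and classify every dose pair of a combination grid.

    Parameters
    ----------
    measurements : iterable of CombinationMeasurement
        One entry per unique (dose_a, dose_b) pair.

    Returns
    -------
    DataFrame ordered by (dose_a, dose_b) ascending with columns
    ``dose_a, dose_b, kea, keb, keab, expected_ke, q, interaction_class``.
    Zero-dose companion rows (keb = 0) reduce to q = keab / kea.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("measurements must be non-empty")
    pairs = [(m.dose_a, m.dose_b) for m in measurements]
    if len(set(pairs)) != len(pairs):
        dup = sorted({p for p in pairs if pairs.count(p) > 1})
        raise ValueError(f"duplicate dose pair(s): {dup}")

    rows = []
    for m in measurements:
        res = q_index(m)
        res = replace(res, interaction_class=classify_interaction(res.q, thresholds))
        rows.append({
            "dose_a": m.dose_a, "dose_b": m.dose_b,
            "kea": m.kea, "keb": m.keb, "keab": m.keab,
            "expected_ke": res.expected_ke, "q": res.q,
            "interaction_class": res.interaction_class,
        })
    out = pd.DataFrame(rows).sort_values(["dose_a", "dose_b"]).reset_index(drop=True)
    return out


def grid_from_killing_effects(
    ke_a: pd.DataFrame,
    ke_b: pd.DataFrame,
    ke_ab: pd.DataFrame,
) -> list[CombinationMeasurement]:
    """Assemble grid measurements from the viability module's KE tables.

    ``ke_a`` and ``ke_b`` are single-agent tables (columns ``dose, ke``);
    ``ke_ab`` is the combination table (columns ``dose_a, dose_b, ke``).
    Single-agent KE at dose 0 is taken as 0.
    """
    def lookup(table: pd.DataFrame, dose: float) -> float:
        if dose == 0:
            return 0.0
        hit = table.loc[np.isclose(table["dose"], dose), "ke"]
        if hit.empty:
            raise ValueError(f"no single-agent killing effect measured at dose {dose}")
        return float(hit.iloc[0])

    out = []
    for _, row in ke_ab.iterrows():
        out.append(CombinationMeasurement(
            dose_a=float(row["dose_a"]),
            dose_b=float(row["dose_b"]),
            kea=lookup(ke_a, float(row["dose_a"])),
            keb=lookup(ke_b, float(row["dose_b"])),
            keab=float(row["ke"]),
        ))
    return out
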