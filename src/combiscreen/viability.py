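"""Viability, killing effect, bead-calibrated live counts and CIK cytotoxicity.

The CCK8 normalization follows the manufacturer-standard computation:

    viability = (OD_treated - OD_blank) / (OD_control - OD_blank)

with replicate optical densities averaged per condition before the ratio is
taken (ratio-of-means, which is more stable against blank noise than
mean-of-ratios). The killing effect is KE = clip(1 - viability, 0, 1);
clipping keeps KE a fraction, as the combination index Q assumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "PlateSchemaError",
    "DegeneratePlateError",
    "normalize_viability",
    "killing_effect",
    "live_cell_count",
    "cytotoxicity",
]

_DOSE_COLS = ("dose", "dose_a", "dose_b")


class PlateSchemaError(ValueError):
    """A plate table is missing a required role or column."""


class DegeneratePlateError(ValueError):
    """Control signal does not exceed blank signal."""


def _dose_columns(plate: pd.DataFrame) -> list[str]:
    cols = [c for c in _DOSE_COLS if c in plate.columns]
    if not cols:
        raise PlateSchemaError("plate has no dose column (expected 'dose' or 'dose_a'/'dose_b')")
    return cols


def normalize_viability(plate: pd.DataFrame) -> pd.DataFrame:
    """Turn a tidy plate reading into a per-(drug, dose) viability table.

    Parameters
    ----------
    plate : DataFrame
        Columns ``role`` (blank / control / treated), ``drug``, one or two
        dose columns (``dose`` or ``dose_a``/``dose_b``), ``replicate``,
        ``od``.

    Returns
    -------
    DataFrame with one row per treated condition: the dose column(s),
    ``drug``, ``viability`` (raw ratio, may exceed 1 under stimulation),
    ``viability_clipped`` (clipped to [0, 1]), ``sd`` and ``n`` (replicate
    count).

    Raises
    ------
    PlateSchemaError
        If a required role or column is absent.
    DegeneratePlateError
        If mean control OD <= mean blank OD.
    """
    for col in ("role", "od"):
        if col not in plate.columns:
            raise PlateSchemaError(f"plate is missing required column '{col}'")
    dose_cols = _dose_columns(plate)
    for role in ("blank", "control", "treated"):
        if not (plate["role"] == role).any():
            raise PlateSchemaError(f"plate has no wells with role '{role}'")

    blank = plate.loc[plate["role"] == "blank", "od"].mean()
    control = plate.loc[plate["role"] == "control", "od"].mean()
    span = control - blank
    if span <= 0:
        raise DegeneratePlateError(
            f"degenerate plate: mean control OD ({control:.4g}) must exceed "
            f"mean blank OD ({blank:.4g})"
        )

    treated = plate[plate["role"] == "treated"]
    keys = (["drug"] if "drug" in treated.columns else []) + dose_cols
    grouped = treated.groupby(keys, dropna=False)["od"]
    table = grouped.agg(["mean", "std", "count"]).reset_index()
    table["viability"] = (table["mean"] - blank) / span
    # replicate SD propagated through the (linear) normalization
    table["sd"] = table.pop("std").fillna(0.0) / span
    table["n"] = table.pop("count")
    table["viability_clipped"] = table["viability"].clip(0.0, 1.0)
    table = table.drop(columns=["mean"])
    return table.sort_values(dose_cols).reset_index(drop=True)


def killing_effect(viab: pd.DataFrame) -> pd.DataFrame:
    """Add the killing effect KE = clip(1 - viability, 0, 1) to a viability table."""
    out = viab.copy()
    out["ke"] = (1.0 - out["viability"]).clip(0.0, 1.0)
    return out


def live_cell_count(cell_events: float, bead_events: float, beads_added: float) -> float:
    """Absolute live-cell count from precision counting beads.

    count = cell_events * beads_added / bead_events — the standard
    bead-ratio calibration of flow-cytometer event counts.
    """
    if bead_events < 1:
        raise ValueError("no beads acquired: bead_events must be >= 1")
    if beads_added < 1:
        raise ValueError("beads_added must be >= 1")
    if cell_events < 0:
        raise ValueError("cell_events must be >= 0")
    return cell_events * (beads_added / bead_events)


def cytotoxicity(tc, tt):
    """CIK-cell cytotoxicity (%) from live-tumor-cell percentages.

    cytotoxicity (%) = ((TC - TT) / TC) * 100, where TC and TT are the
    percentages of live tumor cells in control and test tubes. A negative
    result (TT > TC, i.e. apparent growth stimulation) is returned as-is.
    """
    tc_arr = np.asarray(tc, dtype=float)
    tt_arr = np.asarray(tt, dtype=float)
    if np.any(tc_arr <= 0):
        raise ValueError("TC must be > 0 (no live tumor cells in control tube)")
    if np.any((tc_arr > 100) | (tt_arr < 0) | (tt_arr > 100)):
        raise ValueError("TC and TT are percentages in (0, 100] and [0, 100]")
    out = (tc_arr - tt_arr) / tc_arr * 100.0
    return float(out) if out.ndim == 0 else out
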