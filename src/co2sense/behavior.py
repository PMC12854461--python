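"""Behavioral preference indices from two-choice assays.

OPI = (eggs on 1% CO2 side - eggs on 0.04% side) / total eggs.
PPI = per-reading (flies_high - flies_low) / counted flies, averaged over
the two 15-min readings taken with the CO2 sides swapped.
Eggs per fly = total eggs / flies loaded into the chamber.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .core import PositionAssay, TrialRecord, UndefinedIndexError

__all__ = ["opi", "ppi", "eggs_per_fly", "summarize_trials"]


def opi(rec: TrialRecord) -> float:
    """Oviposition preference index, in [-1, 1].

    Undefined (raises :class:`UndefinedIndexError`) for zero-egg trials
    and for the undivided air / no-air control conditions; such trials
    still count in egg-number summaries.
    """
    if rec.condition != "co2":
        raise UndefinedIndexError("OPI is only defined for two-choice co2 trials")
    total = rec.eggs_high + rec.eggs_low
    if total == 0:
        raise UndefinedIndexError("zero-egg trial: OPI undefined")
    return (rec.eggs_high - rec.eggs_low) / total


def ppi(assay: PositionAssay) -> float:
    """Positional preference index: mean of the two per-reading indices.

    Counts are stored relative to the CO2 condition (the side swap
    between readings is folded into the bookkeeping), and flies not
    visible in either half of a reading are excluded from that reading's
    denominator.
    """
    indices = []
    for high, low in (assay.reading1, assay.reading2):
        counted = high + low
        if counted == 0:
            raise UndefinedIndexError("a reading counted zero flies")
        indices.append((high - low) / counted)
    return float(np.mean(indices))


def eggs_per_fly(rec: TrialRecord) -> float:
    """Total eggs divided by the number of flies loaded."""
    return rec.total_eggs / rec.n_flies


def summarize_trials(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Tidy per-trial summary.

    OPI is NaN where undefined (zero-egg or control trials); those trials
    are retained for the egg-count columns.
    """
    rows = []
    for i, rec in enumerate(records):
        try:
            val = opi(rec)
        except UndefinedIndexError:
            val = math.nan
        rows.append({
            "trial": i,
            "condition": rec.condition,
            "n_flies": rec.n_flies,
            "total_eggs": rec.total_eggs,
            "eggs_per_fly": eggs_per_fly(rec),
            "opi": val,
        })
    return pd.DataFrame(rows)
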