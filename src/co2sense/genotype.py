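"""Heterozygote-correction scaling model over the (cis x CDS) genotype grid.

Nine transgenic genotypes form a 3 x 3 table: a cis-regulatory element
(GAL4 driver) from one of three species crossed with a Gr63a coding
sequence (UAS responder) from one of three species.  One cell could only
be recorded heterozygous; this module predicts its homozygous onset
spike rates by an empirical multiplicative scaling procedure:

* for each *donor* CDS ``d`` (a CDS other than the target's), compute a
  scaling factor as the average over the two non-target cis elements
  ``c`` of ``mean(c, target_cds) / mean(c, d)``;
* multiply ``n_points`` randomly selected recorded rates from the donor
  cell ``(target_cis, d)`` by that factor;
* pool the predicted points from the two donor routes.

Under an exactly multiplicative table (cell mean = base * cis_i * cds_j)
the procedure is exact for every cell.  A leave-the-control-out
validation predicts a cell with known homozygous recordings and compares
predicted vs recorded rates with a rank-based two-sample test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OnsetRateTable",
    "HomozygousPrediction",
    "ValidationResult",
    "scaling_factor",
    "default_routes",
    "predict_homozygous",
    "validate_on_control",
]

CellKey = tuple[str, str]  # (cis_element, cds)


class OnsetRateTable:
    """Onset spike rates keyed by (cis element, CDS), with zygosity flags.

    Backed by a long-format DataFrame with columns
    ``cis, cds, zygosity, replicate_id, onset_rate``.
    """

    COLUMNS = ("cis", "cds", "zygosity", "replicate_id", "onset_rate")

    def __init__(self, data: pd.DataFrame):
        missing = set(self.COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"table missing columns {sorted(missing)}")
        if (data["onset_rate"] <= 0).any():
            raise ValueError("onset rates must be positive")
        bad = set(data["zygosity"]) - {"hom", "het"}
        if bad:
            raise ValueError(f"unknown zygosity flags {sorted(bad)}")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "OnsetRateTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def cis_elements(self) -> list[str]:
        return sorted(self.data["cis"].unique())

    @property
    def cds_elements(self) -> list[str]:
        return sorted(self.data["cds"].unique())

    def cell(self, key: CellKey, zygosity: Optional[str] = "hom") -> np.ndarray:
        cis, cds = key
        m = (self.data["cis"] == cis) & (self.data["cds"] == cds)
        if zygosity is not None:
            m &= self.data["zygosity"] == zygosity
        return self.data.loc[m, "onset_rate"].to_numpy(dtype=float)

    def cell_mean(self, key: CellKey, zygosity: Optional[str] = "hom") -> float:
        vals = self.cell(key, zygosity)
        if vals.size == 0:
            raise ValueError(f"cell {key} is empty")
        return float(vals.mean())


@dataclass
class HomozygousPrediction:
    target: CellKey
    predicted: np.ndarray            # pooled predicted rates, spikes/s
    factors: dict[str, float]        # donor cds -> scaling factor
    donors: dict[str, CellKey]       # donor cds -> donor cell
    n_points: int
    seed: int


@dataclass
class ValidationResult:
    control: CellKey
    predicted: np.ndarray
    recorded: np.ndarray
    predicted_mean: float
    recorded_mean: float
    statistic: float
    p: float
    q: float


def scaling_factor(table: OnsetRateTable,
                   numerator_key_pairs: Sequence[tuple[CellKey, CellKey]]) -> float:
    """Unweighted average of cell-mean ratios over the given (num, den) pairs."""
    if not numerator_key_pairs:
        raise ValueError("need at least one cell pair")
    ratios = []
    for num_key, den_key in numerator_key_pairs:
        num = table.cell_mean(num_key)
        den = table.cell_mean(den_key)
        if den == 0:
            raise ValueError(f"zero denominator mean in cell {den_key}")
        ratios.append(num / den)
    return float(np.mean(ratios))


def default_routes(table: OnsetRateTable, target: CellKey):
    """The two donor routes for a target cell.

    For each donor CDS (the two CDS other than the target's), the factor
    pairs run over the two cis elements other than the target's, and the
    donor cell shares the target's cis element.  Routes are resolvable
    only if every referenced cell has homozygous recordings.
    """
    t_cis, t_cds = target
    other_cis = [c for c in table.cis_elements if c != t_cis]
    other_cds = [d for d in table.cds_elements if d != t_cds]
    if not other_cis or not other_cds:
        raise ValueError("target cell key outside a resolvable table")
    routes = []
    for d in other_cds:
        pairs = [((c, t_cds), (c, d)) for c in other_cis]
        routes.append({"donor_cds": d, "factor_pairs": pairs,
                       "donor_cell": (t_cis, d)})
    return routes


def predict_homozygous(
    table: OnsetRateTable,
    target: CellKey,
    n_points: int = 5,
    seed: int = 0,
    routes=None,
) -> HomozygousPrediction:
    """Predict homozygous onset rates for ``target`` from the other cells.

    Only homozygous recorded values enter the prediction; any recorded
    heterozygous values of the target cell are never mixed in.  Donor
    points are drawn without replacement, seeded.
    """
    t_cis, t_cds = target
    if t_cis not in table.cis_elements or t_cds not in table.cds_elements:
        raise ValueError(f"target cell {target} outside the table")
    if n_points < 1:
        raise ValueError("n_points must be at least 1")
    if routes is None:
        routes = default_routes(table, target)
    rng = np.random.default_rng(seed)
    predicted = []
    factors: dict[str, float] = {}
    donors: dict[str, CellKey] = {}
    for route in routes:
        factor = scaling_factor(table, route["factor_pairs"])
        donor_cell = tuple(route["donor_cell"])
        donor_vals = table.cell(donor_cell)
        if donor_vals.size < n_points:
            raise ValueError(
                f"donor cell {donor_cell} has {donor_vals.size} points, "
                f"need {n_points}"
            )
        picks = rng.choice(donor_vals, size=n_points, replace=False)
        predicted.append(picks * factor)
        factors[route["donor_cds"]] = factor
        donors[route["donor_cds"]] = donor_cell
    return HomozygousPrediction(
        target=target,
        predicted=np.concatenate(predicted),
        factors=factors,
        donors=donors,
        n_points=n_points,
        seed=seed,
    )


def validate_on_control(
    table: OnsetRateTable,
    control: CellKey,
    n_points: int = 5,
    seed: int = 0,
) -> ValidationResult:
    """Predict a cell with known homozygous recordings and compare.

    The control cell itself never feeds its own prediction (its cis
    element is excluded from the factor pairs and its CDS from the donor
    cells by construction).  Predicted and recorded rates are compared
    with a two-sided Wilcoxon rank-sum test; the Holm-adjusted Q equals
    the raw p for this single comparison.
    """
    recorded = table.cell(control)
    if recorded.size == 0:
        raise ValueError(f"control cell {control} has no homozygous recordings")
    pred = predict_homozygous(table, control, n_points=n_points, seed=seed)
    from .stats import holm_adjust, wilcoxon_pair

    stat, p = wilcoxon_pair(pred.predicted, recorded, paired=False)
    q = holm_adjust([p])[0]
    return ValidationResult(
        control=control,
        predicted=pred.predicted,
        recorded=recorded,
        predicted_mean=float(pred.predicted.mean()),
        recorded_mean=float(recorded.mean()),
        statistic=float(stat),
        p=float(p),
        q=float(q),
    )
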