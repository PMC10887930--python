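"""Agronomic heat-tolerance arithmetic and qPCR relative expression.

Heat tolerance of a variety is summarised by the heat-tolerant coefficient,
100 x (grain yield under heat stress) / (grain yield under control), and its
complement, the percentage yield loss.  Relative transcript abundance from
qPCR is computed with the 2^-ddCt estimator against a reference gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "GRAIN_YIELDS",
    "QpcrRecord",
    "heat_tolerant_coefficient",
    "yield_loss",
    "heat_tolerance_table",
    "ddct_relative_expression",
]

# Published field-trial grain yields (kg/ha) for four commercial maize
# hybrids heat-stressed at pre-flowering (HS1), flowering (HS2) and
# pre-grain-filling (HS3), plus unstressed controls (CK).
GRAIN_YIELDS = pd.DataFrame(
    [
        ("XY335", "CK", 7318.2), ("XY335", "HS1", 4481.6),
        ("XY335", "HS2", 2813.5), ("XY335", "HS3", 3148.0),
        ("ZD958", "CK", 6971.0), ("ZD958", "HS1", 5785.9),
        ("ZD958", "HS2", 4702.5), ("ZD958", "HS3", 5928.0),
        ("ZD309", "CK", 6875.0), ("ZD309", "HS1", 6409.5),
        ("ZD309", "HS2", 5974.4), ("ZD309", "HS3", 6141.0),
        ("DH605", "CK", 7182.0), ("DH605", "HS1", 5724.1),
        ("DH605", "HS2", 3363.0), ("DH605", "HS3", 6289.5),
    ],
    columns=["variety", "treatment", "grain_yield_kg_ha"],
)


def _round2(x: float) -> float:
    """Round half away from zero to 2 decimals, matching printed tables."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def heat_tolerant_coefficient(hs_yield: float, ck_yield: float) -> float:
    """Heat-tolerant coefficient in percent: 100 * HS yield / CK yield.

    Reported to 2 decimals.  ``ck_yield`` must be positive.
    """
    if not ck_yield > 0:
        raise ValueError(f"control yield must be positive, got {ck_yield!r}")
    return _round2(100.0 * hs_yield / ck_yield)


def yield_loss(hs_yield: float, ck_yield: float) -> float:
    """Percentage yield loss relative to control: 100 - coefficient.

    Computed pre-rounding so coefficient + loss == 100 exactly, then
    reported to 2 decimals.
    """
    if not ck_yield > 0:
        raise ValueError(f"control yield must be positive, got {ck_yield!r}")
    return _round2(100.0 - 100.0 * hs_yield / ck_yield)


def heat_tolerance_table(yields: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-variety heat-tolerant coefficients and yield losses.

    Parameters
    ----------
    yields
        Long-format table with columns ``variety``, ``treatment``
        (``CK`` plus any number of stress treatments) and
        ``grain_yield_kg_ha``.  Defaults to the bundled field-trial table.

    Returns
    -------
    DataFrame with one row per (variety, stress treatment) carrying the
    control yield, stressed yield, coefficient (%) and loss (%).
    """
    if yields is None:
        yields = GRAIN_YIELDS
    required = {"variety", "treatment", "grain_yield_kg_ha"}
    if not required.issubset(yields.columns):
        raise ValueError(f"yield table must have columns {sorted(required)}")
    rows = []
    for variety, grp in yields.groupby("variety", sort=False):
        ck = grp.loc[grp["treatment"] == "CK", "grain_yield_kg_ha"]
        if ck.empty:
            raise ValueError(f"no CK treatment for variety {variety!r}")
        ck_val = float(ck.iloc[0])
        for _, row in grp[grp["treatment"] != "CK"].iterrows():
            hs_val = float(row["grain_yield_kg_ha"])
            rows.append(
                {
                    "variety": variety,
                    "treatment": row["treatment"],
                    "ck_yield_kg_ha": ck_val,
                    "hs_yield_kg_ha": hs_val,
                    "heat_tolerant_coefficient_pct": heat_tolerant_coefficient(hs_val, ck_val),
                    "yield_loss_pct": yield_loss(hs_val, ck_val),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR measurement: target and reference-gene cycle thresholds."""

    sample: str
    gene: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_relative_expression(treated: QpcrRecord, control: QpcrRecord) -> float:
    """Relative expression of treated vs control by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_ref) in treated minus the same difference in
    control; relative expression is 2 to the minus ddCt.
    """
    ddct = treated.dct - control.dct
    return 2.0 ** (-ddct)
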