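"""Spectrophotometric and biochemical endpoint calculators.

Growth inhibition from 0 h / 96 h optical densities, malondialdehyde
(MDA) content from the TBARS assay absorbances, chlorophyll a/b and
carotenoid content from ethanol-extract absorbances, relative change of
an index versus the untreated control, and the Pearson correlation panel
across biomarkers. All calculators are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ODGrowthRecord",
    "growth_inhibition",
    "mda_content",
    "pigments",
    "relative_change",
    "correlation_panel",
    "biomarker_panel",
]


@dataclass(frozen=True)
class ODGrowthRecord:
    """Optical densities of one treatment and its control at 0 h and i h."""

    od_t0: float
    od_ti: float
    od_00: float
    od_0i: float


def growth_inhibition(od_t0, od_ti, od_00, od_0i):
    """Growth inhibition ``I = 1 - (OD_ti - OD_t0) / (OD_0i - OD_00)``.

    0 when the treatment grows exactly like the control, 1 when it does
    not grow at all; negative under growth stimulation (hormesis). The
    formula uses growth deltas, so adding a constant blank to both ODs of
    the same arm leaves I unchanged. Requires a growing control.
    """
    od_t0 = np.asarray(od_t0, dtype=float)
    od_ti = np.asarray(od_ti, dtype=float)
    control_growth = np.asarray(od_0i, dtype=float) - np.asarray(od_00, dtype=float)
    if np.any(control_growth <= 0):
        raise ValueError("control growth (OD_0i - OD_00) must be > 0")
    i = 1.0 - (od_ti - od_t0) / control_growth
    return i if i.ndim else float(i)


def growth_inhibition_record(rec: ODGrowthRecord) -> float:
    return growth_inhibition(rec.od_t0, rec.od_ti, rec.od_00, rec.od_0i)


def mda_content(od450, od532, od600, dilution_factor=1.0, cells_per_ml=1.0):
    """MDA content from TBARS absorbances:

    ``MDA = [6.45*(OD532 - OD600) - 0.56*OD450] * M / (1000 * N)``

    with M the algae dilution factor and N the cell density (cells/mL).
    Negative values for pathological absorbances are reported, not
    clipped. Units are those native to the formula (per-cell scale).
    """
    m = np.asarray(dilution_factor, dtype=float)
    n = np.asarray(cells_per_ml, dtype=float)
    if np.any(n <= 0) or np.any(m <= 0):
        raise ValueError("dilution factor M and cell density N must be > 0")
    od450 = np.asarray(od450, dtype=float)
    od532 = np.asarray(od532, dtype=float)
    od600 = np.asarray(od600, dtype=float)
    v = (6.45 * (od532 - od600) - 0.56 * od450) * m / (1000.0 * n)
    return v if v.ndim else float(v)


def pigments(od470, od649, od665):
    """Chlorophyll a/b and carotenoids from 470/649/665 nm absorbances.

    ``Chla = 13.59*OD665 - 6.88*OD649``
    ``Chlb = 24.96*OD649 - 7.32*OD665``
    ``Car  = (1000*OD470 - 2.05*OD665 - 114.8*OD649) / 245``

    Values are in the µg/mL-scale units native to the ethanol-extraction
    convention behind these coefficients.
    """
    od470 = np.asarray(od470, dtype=float)
    od649 = np.asarray(od649, dtype=float)
    od665 = np.asarray(od665, dtype=float)
    chla = 13.59 * od665 - 6.88 * od649
    chlb = 24.96 * od649 - 7.32 * od665
    car = (1000.0 * od470 - 2.05 * od665 - 114.8 * od649) / 245.0
    if chla.ndim:
        return chla, chlb, car
    return float(chla), float(chlb), float(car)


def relative_change(treatment, control):
    """Inhibition-positive relative change: ``100*(control - treatment)/control``.

    Positive = index inhibited relative to the control, negative =
    stimulated; a treatment equal to its control gives 0.
    """
    t = np.asarray(treatment, dtype=float)
    c = np.asarray(control, dtype=float)
    if np.any(c == 0):
        raise ValueError("control value must be nonzero")
    v = 100.0 * (c - t) / c
    return v if v.ndim else float(v)


def correlation_panel(panel: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pearson correlation matrix across biomarker indices.

    ``panel`` has one row per concentration and one column per index;
    at least 3 rows are required. Zero-variance indices yield NaN for
    their pairs (and their own diagonal is set to 1).
    """
    data = panel[list(columns)] if columns is not None else panel
    data = data.select_dtypes(include=[np.number])
    if len(data) < 3:
        raise ValueError("need at least 3 concentration points per index")
    corr = data.corr(method="pearson", min_periods=3)
    # pandas leaves the diagonal NaN for zero-variance columns; keep it NaN
    # as the undefined-sentinel, consistent with the off-diagonal pairs.
    return corr


def biomarker_panel(
    values: pd.DataFrame,
    index_columns,
    control_label: str = "control",
    treatment_column: str = "treatment",
    concentration_column: str = "concentration_mol_per_L",
) -> pd.DataFrame:
    """Per-treatment biomarker panel with relative changes vs control.

    ``values`` holds one row per replicate with raw index values. Rows
    with ``treatment == control_label`` define the control mean for each
    index. The result has, per (treatment, concentration), the replicate
    mean and standard deviation of each index plus its inhibition-positive
    relative change (control rows get relative change 0 by construction).
    """
    if treatment_column not in values.columns:
        raise ValueError(f"missing column {treatment_column!r}")
    control = values[values[treatment_column] == control_label]
    if control.empty:
        raise ValueError(f"no control rows (treatment == {control_label!r})")
    control_means = control[list(index_columns)].mean()

    grouped = values.groupby([treatment_column, concentration_column], sort=True)
    rows = []
    for (treatment, conc), grp in grouped:
        row = {"treatment": treatment, "concentration_mol_per_L": conc}
        for col in index_columns:
            mean = grp[col].mean()
            row[f"{col}_mean"] = mean
            row[f"{col}_sd"] = grp[col].std(ddof=1) if len(grp) > 1 else 0.0
            row[f"{col}_rel_change_pct"] = relative_change(mean, control_means[col])
        rows.append(row)
    return pd.DataFrame(rows)
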