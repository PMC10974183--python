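"""Seeded synthetic plate-data generators.

The generators emulate the statistical structure of a 96 h algal
growth-inhibition assay read spectrophotometrically: a 7-level geometric
dilution series (dilution factor 0.4) with triplicate optical-density
readings at 0 h and 96 h, for single compounds and for a fixed-ratio
binary mixture ray. The implied inhibition of each simulated well follows
a chosen Weibull/Hill truth curve (or a CA / IA / synergy mixture
surface), and Gaussian noise is added on the OD scale — measurement error
lives on the instrument, not on the derived effect.

For a synergy truth with potency factor ``s`` the mixture effect at total
concentration ``c`` is the CA-surface effect at ``s*c``: the observed
EC_x shrinks by ``1/s``, so the expected CA-referenced MDR is ``s``
(s > 1 synergy, s < 1 antagonism, s = 1 exactly CA).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dose_response import CurveParams
from .mixture import MixtureComponent, MixtureRay

__all__ = [
    "SimulationScenario",
    "weibull_from_ec50",
    "default_scenario",
    "simulate_single",
    "simulate_mixture",
    "simulate_biomarkers",
]


def weibull_from_ec50(ec50: float, slope: float) -> CurveParams:
    """Weibull CRC with a given EC50 (mol/L) and log10-slope."""
    if not (ec50 > 0):
        raise ValueError("ec50 must be > 0")
    w50 = math.log(-math.log(0.5))
    return CurveParams("weibull", w50 - slope * math.log10(ec50), slope)


@dataclass
class SimulationScenario:
    """Study conditions for one simulated exposure experiment.

    ``truth`` maps component ids to their true CRCs; ``fractions`` are the
    molar fractions of the mixture ray (same order as ``truth``).
    ``interaction`` is ``"CA"``, ``"IA"``, or a positive float — the
    potency-shift synergy factor on the CA surface. ``top_conc`` of None
    defaults to 3x the relevant EC50 (single compound or CA mixture), which
    places the 7-level 0.4-dilution series across the full response range.
    ``noise_sd`` is the OD-scale standard deviation of the replicate noise;
    control wells start at ``od_00`` and grow to ``od_0i``.
    """

    truth: dict[str, CurveParams]
    fractions: tuple[float, ...] = (1.0,)
    interaction: str | float = "CA"
    top_conc: float | None = None
    n_levels: int = 7
    dilution: float = 0.4
    replicates: int = 3
    noise_sd: float = 0.01
    od_00: float = 0.1
    od_0i: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.interaction, str):
            if self.interaction not in ("CA", "IA"):
                raise ValueError("interaction must be 'CA', 'IA', or a factor > 0")
        elif not (float(self.interaction) > 0):
            raise ValueError("synergy factor must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.od_0i <= self.od_00:
            raise ValueError("control must grow: od_0i > od_00")
        if len(self.fractions) != len(self.truth):
            raise ValueError("fractions must match truth components")
        if abs(sum(self.fractions) - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")

    def ray(self) -> MixtureRay:
        comps = [MixtureComponent(id=k, curve=v) for k, v in self.truth.items()]
        return MixtureRay(comps, self.fractions)

    def with_seed(self, seed: int) -> "SimulationScenario":
        return replace(self, seed=seed)


# Default study conditions: two components with EC50s at the single-compound
# potencies reported for the two beta-lactams (1.18e-4 and 1.99e-4 mol/L),
# mixed 0.20:0.80 by moles. Both truth curves are Weibull with a common
# log10-slope of 3.0 — similarly acting compounds have parallel CRCs, and an
# equal-slope pair makes the CA surface itself an exact Weibull, so the
# noise-free analysis identity is well-posed.
DEFAULT_EC50S = {"AMP": 1.18e-4, "CZO": 1.99e-4}
DEFAULT_SLOPE = 3.0
DEFAULT_FRACTIONS = (0.20, 0.80)


def default_scenario(
    interaction: str | float = "CA",
    noise_sd: float = 0.01,
    seed: int = 0,
    **overrides,
) -> SimulationScenario:
    """The stock binary-mixture scenario at the default study conditions."""
    truth = {k: weibull_from_ec50(v, DEFAULT_SLOPE) for k, v in DEFAULT_EC50S.items()}
    return SimulationScenario(
        truth=truth,
        fractions=DEFAULT_FRACTIONS,
        interaction=interaction,
        noise_sd=noise_sd,
        seed=seed,
        **overrides,
    )


def _series(scenario: SimulationScenario, top_conc: float) -> np.ndarray:
    return top_conc * scenario.dilution ** np.arange(scenario.n_levels)


def _od_rows(
    scenario: SimulationScenario,
    treatment: str,
    concentrations: np.ndarray,
    effects: np.ndarray,
    rng: np.random.Generator,
) -> list[dict]:
    """Assemble OD rows: od_t96 = od_t0 + (1 - E)*control_growth + noise."""
    growth = scenario.od_0i - scenario.od_00
    clipped = 0
    rows = []
    for conc, e in zip(concentrations, effects):
        for rep in range(1, scenario.replicates + 1):
            od96 = scenario.od_00 + (1.0 - e) * growth
            if scenario.noise_sd > 0:
                od96 += rng.normal(0.0, scenario.noise_sd)
            if od96 < 0:
                od96 = 0.0
                clipped += 1
            rows.append(
                {
                    "treatment": treatment,
                    "concentration_mol_per_L": conc,
                    "replicate": rep,
                    "od_t0": scenario.od_00,
                    "od_t96": od96,
                }
            )
    if clipped:
        warnings.warn(f"{clipped} simulated OD values clipped at 0", stacklevel=3)
    return rows


def _control_rows(scenario: SimulationScenario) -> list[dict]:
    # control wells carry the scenario's nominal growth exactly; the noise
    # model applies to treatment wells
    return [
        {
            "treatment": "control",
            "concentration_mol_per_L": 0.0,
            "replicate": rep,
            "od_t0": scenario.od_00,
            "od_t96": scenario.od_0i,
        }
        for rep in range(1, scenario.replicates + 1)
    ]


def simulate_single(scenario: SimulationScenario) -> pd.DataFrame:
    """Simulated OD table for each component exposed alone.

    Each compound gets its own 7-level dilution series (top concentration
    3x its EC50 unless ``scenario.top_conc`` overrides) plus shared control
    wells. At ``noise_sd = 0`` the implied growth inhibition of every row
    equals the truth-curve effect exactly.
    """
    rng = np.random.default_rng(scenario.seed)
    rows = _control_rows(scenario)
    for cid, curve in scenario.truth.items():
        top = scenario.top_conc
        if top is None:
            top = 3.0 * curve.inverse(min(0.5, curve.max_effect * 0.999))
        concs = _series(scenario, top)
        effects = np.asarray(curve.effect(concs))
        rows.extend(_od_rows(scenario, cid, concs, effects, rng))
    return pd.DataFrame(rows)


def mixture_truth_effect(scenario: SimulationScenario, c_mix) -> np.ndarray:
    """True mixture effect at total concentration(s) under the scenario."""
    ray = scenario.ray()
    c = np.asarray(c_mix, dtype=float)
    if scenario.interaction == "IA":
        return np.asarray(ray.ia_effect(c))
    s = 1.0 if scenario.interaction == "CA" else float(scenario.interaction)
    return np.asarray(ray.ca_effect(s * c))


def simulate_mixture(scenario: SimulationScenario, treatment: str = "mixture") -> pd.DataFrame:
    """Simulated OD table for the fixed-ratio mixture ray.

    The truth effect at each total concentration comes from the CA
    surface, the IA surface, or the potency-shifted CA surface (synergy
    factor s), per ``scenario.interaction``. A single-component scenario
    reduces to :func:`simulate_single` behaviour on that component.
    """
    rng = np.random.default_rng(scenario.seed)
    ray = scenario.ray()
    top = scenario.top_conc
    if top is None:
        s = (
            1.0
            if isinstance(scenario.interaction, str)
            else float(scenario.interaction)
        )
        level = min(0.5, ray.max_effect_ca * 0.999)
        top = 3.0 * ray.ec_ca(level) / s
    concs = _series(scenario, top)
    effects = mixture_truth_effect(scenario, concs)
    rows = _control_rows(scenario)
    rows.extend(_od_rows(scenario, treatment, concs, effects, rng))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# biomarkers

# Fixed control-level index values (arbitrary but realistic scales, held
# constant so relative changes are reproducible).
CONTROL_INDICES = {
    "chla": 4.0,   # ug/mL extract
    "chlb": 1.5,
    "car": 1.2,
    "mda": 2.0e-9,  # formula-native per-cell units at N=1e6 cells/mL
    "gsh": 50.0,    # kit activity units
    "tp": 100.0,
    "cat": 20.0,
    "sod": 80.0,
}
MDA_CELLS_PER_ML = 1.0e6
MDA_DILUTION = 1.0
_MDA_OD450 = 0.05
_MDA_OD600 = 0.02


def _pigment_absorbances(chla, chlb, car) -> tuple[float, float, float]:
    """Invert the pigment equations: absorbances producing given contents."""
    a = np.array([[13.59, -6.88, 0.0], [-7.32, 24.96, 0.0], [-2.05, -114.8, 1000.0]])
    b = np.array([chla, chlb, 245.0 * car])
    od665, od649, od470 = np.linalg.solve(a, b)
    return float(od470), float(od649), float(od665)


def _mda_od532(target_mda: float) -> float:
    """OD532 producing a target MDA at the fixed OD450/OD600 and M, N."""
    bracket = target_mda * 1000.0 * MDA_CELLS_PER_ML / MDA_DILUTION
    return _MDA_OD600 + (bracket + 0.56 * _MDA_OD450) / 6.45


def simulate_biomarkers(
    scenario: SimulationScenario,
    slopes: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    treatment: str = "mixture",
) -> dict[str, pd.DataFrame]:
    """Simulated biomarker tables for the mixture ray plus controls.

    Each index responds linearly to the truth effect E at its exposure
    concentration: ``value = control * (1 - slope * E)``, so the
    inhibition-positive relative change equals ``100 * slope * E``.
    Pigment and MDA values are then back-converted to the absorbances
    that produce them (so the endpoint calculators recover the targets
    exactly at zero noise); enzyme activities are emitted directly.
    Gaussian noise of relative scale ``noise_sd`` is applied to the target
    index values. Returns ``{"pigments": ..., "mda": ..., "activities": ...}``.
    """
    if slopes is None:
        slopes = {k: 0.8 for k in CONTROL_INDICES}
    rng = np.random.default_rng(scenario.seed + 1)
    top = scenario.top_conc
    ray = scenario.ray()
    if top is None:
        s = 1.0 if isinstance(scenario.interaction, str) else float(scenario.interaction)
        top = 3.0 * ray.ec_ca(min(0.5, ray.max_effect_ca * 0.999)) / s
    concs = _series(scenario, top)
    effects = mixture_truth_effect(scenario, concs)

    pig_rows, mda_rows, act_rows = [], [], []
    # control rows at zero effect, then one row set per concentration
    conditions = [("control", 0.0, 0.0)] + [
        (treatment, c, e) for c, e in zip(concs, effects)
    ]
    for label, conc, effect in conditions:
        for rep in range(1, scenario.replicates + 1):
            values = {}
            for idx, control_value in CONTROL_INDICES.items():
                v = control_value * (1.0 - slopes.get(idx, 0.0) * effect)
                if noise_sd > 0:
                    v *= 1.0 + rng.normal(0.0, noise_sd)
                values[idx] = v
            base = {
                "treatment": label,
                "concentration_mol_per_L": conc,
                "replicate": rep,
            }
            od470, od649, od665 = _pigment_absorbances(
                values["chla"], values["chlb"], values["car"]
            )
            pig_rows.append({**base, "od470": od470, "od649": od649, "od665": od665})
            mda_rows.append(
                {
                    **base,
                    "od450": _MDA_OD450,
                    "od532": _mda_od532(values["mda"]),
                    "od600": _MDA_OD600,
                    "dilution_factor": MDA_DILUTION,
                    "cells_per_ml": MDA_CELLS_PER_ML,
                }
            )
            act_rows.append(
                {**base, **{k: values[k] for k in ("gsh", "tp", "cat", "sod")}}
            )
    return {
        "pigments": pd.DataFrame(pig_rows),
        "mda": pd.DataFrame(mda_rows),
        "activities": pd.DataFrame(act_rows),
    }
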