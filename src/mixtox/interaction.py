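"""Mixture deviation ratio (MDR) interaction assessment.

The MDR compares a reference-model prediction with the observation:
``MDR = EC_x,pred / EC_x,obs`` where the prediction comes from the CA or
IA model built on the single-compound fits and the observation from a
CRC fitted to the mixture's own data. Its 95% observed-confidence bounds
come from the bootstrap interval on the observed EC_x:
``MDR_lower = EC_x,low / EC_x,obs`` and ``MDR_upper = EC_x,up / EC_x,obs``.

Classification rule:

* ``MDR_lower < MDR < MDR_upper``  -> additive,
* ``MDR > MDR_upper``              -> synergism,
* ``MDR < MDR_lower``              -> antagonism,

with boundary equality resolved to additive (the strict inequalities
leave ties undefined). The dose-reduction index of component i is the
standard ``DRI_i = EC_x,i / (p_i * EC_x,mix)`` — the fold-reduction in
its dose achievable inside the mixture at equal effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose_response import ECEstimate, FitResult, bootstrap_ec, fit_curve, select_model
from .mixture import MixtureRay

__all__ = [
    "MDRAssessment",
    "DRIResult",
    "MixtureAssessment",
    "mdr",
    "mdr_bounds",
    "classify",
    "dri",
    "assess",
]

LABELS = ("additive", "synergism", "antagonism")


def mdr(ec_pred: float, ec_obs: float) -> float:
    """Mixture deviation ratio: predicted over observed EC_x."""
    if not (ec_pred > 0 and ec_obs > 0):
        raise ValueError("effect concentrations must be > 0")
    return ec_pred / ec_obs


def mdr_bounds(ec_obs_low: float, ec_obs_up: float, ec_obs: float) -> tuple[float, float]:
    """(MDR_lower, MDR_upper) from the 95% OCI of the observed EC_x."""
    if not (0.0 < ec_obs_low <= ec_obs <= ec_obs_up):
        raise ValueError("require 0 < ec_obs_low <= ec_obs <= ec_obs_up")
    return ec_obs_low / ec_obs, ec_obs_up / ec_obs


def classify(mdr_value: float, mdr_lower: float, mdr_upper: float) -> str:
    """Map an MDR and its bounds to additive / synergism / antagonism."""
    if mdr_lower > mdr_upper:
        raise ValueError("mdr_lower must not exceed mdr_upper")
    if mdr_value > mdr_upper:
        return "synergism"
    if mdr_value < mdr_lower:
        return "antagonism"
    return "additive"


def dri(ec_x_single: float, fraction: float, ec_x_mix: float) -> float:
    """Dose-reduction index ``EC_x,i / (p_i * EC_x,mix)``."""
    if not (ec_x_single > 0 and ec_x_mix > 0):
        raise ValueError("effect concentrations must be > 0")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    return ec_x_single / (fraction * ec_x_mix)


@dataclass
class MDRAssessment:
    """One (effect level, reference model) row of the interaction table."""

    effect_level: float
    reference: str  # "CA" or "IA"
    ec_pred: float
    ec_obs: float
    ec_obs_low: float
    ec_obs_up: float
    mdr: float
    mdr_lower: float
    mdr_upper: float
    label: str

    def to_record(self) -> dict:
        return {
            "effect_level": self.effect_level,
            "reference": self.reference,
            "ec_pred": self.ec_pred,
            "ec_obs": self.ec_obs,
            "ec_obs_low": self.ec_obs_low,
            "ec_obs_up": self.ec_obs_up,
            "mdr": self.mdr,
            "mdr_lower": self.mdr_lower,
            "mdr_upper": self.mdr_upper,
            "label": self.label,
        }


@dataclass
class DRIResult:
    """Dose-reduction index of one component at one effect level."""

    component: str
    effect_level: float
    dri: float

    def to_record(self) -> dict:
        return {
            "component": self.component,
            "effect_level": self.effect_level,
            "dri": self.dri,
        }


@dataclass
class MixtureAssessment:
    """Full output of :func:`assess`: mixture fit, MDR rows, DRI rows."""

    mixture_fit: FitResult
    ec_observed: dict[float, ECEstimate]
    mdr_rows: list[MDRAssessment] = field(default_factory=list)
    dri_rows: list[DRIResult] = field(default_factory=list)
    seed: int | None = None

    def label(self, effect_level: float = 0.5, reference: str = "CA") -> str:
        """Headline interaction call at one level and reference model."""
        for row in self.mdr_rows:
            if row.reference == reference and np.isclose(row.effect_level, effect_level):
                return row.label
        raise KeyError(f"no assessment at x={effect_level} for {reference}")

    def to_records(self) -> dict:
        return {
            "mixture_fit": self.mixture_fit.to_record(),
            "ec_observed": {str(k): v.to_record() for k, v in self.ec_observed.items()},
            "mdr": [r.to_record() for r in self.mdr_rows],
            "dri": [r.to_record() for r in self.dri_rows],
            "seed": self.seed,
        }


def assess(
    ray: MixtureRay,
    concentrations,
    effects,
    effect_levels=(0.10, 0.25, 0.50),
    n_boot: int = 1000,
    seed: int | None = 0,
    families=("weibull", "hill"),
) -> MixtureAssessment:
    """Fit the mixture CRC and score CA/IA deviations at each effect level.

    For every requested effect level x this computes the observed mixture
    EC_x with its bootstrap 95% OCI, the CA and IA predictions from the
    ray's single-compound curves, the MDR against both references with
    its bounds and label, and the per-component DRIs. Deterministic given
    ``seed``.
    """
    x = np.asarray(concentrations, dtype=float).ravel()
    y = np.asarray(effects, dtype=float).ravel()
    fits = [fit_curve(x, y, fam) for fam in families]
    mix_fit = select_model(fits)

    levels = [float(e) for e in effect_levels]
    attainable = [e for e in levels if e < mix_fit.params.max_effect]
    skipped = sorted(set(levels) - set(attainable))
    if not attainable:
        raise ValueError(
            f"fitted mixture curve (max effect {mix_fit.params.max_effect:.3g}) "
            f"attains none of the requested effect levels {levels}"
        )
    ecs = bootstrap_ec(mix_fit, x, y, attainable, n_boot=n_boot, seed=seed)

    result = MixtureAssessment(
        mixture_fit=mix_fit, ec_observed=ecs, seed=seed
    )
    for e in attainable:
        est = ecs[e]
        lo = est.ec_low if est.ec_low is not None else est.ec
        up = est.ec_up if est.ec_up is not None else est.ec
        m_lower, m_upper = mdr_bounds(lo, up, est.ec)
        for reference, predictor in (("CA", ray.ec_ca), ("IA", ray.ec_ia)):
            try:
                ec_pred = predictor(e)
            except ValueError as exc:
                raise ValueError(
                    f"{reference} prediction failed at effect level {e}: {exc}"
                ) from exc
            m = mdr(ec_pred, est.ec)
            result.mdr_rows.append(
                MDRAssessment(
                    effect_level=e,
                    reference=reference,
                    ec_pred=ec_pred,
                    ec_obs=est.ec,
                    ec_obs_low=lo,
                    ec_obs_up=up,
                    mdr=m,
                    mdr_lower=m_lower,
                    mdr_upper=m_upper,
                    label=classify(m, m_lower, m_upper),
                )
            )
        for comp, p in zip(ray.components, ray.fractions):
            result.dri_rows.append(
                DRIResult(
                    component=comp.id,
                    effect_level=e,
                    dri=dri(comp.curve.inverse(e), p, est.ec),
                )
            )
    if skipped:
        result.skipped_levels = skipped  # type: ignore[attr-defined]
    return result
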