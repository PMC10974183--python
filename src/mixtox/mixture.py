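"""Fixed-ratio ray mixture design and the CA / IA reference models.

A *ray* holds the component concentration ratios fixed while the total
mixture concentration is diluted geometrically. With molar fractions
``p_i`` (summing to 1) the i-th component's concentration in a mixture of
total concentration ``c_mix`` is ``c_i = p_i * c_mix``.

Reference models for the mixture effect:

* Concentration addition (CA): ``sum_i c_i / EC_x,i = 1`` — the mixture
  EC_x is the fraction-weighted harmonic mean ``1 / sum_i(p_i / EC_x,i)``
  of the single-compound effect concentrations.
* Independent action (IA): ``E(c_mix) = 1 - prod_i (1 - E_i(c_i))``.

CA is the reference for similarly acting components (toxic units add);
IA multiplies "survival" probabilities of independently acting ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .dose_response import CurveParams, FitResult

__all__ = ["MixtureComponent", "MixtureRay", "MixturePrediction", "design_ray"]

_X_EPS = 1e-9  # effect-level padding away from 0 and the attainable ceiling


@dataclass(frozen=True)
class MixtureComponent:
    """One mixture component: id, molar mass, and its selected CRC."""

    id: str
    curve: CurveParams
    molar_mass: float | None = None
    fit: FitResult | None = None


@dataclass
class MixturePrediction:
    """CA and IA effect-concentration predictions at one effect level."""

    effect_level: float
    ec_ca: float
    ec_ia: float
    component_ec: dict[str, float]

    def to_record(self) -> dict:
        rec = {"effect_level": self.effect_level, "ec_ca": self.ec_ca, "ec_ia": self.ec_ia}
        rec.update({f"ec_{k}": v for k, v in self.component_ec.items()})
        return rec


class MixtureRay:
    """A fixed-ratio (ray) mixture of m >= 1 components.

    Parameters
    ----------
    components : sequence of MixtureComponent
        Components with their selected single-compound curves.
    fractions : sequence of float
        Molar fractions of the total mixture concentration, in the same
        order as ``components``; must sum to 1 within 1e-12.
    """

    def __init__(self, components, fractions):
        components = tuple(components)
        fractions = tuple(float(p) for p in fractions)
        if len(components) < 1:
            raise ValueError("a ray needs at least one component")
        if len(components) != len(fractions):
            raise ValueError("components and fractions must have equal length")
        if any(not (0.0 < p <= 1.0) for p in fractions):
            raise ValueError("fractions must lie in (0, 1]")
        if abs(sum(fractions) - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1 within 1e-12")
        ids = [c.id for c in components]
        if len(set(ids)) != len(ids):
            raise ValueError("component ids must be unique")
        self.components = components
        self.fractions = fractions

    # -- CA ----------------------------------------------------------------

    @property
    def max_effect_ca(self) -> float:
        """Supremum of effect levels attainable by every component."""
        return min(c.curve.max_effect for c in self.components)

    def component_ec(self, effect_level: float) -> dict[str, float]:
        """Single-compound EC_x for each component; errors name the component."""
        out = {}
        for comp in self.components:
            try:
                out[comp.id] = comp.curve.inverse(effect_level)
            except ValueError as exc:
                raise ValueError(
                    f"component {comp.id!r} cannot attain effect {effect_level}: {exc}"
                ) from exc
        return out

    def ec_ca(self, effect_level: float) -> float:
        """CA-predicted mixture EC_x: ``1 / sum_i(p_i / EC_x,i)``."""
        ecs = self.component_ec(effect_level)
        return 1.0 / sum(
            p / ecs[c.id] for c, p in zip(self.components, self.fractions)
        )

    def ca_effect(self, c_mix) -> np.ndarray | float:
        """Effect of the CA surface at total concentration(s) ``c_mix``.

        Solves ``ec_ca(x) = c`` for the effect level x by monotone
        root-finding on the log-concentration scale; concentrations below
        (above) the attainable range map to the padded boundary levels.
        """
        c_arr = np.atleast_1d(np.asarray(c_mix, dtype=float))
        if np.any(c_arr <= 0):
            raise ValueError("mixture concentration must be > 0")
        lo, hi = _X_EPS, self.max_effect_ca * (1.0 - _X_EPS)
        ec_lo, ec_hi = self.ec_ca(lo), self.ec_ca(hi)
        out = np.empty_like(c_arr)
        for i, c in enumerate(c_arr):
            if c <= ec_lo:
                out[i] = lo
            elif c >= ec_hi:
                out[i] = hi
            else:
                out[i] = optimize.brentq(
                    lambda x, c=c: np.log(self.ec_ca(x)) - np.log(c),
                    lo, hi, xtol=1e-15, rtol=8.9e-16,
                )
        return out if np.ndim(c_mix) else float(out[0])

    # -- IA ----------------------------------------------------------------

    @property
    def max_effect_ia(self) -> float:
        """Supremum of the IA mixture effect: ``1 - prod(1 - sup E_i)``."""
        prod = 1.0
        for c in self.components:
            prod *= 1.0 - c.curve.max_effect
        return 1.0 - prod

    def ia_effect(self, c_mix) -> np.ndarray | float:
        """IA mixture effect: ``1 - prod_i (1 - E_i(p_i * c_mix))``."""
        c_arr = np.asarray(c_mix, dtype=float)
        if np.any(c_arr <= 0):
            raise ValueError("mixture concentration must be > 0")
        surv = np.ones_like(c_arr, dtype=float)
        for comp, p in zip(self.components, self.fractions):
            surv = surv * (1.0 - np.asarray(comp.curve.effect(p * c_arr)))
        e = 1.0 - surv
        return e if np.ndim(c_mix) else float(e)

    def ec_ia(self, effect_level: float, rel_tol: float = 1e-10) -> float:
        """Invert the IA surface: total concentration with IA effect ``x``.

        Monotone bracketing (geometric expansion by factor 10 from a
        CA-informed start) followed by bisection on log10-concentration to
        a relative concentration tolerance ``rel_tol``.
        """
        x = float(effect_level)
        if not (0.0 < x < self.max_effect_ia):
            raise ValueError(
                f"effect level {x} not attainable under IA (sup={self.max_effect_ia})"
            )
        # starting scale: CA prediction when available, else component EC
        try:
            c0 = self.ec_ca(min(x, self.max_effect_ca * (1 - _X_EPS)))
        except ValueError:
            c0 = self.components[0].curve.inverse(
                min(x, self.components[0].curve.max_effect * 0.5)
            )
        lo = hi = c0
        while self.ia_effect(lo) >= x:
            lo /= 10.0
        while self.ia_effect(hi) <= x:
            hi *= 10.0

        f = lambda logc: self.ia_effect(10.0**logc) - x
        log_root = optimize.brentq(
            f, np.log10(lo), np.log10(hi),
            xtol=rel_tol / np.log(10.0) / 2.0, rtol=8.9e-16,
        )
        return float(10.0**log_root)

    # -- tables ------------------------------------------------------------

    def predict(self, effect_level: float) -> MixturePrediction:
        """CA and IA EC_x at one effect level."""
        return MixturePrediction(
            effect_level=float(effect_level),
            ec_ca=self.ec_ca(effect_level),
            ec_ia=self.ec_ia(effect_level),
            component_ec=self.component_ec(effect_level),
        )

    def predicted_crcs(self, conc_grid) -> pd.DataFrame:
        """Predicted CA and IA curves on a sorted positive grid.

        Returns a tidy frame with columns ``concentration``, ``effect_ca``,
        ``effect_ia``; both effect columns are nondecreasing.
        """
        grid = np.asarray(conc_grid, dtype=float)
        if np.any(grid <= 0):
            raise ValueError("grid concentrations must be > 0")
        if np.any(np.diff(grid) < 0):
            raise ValueError("grid must be sorted ascending")
        return pd.DataFrame(
            {
                "concentration": grid,
                "effect_ca": np.asarray(self.ca_effect(grid)),
                "effect_ia": np.asarray(self.ia_effect(grid)),
            }
        )


def design_ray(
    top_conc: float,
    n_levels: int = 7,
    dilution: float = 0.4,
    fractions=(1.0,),
    component_ids=None,
) -> pd.DataFrame:
    """Geometric dilution series along a fixed-ratio ray.

    Total concentrations are ``top_conc * dilution**k`` for
    ``k = 0..n_levels-1`` (descending); per-component columns hold
    ``p_i * c_mix``.
    """
    if not (0.0 < dilution < 1.0):
        raise ValueError("dilution must lie in (0, 1)")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if not (top_conc > 0):
        raise ValueError("top_conc must be > 0")
    fractions = tuple(float(p) for p in fractions)
    if abs(sum(fractions) - 1.0) > 1e-12:
        raise ValueError("fractions must sum to 1 within 1e-12")
    if component_ids is None:
        component_ids = [f"component_{i + 1}" for i in range(len(fractions))]
    totals = top_conc * dilution ** np.arange(n_levels)
    out = pd.DataFrame({"level": np.arange(1, n_levels + 1), "c_mix": totals})
    for cid, p in zip(component_ids, fractions):
        out[f"c_{cid}"] = p * totals
    return out
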