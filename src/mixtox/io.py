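"""CSV readers/writers, run configuration, and the end-to-end pipeline.

All concentration columns are in mol/L (mass-based inputs should be
pre-converted with :func:`mixtox.dose_response.mass_to_molar`; the CLI
exposes a ``convert`` subcommand). CSV files are comma-separated UTF-8
with a mandatory header row and "." decimals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import endpoints as ep
from .dose_response import fit_curve, pec, select_model
from .interaction import assess
from .mixture import MixtureComponent, MixtureRay

__all__ = ["RunConfig", "read_od_table", "effect_table", "run_pipeline"]

logger = logging.getLogger("mixtox")

OD_COLUMNS = ("treatment", "concentration_mol_per_L", "replicate", "od_t0", "od_t96")


class TableFormatError(ValueError):
    """A structured input-table validation failure."""


def _json_default(obj):
    """Serialise numpy scalars and enums transparently."""
    import numpy as np

    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if hasattr(obj, "value"):
        return obj.value
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with path context
        raise TableFormatError(f"cannot read CSV {path}: {exc}") from exc


def read_od_table(path) -> tuple[pd.DataFrame, float]:
    """Read an OD table and derive per-row growth inhibition.

    The CSV must have columns ``treatment, concentration_mol_per_L,
    replicate, od_t0, od_t96``; control rows have ``treatment=="control"``
    and concentration 0. Growth inhibition is computed for every
    non-control row against the mean control growth delta. Malformed rows
    are rejected with their (1-based, header-inclusive) line numbers.

    Returns ``(effects, control_growth)`` where ``effects`` has columns
    ``treatment, concentration, replicate, effect``.
    """
    df = _read_csv(path)
    missing = [c for c in OD_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")

    numeric = ["concentration_mol_per_L", "od_t0", "od_t96"]
    coerced = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1) | df["treatment"].isna()
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
        raise TableFormatError(f"{path}: malformed rows at lines {lines}")
    df[numeric] = coerced

    controls = df[df["treatment"] == "control"]
    if controls.empty:
        raise TableFormatError(f"{path}: no control rows (treatment=='control')")
    control_growth = float((controls["od_t96"] - controls["od_t0"]).mean())
    if control_growth <= 0:
        raise TableFormatError(f"{path}: control growth must be positive")

    treated = df[df["treatment"] != "control"].copy()
    if (treated["concentration_mol_per_L"] <= 0).any():
        lines = [
            int(i) + 2
            for i in treated.index[treated["concentration_mol_per_L"] <= 0]
        ]
        raise TableFormatError(
            f"{path}: non-positive treatment concentrations at lines {lines}"
        )
    effect = 1.0 - (treated["od_t96"] - treated["od_t0"]) / control_growth
    n_hormesis = int((effect < 0).sum())
    if n_hormesis:
        logger.warning(
            "%s: %d observation(s) with negative inhibition (growth stimulation)",
            path, n_hormesis,
        )
    out = pd.DataFrame(
        {
            "treatment": treated["treatment"].to_numpy(),
            "concentration": treated["concentration_mol_per_L"].to_numpy(),
            "replicate": treated["replicate"].to_numpy(),
            "effect": effect.to_numpy(),
        }
    )
    return out, control_growth


def effect_table(od_frame: pd.DataFrame):
    """Effect table directly from an in-memory OD frame (same schema)."""
    import io as _io

    buf = _io.StringIO()
    od_frame.to_csv(buf, index=False)
    buf.seek(0)
    return read_od_table(buf)


@dataclass
class RunConfig:
    """Configuration of one end-to-end mixture analysis run."""

    compounds: list[dict]  # [{id, molar_mass, od_csv}]
    mixture_od_csv: str
    fractions: dict[str, float]
    effect_levels: tuple[float, ...] = (0.10, 0.25, 0.50)
    families: tuple[str, ...] = ("weibull", "hill")
    n_boot: int = 1000
    seed: int = 0
    biomarkers: dict | None = None  # {pigments, mda, activities} csv paths
    output_dir: str = "mixtox_output"

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions sum to {total}, expected 1")
        if self.n_boot < 0:
            raise ValueError("n_boot must be >= 0")
        ids = {c["id"] for c in self.compounds}
        if set(self.fractions) != ids:
            raise ValueError("fractions keys must match compound ids")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {
            "compounds", "mixture_od_csv", "fractions", "effect_levels",
            "families", "n_boot", "seed", "biomarkers", "output_dir",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("effect_levels", "families"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


BIOMARKER_INDICES = ("chla", "chlb", "car", "mda", "gsh", "tp", "cat", "sod")


def _biomarker_values(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge raw biomarker tables into one value-per-index frame."""
    keys = ["treatment", "concentration_mol_per_L", "replicate"]
    pig = tables["pigments"].copy()
    chla, chlb, car = ep.pigments(pig["od470"], pig["od649"], pig["od665"])
    pig["chla"], pig["chlb"], pig["car"] = chla, chlb, car
    mda = tables["mda"].copy()
    mda["mda"] = ep.mda_content(
        mda["od450"], mda["od532"], mda["od600"],
        mda["dilution_factor"], mda["cells_per_ml"],
    )
    merged = pig[keys + ["chla", "chlb", "car"]].merge(
        mda[keys + ["mda"]], on=keys
    )
    return merged.merge(tables["activities"], on=keys)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis: fits, CA/IA predictions, MDR, biomarkers.

    Writes ``report.json``, ``fits.csv``, ``assessment.csv`` (and, when
    biomarker inputs are configured, ``panel.csv`` and ``correlation.csv``)
    under ``config.output_dir`` and returns the report dict. The report
    carries every number needed to recompute the MDRs by hand.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "n_boot": config.n_boot, "compounds": {}}

    components = []
    fit_records = []
    for comp in config.compounds:
        effects, growth = read_od_table(comp["od_csv"])
        fits = [
            fit_curve(effects["concentration"], effects["effect"], fam)
            for fam in config.families
        ]
        best = select_model(fits)
        logger.info(
            "compound %s: selected %s (R2=%.6f, RMSE=%.6f) from %d candidates",
            comp["id"], best.params.family.value, best.r_squared, best.rmse, len(fits),
        )
        est = None
        from .dose_response import ec_with_oci

        if 0.5 < best.params.max_effect:
            est = ec_with_oci(
                best, effects["concentration"], effects["effect"], 0.5,
                n_boot=config.n_boot, seed=config.seed,
            )
        components.append(MixtureComponent(comp["id"], best.params, comp.get("molar_mass"), best))
        rec = {
            "id": comp["id"],
            **best.to_record(),
            "control_growth": growth,
            "pec50": pec(est.ec, 2) if est else None,
            "ec50": est.ec if est else None,
            "ec50_low": est.ec_low if est else None,
            "ec50_up": est.ec_up if est else None,
        }
        fit_records.append(rec)
        report["compounds"][comp["id"]] = rec

    order = [c["id"] for c in config.compounds]
    ray = MixtureRay(components, [config.fractions[cid] for cid in order])

    mix_effects, mix_growth = read_od_table(config.mixture_od_csv)
    result = assess(
        ray,
        mix_effects["concentration"],
        mix_effects["effect"],
        effect_levels=config.effect_levels,
        n_boot=config.n_boot,
        seed=config.seed,
        families=config.families,
    )
    mix_rec = {
        **result.mixture_fit.to_record(),
        "control_growth": mix_growth,
    }
    if 0.5 in result.ec_observed:
        mix_rec["ec50"] = result.ec_observed[0.5].ec
        mix_rec["pec50"] = pec(result.ec_observed[0.5].ec, 2)
    report["mixture"] = mix_rec
    report["assessment"] = result.to_records()

    fits_df = pd.DataFrame(fit_records + [{"id": "mixture", **mix_rec}])
    fits_df.to_csv(outdir / "fits.csv", index=False)
    pd.DataFrame([r.to_record() for r in result.mdr_rows]).to_csv(
        outdir / "assessment.csv", index=False
    )
    pd.DataFrame([r.to_record() for r in result.dri_rows]).to_csv(
        outdir / "dri.csv", index=False
    )

    if config.biomarkers:
        tables = {k: _read_csv(v) for k, v in config.biomarkers.items()}
        values = _biomarker_values(tables)
        panel = ep.biomarker_panel(values, BIOMARKER_INDICES)
        panel.to_csv(outdir / "panel.csv", index=False)
        treated = values[values["treatment"] != "control"]
        by_conc = treated.groupby("concentration_mol_per_L")[
            list(BIOMARKER_INDICES)
        ].mean()
        corr = ep.correlation_panel(by_conc)
        corr.to_csv(outdir / "correlation.csv")
        report["biomarkers"] = {
            "panel_rows": int(len(panel)),
            "correlation_indices": list(corr.columns),
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    logger.info("pipeline complete: report written to %s", outdir / "report.json")
    return report
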