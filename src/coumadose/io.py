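"""Readers and writers: population configs and patient history files.

The population-parameter config is TOML (schema documented in the shipped
``data/demo_population.toml``). Patient histories are long-format tables —
CSV or XLSX — with three columns ``type,time,value``: covariate rows first
(``age``, ``weight``, ``cyp2c9``, ``vkorc1``, ``ethnicity``,
``baseline_inr``, ``target_low``, ``target_high``, ``interval``; the time
cell is left empty), then ``dose`` and ``inr`` event rows. Event times are
either plain hours since the first dose or ISO timestamps; timestamps are
converted to hours relative to the first dose.
"""

from __future__ import annotations

import logging
import tomllib
from importlib import resources
from pathlib import Path

import pandas as pd

from .model_core import (
    ConfigurationError,
    CovariateRelations,
    PatientCovariates,
    PopulationModel,
)
from .posteriori import INRObservation, PatientHistory
from .solver import DoseEvent

__all__ = ["read_config", "demo_population", "read_history", "write_history",
            "SchemaError"]

log = logging.getLogger(__name__)

_COVARIATE_KEYS = (
    "age", "weight", "cyp2c9", "vkorc1", "ethnicity",
    "baseline_inr", "target_low", "target_high", "interval",
)


class SchemaError(ValueError):
    """An input file does not match the documented schema."""


def _require(section: dict, key: str, where: str):
    if key not in section:
        raise ConfigurationError(f"config is missing required key '{where}.{key}'")
    return section[key]


def read_config(path: str | Path) -> PopulationModel:
    """Load and validate a population-parameter TOML file.

    EDK50 entries may be declared in mg/day or mg/h; per-day values are
    converted to the internal mg/h time base on load. Refuses configs with
    missing keys or non-positive rates/variances and logs the provenance
    string, which should identify the parameter source publication.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    provenance = raw.get("provenance", "unspecified")
    pk = _require(raw, "pk", "")
    pd_sec = _require(raw, "pd", "")
    var = _require(raw, "variability", "")
    edk = dict(_require(pd_sec, "edk50", "pd"))
    units = edk.pop("units", "mg/h")
    if units not in ("mg/h", "mg/day"):
        raise ConfigurationError(f"unknown edk50 units {units!r}")
    scale = 1.0 / 24.0 if units == "mg/day" else 1.0
    edk50 = {g: float(v) * scale for g, v in edk.items()}
    if units == "mg/day":
        log.info("edk50 entries declared in mg/day; converted to mg/h (/24)")

    cov_sec = raw.get("covariates", {})
    rel_kwargs = {
        k: cov_sec[k]
        for k in ("ref_weight", "ref_age", "cl_weight_exp", "v_weight_exp",
                  "cl_age_slope", "edk50_weight_exp")
        if k in cov_sec
    }
    if "cyp2c9_cl_mult" in cov_sec:
        rel_kwargs["cyp2c9_cl_mult"] = dict(cov_sec["cyp2c9_cl_mult"])
    if "cyp2c9_edk50_mult" in cov_sec:
        rel_kwargs["cyp2c9_edk50_mult"] = dict(cov_sec["cyp2c9_edk50_mult"])

    pop = PopulationModel(
        tv_cl=float(_require(pk, "tv_cl", "pk")),
        tv_v=float(_require(pk, "tv_v", "pk")),
        edk50_by_vkorc1=edk50,
        gamma=float(_require(pd_sec, "gamma", "pd")),
        emax=float(pd_sec.get("emax", 1.0)),
        mtt1=float(_require(pd_sec, "mtt1", "pd")),
        mtt2=float(_require(pd_sec, "mtt2", "pd")),
        n_transit=int(pd_sec.get("n_transit", 3)),
        inr_max=float(pd_sec.get("inr_max", 20.0)),
        omega_k10=float(_require(var, "omega_k10", "variability")),
        omega_edk50=float(_require(var, "omega_edk50", "variability")),
        sigma_add=float(_require(var, "sigma_add", "variability")),
        residual_model=str(var.get("residual_model", "additive")),
        covariate_relations=CovariateRelations(**rel_kwargs),
        provenance=str(provenance),
    )
    log.info("loaded population model: %s", pop.provenance)
    return pop


def demo_population() -> PopulationModel:
    """The bundled DEMO parameter set (plausible values; not for clinical use)."""
    ref = resources.files("coumadose.data") / "demo_population.toml"
    with resources.as_file(ref) as path:
        return read_config(path)


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        return pd.read_excel(path, dtype=str)
    return pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)


def _parse_times(series: pd.Series, rows: pd.Series) -> pd.Series:
    """Hours-offset floats, or ISO timestamps converted to hours from the
    earliest dose row."""
    try:
        return series.astype(float)
    except (TypeError, ValueError):
        pass
    try:
        stamps = pd.to_datetime(series, format="ISO8601")
    except (ValueError, TypeError) as exc:
        bad = []
        for line, v in zip(rows, series):
            try:
                float(v)
            except (TypeError, ValueError):
                try:
                    pd.to_datetime(v)
                except (ValueError, TypeError):
                    bad.append(f"line {line}: {v!r}")
        raise SchemaError("unparseable time value(s): " + "; ".join(bad)) from exc
    return (stamps - stamps.min()) / pd.Timedelta(hours=1)


def read_history(path: str | Path) -> PatientHistory:
    """Read a patient history file (CSV or XLSX, long format).

    Validates the schema, requires non-decreasing times within each record
    type, and retains pre-first-dose INR rows with a warning (they inform
    the baseline only, never the fit).
    """
    path = Path(path)
    df = _read_table(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("type", "time", "value"):
        if col not in df.columns:
            raise SchemaError(f"history file is missing required column '{col}'")
    df["line"] = df.index + 2  # 1-based, after the header row
    df["type"] = df["type"].str.strip().str.lower()

    cov_rows = df[df["type"].isin(_COVARIATE_KEYS)]
    cov_kwargs: dict = {}
    for _, row in cov_rows.iterrows():
        key, val = row["type"], row["value"]
        if key in ("cyp2c9", "vkorc1", "ethnicity"):
            cov_kwargs[key] = str(val).strip()
        elif key == "interval":
            cov_kwargs["dosing_interval"] = float(val)
        else:
            cov_kwargs[key] = float(val)
    if "age" not in cov_kwargs or "weight" not in cov_kwargs:
        raise SchemaError("history file must provide 'age' and 'weight' rows")
    covariates = PatientCovariates(**cov_kwargs)

    events = df[df["type"].isin(("dose", "inr"))].copy()
    unknown = df[~df["type"].isin(_COVARIATE_KEYS + ("dose", "inr"))]
    if len(unknown):
        raise SchemaError(
            "unknown record type(s): "
            + "; ".join(f"line {r.line}: {r.type!r}" for r in unknown.itertuples())
        )
    events["t"] = _parse_times(events["time"], events["line"])
    try:
        events["v"] = events["value"].astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"non-numeric dose/INR value in {path.name}") from exc

    for kind in ("dose", "inr"):
        sub = events[events["type"] == kind]
        bad = sub[sub["t"].diff() < 0]
        if len(bad):
            raise SchemaError(
                f"{kind} rows out of time order at line(s): "
                + ", ".join(str(l) for l in bad["line"])
            )

    doses = tuple(
        DoseEvent(time=float(r.t), amount=float(r.v))
        for r in events[events["type"] == "dose"].itertuples()
    )
    obs = tuple(
        INRObservation(time=float(r.t), value=float(r.v))
        for r in events[events["type"] == "inr"].itertuples()
    )
    if doses:
        n_pre = sum(o.time < doses[0].time for o in obs)
        if n_pre:
            log.warning(
                "%d INR observation(s) precede the first dose; they inform "
                "the baseline only", n_pre,
            )
    history = PatientHistory(covariates=covariates, doses=doses, observations=obs)
    span = history.end_time - (doses[0].time if doses else 0.0)
    log.info("read %s: %d dose rows, %d INR rows, %.0f h span",
             path.name, len(doses), len(obs), span)
    return history


def write_history(history: PatientHistory, path: str | Path) -> None:
    """Write a history in the same long format `read_history` accepts."""
    cov = history.covariates
    rows: list[tuple] = [
        ("age", "", cov.age),
        ("weight", "", cov.weight),
    ]
    for key, val in (
        ("cyp2c9", cov.cyp2c9), ("vkorc1", cov.vkorc1),
        ("ethnicity", cov.ethnicity), ("baseline_inr", cov.baseline_inr),
        ("target_low", cov.target_low), ("target_high", cov.target_high),
        ("interval", cov.dosing_interval),
    ):
        if val is not None:
            rows.append((key, "", val))
    rows += [("dose", e.time, e.amount) for e in history.doses]
    rows += [("inr", o.time, o.value) for o in history.observations]
    pd.DataFrame(rows, columns=["type", "time", "value"]).to_csv(path, index=False)
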