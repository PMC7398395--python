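"""Dataset I/O: reading the NONMEM-style CSV back into analysis tables.

The on-disk dialect is a single long-format CSV (comma, UTF-8, header
row, "." for missing) as written by :func:`hairpk.simulate.export_dataset`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simulate import BMI_CODES, CAREGIVER_CODES, EXPORT_COLUMNS, OCCASION_CODES

__all__ = ["read_dataset", "to_analysis_frame", "SchemaError"]

log = logging.getLogger("hairpk")

_BMI_DECODE = {v: k for k, v in BMI_CODES.items()}
_CG_DECODE = {v: k for k, v in CAREGIVER_CODES.items()}
_OCC_DECODE = {v: k for k, v in OCCASION_CODES.items()}


class SchemaError(ValueError):
    """The dataset file violates the documented column contract."""


def read_dataset(path, analyte: str = "ATV") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse an exported dataset CSV into (covariates, observations).

    Validates the schema and category encodings; raises SchemaError
    with row/column context on violations.
    """
    raw = pd.read_csv(path, na_values=["."], dtype={"DV": float, "AMT": float})
    if raw.empty:
        raise SchemaError(f"{path}: file contains no records")
    missing = [c for c in EXPORT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    extra = [c for c in raw.columns if c not in EXPORT_COLUMNS]
    if extra:
        raise SchemaError(f"{path}: unexpected columns {extra}")
    for col, decode in (("BMI", _BMI_DECODE), ("CG", _CG_DECODE), ("OCC", _OCC_DECODE)):
        bad = set(raw[col].dropna().astype(int)) - set(decode)
        if bad:
            rows = raw.index[raw[col].isin(bad)].tolist()[:5]
            raise SchemaError(
                f"{path}: unknown {col} level(s) {sorted(bad)} (rows {rows})"
            )
    obs_rows = raw[raw["EVID"] == 0]
    if obs_rows.empty:
        raise SchemaError(f"{path}: no observation (EVID=0) records")
    non_blq = obs_rows[obs_rows["BLQ"] == 0]
    if non_blq["DV"].isna().any():
        rows = non_blq.index[non_blq["DV"].isna()].tolist()[:5]
        raise SchemaError(f"{path}: non-numeric DV on quantifiable rows {rows}")

    cov_rows = raw.groupby("ID", sort=True).first().reset_index()
    covariates = pd.DataFrame(
        {
            "subject": cov_rows["ID"],
            "weight": cov_rows["WT"].astype(float),
            "bmi_category": cov_rows["BMI"].astype(int).map(_BMI_DECODE),
            "caregiver": cov_rows["CG"].astype(int).map(_CG_DECODE),
            "adherence_vas": cov_rows["VAS"].astype(float),
        }
    )
    observations = pd.DataFrame(
        {
            "subject": obs_rows["ID"].to_numpy(),
            "occasion": obs_rows["OCC"].astype(int).map(_OCC_DECODE).to_numpy(),
            "time_h": obs_rows["TIME"].astype(float).to_numpy(),
            "analyte": analyte,
            "concentration": obs_rows["DV"].to_numpy(float),
            "adherence_vas": obs_rows["VAS"].to_numpy(float),
            "blq": obs_rows["BLQ"].astype(bool).to_numpy(),
            "lloq": obs_rows["LLOQ"].to_numpy(float),
        }
    ).reset_index(drop=True)
    return covariates, observations


def to_analysis_frame(
    covariates: pd.DataFrame, observations: pd.DataFrame, analyte: str = "ATV"
) -> pd.DataFrame:
    """Merge covariates onto one analyte's observations.

    Produces the long frame consumed by :mod:`hairpk.estimation`
    (columns: subject, occasion, concentration, blq, weight,
    bmi_category, caregiver, adherence_vas).
    """
    obs = observations
    if "analyte" in obs.columns:
        obs = obs.loc[obs["analyte"] == analyte]
    cols = ["subject", "weight", "bmi_category", "caregiver"]
    merged = obs.merge(covariates[cols], on="subject", how="left", validate="m:1")
    if merged["weight"].isna().any():
        bad = sorted(set(merged.loc[merged["weight"].isna(), "subject"]))
        raise ValueError(f"observations reference unknown subjects: {bad[:5]}")
    if "adherence_vas" not in merged.columns:
        merged = merged.merge(
            covariates[["subject", "adherence_vas"]], on="subject", how="left"
        )
    keep = [
        "subject", "occasion", "concentration", "blq",
        "weight", "bmi_category", "caregiver", "adherence_vas",
    ]
    if "time_h" in merged.columns:
        keep.append("time_h")
    return merged[keep].reset_index(drop=True)
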