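"""Synthetic cohorts with the statistical structure of the hair study.

Emulates: n=50 adolescents on once-daily boosted atazanavir, hair
sampled at enrolment (day 0) and follow-up (day 90), covariate
distributions matching the published cohort summary (BMI-for-age,
caregiver, adherence VAS 84.2 +/- 18.1 truncated to [30, 100]), and
assay-range censoring (LLOQ 0.05 ng/mg ATV, 0.01 ng/mg RTV).

Body weight is not published; it is drawn log-normally (median 50 kg,
CV 20%, clipped to 25-90 kg) as a plausible adolescent distribution.
Recovery-mode experiments default to n=500 subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .population import (
    BMI_LEVELS,
    CAREGIVER_LEVELS,
    ModelParameters,
    atv_final_model,
    rtv_final_model,
)
from .structural import trough_core

__all__ = [
    "CohortSpec",
    "simulate_cohort",
    "apply_blq",
    "export_dataset",
    "EXPORT_COLUMNS",
    "BMI_CODES",
    "CAREGIVER_CODES",
    "OCCASION_CODES",
]

#: Assay quantification ranges, ng/mg hair.
DEFAULT_LLOQ = {"ATV": 0.05, "RTV": 0.01}
DEFAULT_ULOQ = {"ATV": 20.0, "RTV": 4.0}

#: Published cohort covariate frequencies (printed percentages,
#: normalized to sum to one).
DEFAULT_BMI_PROPS = {"normal": 54 / 99, "thin": 30 / 99, "overweight": 15 / 99}
DEFAULT_CAREGIVER_PROPS = {
    "grandparent": 0.40,
    "parent": 0.20,
    "uncle/aunt": 0.30,
    "sibling": 0.10,
}


@dataclass
class CohortSpec:
    """Everything needed to draw one virtual cohort, deterministically."""

    n_subjects: int = 50
    seed: int = 0
    female_prop: float = 0.54
    bmi_props: dict = field(default_factory=lambda: dict(DEFAULT_BMI_PROPS))
    caregiver_props: dict = field(default_factory=lambda: dict(DEFAULT_CAREGIVER_PROPS))
    adherence_mean: float = 84.2
    adherence_sd: float = 18.1
    adherence_bounds: tuple = (30.0, 100.0)
    weight_median: float = 50.0
    weight_cv: float = 0.20
    weight_bounds: tuple = (25.0, 90.0)
    occasion_days: tuple = (0, 90)
    analytes: tuple = ("ATV", "RTV")
    models: dict = field(default_factory=lambda: {"ATV": atv_final_model(),
                                                  "RTV": rtv_final_model()})
    lloq: dict = field(default_factory=lambda: dict(DEFAULT_LLOQ))
    uloq: dict = field(default_factory=lambda: dict(DEFAULT_ULOQ))
    #: adherence drawn once per subject (published summary is per subject);
    #: set True to redraw at each occasion
    adherence_per_occasion: bool = False
    #: apply assay LLOQ censoring (the study's data structure). Set
    #: False for estimator-validation cohorts: excluding BLQ records
    #: (M1) from a censored cohort leaves the refit estimand slightly
    #: below the generating value, so recovery experiments simulate the
    #: assay without its quantification limit.
    censoring: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name, props, levels in (
            ("bmi_props", self.bmi_props, BMI_LEVELS),
            ("caregiver_props", self.caregiver_props, CAREGIVER_LEVELS),
        ):
            if set(props) != set(levels):
                raise ValueError(f"{name} must have levels {levels}")
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if len(set(self.occasion_days)) != len(self.occasion_days):
            raise ValueError("occasion days must be distinct")
        for a in self.analytes:
            if self.lloq[a] <= 0 or self.lloq[a] >= self.uloq[a]:
                raise ValueError(f"need 0 < LLOQ < ULOQ for {a}")

    def to_yaml(self, path) -> None:
        _cohortspec_to_yaml(self, path)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        return _cohortspec_from_yaml(path)


def _cohortspec_to_yaml(spec: "CohortSpec", path) -> None:
    import yaml
    from dataclasses import asdict

    doc = asdict(spec)
    doc["models"] = {a: m.to_dict() for a, m in spec.models.items()}
    doc["adherence_bounds"] = list(spec.adherence_bounds)
    doc["weight_bounds"] = list(spec.weight_bounds)
    doc["occasion_days"] = list(spec.occasion_days)
    doc["analytes"] = list(spec.analytes)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _cohortspec_from_yaml(path) -> "CohortSpec":
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    doc["models"] = {a: ModelParameters.from_dict(d) for a, d in doc["models"].items()}
    for key in ("adherence_bounds", "weight_bounds", "occasion_days", "analytes"):
        doc[key] = tuple(doc[key])
    return CohortSpec(**doc)


_OCCASION_NAMES = ("enrolment", "follow-up")


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort: a covariate table and a BLQ-flagged observation table.

    Returns ``(covariates, observations)``. The observation table keeps
    the pre-censoring value in ``concentration`` and sets ``blq`` where
    it falls below the analyte LLOQ; exports mask those values.
    Byte-identical output for equal specs (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    subjects = np.arange(1, n + 1)

    sex = np.where(rng.random(n) < spec.female_prop, "female", "male")
    bmi = rng.choice(list(spec.bmi_props), size=n, p=list(spec.bmi_props.values()))
    caregiver = rng.choice(
        list(spec.caregiver_props), size=n, p=list(spec.caregiver_props.values())
    )
    lo, hi = spec.adherence_bounds
    a, b = (lo - spec.adherence_mean) / spec.adherence_sd, (hi - spec.adherence_mean) / spec.adherence_sd
    vas = truncnorm.rvs(a, b, loc=spec.adherence_mean, scale=spec.adherence_sd,
                        size=n, random_state=rng)
    sigma_w = float(np.sqrt(np.log1p(spec.weight_cv**2)))
    weight = np.exp(rng.normal(np.log(spec.weight_median), sigma_w, size=n))
    weight = np.clip(weight, *spec.weight_bounds)

    cov = pd.DataFrame(
        {
            "subject": subjects,
            "sex": sex,
            "weight": weight,
            "bmi_category": bmi,
            "caregiver": caregiver,
            "adherence_vas": vas,
        }
    )

    rows = []
    for analyte in spec.analytes:
        model = spec.models[analyte]
        fe = model.fixed_effects
        re = model.random_effects
        res = model.residual
        # per-subject log-normal random effects (shared across occasions);
        # always drawn to keep the rng stream layout stable, but they
        # reach the hair prediction only under the individual-trough
        # convention (plasma_iiv_in_hair)
        eta_cl = rng.normal(0, np.sqrt(re.omega2_cl), n) if re.omega2_cl > 0 else np.zeros(n)
        eta_k12 = rng.normal(0, np.sqrt(re.omega2_k12), n) if re.omega2_k12 > 0 else np.zeros(n)
        eta_vc = rng.normal(0, np.sqrt(re.omega2_vc), n) if re.omega2_vc > 0 else np.zeros(n)
        w = weight / model.ref_weight
        if model.plasma_iiv_in_hair:
            cl_i = model.plasma.cl * w**0.75 * np.exp(eta_cl)
            k12_i = model.plasma.k12 * np.exp(eta_k12)
            vc_i = model.plasma.vc * w * np.exp(eta_vc)
        else:
            cl_i = model.plasma.cl * w**0.75
            k12_i = np.full(n, model.plasma.k12)
            vc_i = model.plasma.vc * w
        trough = model.hair_scale * trough_core(
            model.regimen.dose_amount, model.regimen.interval, k12_i, cl_i, vc_i
        )
        for occ_idx, (occ_name, occ_day) in enumerate(
            zip(_OCCASION_NAMES, spec.occasion_days)
        ):
            if spec.adherence_per_occasion and occ_idx > 0:
                vas_occ = truncnorm.rvs(
                    a, b, loc=spec.adherence_mean, scale=spec.adherence_sd,
                    size=n, random_state=rng,
                )
            else:
                vas_occ = vas
            factors = (
                np.maximum(1.0 + fe.beta_occasion_enrolment * (occ_name == "enrolment"), 1e-3)
                * np.maximum(1.0 + fe.beta_adherence * (vas_occ - model.adherence_ref), 1e-3)
                * np.maximum(
                    1.0
                    + fe.beta_bmi_thin * (bmi == "thin")
                    + fe.beta_bmi_overweight * (bmi == "overweight"),
                    1e-3,
                )
                * np.maximum(
                    1.0
                    + fe.beta_caregiver_parent * (caregiver == "parent")
                    + fe.beta_caregiver_uncle_aunt * (caregiver == "uncle/aunt")
                    + fe.beta_caregiver_sibling * (caregiver == "sibling"),
                    1e-3,
                )
            )
            frac_i = fe.frac_pop * factors
            if re.omega2_frac_iov > 0:
                frac_i = frac_i * np.exp(
                    rng.normal(0, np.sqrt(re.omega2_frac_iov), n)
                )
            f = frac_i * trough
            eps_prop = rng.normal(0, res.sd_prop, n) if res.sd_prop > 0 else np.zeros(n)
            eps_add = rng.normal(0, res.sd_add, n) if res.sd_add > 0 else np.zeros(n)
            y = f * (1.0 + eps_prop) + eps_add
            rows.append(
                pd.DataFrame(
                    {
                        "subject": subjects,
                        "occasion": occ_name,
                        "time_h": 24.0 * occ_day,
                        "analyte": analyte,
                        "concentration": y,
                        "adherence_vas": vas_occ,
                        "prediction": f,
                    }
                )
            )
    obs = pd.concat(rows, ignore_index=True)
    if spec.censoring:
        obs, _counts = apply_blq(obs, spec.lloq)
    else:
        obs["blq"] = False
        obs["lloq"] = obs["analyte"].map(spec.lloq).astype(float)
    obs = obs.sort_values(["analyte", "subject", "time_h"], kind="mergesort")
    return cov, obs.reset_index(drop=True)


def apply_blq(observations: pd.DataFrame, lloq: dict) -> tuple[pd.DataFrame, dict]:
    """Flag records below the analyte LLOQ (value exactly at LLOQ passes).

    Returns the flagged table and a per-analyte summary
    {analyte: {'n': records, 'blq': flagged}}. Values are retained in
    the frame (masking happens at export).
    """
    out = observations.copy()
    for a in out.get("analyte", pd.Series(dtype=str)).unique():
        if a not in lloq or lloq[a] <= 0:
            raise ValueError(f"positive LLOQ required for analyte {a!r}")
    if out.empty:
        out["blq"] = pd.Series(dtype=bool)
        out["lloq"] = pd.Series(dtype=float)
        return out, {}
    lv = out["analyte"].map(lloq).astype(float)
    out["blq"] = out["concentration"] < lv
    out["lloq"] = lv
    counts = {
        a: {"n": int((out["analyte"] == a).sum()),
            "blq": int(out.loc[out["analyte"] == a, "blq"].sum())}
        for a in out["analyte"].unique()
    }
    return out, counts


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

EXPORT_COLUMNS = [
    "ID", "TIME", "DV", "AMT", "EVID", "MDV", "OCC",
    "WT", "BMI", "CG", "VAS", "BLQ", "LLOQ",
]

BMI_CODES = {"normal": 0, "thin": 1, "overweight": 2}
CAREGIVER_CODES = {"grandparent": 0, "parent": 1, "uncle/aunt": 2, "sibling": 3}
OCCASION_CODES = {"enrolment": 1, "follow-up": 2}


def export_dataset(
    covariates: pd.DataFrame,
    observations: pd.DataFrame,
    path,
    analyte: str = "ATV",
    dose_amount: float | None = None,
) -> pd.DataFrame:
    """Write one analyte as a NONMEM-style long CSV and return the frame.

    Encodings: dose rows EVID=1/MDV=1 with AMT at TIME 0; observation
    rows EVID=0 with DV in ng/mg; BLQ rows have DV masked to "." and
    MDV=1; OCC 1=enrolment 2=follow-up; BMI 0=normal 1=thin
    2=overweight; CG 0=grandparent 1=parent 2=uncle/aunt 3=sibling.
    Missing values are ".".
    """
    obs = observations.loc[observations["analyte"] == analyte]
    unknown = set(obs["subject"]) - set(covariates["subject"])
    if unknown:
        raise ValueError(f"observations reference unknown subjects: {sorted(unknown)}")
    if dose_amount is None:
        dose_amount = 300.0 if analyte == "ATV" else 100.0
    cov = covariates.set_index("subject")
    rows = []
    for sid in covariates["subject"]:
        c = cov.loc[sid]
        base = {
            "ID": sid,
            "WT": round(float(c["weight"]), 4),
            "BMI": BMI_CODES[c["bmi_category"]],
            "CG": CAREGIVER_CODES[c["caregiver"]],
        }
        rows.append(
            base | {
                "TIME": 0.0, "DV": ".", "AMT": dose_amount, "EVID": 1, "MDV": 1,
                "OCC": 1, "VAS": round(float(c["adherence_vas"]), 4),
                "BLQ": 0, "LLOQ": ".",
            }
        )
        for _, r in obs.loc[obs["subject"] == sid].iterrows():
            blq = bool(r["blq"])
            rows.append(
                base | {
                    "TIME": float(r["time_h"]),
                    "DV": "." if blq else round(float(r["concentration"]), 6),
                    "AMT": ".", "EVID": 0, "MDV": int(blq),
                    "OCC": OCCASION_CODES[r["occasion"]],
                    "VAS": round(float(r["adherence_vas"]), 4),
                    "BLQ": int(blq), "LLOQ": float(r["lloq"]),
                }
            )
    frame = pd.DataFrame(rows, columns=EXPORT_COLUMNS)
    frame.to_csv(path, index=False)
    return frame
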