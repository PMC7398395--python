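"""Population layer: covariates, fixed/random effects, residual error.

Maps population parameters to individual ones:

* plasma: allometric body-weight scaling (CL exponent 0.75, Vc exponent 1)
  times log-normal inter-individual random effects;
* hair fraction: proportional-linear covariate factors
  ``frac_i = frac_pop * prod(1 + beta_k * x_k)`` with reference levels
  (follow-up occasion, normal BMI-for-age, grandparent caregiver,
  adherence at the cohort mean) contributing factor 1;
* residual error: combined additive + proportional,
  ``sd(f) = sqrt((sd_prop * f)^2 + sd_add^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

from .structural import (
    ATV_DOSE,
    ATV_PLASMA,
    RTV_DOSE,
    RTV_PLASMA,
    DoseRegimen,
    HAIR_UNIT_PER_MG_L,
    PlasmaParams,
    trough_core,
)

__all__ = [
    "OCCASIONS",
    "BMI_LEVELS",
    "CAREGIVER_LEVELS",
    "SubjectCovariates",
    "FixedEffects",
    "RandomEffectSpec",
    "ResidualSpec",
    "IndividualParams",
    "ModelParameters",
    "CovariateDomainError",
    "individual_plasma_params",
    "individual_frac",
    "residual_sd",
    "simulate_observation",
    "atv_final_model",
    "rtv_final_model",
    "neutral_start",
]

OCCASIONS = ("enrolment", "follow-up")
BMI_LEVELS = ("normal", "thin", "overweight")
CAREGIVER_LEVELS = ("grandparent", "parent", "uncle/aunt", "sibling")

#: Cohort mean adherence VAS used to center the adherence effect.
DEFAULT_ADHERENCE_REF = 84.2
#: Reference body weight for allometric scaling (kg).
DEFAULT_REF_WEIGHT = 70.0
#: Floor applied to each covariate factor inside likelihood evaluation
#: (the public individual_frac raises instead).
FACTOR_FLOOR = 1e-3


class CovariateDomainError(ValueError):
    """A covariate factor (1 + beta*x) fell to zero or below."""


@dataclass(frozen=True)
class SubjectCovariates:
    subject: int | str
    occasion: str = "follow-up"
    weight: float = 50.0
    bmi_category: str = "normal"
    caregiver: str = "grandparent"
    adherence_vas: float = DEFAULT_ADHERENCE_REF

    def __post_init__(self) -> None:
        if self.occasion not in OCCASIONS:
            raise ValueError(f"unknown occasion {self.occasion!r}; expected one of {OCCASIONS}")
        if self.bmi_category not in BMI_LEVELS:
            raise ValueError(f"unknown BMI category {self.bmi_category!r}; expected one of {BMI_LEVELS}")
        if self.caregiver not in CAREGIVER_LEVELS:
            raise ValueError(f"unknown caregiver {self.caregiver!r}; expected one of {CAREGIVER_LEVELS}")
        if not 0 <= self.adherence_vas <= 100:
            raise ValueError(f"adherence_vas must lie in [0, 100], got {self.adherence_vas}")
        if self.weight <= 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")


@dataclass
class FixedEffects:
    """Population hair fraction and its proportional covariate effects."""

    frac_pop: float = 0.16
    beta_occasion_enrolment: float = 0.0
    beta_adherence: float = 0.0
    beta_bmi_thin: float = 0.0
    beta_bmi_overweight: float = 0.0
    beta_caregiver_parent: float = 0.0
    beta_caregiver_uncle_aunt: float = 0.0
    beta_caregiver_sibling: float = 0.0

    def __post_init__(self) -> None:
        if self.frac_pop <= 0:
            raise ValueError(f"frac_pop must be > 0, got {self.frac_pop}")


@dataclass
class RandomEffectSpec:
    """Variances (omega^2) of log-normal inter-individual effects.

    ``omega2_frac_iov`` is an optional inter-occasion variance on the
    hair fraction, default off (the published model reports none).
    """

    omega2_cl: float = 1.04
    omega2_k12: float = 0.45
    omega2_vc: float = 0.50
    omega2_frac_iov: float = 0.0

    def __post_init__(self) -> None:
        for name in ("omega2_cl", "omega2_k12", "omega2_vc", "omega2_frac_iov"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ResidualSpec:
    """Combined residual error: additive SD (hair units) + proportional SD."""

    sd_add: float = 0.30
    sd_prop: float = 0.50

    def __post_init__(self) -> None:
        if self.sd_add < 0 or self.sd_prop < 0:
            raise ValueError("residual SDs must be >= 0")
        if self.sd_add == 0 and self.sd_prop == 0:
            raise ValueError("sd_add and sd_prop cannot both be 0")


@dataclass
class IndividualParams:
    cl_i: float
    k12_i: float
    vc_i: float
    frac_i: float

    def __post_init__(self) -> None:
        for name in ("cl_i", "k12_i", "vc_i", "frac_i"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ModelParameters:
    """Full parameter set of the joint plasma-hair model for one analyte.

    ``estimated`` lists the names of parameters free in estimation; all
    others are fixed. Plasma constants are always fixed (published
    steady-state values).
    """

    plasma: PlasmaParams = field(default_factory=lambda: ATV_PLASMA)
    regimen: DoseRegimen = field(default_factory=lambda: ATV_DOSE)
    fixed_effects: FixedEffects = field(default_factory=FixedEffects)
    random_effects: RandomEffectSpec = field(default_factory=RandomEffectSpec)
    residual: ResidualSpec = field(default_factory=ResidualSpec)
    adherence_ref: float = DEFAULT_ADHERENCE_REF
    ref_weight: float = DEFAULT_REF_WEIGHT
    hair_scale: float = HAIR_UNIT_PER_MG_L
    #: If True, the subject's plasma random effects enter the hair
    #: prediction through the individual steady-state trough. Default
    #: False: at steady state the hair uptake integral Frac*k20*A2
    #: equals Frac times the absorbed dose, so plasma IIV cancels out
    #: of hair accumulation and the hair anchor is the weight-adjusted
    #: typical trough (see docs/methods.md).
    plasma_iiv_in_hair: bool = False
    estimated: tuple[str, ...] = (
        "frac_pop",
        "sd_add",
        "sd_prop",
    )

    # --- flat parameter access used by estimation/serialization ---------
    _FE_NAMES = (
        "frac_pop",
        "beta_occasion_enrolment",
        "beta_adherence",
        "beta_bmi_thin",
        "beta_bmi_overweight",
        "beta_caregiver_parent",
        "beta_caregiver_uncle_aunt",
        "beta_caregiver_sibling",
    )
    _RE_NAMES = ("omega2_cl", "omega2_k12", "omega2_vc", "omega2_frac_iov")
    _RES_NAMES = ("sd_add", "sd_prop")

    def get(self, name: str) -> float:
        for holder, names in (
            (self.fixed_effects, self._FE_NAMES),
            (self.random_effects, self._RE_NAMES),
            (self.residual, self._RES_NAMES),
        ):
            if name in names:
                return getattr(holder, name)
        raise KeyError(name)

    def with_values(self, **values: float) -> "ModelParameters":
        """Return a copy with the given flat parameters replaced."""
        fe = {k: v for k, v in values.items() if k in self._FE_NAMES}
        re_ = {k: v for k, v in values.items() if k in self._RE_NAMES}
        res = {k: v for k, v in values.items() if k in self._RES_NAMES}
        unknown = set(values) - set(fe) - set(re_) - set(res)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        return replace(
            self,
            fixed_effects=replace(self.fixed_effects, **fe),
            random_effects=replace(self.random_effects, **re_),
            residual=replace(self.residual, **res),
        )

    # --- YAML / dict round trip ------------------------------------------
    def to_dict(self) -> dict:
        return {
            "plasma": {"k12": self.plasma.k12, "cl": self.plasma.cl, "vc": self.plasma.vc},
            "regimen": {
                "dose_amount": self.regimen.dose_amount,
                "interval": self.regimen.interval,
            },
            "fixed_effects": asdict(self.fixed_effects),
            "random_effects": asdict(self.random_effects),
            "residual": asdict(self.residual),
            "adherence_ref": self.adherence_ref,
            "ref_weight": self.ref_weight,
            "hair_scale": self.hair_scale,
            "plasma_iiv_in_hair": self.plasma_iiv_in_hair,
            "estimated": list(self.estimated),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelParameters":
        return cls(
            plasma=PlasmaParams(**doc["plasma"]),
            regimen=DoseRegimen(**doc["regimen"]),
            fixed_effects=FixedEffects(**doc["fixed_effects"]),
            random_effects=RandomEffectSpec(**doc["random_effects"]),
            residual=ResidualSpec(**doc["residual"]),
            adherence_ref=doc.get("adherence_ref", DEFAULT_ADHERENCE_REF),
            ref_weight=doc.get("ref_weight", DEFAULT_REF_WEIGHT),
            hair_scale=doc.get("hair_scale", HAIR_UNIT_PER_MG_L),
            plasma_iiv_in_hair=bool(doc.get("plasma_iiv_in_hair", False)),
            estimated=tuple(doc.get("estimated", ())),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def atv_final_model() -> ModelParameters:
    """Published final atazanavir model (simulation truth for recovery)."""
    return ModelParameters(
        plasma=ATV_PLASMA,
        regimen=ATV_DOSE,
        fixed_effects=FixedEffects(
            frac_pop=0.16,
            beta_occasion_enrolment=-0.30,
            beta_adherence=0.02,
            beta_bmi_thin=0.54,
            beta_bmi_overweight=-0.21,
            beta_caregiver_parent=0.53,
            beta_caregiver_uncle_aunt=0.12,
            beta_caregiver_sibling=-0.54,
        ),
        random_effects=RandomEffectSpec(
            omega2_cl=1.04, omega2_k12=0.45, omega2_vc=0.50
        ),
        residual=ResidualSpec(sd_add=0.30, sd_prop=0.50),
        estimated=(
            "frac_pop",
            "beta_occasion_enrolment",
            "beta_adherence",
            "beta_bmi_thin",
            "beta_bmi_overweight",
            "beta_caregiver_parent",
            "beta_caregiver_uncle_aunt",
            "beta_caregiver_sibling",
            "sd_add",
            "sd_prop",
        ),
    )


def rtv_final_model() -> ModelParameters:
    """Published final ritonavir model (simulation truth for recovery)."""
    return ModelParameters(
        plasma=RTV_PLASMA,
        regimen=RTV_DOSE,
        fixed_effects=FixedEffects(
            frac_pop=0.18,
            beta_occasion_enrolment=-0.42,
            beta_adherence=0.02,
        ),
        random_effects=RandomEffectSpec(
            omega2_cl=0.28, omega2_k12=0.45, omega2_vc=0.50
        ),
        residual=ResidualSpec(sd_add=0.34, sd_prop=0.26),
        estimated=(
            "frac_pop",
            "beta_occasion_enrolment",
            "beta_adherence",
            "sd_add",
            "sd_prop",
        ),
    )


def neutral_start(analyte: str = "ATV", estimated: tuple[str, ...] | None = None) -> ModelParameters:
    """Generic starting values for estimation (not the published answers).

    Plasma constants and the fixed variance components keep their
    published values (they are not estimated); everything free starts
    from bland initials: frac_pop 0.10, covariate coefficients 0,
    omega2_CL 0.5, residual SDs 0.2 / 0.3.
    """
    final = atv_final_model() if analyte.upper() == "ATV" else rtv_final_model()
    if estimated is None:
        estimated = final.estimated
    return replace(
        final,
        fixed_effects=FixedEffects(frac_pop=0.10),
        residual=ResidualSpec(sd_add=0.2, sd_prop=0.3),
        estimated=tuple(estimated),
    )


# ---------------------------------------------------------------------------
# individual-level mappings
# ---------------------------------------------------------------------------

def individual_plasma_params(
    pop: PlasmaParams,
    eta,
    weight: float,
    ref_weight: float = DEFAULT_REF_WEIGHT,
) -> IndividualParams:
    """Allometric + log-normal individual plasma parameters.

    ``eta`` is a mapping or 3-sequence (eta_cl, eta_k12, eta_vc).
    CL scales with (W/W_ref)^0.75, Vc with (W/W_ref)^1.
    """
    if weight <= 0 or ref_weight <= 0:
        raise ValueError("weight and ref_weight must be > 0")
    if hasattr(eta, "get"):
        e_cl = eta.get("cl", 0.0)
        e_k12 = eta.get("k12", 0.0)
        e_vc = eta.get("vc", 0.0)
    else:
        e_cl, e_k12, e_vc = eta
    w = weight / ref_weight
    return IndividualParams(
        cl_i=float(pop.cl * w**0.75 * np.exp(e_cl)),
        k12_i=float(pop.k12 * np.exp(e_k12)),
        vc_i=float(pop.vc * w * np.exp(e_vc)),
        frac_i=0.0,  # filled in by individual_frac
    )


def covariate_factors(fe: FixedEffects, cov: SubjectCovariates, adherence_ref: float):
    """The four named multiplicative factors for one subject-occasion."""
    return {
        "occasion": 1.0 + fe.beta_occasion_enrolment * (cov.occasion == "enrolment"),
        "adherence": 1.0 + fe.beta_adherence * (cov.adherence_vas - adherence_ref),
        "bmi": 1.0
        + fe.beta_bmi_thin * (cov.bmi_category == "thin")
        + fe.beta_bmi_overweight * (cov.bmi_category == "overweight"),
        "caregiver": 1.0
        + fe.beta_caregiver_parent * (cov.caregiver == "parent")
        + fe.beta_caregiver_uncle_aunt * (cov.caregiver == "uncle/aunt")
        + fe.beta_caregiver_sibling * (cov.caregiver == "sibling"),
    }


def individual_frac(
    fe: FixedEffects,
    cov: SubjectCovariates,
    adherence_ref: float = DEFAULT_ADHERENCE_REF,
) -> float:
    """Individual hair fraction: frac_pop times the covariate factors.

    Raises CovariateDomainError naming the offending covariate if any
    factor (1 + beta*x) is <= 0.
    """
    factors = covariate_factors(fe, cov, adherence_ref)
    for name, f in factors.items():
        if f <= 0:
            raise CovariateDomainError(
                f"covariate factor {name!r} is non-positive ({f:.4g}) "
                f"for subject {cov.subject}"
            )
    return fe.frac_pop * float(np.prod(list(factors.values())))


def residual_sd(f, r: ResidualSpec):
    """Combined residual SD at prediction ``f``: sqrt((sd_prop f)^2 + sd_add^2)."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("prediction f must be >= 0")
    out = np.sqrt((r.sd_prop * f) ** 2 + r.sd_add**2)
    return out if out.ndim else float(out)


def predict_individual(
    ind: IndividualParams, regimen: DoseRegimen, hair_scale: float = HAIR_UNIT_PER_MG_L
) -> float:
    """Deterministic hair-scale prediction for one individual."""
    trough = trough_core(regimen.dose_amount, regimen.interval, ind.k12_i, ind.cl_i, ind.vc_i)
    return float(ind.frac_i * hair_scale * trough)


def simulate_observation(
    ind: IndividualParams,
    regimen: DoseRegimen,
    r: ResidualSpec,
    rng,
    hair_scale: float = HAIR_UNIT_PER_MG_L,
) -> float:
    """One simulated hair concentration: y = f (1 + eps_prop) + eps_add.

    ``rng`` is a seed or numpy Generator. Negative draws are retained
    (BLQ censoring is applied downstream).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    f = predict_individual(ind, regimen, hair_scale)
    eps_prop = rng.normal(0.0, r.sd_prop) if r.sd_prop > 0 else 0.0
    eps_add = rng.normal(0.0, r.sd_add) if r.sd_add > 0 else 0.0
    return float(f * (1.0 + eps_prop) + eps_add)
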