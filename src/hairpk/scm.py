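"""Stepwise covariate model building on the hair fraction.

Forward inclusion then backward elimination of covariate-parameter
relations, judged by the drop in OFV against chi-square quantiles:
alpha = 0.05 forward, 0.01 backward, at each candidate's degrees of
freedom. A strict 1-df compatibility mode reproduces the conventional
printed constants 3.83 (forward) and 6.64 (backward) regardless of df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd
from scipy.stats import chi2

from .estimation import FitResult, FitSpec, fit
from .population import ModelParameters

__all__ = [
    "CandidateRelation",
    "STANDARD_CANDIDATES",
    "ScmStep",
    "ScmTrace",
    "forward_step",
    "backward_step",
    "run_scm",
]

log = logging.getLogger("hairpk")

#: Printed 1-df thresholds used by the compatibility mode.
STRICT_FORWARD_THRESHOLD = 3.83
STRICT_BACKWARD_THRESHOLD = 6.64


@dataclass(frozen=True)
class CandidateRelation:
    """A covariate relation on the hair fraction: name -> beta parameters."""

    name: str
    betas: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.betas:
            raise ValueError("a relation needs at least one coefficient")

    @property
    def df(self) -> int:
        return len(self.betas)


STANDARD_CANDIDATES = {
    "occasion": CandidateRelation("occasion", ("beta_occasion_enrolment",)),
    "adherence": CandidateRelation("adherence", ("beta_adherence",)),
    "bmi": CandidateRelation("bmi", ("beta_bmi_thin", "beta_bmi_overweight")),
    "caregiver": CandidateRelation(
        "caregiver",
        ("beta_caregiver_parent", "beta_caregiver_uncle_aunt", "beta_caregiver_sibling"),
    ),
}


def _threshold(df: int, phase: str, strict_1df: bool) -> float:
    if strict_1df:
        return STRICT_FORWARD_THRESHOLD if phase == "forward" else STRICT_BACKWARD_THRESHOLD
    alpha = 0.05 if phase == "forward" else 0.01
    return float(chi2.ppf(1.0 - alpha, df))


@dataclass
class ScmStep:
    phase: str
    candidate: str
    ofv: float
    delta_ofv: float
    df: int
    threshold: float
    decision: str          # accepted | rejected | removed | retained | skipped
    cumulative_df: int = 0


@dataclass
class ScmTrace:
    steps: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @property
    def cumulative_df(self) -> int:
        return max((s.cumulative_df for s in self.steps), default=0)


def _with_relation(model: ModelParameters, rel: CandidateRelation) -> ModelParameters:
    """Add a relation's coefficients to the estimated set (initial 0)."""
    m = model.with_values(**{b: 0.0 for b in rel.betas})
    return replace(m, estimated=tuple(model.estimated) + rel.betas)


def _without_relation(model: ModelParameters, rel: CandidateRelation) -> ModelParameters:
    m = model.with_values(**{b: 0.0 for b in rel.betas})
    return replace(m, estimated=tuple(n for n in model.estimated if n not in rel.betas))


def _fit(model: ModelParameters, dataset: pd.DataFrame, **fit_options) -> FitResult:
    spec = FitSpec(initial=model, compute_se=False, **fit_options)
    return fit(dataset, spec)


def forward_step(
    current: FitResult,
    candidates,
    dataset: pd.DataFrame,
    strict_1df: bool = False,
    **fit_options,
):
    """Try each candidate; return (best_relation, best_fit, steps).

    A candidate is eligible when its OFV drop exceeds the df-adjusted
    chi2(0.05) threshold; the largest drop wins, ties broken by fewer
    df then lexicographic name. Returns (None, None, steps) when no
    candidate passes.
    """
    steps: list[ScmStep] = []
    results = []
    for rel in sorted(candidates, key=lambda r: r.name):
        if any(b in current.params.estimated for b in rel.betas):
            raise ValueError(f"candidate {rel.name!r} is already in the model")
        thr = _threshold(rel.df, "forward", strict_1df)
        try:
            cand_fit = _fit(_with_relation(current.params, rel), dataset, **fit_options)
        except Exception as exc:  # noqa: BLE001 - candidate failure must not abort SCM
            log.warning("forward candidate %s failed to fit: %s", rel.name, exc)
            steps.append(ScmStep("forward", rel.name, float("nan"), float("nan"),
                                 rel.df, thr, "skipped"))
            continue
        if not cand_fit.converged:
            log.warning("forward candidate %s did not converge; skipped", rel.name)
            steps.append(ScmStep("forward", rel.name, cand_fit.ofv, float("nan"),
                                 rel.df, thr, "skipped"))
            continue
        delta = current.ofv - cand_fit.ofv
        accepted = delta > thr
        steps.append(ScmStep("forward", rel.name, cand_fit.ofv, delta, rel.df, thr,
                             "accepted" if accepted else "rejected"))
        if accepted:
            results.append((rel, cand_fit, delta))
    if not results:
        return None, None, steps
    results.sort(key=lambda t: (-t[2], t[0].df, t[0].name))
    best_rel, best_fit, _ = results[0]
    for s in steps:
        if s.candidate != best_rel.name and s.decision == "accepted":
            s.decision = "rejected"  # only the single best relation enters per round
    return best_rel, best_fit, steps


def backward_step(
    current: FitResult,
    relations,
    dataset: pd.DataFrame,
    strict_1df: bool = False,
    **fit_options,
):
    """Refit without each relation; drop the least-supported one.

    A relation survives only if removing it worsens OFV by more than
    the df-adjusted chi2(0.01) threshold. Returns
    (removed_relation, fit_without_it, steps) or (None, None, steps).
    """
    steps: list[ScmStep] = []
    removable = []
    for rel in sorted(relations, key=lambda r: r.name):
        thr = _threshold(rel.df, "backward", strict_1df)
        try:
            red_fit = _fit(_without_relation(current.params, rel), dataset, **fit_options)
        except Exception as exc:  # noqa: BLE001
            log.warning("backward removal of %s failed to fit: %s", rel.name, exc)
            steps.append(ScmStep("backward", rel.name, float("nan"), float("nan"),
                                 rel.df, thr, "skipped"))
            continue
        delta = red_fit.ofv - current.ofv
        retained = delta > thr
        steps.append(ScmStep("backward", rel.name, red_fit.ofv, delta, rel.df, thr,
                             "retained" if retained else "removed"))
        if not retained:
            removable.append((rel, red_fit, delta))
    if not removable:
        return None, None, steps
    removable.sort(key=lambda t: (t[2], t[0].name))
    rel, red_fit, _ = removable[0]
    for s in steps:
        if s.candidate != rel.name and s.decision == "removed":
            s.decision = "retained"  # only the weakest relation leaves per round
    return rel, red_fit, steps


def run_scm(
    base_model: ModelParameters,
    candidates,
    dataset: pd.DataFrame,
    strict_1df: bool = False,
    **fit_options,
):
    """Full stepwise search: forward-until-none, then backward-until-none.

    Returns (trace, final_fit, selected_relations).
    """
    candidates = list(candidates)
    trace = ScmTrace()
    current = _fit(base_model, dataset, **fit_options)
    if not current.converged:
        raise RuntimeError("base model did not converge; cannot start SCM")
    selected: list[CandidateRelation] = []
    cum_df = 0
    remaining = list(candidates)
    while remaining:
        rel, new_fit, steps = forward_step(
            current, remaining, dataset, strict_1df, **fit_options
        )
        trace.steps.extend(steps)
        if rel is None:
            break
        cum_df += rel.df
        for s in steps:
            if s.candidate == rel.name:
                s.cumulative_df = cum_df
        selected.append(rel)
        remaining = [r for r in remaining if r.name != rel.name]
        current = new_fit
    while selected:
        rel, red_fit, steps = backward_step(
            current, selected, dataset, strict_1df, **fit_options
        )
        trace.steps.extend(steps)
        if rel is None:
            break
        cum_df -= rel.df
        for s in steps:
            if s.candidate == rel.name:
                s.cumulative_df = cum_df
        selected = [r for r in selected if r.name != rel.name]
        current = red_fit
    return trace, current, selected
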