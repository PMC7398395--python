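"""Nonparametric bootstrap of the final model.

Subjects are resampled with replacement (all of a subject's occasions
travel together), the model is refit to each resample starting from the
original final estimates, and per-parameter medians with 90% percentile
confidence intervals are reported over the converged resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import FitSpec, fit
from .population import ModelParameters

__all__ = ["BootstrapResult", "resample_subjects", "run_bootstrap"]

log = logging.getLogger("hairpk")


@dataclass
class BootstrapResult:
    """Resample estimates with percentile summaries.

    ``estimates`` has one row per resample (converged flag included);
    summaries are computed over converged rows only with type-7
    (linear-interpolation) quantiles.
    """

    estimates: pd.DataFrame
    median: pd.Series = field(init=False)
    ci_lower: pd.Series = field(init=False)
    ci_upper: pd.Series = field(init=False)
    n_converged: int = field(init=False)
    reliable: bool = field(init=False)
    ci_level: float = 0.90

    def __post_init__(self) -> None:
        ok = self.estimates[self.estimates["converged"]]
        params = [c for c in self.estimates.columns if c != "converged"]
        lo = (1.0 - self.ci_level) / 2.0
        self.n_converged = len(ok)
        if self.n_converged:
            self.median = ok[params].median()
            self.ci_lower = ok[params].quantile(lo)
            self.ci_upper = ok[params].quantile(1.0 - lo)
        else:
            self.median = pd.Series(np.nan, index=params)
            self.ci_lower = pd.Series(np.nan, index=params)
            self.ci_upper = pd.Series(np.nan, index=params)
        self.reliable = self.n_converged > 0.5 * len(self.estimates)
        if not self.reliable:
            log.warning(
                "bootstrap unreliable: only %d/%d resamples converged",
                self.n_converged, len(self.estimates),
            )

    def to_csv(self, path) -> None:
        self.estimates.to_csv(path, index_label="resample")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"median": self.median, "ci_lower": self.ci_lower, "ci_upper": self.ci_upper}
        )


def resample_subjects(dataset: pd.DataFrame, rng) -> pd.DataFrame:
    """Draw n subjects with replacement from a long analysis frame.

    Drawn subjects are re-identified 1..n so repeated draws of the same
    original subject stay distinct; every row (occasion) of a drawn
    subject is carried along.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    subjects = pd.unique(dataset["subject"])
    if len(subjects) < 2:
        raise ValueError("resampling needs at least 2 subjects")
    drawn = rng.choice(subjects, size=len(subjects), replace=True)
    parts = []
    groups = {s: g for s, g in dataset.groupby("subject", sort=False)}
    for new_id, sid in enumerate(drawn, start=1):
        g = groups[sid].copy()
        g["subject"] = new_id
        parts.append(g)
    return pd.concat(parts, ignore_index=True)


def run_bootstrap(
    dataset: pd.DataFrame,
    final_model: ModelParameters,
    n_resamples: int = 1000,
    seed: int = 0,
    stratify_by_occasion_count: bool = False,
    **fit_options,
) -> BootstrapResult:
    """Refit ``final_model`` to ``n_resamples`` subject resamples.

    Each refit starts from the final estimates. Fully reproducible from
    (dataset, model, n_resamples, seed). Optional stratification keeps
    the mix of per-subject occasion counts fixed across resamples.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(final_model.estimated)
    rows = []
    for b in range(n_resamples):
        if stratify_by_occasion_count:
            boot = _stratified_resample(dataset, rng)
        else:
            boot = resample_subjects(dataset, rng)
        try:
            res = fit(boot, FitSpec(initial=final_model, compute_se=False, **fit_options))
            row = {n: res.params.get(n) for n in names}
            row["converged"] = bool(res.converged)
        except Exception as exc:  # noqa: BLE001 - a failed resample is recorded, not fatal
            log.warning("bootstrap resample %d failed: %s", b, exc)
            row = {n: np.nan for n in names}
            row["converged"] = False
        rows.append(row)
    return BootstrapResult(estimates=pd.DataFrame(rows))


def _stratified_resample(dataset: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    counts = dataset.groupby("subject", sort=False).size()
    parts = []
    new_id = 0
    groups = {s: g for s, g in dataset.groupby("subject", sort=False)}
    for k in sorted(counts.unique()):
        stratum = counts.index[counts == k].to_numpy()
        drawn = rng.choice(stratum, size=len(stratum), replace=True)
        for sid in drawn:
            new_id += 1
            g = groups[sid].copy()
            g["subject"] = new_id
            parts.append(g)
    return pd.concat(parts, ignore_index=True)
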