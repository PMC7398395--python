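"""Goodness-of-fit computations: PRED/IPRED, IWRES, CWRES, plots.

IWRES standardizes the individual residual by the residual SD at the
individual prediction. CWRES uses the standard first-order expansion of
the model around the conditional modes: per subject,
``V^{-1/2} (y - f(eta_hat) + G eta_hat)`` with G the Jacobian df/deta
at the mode and ``V = G Omega G' + diag(residual variances)``. The
matrix square root is taken by symmetric eigendecomposition.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .estimation import LikelihoodEngine, PreparedData, prepare_dataset
from .population import ModelParameters

__all__ = [
    "population_predictions",
    "iwres",
    "cwres",
    "gof_table",
    "plot_gof",
]

log = logging.getLogger("hairpk")

#: relative finite-difference step for the Jacobian df/deta
JACOBIAN_REL_STEP = 1e-5


def _engine(df: pd.DataFrame, params: ModelParameters):
    data = prepare_dataset(df)
    return data, LikelihoodEngine(data, params)


def _record_frame(data: PreparedData, values: dict) -> pd.DataFrame:
    """Flatten masked (n, m) arrays to one row per quantifiable record."""
    mask = data.mask
    n, m = mask.shape
    sub = np.repeat(data.subject_ids, m).reshape(n, m)
    occ = np.where(data.occ_enrol > 0, "enrolment", "follow-up")
    out = {"subject": sub[mask], "occasion": occ[mask]}
    for k, v in values.items():
        out[k] = v[mask]
    return pd.DataFrame(out)


def _modes(engine: LikelihoodEngine, ebes: pd.DataFrame | None) -> np.ndarray:
    """Conditional modes, either recomputed or taken from a fit's EBE table."""
    if ebes is None:
        eta, _, _, conv = engine.conditional_modes()
        if not conv.all():
            log.warning("EBE iteration incomplete for %d subject(s)", int((~conv).sum()))
        return eta
    cols = [f"eta_{c}" for c in engine.plasma_dims]
    if engine.iov:
        cols += [f"eta_iov{j}" for j in range(engine.data.n_occ)]
    tab = ebes.set_index("subject")
    missing = [s for s in engine.data.subject_ids if s not in tab.index]
    if missing:
        raise ValueError(f"EBE table lacks subjects {missing[:5]}")
    return tab.loc[engine.data.subject_ids, cols].to_numpy(float)


def population_predictions(df: pd.DataFrame, params: ModelParameters) -> pd.DataFrame:
    """Typical-subject predictions (eta = 0), one row per record."""
    data, eng = _engine(df, params)
    f = eng.predictions(np.zeros((data.n_subjects, eng.n_dim)))
    return _record_frame(data, {"pred": f})


def iwres(df: pd.DataFrame, params: ModelParameters, ebes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Individually weighted residuals: (y - f(eta_hat)) / sd(f(eta_hat))."""
    data, eng = _engine(df, params)
    eta = _modes(eng, ebes)
    f = eng.predictions(eta)
    sd = np.sqrt((eng.sd_prop * f) ** 2 + eng.sd_add**2)
    if np.any(sd[data.mask] == 0):
        raise ZeroDivisionError("residual SD is zero for some records")
    return _record_frame(data, {"ipred": f, "iwres": (data.y - f) / sd})


def _jacobian(eng: LikelihoodEngine, eta: np.ndarray) -> np.ndarray:
    """df/deta at eta by central differences, shape (n, m, d)."""
    n, m = eng.data.y.shape
    d = eng.n_dim
    G = np.zeros((n, m, d))
    for k in range(d):
        h = JACOBIAN_REL_STEP * np.maximum(1.0, np.abs(eta[:, k]))
        e = np.zeros_like(eta)
        e[:, k] = h
        G[:, :, k] = (eng.predictions(eta + e) - eng.predictions(eta - e)) / (2 * h[:, None])
    return G


def cwres(df: pd.DataFrame, params: ModelParameters, ebes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Conditional weighted residuals (first-order expansion at the modes)."""
    data, eng = _engine(df, params)
    eta = _modes(eng, ebes)
    f = eng.predictions(eta)
    d = eng.n_dim
    res_var = (eng.sd_prop * f) ** 2 + eng.sd_add**2
    out = np.zeros_like(data.y)
    if d == 0:
        out = (data.y - f) / np.sqrt(res_var)
        return _record_frame(data, {"cwres": out})
    G = _jacobian(eng, eta)
    omega = np.diag(eng.omega2)
    for i in range(data.n_subjects):
        sel = data.mask[i]
        Gi = G[i][sel]                              # (k, d)
        V = Gi @ omega @ Gi.T + np.diag(res_var[i][sel])
        vals, vecs = np.linalg.eigh(V)
        if vals.min() <= 0:
            log.warning("non-PD CWRES covariance for subject %s; regularized",
                        data.subject_ids[i])
            vals = np.clip(vals, 1e-10, None)
        inv_sqrt = vecs @ np.diag(vals**-0.5) @ vecs.T
        r = data.y[i][sel] - f[i][sel] + Gi @ eta[i]
        out[i][sel] = inv_sqrt @ r
    return _record_frame(data, {"cwres": out})


def gof_table(
    df: pd.DataFrame,
    params: ModelParameters,
    ebes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per quantifiable record: DV, PRED, IPRED, IWRES, CWRES, time.

    The plot-ready export behind the standard four-panel layout.
    """
    data, eng = _engine(df, params)
    eta = _modes(eng, ebes)
    f_pop = eng.predictions(np.zeros_like(eta))
    f_ind = eng.predictions(eta)
    sd = np.sqrt((eng.sd_prop * f_ind) ** 2 + eng.sd_add**2)
    tab = _record_frame(
        data,
        {"dv": data.y, "pred": f_pop, "ipred": f_ind, "iwres": (data.y - f_ind) / sd},
    )
    tab["cwres"] = cwres(df, params, ebes)["cwres"].to_numpy()
    if "time_h" in df.columns:
        times = (
            df.loc[~df["blq"].astype(bool)]
            .sort_values(["subject", "occasion"], kind="mergesort")["time_h"]
            .to_numpy(float)
        )
        tab["time_h"] = times
    else:
        tab["time_h"] = np.where(tab["occasion"] == "enrolment", 0.0, 2160.0)
    bad = ~np.isfinite(tab[["iwres", "cwres"]].to_numpy()).all(axis=1)
    if bad.any():
        raise FloatingPointError(f"non-finite residuals for {int(bad.sum())} record(s)")
    return tab


def plot_gof(gof: pd.DataFrame, path) -> None:
    """Four-panel goodness-of-fit figure with LOESS smoothers.

    Panels: DV vs PRED, DV vs IPRED, IWRES vs IPRED, CWRES vs time.
    """
    from matplotlib.figure import Figure
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fig = Figure(figsize=(9, 8))
    axes = fig.subplots(2, 2)
    panels = [
        ("pred", "dv", "Population prediction", "Observed (ng/mg)", "identity"),
        ("ipred", "dv", "Individual prediction", "Observed (ng/mg)", "identity"),
        ("ipred", "iwres", "Individual prediction", "IWRES", "zero"),
        ("time_h", "cwres", "Time (h)", "CWRES", "zero"),
    ]
    for ax, (xc, yc, xl, yl, ref) in zip(axes.ravel(), panels):
        x, y = gof[xc].to_numpy(), gof[yc].to_numpy()
        ax.plot(x, y, "o", ms=3, alpha=0.5, color="tab:blue")
        if len(np.unique(x)) > 3:
            sm = lowess(y, x, frac=0.6, return_sorted=True)
            ax.plot(sm[:, 0], sm[:, 1], "-", color="tab:red", lw=1.5)
        if ref == "identity":
            lim = [0, max(x.max(), y.max()) * 1.05]
            ax.plot(lim, lim, "k--", lw=1)
        else:
            ax.axhline(0.0, color="k", ls="--", lw=1)
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
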