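"""Laplace estimator: closed-form oracles, quadrature checks, fit contracts."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from hairpk import (
    FitSpec,
    RandomEffectSpec,
    ResidualSpec,
    atv_final_model,
    estimate_ebe,
    fit,
    laplace_ofv,
    quadrature_ofv,
    subject_joint_loglik,
)
from hairpk.estimation import LikelihoodEngine, prepare_dataset
from tests.conftest import iov_frame


def _frame(rows):
    base = dict(
        blq=False, weight=70.0, bmi_category="normal",
        caregiver="grandparent", adherence_vas=84.2,
    )
    return pd.DataFrame([base | r for r in rows])


def _zero_omega(model):
    return replace(model, random_effects=RandomEffectSpec(0.0, 0.0, 0.0, 0.0))


class TestPrepareDataset:
    def test_blq_rows_excluded(self, atv_frame):
        data = prepare_dataset(atv_frame)
        assert data.n_obs == (~atv_frame["blq"]).sum()

    def test_missing_column_rejected(self, atv_frame):
        with pytest.raises(ValueError, match="missing columns"):
            prepare_dataset(atv_frame.drop(columns=["weight"]))

    def test_all_blq_rejected(self, atv_frame):
        with pytest.raises(ValueError, match="quantifiable"):
            prepare_dataset(atv_frame.assign(blq=True))


class TestSubjectJointLoglik:
    def test_single_observation_closed_form(self, atv_model):
        # additive-only error: a plain Gaussian density plus the eta prior
        model = replace(
            _zero_omega(atv_model), residual=ResidualSpec(sd_add=0.4, sd_prop=0.0)
        )
        df = _frame([dict(subject=1, occasion="follow-up", concentration=3.0)])
        eng = LikelihoodEngine(prepare_dataset(df), model)
        f = eng.predictions(np.zeros((1, 0)))[0, 0]
        expected = norm.logpdf(3.0, loc=f, scale=0.4)
        assert subject_joint_loglik(df, model, ()) == pytest.approx(expected, rel=1e-12)

    def test_duplicate_implementation_oracle(self, iov_model):
        # plain-float reimplementation of the joint density on a random instance
        rng = np.random.default_rng(17)
        y = rng.uniform(0.5, 5.0, size=2)
        eta = rng.normal(0, 0.3, size=2)
        df = _frame(
            [
                dict(subject=1, occasion="enrolment", concentration=y[0]),
                dict(subject=1, occasion="follow-up", concentration=y[1]),
            ]
        )
        eng = LikelihoodEngine(prepare_dataset(df), iov_model)
        f = eng.predictions(eta[None, :])[0]
        om2 = iov_model.random_effects.omega2_frac_iov
        sd = np.sqrt(
            (iov_model.residual.sd_prop * f) ** 2 + iov_model.residual.sd_add**2
        )
        expected = sum(
            norm.logpdf(yi, loc=fi, scale=si) for yi, fi, si in zip(y, f, sd)
        ) + sum(norm.logpdf(e, scale=np.sqrt(om2)) for e in eta)
        got = subject_joint_loglik(df, iov_model, eta)
        assert got == pytest.approx(expected, rel=1e-10)


class LinearEngine(LikelihoodEngine):
    """Toy engine: f = c * (1 + eta), linear in a single random effect.

    With additive-only residual error the marginal likelihood is an
    exact Gaussian integral, so Laplace and quadrature must reproduce
    it to numerical precision, and the conditional mode is the ridge
    estimator.
    """

    def predictions(self, eta, idx=None):
        c = self.c if idx is None else self.c[idx]
        return c * (1.0 + eta[:, :1])


def _linear_setup(y_rows, omega2=0.25, sd_add=0.4):
    model = replace(
        atv_final_model(),
        plasma_iiv_in_hair=True,
        random_effects=RandomEffectSpec(omega2, 0.0, 0.0, 0.0),
        residual=ResidualSpec(sd_add=sd_add, sd_prop=0.0),
    )
    df = _frame(y_rows)
    eng = LinearEngine(prepare_dataset(df), model)
    return model, df, eng


class TestLinearToyOracles:
    def test_ebe_is_ridge_solution(self):
        _, _, eng = _linear_setup(
            [
                dict(subject=1, occasion="enrolment", concentration=2.0),
                dict(subject=1, occasion="follow-up", concentration=3.4),
            ]
        )
        eta, _, _, conv = eng.conditional_modes()
        assert conv.all()
        c = eng.c[0]
        y = eng.data.y[0]
        ridge = (c @ (y - c) / 0.4**2) / (c @ c / 0.4**2 + 1 / 0.25)
        assert eta[0, 0] == pytest.approx(ridge, abs=1e-7)

    def test_laplace_equals_exact_marginal(self):
        rng = np.random.default_rng(3)
        rows = []
        for s in range(1, 6):
            for occ in ("enrolment", "follow-up"):
                rows.append(
                    dict(subject=s, occasion=occ, concentration=rng.uniform(0.5, 5.0))
                )
        model, df, eng = _linear_setup(rows)
        ofv, _, _ = eng.ofv()
        # exact marginal: y_i ~ N(c_i, c_i c_i' omega2 + sd^2 I) per subject
        total = 0.0
        for i in range(eng.data.n_subjects):
            c = eng.c[i]
            y = eng.data.y[i]
            cov = 0.25 * np.outer(c, c) + 0.4**2 * np.eye(len(c))
            from scipy.stats import multivariate_normal

            total += -2.0 * multivariate_normal.logpdf(y, mean=c, cov=cov)
        assert ofv == pytest.approx(total, abs=1e-6)

    def test_symmetric_observations_order_invariant(self):
        _, _, eng1 = _linear_setup(
            [
                dict(subject=1, occasion="enrolment", concentration=2.0),
                dict(subject=1, occasion="follow-up", concentration=3.0),
            ]
        )
        # occasion labels swapped: same pair of (c, y) records
        _, _, eng2 = _linear_setup(
            [
                dict(subject=1, occasion="follow-up", concentration=3.0),
                dict(subject=1, occasion="enrolment", concentration=2.0),
            ]
        )
        e1, _, _, _ = eng1.conditional_modes()
        e2, _, _, _ = eng2.conditional_modes()
        assert e1[0, 0] == pytest.approx(e2[0, 0], abs=1e-9)


class TestEstimateEbe:
    def test_zero_variances_give_empty_eta(self, atv_model):
        df = _frame([dict(subject=1, occasion="follow-up", concentration=3.0)])
        assert estimate_ebe(df, _zero_omega(atv_model)) == {}

    def test_iov_mode_is_deterministic(self, iov_model):
        df = _frame(
            [
                dict(subject=1, occasion="enrolment", concentration=1.2),
                dict(subject=1, occasion="follow-up", concentration=4.0),
            ]
        )
        a = estimate_ebe(df, iov_model)
        b = estimate_ebe(df, iov_model)
        assert a == b
        assert set(a) == {"iov0", "iov1"}
        # higher-than-typical follow-up observation pulls its occasion eta up
        assert a["iov1"] > a["iov0"]


class TestOfv:
    def test_zero_omega_is_exact_likelihood(self, atv_model, atv_frame):
        model = _zero_omega(atv_model)
        data = prepare_dataset(atv_frame)
        eng = LikelihoodEngine(data, model)
        f = eng.predictions(np.zeros((data.n_subjects, 0)))
        sd = np.sqrt((model.residual.sd_prop * f) ** 2 + model.residual.sd_add**2)
        direct = -2.0 * norm.logpdf(data.y[data.mask], f[data.mask], sd[data.mask]).sum()
        assert laplace_ofv(atv_frame, model) == pytest.approx(direct, rel=1e-12)
        assert quadrature_ofv(atv_frame, model, 8) == pytest.approx(direct, rel=1e-12)

    def test_quadrature_node_convergence(self, iov_model):
        frame = iov_frame(iov_model, n_subjects=5, seed=21)
        vals = [quadrature_ofv(frame, iov_model, n) for n in (8, 16, 32, 48)]
        diffs = np.abs(np.diff(vals))
        assert diffs[-1] <= 1e-4  # Cauchy criterion at high node counts
        assert diffs[-1] <= diffs[0] + 1e-12

    def test_quadrature_rejects_bad_requests(self, iov_model, atv_frame):
        with pytest.raises(ValueError, match="n_nodes"):
            quadrature_ofv(atv_frame, iov_model, 1)
        too_many = replace(
            iov_model, plasma_iiv_in_hair=True,
            random_effects=RandomEffectSpec(0.5, 0.5, 0.5, 0.1),
        )
        with pytest.raises(ValueError, match="<= 2"):
            quadrature_ofv(atv_frame, too_many, 8)

    def test_invariant_to_relabeling_and_order(self, atv_model, atv_frame):
        base = laplace_ofv(atv_frame, atv_model)
        shuffled = atv_frame.sample(frac=1.0, random_state=4)
        relabeled = shuffled.assign(subject=shuffled["subject"].map(lambda s: 1000 - s))
        assert laplace_ofv(relabeled, atv_model) == pytest.approx(base, abs=1e-8)


@pytest.fixture(scope="module")
def small_fit(atv_frame, atv_model):
    start = replace(
        atv_model, estimated=("frac_pop", "beta_occasion_enrolment", "sd_add", "sd_prop")
    )
    return fit(atv_frame, FitSpec(initial=start, compute_se=True))


class TestFit:
    def test_converges_with_finite_ofv(self, small_fit):
        assert small_fit.converged
        assert np.isfinite(small_fit.ofv)

    def test_refit_from_optimum_is_fixed_point(self, atv_frame, small_fit):
        again = fit(atv_frame, FitSpec(initial=small_fit.params, compute_se=False))
        assert abs(again.ofv - small_fit.ofv) <= 0.01

    def test_duplicated_dataset_doubles_ofv(self, atv_frame, small_fit):
        twin = atv_frame.assign(subject=atv_frame["subject"] + 10000)
        doubled = pd.concat([atv_frame, twin], ignore_index=True)
        res = fit(doubled, FitSpec(initial=small_fit.params, compute_se=False))
        assert res.ofv == pytest.approx(2 * small_fit.ofv, abs=0.05)
        for name in small_fit.estimated:
            assert res.params.get(name) == pytest.approx(
                small_fit.params.get(name), abs=1e-3
            )

    def test_nested_model_never_fits_better(self, atv_frame, atv_model, small_fit):
        # the richer model contains the poorer model's optimum
        poorer = replace(
            small_fit.params, estimated=("frac_pop", "sd_add", "sd_prop")
        )
        poorer = poorer.with_values(beta_occasion_enrolment=0.0)
        res_poor = fit(atv_frame, FitSpec(initial=poorer, compute_se=False))
        assert res_poor.ofv >= small_fit.ofv - 0.01

    def test_se_reported_only_for_estimated(self, small_fit):
        assert set(small_fit.se_percent) == set(small_fit.estimated)
        assert all(np.isfinite(v) for v in small_fit.se_percent.values())

    def test_result_serializes(self, small_fit, tmp_path):
        import json

        path = tmp_path / "fit.json"
        small_fit.to_json(path)
        doc = json.loads(path.read_text())
        assert doc["ofv"] == pytest.approx(small_fit.ofv)
        assert set(doc["estimates"]) == set(small_fit.estimated)
        assert "frac_pop" in small_fit.report()

    def test_requires_free_parameters(self, atv_model):
        with pytest.raises(ValueError, match="at least one"):
            FitSpec(initial=replace(atv_model, estimated=()))
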