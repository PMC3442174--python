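"""Parametrization, constraint, transforms, likelihood and log posterior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from twinbayes import (
    HyperParams,
    ModelParams,
    TransformedParams,
    TwinCounts,
    cell_probs,
    concordance,
    constraint_ok,
    delta_from_concordance,
    from_real,
    log_likelihood,
    log_posterior,
    make_log_posterior,
    to_real,
)

NEG_INF = float("-inf")


def admissible_grid():
    """Dense grid of admissible (pi, delta) pairs."""
    out = []
    for pi in np.linspace(0.005, 0.995, 40):
        lo = max(-1.0, (2.0 - 1.0 / pi - pi) / (1.0 - pi), -pi / (1.0 - pi))
        for delta in np.linspace(lo + 1e-9, 1.0, 40):
            out.append((float(pi), float(delta)))
    return out


class TestConcordance:
    @pytest.mark.parametrize(
        "pi, delta, expected",
        [
            (0.01, 0.0, 0.01),  # independence: q equals prevalence
            (0.3, 1.0, 1.0),  # perfect dependence
            (0.2, 0.5, 0.6),  # direct substitution
        ],
    )
    def test_known_values(self, pi, delta, expected):
        assert concordance(pi, delta) == pytest.approx(expected, abs=1e-12)

    def test_inadmissible_raises_naming_value(self):
        with pytest.raises(ValueError, match="-0.95"):
            concordance(0.1, -0.95)

    def test_monotone_in_delta(self):
        pi = 0.05
        qs = [concordance(pi, d) for d in np.linspace(0.0, 1.0, 50)]
        assert all(b > a for a, b in zip(qs, qs[1:]))


class TestDeltaFromConcordance:
    @pytest.mark.parametrize(
        "pi, q, expected",
        [
            (0.01, 0.01, 0.0),
            (0.2, 0.6, 0.5),
            (0.01, 0.40, (0.40 - 0.01) / 0.99),  # familial-clustering setting
        ],
    )
    def test_known_values(self, pi, q, expected):
        assert delta_from_concordance(pi, q) == pytest.approx(expected, abs=1e-12)

    def test_inverse_of_concordance(self):
        for pi, delta in admissible_grid()[::7]:
            q = concordance(pi, delta)
            assert delta_from_concordance(pi, q) == pytest.approx(delta, abs=1e-9)

    def test_bad_domain(self):
        with pytest.raises(ValueError):
            delta_from_concordance(1.0, 0.5)


class TestCellProbs:
    @pytest.mark.parametrize(
        "pi, delta, expected",
        [
            (0.01, 0.0, (1e-4, 0.0198, 0.9801)),  # independence: p11 = pi^2
            (0.3, 1.0, (0.3, 0.0, 0.7)),  # no discordant pairs
            (0.01, (0.40 - 0.01) / 0.99, (0.004, 0.012, 0.984)),  # q = 0.40
        ],
    )
    def test_known_values(self, pi, delta, expected):
        p = cell_probs(pi, delta)
        assert p.as_tuple() == pytest.approx(expected, abs=1e-12)

    def test_sum_to_one_on_grid(self):
        for pi, delta in admissible_grid():
            p = cell_probs(pi, delta)
            assert abs(sum(p.as_tuple()) - 1.0) < 1e-12

    def test_consistent_with_concordance(self):
        # p11 = pi*q and pd = 2*pi*(1-q) hold exactly
        for pi, delta in admissible_grid()[::5]:
            q = concordance(pi, delta)
            p = cell_probs(pi, delta)
            assert p.p11 == pi * q
            assert p.pd == 2.0 * pi * (1.0 - q)

    def test_inadmissible_raises(self):
        with pytest.raises(ValueError):
            cell_probs(0.1, -0.95)


class TestConstraint:
    @pytest.mark.parametrize(
        "pi, delta, ok",
        [
            (0.5, -0.5, True),  # bound (pi-1)/pi = -1 exactly
            (0.1, -0.95, False),  # q would be negative
            (0.01, 0.0, True),  # independence always admissible
            (0.9, -0.5, False),  # p00 would be negative
            (0.3, 1.0, True),
        ],
    )
    def test_cases(self, pi, delta, ok):
        assert constraint_ok(pi, delta) is ok

    def test_stronger_than_p00_bound_alone(self):
        # delta > (pi-1)/pi holds here, yet q < 0 makes the point inadmissible
        pi, delta = 0.1, -0.5
        assert delta > (pi - 1.0) / pi
        assert not constraint_ok(pi, delta)


class TestTransforms:
    def test_symmetry_point(self):
        t = to_real(ModelParams(0.5, 0.0, 0.0))
        assert (t.lam, t.mu_mz, t.mu_dz) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_closed_forms(self):
        t = to_real(ModelParams(0.01, 0.5, 0.0))
        assert t.lam == pytest.approx(math.log(0.01 / 0.99), abs=1e-9)
        assert t.mu_mz == pytest.approx(math.log(1.5 / 0.5), abs=1e-9)

    def test_from_real_inverse(self):
        p = from_real(TransformedParams(0.0, 0.0, 0.0))
        assert (p.pi, p.delta_mz, p.delta_dz) == (0.5, 0.0, 0.0)
        assert from_real(TransformedParams(math.log(0.01 / 0.99), 0.0, 0.0)).pi == pytest.approx(
            0.01, abs=1e-12
        )

    def test_large_mu_asymptotes(self):
        p = from_real(TransformedParams(0.0, 80.0, -80.0))
        assert p.delta_mz == pytest.approx(1.0, abs=1e-12)
        assert p.delta_dz == pytest.approx(-1.0, abs=1e-12)

    def test_boundary_raises(self):
        with pytest.raises(ValueError):
            to_real(ModelParams(0.5, 1.0, 0.0))

    @settings(deadline=None, derandomize=True)
    @given(
        pi=st.floats(1e-4, 1.0 - 1e-4),
        dm=st.floats(-0.9999, 0.9999),
        dd=st.floats(-0.9999, 0.9999),
    )
    def test_round_trip(self, pi, dm, dd):
        p = ModelParams(pi, dm, dd)
        back = from_real(to_real(p))
        assert back.pi == pytest.approx(pi, abs=1e-10)
        assert back.delta_mz == pytest.approx(dm, abs=1e-10)
        assert back.delta_dz == pytest.approx(dd, abs=1e-10)


class TestTwinCounts:
    def test_rejects_negative_and_fractional(self):
        with pytest.raises(ValueError):
            TwinCounts(-1, 0, 0)
        with pytest.raises(ValueError):
            TwinCounts(1.5, 0, 0)

    def test_affected_count(self):
        assert TwinCounts(3, 8, 4474).n_affected == 14
        assert TwinCounts(3, 8, 4474).n_pairs == 4485


def _multinomial_logpmf(y: TwinCounts, probs) -> float:
    """Independent oracle: full multinomial log-pmf via log-gamma."""
    counts = np.array([y.y11, y.yd, y.y00], dtype=float)
    p = np.asarray(probs, dtype=float)
    if np.any((p == 0) & (counts > 0)):
        return NEG_INF
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log(np.where(p > 0, p, 1.0)), 0.0)
    coef = gammaln(counts.sum() + 1) - gammaln(counts + 1).sum()
    return float(coef + terms.sum())


class TestLogLikelihood:
    def test_empty_data_is_zero(self):
        p = ModelParams(0.3, 0.2, 0.1)
        assert log_likelihood(p, TwinCounts(0, 0, 0), TwinCounts(0, 0, 0)) == 0.0

    def test_single_concordant_pair_at_full_dependence(self):
        p = ModelParams(0.3, 1.0, 0.0)
        ll = log_likelihood(p, TwinCounts(1, 0, 0), TwinCounts(0, 0, 0))
        assert ll == pytest.approx(math.log(0.3), abs=1e-12)

    def test_zero_cell_with_positive_count(self):
        # delta = 1 makes pd = 0; a discordant pair then has -inf likelihood
        p = ModelParams(0.3, 1.0, 0.0)
        assert log_likelihood(p, TwinCounts(0, 1, 0), TwinCounts(0, 0, 0)) == NEG_INF

    def test_inadmissible_params_give_neg_inf(self):
        p = ModelParams(0.1, -0.5, 0.0)
        assert log_likelihood(p, TwinCounts(1, 1, 1), TwinCounts(1, 1, 1)) == NEG_INF

    def test_agrees_with_multinomial_oracle(self, independence_counts):
        y_mz, y_dz = independence_counts
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            pi = rng.uniform(0.001, 0.6)
            lo = max(-1.0, -pi / (1.0 - pi), (2.0 - 1.0 / pi - pi) / (1.0 - pi))
            dm, dd = rng.uniform(lo + 1e-6, 1.0, size=2)
            params = ModelParams(pi, dm, dd)
            cm = [rng.integers(0, 30) for _ in range(3)]
            cd = [rng.integers(0, 30) for _ in range(3)]
            ym, yd = TwinCounts(*map(int, cm)), TwinCounts(*map(int, cd))
            expected = (
                _multinomial_logpmf(ym, cell_probs(pi, dm).as_tuple())
                + _multinomial_logpmf(yd, cell_probs(pi, dd).as_tuple())
                - (gammaln(ym.n_pairs + 1) - sum(gammaln(c + 1) for c in cm))
                - (gammaln(yd.n_pairs + 1) - sum(gammaln(c + 1) for c in cd))
            )
            assert log_likelihood(params, ym, yd) == pytest.approx(expected, rel=1e-10, abs=1e-9)
            checked += 1
        # and on the printed independence-simulation vectors at the truth
        params = ModelParams(0.01, 0.0, 0.0)
        expected = sum(
            _multinomial_logpmf(y, cell_probs(0.01, 0.0).as_tuple())
            - gammaln(y.n_pairs + 1)
            + sum(gammaln(c + 1) for c in (y.y11, y.yd, y.y00))
            for y in (y_mz, y_dz)
        )
        assert log_likelihood(params, y_mz, y_dz) == pytest.approx(expected, rel=1e-12)


def _log_jacobian(t: TransformedParams) -> float:
    out = 0.0
    for x in (t.lam, t.mu_mz, t.mu_dz):
        out += x - 2.0 * math.log1p(math.exp(x))
    return out


class TestLogPosterior:
    def test_flat_prior_zero_data_equals_jacobian(self):
        zero = TwinCounts(0, 0, 0)
        h = HyperParams.flat()
        for t in (
            TransformedParams(0.0, 0.0, 0.0),
            TransformedParams(-4.0, 0.3, -0.001),
            TransformedParams(1.2, -0.01, 2.0),
        ):
            assert log_posterior(t, zero, zero, h) == pytest.approx(
                _log_jacobian(t), abs=1e-10
            )

    def test_flat_prior_is_jacobian_plus_likelihood(self, cleft_lip_counts):
        y_mz, y_dz = cleft_lip_counts
        h = HyperParams.flat()
        t = TransformedParams(-6.0, 0.5, 0.2)
        expected = _log_jacobian(t) + log_likelihood(from_real(t), y_mz, y_dz)
        assert log_posterior(t, y_mz, y_dz, h) == pytest.approx(expected, rel=1e-10)

    def test_constraint_violation_is_neg_inf(self):
        # pi = 0.5 requires delta >= -1/3... actually q >= 0 -> delta >= -1;
        # use pi near 1 where p00 < 0 for negative delta
        t = TransformedParams(3.0, -2.0, 0.0)  # pi ~ 0.95, delta_mz ~ -0.76
        h = HyperParams.flat()
        assert log_posterior(t, TwinCounts(0, 0, 0), TwinCounts(0, 0, 0), h) == NEG_INF

    def test_jacobian_ratio_closed_form(self):
        zero = TwinCounts(0, 0, 0)
        h = HyperParams.flat()
        t1 = TransformedParams(-1.0, 0.1, 0.2)
        t2 = TransformedParams(0.5, -0.02, 1.0)
        diff = log_posterior(t1, zero, zero, h) - log_posterior(t2, zero, zero, h)
        assert math.exp(diff) == pytest.approx(
            math.exp(_log_jacobian(t1)) / math.exp(_log_jacobian(t2)), rel=1e-9
        )

    def test_informative_prior_terms(self):
        # Beta(a1, a2) prior contributes (a1-1)ln pi + (a2-1)ln(1-pi)
        zero = TwinCounts(0, 0, 0)
        t = TransformedParams(-2.0, 0.0, 0.0)
        pi = from_real(t).pi
        flat = log_posterior(t, zero, zero, HyperParams.flat())
        informative = log_posterior(t, zero, zero, HyperParams(a1=5.0, a2=11.0))
        assert informative - flat == pytest.approx(
            4.0 * math.log(pi) + 10.0 * math.log(1.0 - pi), rel=1e-10
        )

    def test_factory_matches_wrapper(self, ra_danish_counts):
        y_mz, y_dz = ra_danish_counts
        h = HyperParams(a1=1334.0, a2=355154.0)
        f = make_log_posterior(y_mz, y_dz, h)
        t = TransformedParams(-5.3, 0.4, 0.05)
        assert f((t.lam, t.mu_mz, t.mu_dz)) == log_posterior(t, y_mz, y_dz, h)


class TestHyperParams:
    def test_positive_required(self):
        with pytest.raises(ValueError):
            HyperParams(a1=0.0)

    def test_flat_default(self):
        assert HyperParams.flat().is_flat()
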