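"""Rate terms, the dosed ODE system, and its structural invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorpkpd import pk
from tumorpkpd.dynamics import (
    SystemState,
    gcv_death_rate,
    logistic_closed_form,
    logistic_growth_rate,
    peptide_death_rate,
    rhs,
    simulate,
)
from tumorpkpd.errors import InputDomainError
from tumorpkpd.params import (
    DoseEvent,
    DoseSchedule,
    ModelParameters,
    gene_therapy_schedule,
)


def make_params(**over):
    base = dict(
        sigma=0.5, K=1e4, V0=500.0, D_pep=0.2, Kd=0.5, lam=25.0,
        kex_pep=0.35, kex_pep_sol=38.0, ka_gcv=12.0, kex_gcv=3.0,
    )
    base.update(over)
    return ModelParameters(**base)


class TestRateTerms:
    @pytest.mark.parametrize(
        "V,sigma,K,expected",
        [(0.0, 0.5, 1e4, 0.0), (1e4, 0.5, 1e4, 0.0), (5000.0, 1.0, 1e4, 2500.0)],
    )
    def test_logistic_growth(self, V, sigma, K, expected):
        assert logistic_growth_rate(V, sigma, K) == pytest.approx(expected)

    def test_logistic_domain_errors(self):
        with pytest.raises(InputDomainError):
            logistic_growth_rate(-1.0, 0.5, 1e4)
        with pytest.raises(InputDomainError):
            logistic_growth_rate(1.0, 0.5, 0.0)

    def test_peptide_kill_saturation(self):
        # no drug -> no kill; half-saturation at c = Kd; asymptote D_pep
        assert peptide_death_rate(100.0, 0.0, 0.3, 0.5) == 0.0
        assert peptide_death_rate(1.0, 0.5, 0.3, 0.5) == pytest.approx(0.15)
        assert peptide_death_rate(1.0, 1e9, 0.3, 0.5) == pytest.approx(0.3, rel=1e-8)

    def test_peptide_kill_rejects_bad_kd(self):
        with pytest.raises(InputDomainError):
            peptide_death_rate(1.0, 1.0, 0.3, 0.0)

    def test_gcv_kill_linear(self):
        assert gcv_death_rate(100.0, 0.0, 25.0) == 0.0
        assert gcv_death_rate(100.0, 0.008, 0.0) == 0.0
        assert gcv_death_rate(1.0, 0.008, 2.0) == pytest.approx(0.016)

    def test_absolute_scaling_drops_volume_factor(self):
        prop = peptide_death_rate(50.0, 0.5, 0.3, 0.5, scaling="proportional")
        absolute = peptide_death_rate(50.0, 0.5, 0.3, 0.5, scaling="absolute")
        assert prop == pytest.approx(50.0 * absolute)


class TestRHS:
    def test_drug_free_reduces_to_logistic(self):
        p = make_params()
        dy = rhs(0.0, np.array([p.V0, 0, 0, 0]), p, DoseSchedule.empty())
        assert dy[0] == pytest.approx(logistic_growth_rate(p.V0, p.sigma, p.K))
        assert np.all(dy[1:] == 0)

    def test_zero_volume_is_absorbing(self):
        p = make_params()
        dy = rhs(0.0, np.array([0.0, 0.5, 0.004, 0.008]), p, DoseSchedule.empty())
        assert dy[0] == 0.0

    def test_derivatives_match_closed_form_finite_differences(self):
        """On a bolus-only run the PK derivatives must match the closed forms."""
        p = make_params()
        sched = DoseSchedule.empty()
        h = 1e-6
        for t in (0.05, 0.3, 1.0):
            c_pep = pk.iv_bolus_concentration(t, 0.8, p.kex_pep)
            c_gp = pk.ip_bateman_concentration(t, 0.008, p.ka_gcv, p.kex_gcv)
            c_gip = 0.008 * np.exp(-p.ka_gcv * t)
            dy = rhs(t, np.array([0.0, c_pep, c_gp, c_gip]), p, sched)
            fd = [
                (pk.iv_bolus_concentration(t + h, 0.8, p.kex_pep)
                 - pk.iv_bolus_concentration(t - h, 0.8, p.kex_pep)) / (2 * h),
                (pk.ip_bateman_concentration(t + h, 0.008, p.ka_gcv, p.kex_gcv)
                 - pk.ip_bateman_concentration(t - h, 0.008, p.ka_gcv, p.kex_gcv)) / (2 * h),
                (0.008 * np.exp(-p.ka_gcv * (t + h))
                 - 0.008 * np.exp(-p.ka_gcv * (t - h))) / (2 * h),
            ]
            assert dy[1] == pytest.approx(fd[0], rel=1e-6)
            assert dy[2] == pytest.approx(fd[1], rel=1e-6)
            assert dy[3] == pytest.approx(fd[2], rel=1e-6)

    def test_kill_terms_monotone_in_concentration(self):
        p = make_params()
        sched = DoseSchedule.empty()
        V = 1000.0
        dv = [
            rhs(0, np.array([V, c, 0, 0]), p, sched)[0] for c in (0.0, 0.2, 0.5, 2.0)
        ]
        assert np.all(np.diff(dv) <= 0)
        dv = [
            rhs(0, np.array([V, 0, c, 0]), p, sched)[0]
            for c in (0.0, 0.002, 0.005, 0.01)
        ]
        assert np.all(np.diff(dv) < 0)


class TestSimulate:
    def test_untreated_matches_logistic_closed_form(self):
        p = make_params(D_pep=0.0, lam=0.0, sigma=0.45, V0=250.0)
        traj = simulate(p, DoseSchedule.empty(), t_span=(0, 21))
        expected = logistic_closed_form(traj.times, p.V0, p.sigma, p.K)
        assert np.allclose(traj.V, expected, rtol=1e-6)

    def test_dose_events_jump_compartments(self):
        p = make_params()
        sched = gene_therapy_schedule()
        traj = simulate(p, sched, t_span=(0, 21))
        i5 = np.searchsorted(traj.times, 5.0)
        # peptide appears exactly at the bolus time
        assert traj.c_pep_p[i5 - 1] == 0.0
        assert traj.c_pep_p[i5] == pytest.approx(0.8, rel=1e-9)
        i12 = np.searchsorted(traj.times, 12.0)
        assert traj.c_gcv_ip[i12 - 1] == 0.0
        assert traj.c_gcv_ip[i12] == pytest.approx(0.008, rel=1e-9)

    def test_peritoneal_gcv_decays_between_doses(self):
        p = make_params()
        traj = simulate(p, gene_therapy_schedule(), t_span=(0, 21))
        dose_days = {12.0 + k for k in range(10)}
        for i in range(1, len(traj.times)):
            if traj.times[i] not in dose_days:
                assert traj.c_gcv_ip[i] <= traj.c_gcv_ip[i - 1] + 1e-12

    def test_pk_compartments_match_closed_form_superposition(self):
        """Numerical integration of the dose compartments agrees with the
        analytic single-dose solutions superposed over the schedule."""
        p = make_params(D_pep=0.0, lam=0.0)
        sched = gene_therapy_schedule()
        traj = simulate(p, sched, t_span=(0, 21))
        t = traj.times
        c_pep = np.where(t >= 5.0, pk.iv_bolus_concentration(
            np.clip(t - 5.0, 0, None), 0.8, p.kex_pep), 0.0)
        c_gp = np.zeros_like(t)
        c_gip = np.zeros_like(t)
        for day in range(12, 22):
            tau = np.clip(t - day, 0, None)
            active = t >= day
            c_gp += active * pk.ip_bateman_concentration(tau, 0.008, p.ka_gcv, p.kex_gcv)
            c_gip += active * 0.008 * np.exp(-p.ka_gcv * tau)
        scale = np.max(c_gp)
        assert np.allclose(traj.c_pep_p, c_pep, rtol=1e-6, atol=1e-6 * 0.8)
        assert np.allclose(traj.c_gcv_p, c_gp, rtol=1e-6, atol=1e-6 * scale)
        assert np.allclose(traj.c_gcv_ip, c_gip, rtol=1e-6, atol=1e-6 * 0.008)

    def test_infusion_reaches_asymptote(self):
        p = make_params()
        sched = DoseSchedule(events=(), infusion_mu=0.75, infusion_start=5.0)
        traj = simulate(p, sched, t_span=(0, 10), mode="soluble")
        assert traj.c_pep_p[-1] == pytest.approx(0.75, abs=1e-4)
        before = traj.c_pep_p[traj.times < 5.0]
        assert np.all(before == 0.0)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    sigma=st.floats(0.0, 1.0),
    d_pep=st.floats(0.0, 5.0),
    kd=st.floats(0.05, 2.0),
    lam=st.floats(0.0, 200.0),
    kex_pep=st.floats(0.05, 5.0),
    v0=st.floats(1.0, 9000.0),
)
def test_trajectories_stay_nonnegative_and_below_capacity(
    sigma, d_pep, kd, lam, kex_pep, v0
):
    """From any non-negative start, V and all concentrations stay >= 0 and
    V never exceeds the carrying capacity."""
    p = make_params(sigma=sigma, D_pep=d_pep, Kd=kd, lam=lam, kex_pep=kex_pep, V0=v0)
    traj = simulate(p, gene_therapy_schedule(), t_span=(0, 21), rtol=1e-6, atol=1e-9)
    assert np.all(traj.V >= 0)
    assert np.all(traj.V <= p.K * (1 + 1e-9))
    assert np.all(traj.c_pep_p >= 0)
    assert np.all(traj.c_gcv_p >= 0)
    assert np.all(traj.c_gcv_ip >= 0)
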