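"""LQ repair factors, BED algebra, optimum dose, TCP and the dose coupling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stemrad import for_cancer
from stemrad.parameters import RadioParameters
from stemrad.radiotherapy import (
    FractionationSchedule,
    RadiationTerm,
    TCPInputs,
    bed_cancer,
    bed_late,
    effective_radiation,
    incomplete_repair_h,
    log_cell_kill_E,
    optimum_dose,
    phi_factor,
    repair_correction_M,
    repair_g,
    schedule_scan,
    simulate_with_radiotherapy,
    tcp,
)
from stemrad.simulator import simulate

SLOW_DIFFUSION = dict(DS=0.0031536, DD=0.0031536, Da=0.0365, Dm=0.0365)


def radio_grid():
    """A small family of valid parameter variations for identity checks."""
    out = []
    for dose in (0.3, 1.328, 2.5):
        for n in (1, 2, 4):
            for dtr in (6.9e-4, 1.2e-3):
                out.append(RadioParameters(dose_per_fraction=dose, n=n,
                                           delta_tau_r=dtr))
    return out


class TestRepairFactors:
    def test_g_values(self):
        assert repair_g(0.0) == 1.0
        assert repair_g(1.0) == pytest.approx(2.0 / math.e)
        assert repair_g(1e-5) == pytest.approx(
            1.0 - 1e-5 / 3.0 + 1e-10 / 12.0, abs=1e-14)
        assert repair_g(500.0) == pytest.approx(2.0 / 500.0, rel=1e-2)
        with pytest.raises(ValueError):
            repair_g(-0.1)

    def test_g_monotone_decreasing(self):
        x = np.linspace(0.0, 10.0, 200)
        g = np.array([repair_g(v) for v in x])
        assert np.all(np.diff(g) < 0.0)
        assert np.all((g > 0.0) & (g <= 1.0))

    def test_h_degenerate_cases(self):
        assert incomplete_repair_h(1, 0.4) == 0.0
        assert incomplete_repair_h(5, 0.0) == 0.0
        with pytest.raises(ValueError):
            incomplete_repair_h(2, 1.0)
        with pytest.raises(ValueError):
            incomplete_repair_h(0, 0.5)

    def test_h_two_fraction_identity(self):
        # for n=2 the expression collapses algebraically to phi itself
        for phi in np.linspace(0.0, 0.95, 40):
            assert incomplete_repair_h(2, phi) == pytest.approx(phi, abs=1e-12)

    def test_h_increases_with_fraction_count(self):
        values = [incomplete_repair_h(n, 0.107) for n in (1, 2, 4, 8, 50)]
        assert np.all(np.diff(values) > 0.0)
        # bounded by the infinite-sequence limit 2 phi / (1 - phi)
        assert values[-1] < 2 * 0.107 / (1 - 0.107)

    def test_M_reduces_to_unity_for_instant_single_fraction(self):
        radio = RadioParameters(n=1, tau_r=1e-12, delta_tau_r=1e-11)
        assert repair_correction_M(radio) == pytest.approx(1.0, abs=1e-8)

    def test_M_at_figure_schedule(self):
        # direct evaluation chain at the published fraction timing
        radio = RadioParameters()     # tau_r=9e-6 yr, delta_tau_r=6.9e-4 yr, n=2
        x = radio.mu * radio.tau_r
        g = 2.0 * (x - 1.0 + math.exp(-x)) / x**2
        phi = math.exp(-radio.mu * (radio.tau_r + radio.delta_tau_r))
        expected = g + 2.0 * (math.cosh(x) - 1.0) / x**2 * phi
        M = repair_correction_M(radio)
        assert M == pytest.approx(expected, rel=1e-12)
        assert M == pytest.approx(1.0976046, abs=1e-6)   # regression anchor
        assert M >= g

    def test_effective_radiation(self):
        radio = RadioParameters(dose_per_fraction=0.0)
        assert effective_radiation(radio) == 0.0
        doses = np.linspace(0.01, 3.0, 50)
        values = [effective_radiation(RadioParameters(dose_per_fraction=d))
                  for d in doses]
        assert np.all(np.diff(values) > 0.0)
        lin = RadioParameters(dose_per_fraction=1.5, beta_s=1e-300)
        assert effective_radiation(lin) == pytest.approx(
            lin.alpha_s * lin.n * 1.5)


class TestSchedule:
    def test_switch_bookkeeping(self):
        sched = FractionationSchedule(start=1.0, n=2, tau_r=9e-6,
                                      delta_tau_r=6.9e-4, duration_days=45.0)
        assert sched.switch(0.5) == 0                       # before treatment
        assert sched.switch(1.0 + 4e-6) == 1                # inside fraction 1
        assert sched.switch(1.0 + 1e-4) == 0                # between fractions
        assert sched.switch(1.0 + 6.9e-4 + 4e-6) == 1       # inside fraction 2
        day = 1.0 / 365.0
        assert sched.switch(1.0 + 5.5 * day) == 0           # weekend day
        # total irradiated time over one treatment day is n * tau_r
        measure = sched.irradiated_measure(1.0, 1.0 + day)
        assert measure == pytest.approx(2 * 9e-6, rel=1e-12)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            FractionationSchedule(start=0.0, tau_r=1e-3, delta_tau_r=1e-4)


class TestBEDAlgebra:
    @pytest.mark.parametrize("radio", radio_grid())
    def test_direct_and_rearranged_forms_agree_under_schedule_relation(self, radio):
        T = radio.f * radio.n - 1.0
        direct = bed_cancer(radio, T=T, form="direct")
        via = bed_cancer(radio, T=T, form="via_late")
        assert direct == pytest.approx(via, abs=1e-10)

    @pytest.mark.parametrize("radio", radio_grid())
    def test_log_cell_kill_is_alpha_times_tumour_bed(self, radio):
        assert log_cell_kill_E(radio) == pytest.approx(
            radio.alpha_s * bed_cancer(radio), abs=1e-12)

    def test_bed_late_shape(self):
        assert bed_late(RadioParameters(dose_per_fraction=0.0)) == 0.0
        doses = np.linspace(0.0, 5.0, 60)
        values = np.array([bed_late(RadioParameters(dose_per_fraction=d))
                           for d in doses])
        assert np.all(np.diff(values) > 0.0)
        assert np.all(np.diff(values, 2) > -1e-12)      # convex in dose

    def test_repopulation_clamped_before_kickoff(self):
        radio = RadioParameters(dose_per_fraction=1.0)
        early = bed_cancer(radio, T=10.0)               # T < T_d: no subtraction
        assert early == pytest.approx(
            radio.n * 1.0 * (1.0 + 1.0 / radio.theta_can)
            * repair_correction_M(radio))
        assert bed_cancer(radio, T=45.0) == pytest.approx(
            early - radio.K * 5.0)

    def test_k_zero_mirrors_late_tissue_form(self):
        radio = RadioParameters(dose_per_fraction=1.0, K=1e-300,
                                theta_late=RadioParameters().alpha_s
                                / RadioParameters().beta_s)
        assert bed_cancer(radio, T=45.0) == pytest.approx(bed_late(radio), abs=1e-12)


class TestOptimumDose:
    def test_root_zeroes_the_quadratic(self):
        radio = RadioParameters()
        d_opt = optimum_dose(radio)
        M = repair_correction_M(radio)
        c = 1.0 - radio.theta_late / radio.theta_can
        residual = c * M * d_opt**2 - 2.0 * radio.K * radio.f * d_opt \
            - radio.K * radio.f * radio.theta_late
        assert abs(residual) < 1e-10

    def test_brute_force_grid_confirms_the_optimum(self):
        # maximise tumour BED over the dose at fixed normal-tissue BED
        radio = RadioParameters()
        M = repair_correction_M(radio)
        # a normal-tissue budget large enough that the schedule stays in the
        # repopulation regime (T > T_d) around the optimum
        late_target = 100.0
        doses = np.arange(0.02, 10.0, 0.002)
        values = []
        for d in doses:
            r = radio.replace(dose_per_fraction=float(d))
            n_eff = late_target / (d * (1.0 + d / radio.theta_late) * M)
            T_eff = radio.f * n_eff - 1.0
            bed = n_eff * d * (1.0 + d / radio.theta_can) * M \
                - radio.K * max(T_eff - radio.T_d, 0.0)
            values.append(bed)
        best = doses[int(np.argmax(values))]
        assert best == pytest.approx(optimum_dose(radio), abs=0.005)

    def test_vanishing_repopulation_drives_optimum_to_zero(self):
        assert optimum_dose(RadioParameters(K=1e-12)) < 1e-5

    def test_inverted_ratios_have_no_finite_optimum(self):
        radio = RadioParameters(theta_late=10.0, theta_can=3.0)
        with pytest.raises(ValueError, match="no finite optimum"):
            optimum_dose(radio)

    def test_schedule_scan_documents_sensitivity(self):
        table = schedule_scan(RadioParameters())
        assert {"tau_r", "delta_tau_r", "n", "M", "optimum_dose",
                "bed_can"}.issubset(table.columns)
        assert len(table) > 10
        assert (table.M >= 0.5).all() and (table.M <= 2.0).all()
        assert (table.optimum_dose > 0).all()


class TestTCP:
    def test_empty_tumour_is_controlled(self):
        control, survival = tcp(RadioParameters(dose_per_fraction=1.0),
                                TCPInputs(0.0, 80000.0))
        assert control == 1.0 and 0.0 < survival <= 1.0

    def test_limits_in_bed(self):
        radio = RadioParameters(dose_per_fraction=50.0)    # huge dose
        control, _ = tcp(radio, TCPInputs(0.000805, 80000.0))
        assert control == pytest.approx(1.0, abs=1e-9)
        zero = RadioParameters(dose_per_fraction=0.0, K=1e-300)
        control0, survival0 = tcp(zero, TCPInputs(0.000805, 80000.0))
        assert survival0 == pytest.approx(1.0)
        assert control0 == pytest.approx(math.exp(-0.000805 * 80000.0))

    def test_monotone_in_dose_and_volume_ordering(self):
        doses = np.linspace(0.0, 2.0, 81)
        small, large = TCPInputs(0.000805, 80000.0), TCPInputs(0.000805, 250000.0)
        tcp_small, tcp_large = [], []
        for d in doses:
            radio = RadioParameters(dose_per_fraction=float(d), n=2, T=45.0)
            tcp_small.append(tcp(radio, small)[0])
            tcp_large.append(tcp(radio, large)[0])
        tcp_small, tcp_large = np.array(tcp_small), np.array(tcp_large)
        assert np.all(np.diff(tcp_small) >= 0.0)
        assert np.all(tcp_large <= tcp_small)

    @given(density=st.floats(1e-6, 1e-2), volume=st.floats(1e3, 1e6),
           dose=st.floats(0.0, 10.0))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_probability_bounds(self, density, volume, dose):
        radio = RadioParameters(dose_per_fraction=dose)
        control, survival = tcp(radio, TCPInputs(density, volume))
        assert 0.0 <= control <= 1.0
        assert 0.0 < survival <= 1.0


class TestDoseCoupling:
    @pytest.fixture
    def treated_params(self, prostate):
        return prostate.replace(tau=6.8964, **SLOW_DIFFUSION)

    def test_zero_dose_reproduces_untreated_run(self, treated_params):
        untreated = simulate(treated_params, t_end=8.0, dt=0.01)
        radio = RadioParameters(dose_per_fraction=0.0)
        treated = simulate_with_radiotherapy(
            treated_params, radio, t_start_rt=6.8964, t_end=8.0, dt=0.01)
        assert np.array_equal(untreated.means, treated.means)

    def test_fractionated_windows_integrate_to_duty_cycle(self):
        radio = RadioParameters(dose_per_fraction=0.05)
        sched = FractionationSchedule(start=0.0, n=2, tau_r=9e-6,
                                      delta_tau_r=6.9e-4, duration_days=45.0)
        term = RadiationTerm(radio, sched, mode="fractionated")
        dt = 0.01
        total = sum(term.rate_for_step(i * dt, dt) * dt
                    for i in range(int(0.2 / dt)))
        # equals delta * R_eff * (total beam-on time of the whole course)
        expected = radio.delta * effective_radiation(radio) \
            * sched.irradiated_measure(0.0, 0.2)
        assert total == pytest.approx(expected, rel=1e-9)

    def test_eradication_ordering_with_dose(self, treated_params):
        # continuous course from t = 6.8964: higher dose depresses both cell
        # populations and raises the microRNA level
        finals = {}
        for dose in (0.0, 0.02, 0.05):
            radio = RadioParameters(dose_per_fraction=dose)
            res = simulate_with_radiotherapy(
                treated_params, radio, t_start_rt=6.8964, t_end=16.0, dt=0.01)
            finals[dose] = res.means[-1]
        S = [finals[d][0] for d in (0.0, 0.02, 0.05)]
        D = [finals[d][1] for d in (0.0, 0.02, 0.05)]
        m = [finals[d][3] for d in (0.0, 0.02, 0.05)]
        assert S[0] > S[1] > S[2]
        assert D[0] > D[1] > D[2]
        assert m[0] < m[1] < m[2]

    def test_high_dose_collapses_csc_population(self, treated_params):
        # at the optimum-scale dose the published "eradication within 0.3
        # year" behaviour: kill rate delta*R_eff ~ 24/yr
        radio = RadioParameters(dose_per_fraction=1.323)
        res = simulate_with_radiotherapy(
            treated_params, radio, t_start_rt=6.8964, t_end=7.3, dt=0.01)
        untreated = simulate(treated_params, t_end=7.3, dt=0.01)
        assert res.means[-1][0] < 0.05 * untreated.means[-1][0]
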