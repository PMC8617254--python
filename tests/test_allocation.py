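import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from volscale import (
    CellState,
    GlobalParams,
    make_genome,
    production_rates,
    solve_free_rnap,
    solve_free_ribosome,
)
from volscale.allocation import _solve_free_fraction
from volscale.genome import calibrate


def quadratic_root(total, slots_sum, K, c):
    """Closed-form homogeneous-K root (cancellation-stable form)."""
    b = c * (slots_sum - total) + K * total
    return 2.0 * K * total / (b + math.sqrt(b * b + 4.0 * c * total * K * total))


class TestFreeFractionSolver:
    def test_printed_quadratic_example(self):
        # n=50, 100 slots, c = 1000 K: the quadratic 5e4 F^2 + 50050 F - 50 = 0
        K = 6e3
        c = 1000 * K
        F = _solve_free_fraction(50.0, np.array([100.0]), np.array([K]), c)
        expected = (-50050 + math.sqrt(50050**2 + 4 * 5e4 * 50)) / 1e5
        assert F == pytest.approx(expected, rel=1e-9)
        assert F == pytest.approx(9.98e-4, rel=1e-3)

    def test_oracle_equivalence_1000_random(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            total = rng.uniform(1, 1e4)
            slots = rng.uniform(0.5 * total, 2e4)
            K = rng.uniform(1, 1e4)
            c = rng.uniform(1, 1e4) * K
            F = _solve_free_fraction(total, np.array([slots]), np.array([K]), c)
            assert F == pytest.approx(quadratic_root(total, slots, K, c), rel=1e-10)

    def test_bookkeeping_closure_random(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            n_species = int(rng.integers(1, 20))
            slots = rng.uniform(0.1, 1e3, n_species)
            K = rng.uniform(1, 1e4, n_species)
            total = rng.uniform(0.1, 2 * slots.sum())
            c = rng.uniform(10, 1e6)
            F = _solve_free_fraction(total, slots, K, c)
            bound = float(np.sum(slots * c * F / (c * F + K)))
            assert abs(bound + total * F - total) / total < 1e-9

    def test_zero_total(self):
        assert _solve_free_fraction(0.0, np.array([10.0]), np.array([1.0]), 5.0) == 0.0

    def test_no_slots_all_free(self):
        assert _solve_free_fraction(5.0, np.array([0.0]), np.array([1.0]), 5.0) == 1.0

    @given(
        total=st.floats(0.1, 1e5),
        slot_scale=st.floats(0.1, 1e5),
        K=st.floats(1e-2, 1e6),
        c_mult=st.floats(1e-2, 1e5),
        n_species=st.integers(1, 8),
    )
    @settings(max_examples=200, deadline=None)
    def test_root_always_valid(self, total, slot_scale, K, c_mult, n_species):
        rng = np.random.default_rng(3)
        slots = rng.uniform(0.1, 1.0, n_species) * slot_scale
        Ks = rng.uniform(0.5, 2.0, n_species) * K
        c = c_mult * K
        F = _solve_free_fraction(total, slots, Ks, c)
        assert 0.0 < F < 1.0
        bound = float(np.sum(slots * c * F / (c * F + Ks)))
        assert abs(bound - total * (1.0 - F)) <= 1e-8 * total


def _homog_state(gl, n=50.0, n_slots=100.0, c_over_K=1000.0, K=6e3):
    """Three-gene homogeneous genome and a state with the requested RNAP
    count, slot capacity and nuclear RNAP concentration."""
    from volscale.genome import GeneParams, Genome

    # slots: rnap gene 1, ribosome gene 1, generic the rest (Gamma_n = 0)
    g_generic = n_slots - 2
    genes = [
        GeneParams("rnap", 100, 1, K, K, 0.0, 1.0, 10.0, np.inf, "rnap"),
        GeneParams("ribosome", 100, 1, K, K, 0.0, 1.0, 10.0, np.inf, "ribosome"),
        GeneParams("g0", 100, int(g_generic), K, K, 0.0, 1.0, 10.0, np.inf, "generic"),
    ]
    genome = Genome.from_genes(genes)
    # choose total mass so that c_n = n / V_n equals c_over_K * K
    V_n = n / (c_over_K * K)
    M = V_n * gl.a * gl.rho
    p = np.zeros(3)
    p[0] = n
    p[1] = 1.0
    p[2] = (M - n * 100 - 100) / 100
    assert p[2] > 0
    m = np.zeros(3)
    return genome, CellState(t=0.0, m=m, p=p)


class TestSolveFreeRnap:
    def test_matches_quadratic_via_state(self, gl):
        genome, state = _homog_state(gl)
        F, c_free = solve_free_rnap(state, genome, gl)
        expected = quadratic_root(50.0, 100.0, 6e3, 1000 * 6e3)
        assert F == pytest.approx(expected, rel=1e-10)
        assert c_free == pytest.approx(1000 * 6e3 * expected, rel=1e-10)

    def test_binding_probability_near_n_over_nc(self, gl):
        genome, state = _homog_state(gl)
        _, c_free = solve_free_rnap(state, genome, gl)
        P_b = c_free / (c_free + 6e3)
        assert P_b == pytest.approx(0.5, rel=2e-3)

    def test_strong_recruitment_binds_everything(self, gl):
        genome, state = _homog_state(gl, K=1e-6, c_over_K=1e9)
        F, c_free = solve_free_rnap(state, genome, gl)
        assert F < 1e-6  # n = n_c/2: every RNAP finds a slot
        bound = 100.0 * c_free / (c_free + 1e-6)
        assert bound == pytest.approx(50.0, rel=1e-6)

    def test_zero_rnap_warns(self, gl):
        genome, state = _homog_state(gl)
        state.p[0] = 0.0
        state.p[2] += 50.0  # keep mass positive
        with pytest.warns(UserWarning, match="free fraction undefined"):
            F, c_free = solve_free_rnap(state, genome, gl)
        assert (F, c_free) == (0.0, 0.0)

    def test_monotone_in_n(self, gl):
        Fs = []
        for n in [10.0, 30.0, 60.0, 90.0, 120.0, 200.0]:
            genome, state = _homog_state(gl, n=n)
            F, _ = solve_free_rnap(state, genome, gl)
            Fs.append(F)
        assert np.all(np.diff(Fs) > 0)

    def test_homogeneous_limit_bound(self, gl):
        # |P_b - n/n_c| / (n/n_c) <= K/c * n_c/(n_c - n) for n/n_c <= 0.9
        for nu in [0.1, 0.3, 0.5, 0.7, 0.9]:
            genome, state = _homog_state(gl, n=nu * 100.0, c_over_K=500.0)
            _, c_free = solve_free_rnap(state, genome, gl)
            P_b = c_free / (c_free + 6e3)
            rel = abs(P_b - nu) / nu
            assert rel <= (1.0 / 500.0) * 100.0 / (100.0 - nu * 100.0) + 1e-12


class TestSolveFreeRibosome:
    def test_no_mrna_all_free(self, gl, small_homog):
        genome = small_homog.genome
        state = CellState(t=0.0, m=np.zeros(genome.n_genes), p=small_homog.p0)
        F, c_free = solve_free_ribosome(state, genome, gl)
        assert F == 1.0
        M = np.dot(state.p, genome.L)
        V_c = M / gl.rho * (1 - 1 / gl.a)
        assert c_free == pytest.approx(state.p[genome.i_ribosome] / V_c, rel=1e-12)

    def test_surplus_ribosomes(self, gl, small_homog):
        genome = small_homog.genome
        m = small_homog.m0 * 1e-4  # starve the mRNA pool
        state = CellState(t=0.0, m=m, p=small_homog.p0)
        F, _ = solve_free_ribosome(state, genome, gl)
        slots = float(np.sum(m * (1.0 + genome.lambda_r(gl))))
        r = state.p[genome.i_ribosome]
        # with c_r >> K_r the occupied slots saturate: F -> 1 - slots/r
        assert F == pytest.approx(1.0 - slots / r, rel=1e-3)

    def test_symmetric_quadratic(self, gl):
        # single mRNA species with m(1+Lambda_r) = 100, r = 50, c_r = 1000 K
        K = 6e3
        F = _solve_free_fraction(50.0, np.array([100.0]), np.array([K]), 1000 * K)
        expected = (-50050 + math.sqrt(50050**2 + 4 * 5e4 * 50)) / 1e5
        assert F == pytest.approx(expected, rel=1e-9)


class TestProductionRates:
    def test_homogeneous_rate_law(self):
        # k_n_i ~= Gamma_n_i (g_i / n_c) n within 1% when c_n >> K
        from volscale.genome import GeneParams, Genome

        K = 6e3
        genes = [
            GeneParams("rnap", 100, 1, K, K, 1.0, 1.0, 10.0, np.inf, "rnap"),
            GeneParams("ribosome", 100, 1, K, K, 1.0, 1.0, 10.0, np.inf, "ribosome"),
            GeneParams("g0", 100, 1, K, K, 1.0, 1.0, 10.0, np.inf, "generic"),
        ]
        genome = Genome.from_genes(genes)
        gl2 = GlobalParams(v_n=100.0)  # Lambda = 1 per gene -> n_c = 6
        n = 3.0
        V_n = n / (1000.0 * K)
        M = V_n * gl2.a * gl2.rho
        p = np.array([n, 1.0, (M - n * 100 - 100) / 100.0])
        state = CellState(t=0.0, m=np.ones(3), p=p)
        res = production_rates(state, genome, gl2)
        expected = 1.0 * (1.0 / 6.0) * n  # Gamma (g/n_c) n
        for k in res.k_n:
            assert k == pytest.approx(expected, rel=0.01)
        assert res.phase1

    def test_special_gene_rate_example(self, gl):
        # one gene at 20x the background K with n/n_c = 1/2 and Gamma g = 1:
        # k = 50/1050 in the F_n -> 0 limit
        from volscale.genome import GeneParams, Genome

        K = 6e3
        genes = [
            GeneParams("rnap", 100, 1, K, K, 0.0, 1.0, 10.0, np.inf, "rnap"),
            GeneParams("ribosome", 100, 1, K, K, 0.0, 1.0, 10.0, np.inf, "ribosome"),
            GeneParams("bg", 100, 97, K, K, 0.0, 1.0, 10.0, np.inf, "generic"),
            GeneParams("special", 100, 1, 20 * K, K, 1.0, 1.0, 10.0, np.inf, "generic"),
        ]
        # 100 promoter slots (special gene's Lambda_n ~ 1/24 is a small
        # perturbation); use a huge c/K so F_n -> 0
        genome = Genome.from_genes(genes)
        n = 50.0
        V_n = n / (1e5 * K)
        M = V_n * gl.a * gl.rho
        p = np.zeros(4)
        p[0] = n
        p[1] = 1.0
        p[3] = 1.0
        p[2] = (M - n * 100 - 200) / 100.0
        state = CellState(t=0.0, m=np.zeros(4), p=p)
        res = production_rates(state, genome, gl)
        assert res.k_n[3] == pytest.approx(50.0 / 1050.0, rel=0.02)

    def test_zero_initiation_zero_rate(self, gl, small_homog):
        genome = small_homog.genome.replace(Gamma_n=np.zeros(small_homog.genome.n_genes))
        state = CellState(t=0.0, m=small_homog.m0, p=small_homog.p0)
        res = production_rates(state, genome, gl)
        assert np.all(res.k_n == 0.0)

    def test_bookkeeping_closure_full_states(self, gl, small_lognormal):
        cal = small_lognormal
        genome = cal.genome
        rng = np.random.default_rng(5)
        lam_n = genome.lambda_n(gl)
        slots = genome.g * (1.0 + lam_n)
        for _ in range(50):
            scale = rng.uniform(0.5, 5.0)
            state = CellState(
                t=0.0,
                m=cal.m0 * rng.uniform(0.5, 2.0, genome.n_genes),
                p=cal.p0 * scale,
            )
            res = production_rates(state, genome, gl)
            n = state.p[genome.i_rnap]
            bound = float(np.sum(slots * res.P_b))
            assert abs(n * res.F_n + bound - n) / n < 1e-9

    def test_P_b_decreasing_in_K(self):
        c_free = 100.0
        K = np.array([1.0, 10.0, 100.0, 1000.0])
        P = c_free / (c_free + K)
        assert np.all(np.diff(P) < 0)
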