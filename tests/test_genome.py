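import numpy as np
import pytest

from volscale import GlobalParams, make_genome, nc_of
from volscale.genome import GeneParams, Genome, calibrate


class TestMakeGenome:
    def test_lognormal_mean_and_cv(self):
        genome = make_genome(2000, K_mean=6e3, K_cv=0.5, seed=1)
        K = genome.K_n[genome.is_generic]
        assert abs(K.mean() - 6e3) / 6e3 < 0.05
        cv = K.std() / K.mean()
        assert abs(cv - 0.5) / 0.5 < 0.10

    def test_degenerate_cv_gives_exact_constants(self):
        genome = make_genome(50, K_mean=6e3, K_cv=0.0, seed=2)
        assert np.all(genome.K_n[genome.is_generic] == 6e3)

    def test_special_overrides_exact(self):
        genome = make_genome(
            100, K_mean=6e3, K_cv=0.0,
            special_overrides={"g0000": 20.0, "g0001": 0.2}, seed=3,
        )
        assert genome.K_n[genome.index_of("g0000")] == 20.0 * 6e3
        assert genome.K_n[genome.index_of("g0001")] == 0.2 * 6e3

    def test_machine_gene_override_rejected(self):
        with pytest.raises(ValueError, match="model assumption"):
            make_genome(10, special_overrides={"rnap": 2.0}, seed=1)
        with pytest.raises(ValueError, match="model assumption"):
            make_genome(10, special_overrides={"ribosome": 2.0}, seed=1)

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            make_genome(10, special_overrides={"nope": 2.0}, seed=1)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_genome(10, K_mean=-1.0, seed=1)
        with pytest.raises(ValueError):
            make_genome(10, lifetime_mean=0.0, seed=1)
        with pytest.raises(ValueError):
            make_genome(10, K_cv=-0.1, seed=1)
        with pytest.raises(ValueError):
            make_genome(2, seed=1)

    def test_seed_reproducibility(self):
        a = make_genome(100, seed=7)
        b = make_genome(100, seed=7)
        for col in ("K_n", "tau_m", "L", "tau_p"):
            np.testing.assert_array_equal(getattr(a, col), getattr(b, col))
        c = make_genome(100, seed=8)
        assert not np.array_equal(a.K_n, c.K_n)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            make_genome(10)

    def test_copy_numbers(self):
        genome = make_genome(40, seed=4)
        assert genome.g[genome.i_ribosome] == 5
        others = np.delete(genome.g, genome.i_ribosome)
        assert np.all(others == 1)

    def test_machine_K_is_weighted_generic_average(self):
        genome = make_genome(300, K_cv=0.5, seed=5)
        gen = genome.is_generic
        w = genome.g[gen] * genome.tau_m[gen] * genome.L[gen] / genome.K_n[gen]
        expected = np.dot(w, genome.K_n[gen]) / w.sum()
        assert genome.K_n[genome.i_rnap] == pytest.approx(expected, rel=1e-12)
        assert genome.K_n[genome.i_ribosome] == genome.K_n[genome.i_rnap]

    def test_degradable_assignment(self):
        genome = make_genome(100, n_degradable=20, tau_p_deg=10.0, seed=6)
        finite = np.isfinite(genome.tau_p)
        assert finite.sum() == 20
        assert np.all(genome.tau_p[finite] == 10.0)
        assert np.all(genome.role[finite] == "generic")

    def test_gamma_multipliers_only_on_generics(self):
        genome = make_genome(100, gamma_cv=1.0, seed=9)
        assert genome.gamma_mult is not None
        assert genome.gamma_mult[genome.i_rnap] == 1.0
        assert genome.gamma_mult[genome.i_ribosome] == 1.0
        assert np.std(genome.gamma_mult[genome.is_generic]) > 0


class TestGenomeValidation:
    def test_requires_unique_roles(self):
        genes = [
            GeneParams("a", 100, 1, 1.0, 1.0, 1.0, 1.0, 10.0, np.inf, "rnap"),
            GeneParams("b", 100, 1, 1.0, 1.0, 1.0, 1.0, 10.0, np.inf, "rnap"),
            GeneParams("c", 100, 1, 1.0, 1.0, 1.0, 1.0, 10.0, np.inf, "generic"),
        ]
        with pytest.raises(ValueError):
            Genome.from_genes(genes)

    def test_gene_params_positivity(self):
        with pytest.raises(ValueError):
            GeneParams("a", 0, 1, 1.0, 1.0, 1.0, 1.0, 10.0, np.inf)
        with pytest.raises(ValueError):
            GeneParams("a", 100, 1, 1.0, 1.0, 1.0, 1.0, 10.0, 0.0)
        # zero initiation rates are legal (silent gene)
        GeneParams("a", 100, 1, 1.0, 1.0, 0.0, 0.0, 10.0, np.inf)


class TestCalibrate:
    def test_phi_hand_example(self):
        # by hand: phi_r = 0.006 * 10000 / 600 = 0.1;
        #          phi_n = 0.1 * 0.1 * 5000 / 10000 = 0.005
        gl = GlobalParams(mu0=0.006, v_r=600.0)
        genome = make_genome(20, seed=1, L_rnap=5000, L_ribosome=10000)
        cal = calibrate(genome, gl)
        assert cal.phi_r == pytest.approx(0.1, rel=1e-12)
        assert cal.phi_n == pytest.approx(0.005, rel=1e-12)

    def test_nc_target_hit_exactly_random_genomes(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            gl = GlobalParams(
                mu0=rng.uniform(0.003, 0.007),
                n_c_target=rng.uniform(5e3, 5e4),
            )
            genome = make_genome(
                int(rng.integers(5, 40)),
                K_cv=rng.uniform(0, 1),
                lifetime_cv=rng.uniform(0, 1),
                seed=int(rng.integers(1e6)),
            )
            cal = calibrate(genome, gl)
            realized = nc_of(cal.genome, gl)
            assert abs(realized - gl.n_c_target) / gl.n_c_target < 1e-12

    @pytest.mark.parametrize(
        "L_rnap,L_ribosome,mu0",
        [(5000, 10000, 0.006), (3000, 12000, 0.004), (8000, 9000, 0.0055)],
    )
    def test_rnap_ribosome_copy_ratio(self, L_rnap, L_ribosome, mu0):
        gl = GlobalParams(mu0=mu0)
        genome = make_genome(20, seed=2, L_rnap=L_rnap, L_ribosome=L_ribosome)
        cal = calibrate(genome, gl)
        ratio = (cal.phi_n / L_rnap) / (cal.phi_r / L_ribosome)
        assert ratio == pytest.approx(0.1, rel=1e-12)

    def test_idempotent(self, gl):
        genome = make_genome(50, K_cv=0.5, gamma_cv=0.5, seed=3)
        cal1 = calibrate(genome, gl)
        cal2 = calibrate(cal1.genome, gl)
        np.testing.assert_array_equal(cal1.genome.Gamma_n, cal2.genome.Gamma_n)

    def test_mass_shift_rule(self, gl, small_homog):
        cal = small_homog
        genome = cal.genome
        mass = cal.p0 * genome.L
        phi_n_actual = mass[genome.i_rnap] / mass.sum()
        assert phi_n_actual * cal.M0_actual == pytest.approx(
            cal.phi_n * gl.M_b, rel=1e-9
        )
        assert np.dot(cal.p0, genome.L) == pytest.approx(cal.M0_actual, rel=1e-12)

    def test_heterogeneous_gamma_keeps_nc_exact(self, gl):
        genome = make_genome(80, gamma_cv=1.0, seed=10)
        cal = calibrate(genome, gl)
        assert nc_of(cal.genome, gl) == pytest.approx(gl.n_c_target, rel=1e-12)
        gammas = cal.genome.Gamma_n[cal.genome.is_generic]
        assert np.std(gammas) / np.mean(gammas) > 0.3

    def test_infeasible_growth_rate(self):
        gl = GlobalParams(mu0=0.1)  # phi_r = 0.1*10000/600 > 1
        genome = make_genome(10, seed=1)
        with pytest.raises(ValueError, match="phi_r"):
            calibrate(genome, gl)

    def test_nc_target_below_copy_total(self):
        gl = GlobalParams(n_c_target=3.0)
        genome = make_genome(10, seed=1)
        with pytest.raises(ValueError, match="n_c_target"):
            calibrate(genome, gl)


class TestNcOf:
    def _tiny(self, Gamma_n):
        genes = [
            GeneParams("rnap", 100, 1, 1.0, 1.0, Gamma_n, 1.0, 10.0, np.inf, "rnap"),
            GeneParams("ribosome", 100, 1, 1.0, 1.0, Gamma_n, 1.0, 10.0, np.inf, "ribosome"),
            GeneParams("g0", 100, 1, 1.0, 1.0, Gamma_n, 1.0, 10.0, np.inf, "generic"),
        ]
        return Genome.from_genes(genes)

    def test_single_term_by_hand(self):
        # each gene: g=1, Gamma*L/v_n = 9  ->  contributes 10
        gl = GlobalParams(v_n=100.0)
        genome = self._tiny(Gamma_n=9.0)
        assert nc_of(genome, gl) == pytest.approx(30.0, rel=1e-14)

    def test_zero_initiation_counts_copies_only(self, gl):
        genome = self._tiny(Gamma_n=0.0)
        assert nc_of(genome, gl) == pytest.approx(3.0, rel=1e-14)

    def test_matches_bruteforce_sum(self, gl):
        genome = make_genome(30, seed=13)
        cal = calibrate(genome, gl)
        g = cal.genome
        brute = sum(
            g.g[i] * (1.0 + g.Gamma_n[i] * g.L[i] / gl.v_n) for i in range(g.n_genes)
        )
        assert nc_of(g, gl) == pytest.approx(brute, rel=1e-12)
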