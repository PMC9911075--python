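"""Forensic expected LR, Haldane map, realized-relatedness variance,
and the two-locus IBD correlation."""

import numpy as np
import pytest

import ibd2loc as ib
from ibd2loc.errors import PedigreeError

from conftest import fixture_pair


class TestElrMatrix:
    def test_entries(self):
        m = ib.elr_matrix(10)
        assert m[0].tolist() == [1, 1, 1] and m[:, 0].tolist() == [1, 1, 1]
        assert m[1, 1] == 3.25
        assert m[1, 2] == m[2, 1] == 5.5
        assert m[2, 2] == 55
        assert ib.elr_matrix(15)[2, 2] == 120

    def test_monomorphic_marker_is_uninformative(self):
        assert np.all(ib.elr_matrix(1) == 1)

    def test_rejects_zero_alleles(self):
        with pytest.raises(PedigreeError):
            ib.elr_matrix(0)


class TestExpectedLr:
    def test_unrelated_truth_gives_one(self):
        ped, a, b = fixture_pair("full_sibs")
        K_hyp = ib.two_locus_ibd(ped, a, b, 0.2)
        K_unrel = np.zeros((3, 3))
        K_unrel[0, 0] = 1.0
        assert ib.expected_lr(K_hyp, K_unrel, 10, 15) == pytest.approx(1.0)

    def test_parent_offspring_at_independence(self):
        ped, a, b = fixture_pair("parent_offspring")
        K = ib.two_locus_ibd(ped, a, b, 0.5)
        assert ib.expected_lr(K, K, 10, 15) == pytest.approx(3.25 * 4.5)

    def test_factorizes_at_independence(self):
        """At rho = 1/2, E[LR] is the product of the two single-marker
        expected LRs (sum_{i,i'} kappa_i kappa_i' M[i, i'])."""
        ped, a, b = fixture_pair("half_sibs")
        K = ib.two_locus_ibd(ped, a, b, 0.5)
        ks = np.asarray(ib.kappa(ped, a, b), dtype=float)
        singles = [float(ks @ ib.elr_matrix(n) @ ks) for n in (10, 15)]
        assert ib.expected_lr(K, K, 10, 15) == pytest.approx(
            singles[0] * singles[1], abs=1e-10
        )

    @pytest.mark.parametrize(
        "name,params",
        [
            ("grandparent", ()),
            ("half_sibs", ()),
            ("full_sibs", ()),
            ("quad_half_first_cousins", ()),
            ("cousins", (1, 1)),
        ],
    )
    @pytest.mark.parametrize("rho", [0.1, 0.5])
    def test_information_inequality(self, name, params, rho):
        """Testing the true relationship is never expected to lose: E[LR] >= 1."""
        ped, a, b = fixture_pair(name, *params)
        K = ib.two_locus_ibd(ped, a, b, rho)
        assert ib.expected_lr(K, K, 10, 15) >= 1.0

    def test_ranking_depends_on_marker_distance(self):
        """With markers of 10 and 15 alleles, grandparent beats half sibs at
        tight linkage but ties at independence, and QHFC drops below HS+HSC:
        the E[LR] ranking genuinely changes with rho."""
        pairs = {
            "grandparent": fixture_pair("grandparent"),
            "half_sibs": fixture_pair("half_sibs"),
            "uncle": fixture_pair("cousins", 0, 1),
            "qhfc": fixture_pair("quad_half_first_cousins"),
            "hs_hsc": fixture_pair("hs_plus_half_second_cousins"),
        }

        def elr(name, rho):
            ped, a, b = pairs[name]
            K = ib.two_locus_ibd(ped, a, b, rho)
            return ib.expected_lr(K, K, 10, 15)

        tight = {n: elr(n, 0.05) for n in pairs}
        free = {n: elr(n, 0.5) for n in pairs}
        assert tight["grandparent"] > tight["half_sibs"] > tight["uncle"]
        assert free["grandparent"] == pytest.approx(free["half_sibs"], abs=1e-10)
        assert tight["qhfc"] > tight["hs_hsc"]
        assert free["qhfc"] < free["hs_hsc"]


class TestHaldane:
    def test_values(self):
        assert float(ib.haldane_rho(0.0)) == 0.0
        assert float(ib.haldane_rho(0.5)) == pytest.approx(0.3160602794142788)
        assert float(ib.haldane_rho(10.0)) == pytest.approx(0.5, abs=1e-8)

    def test_negative_distance_rejected(self):
        with pytest.raises(PedigreeError):
            ib.haldane_rho(-0.1)


class TestRealizedVariance:
    def test_parent_offspring_zero(self):
        ped, a, b = fixture_pair("parent_offspring")
        assert ib.var_realized_k(ped, a, b, 1, 1.0) == 0.0

    def test_unrelated_pair_zero(self):
        ped, _ = ib.make_fixture("half_sibs")
        for j in (0, 1, 2):
            assert ib.var_realized_k(ped, "1", "3", j, 2.3) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_half_sib_closed_form(self):
        """For half sibs kappa11 = (rho^2 + rbar^2)/2, so the variance
        integral has the closed form (integrating Haldane's map):
        Var(k1) = (e^{-4L} - 1 + 4L) / (32 L^2)."""
        for L in (0.5, 1.0, 2.7):
            ped, a, b = fixture_pair("half_sibs")
            closed = (np.exp(-4 * L) - 1 + 4 * L) / (32 * L * L)
            assert ib.var_realized_k(ped, a, b, 1, L) == pytest.approx(
                closed, abs=1e-9
            )

    def test_matches_poisson_crossover_simulation(self, halfsib_k1_sims):
        ped, a, b = fixture_pair("half_sibs")
        exact = ib.var_realized_k(ped, a, b, 1, 1.0)
        sims = halfsib_k1_sims
        sv = sims.var(ddof=1)
        m4 = ((sims - sims.mean()) ** 4).mean()
        se = np.sqrt(max(m4 - sv**2, 0.0) / sims.size)
        assert abs(sv - exact) <= 4 * se

    def test_quadrature_converged(self):
        ped, a, b = fixture_pair("half_sibs")
        v64 = ib.var_realized_k(ped, a, b, 1, 1.0, n_nodes=64)
        v128 = ib.var_realized_k(ped, a, b, 1, 1.0, n_nodes=128)
        assert abs(v64 - v128) < 1e-6

    def test_decreasing_in_chromosome_length(self):
        ped, a, b = fixture_pair("half_sibs")
        vals = [ib.var_realized_k(ped, a, b, 1, L) for L in (0.5, 1.0, 2.0, 3.0)]
        assert all(x > y > 0 for x, y in zip(vals, vals[1:]))

    def test_multi_chromosome_combination(self):
        """Two chromosomes combine by squared length weights (independent
        chromosomes), so two 1-Morgan chromosomes halve the variance."""
        ped, a, b = fixture_pair("half_sibs")
        one = ib.var_realized_k(ped, a, b, 1, 1.0)
        two = ib.var_realized_k(ped, a, b, 1, ib.GenomeSpec((1.0, 1.0)))
        assert two == pytest.approx(one / 2, abs=1e-10)


class TestIbdCorrelation:
    def test_endpoints(self):
        ped, a, b = fixture_pair("full_sibs")
        assert ib.ibd_correlation(ped, a, b, 0.0) == pytest.approx(1.0, abs=1e-10)
        assert ib.ibd_correlation(ped, a, b, 0.5) == pytest.approx(0.0, abs=1e-10)

    def test_double_second_cousins_decreasing(self):
        ped, a, b = fixture_pair("double_second_cousins_A")
        rhos = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
        vals = [ib.ibd_correlation(ped, a, b, r) for r in rhos]
        assert vals[0] == pytest.approx(1.0, abs=1e-10)
        assert vals[-1] == pytest.approx(0.0, abs=1e-10)
        assert all(x > y for x, y in zip(vals, vals[1:]))
        assert all(0 < v < 1 for v in vals[1:-1])

    def test_zero_variance_relationship_rejected(self):
        ped, a, b = fixture_pair("parent_offspring")
        with pytest.raises(PedigreeError):
            ib.ibd_correlation(ped, a, b, 0.25)
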