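"""Two-locus coefficient matrices K, phased components, and D."""

import numpy as np
import pytest

import ibd2loc as ib
from ibd2loc.errors import (
    InbredPairError,
    PedigreeError,
    UnsupportedFounderInbreedingError,
)

from conftest import fixture_pair

UNILINEAL = [("grandparent", ()), ("half_sibs", ()), ("cousins", (0, 2))]
SIX_FIXTURES = [
    ("grandparent", ()),
    ("half_sibs", ()),
    ("full_sibs", ()),
    ("cousins", (1, 1)),
    ("quad_half_first_cousins", ()),
    ("hs_plus_half_second_cousins", ()),
]


class TestKappa11Unilineal:
    def test_grandparent_and_half_sib_closed_forms(self):
        """kappa11(G) = rbar/2 and kappa11(H) = (rho^2 + rbar^2)/2."""
        pg, ga, gb = fixture_pair("grandparent")
        ph, ha, hb = fixture_pair("half_sibs")
        assert ib.kappa11_unilineal(pg, ga, gb, 0.25) == pytest.approx(0.375)
        assert ib.kappa11_unilineal(ph, ha, hb, 0.25) == pytest.approx(0.3125)
        for rho in (0.05, 0.15, 0.3, 0.45, 0.5):
            rb = 1 - rho
            assert ib.kappa11_unilineal(pg, ga, gb, rho) == pytest.approx(
                rb / 2, abs=1e-12
            )
            assert ib.kappa11_unilineal(ph, ha, hb, rho) == pytest.approx(
                (rho * rho + rb * rb) / 2, abs=1e-12
            )

    def test_parent_offspring_constant_one(self):
        ped, a, b = fixture_pair("parent_offspring")
        for rho in (0.0, 0.1, 0.25, 0.5):
            assert ib.kappa11_unilineal(ped, a, b, rho) == pytest.approx(1.0, abs=1e-12)

    def test_rho_zero_returns_kappa1(self):
        ped, a, b = fixture_pair("grandparent")
        assert ib.kappa11_unilineal(ped, a, b, 0.0) == 0.5

    def test_bilineal_pair_rejected(self):
        ped, a, b = fixture_pair("full_sibs")
        with pytest.raises(PedigreeError):
            ib.kappa11_unilineal(ped, a, b, 0.25)


class TestKappaMatrix:
    def test_half_sibs_quarter(self):
        ped, a, b = fixture_pair("half_sibs")
        K = ib.two_locus_ibd(ped, a, b, 0.25)
        expect = np.array([[0.3125, 0.1875, 0], [0.1875, 0.3125, 0], [0, 0, 0]])
        assert np.abs(K.k - expect).max() < 1e-12

    def test_full_sibs_independence_endpoint(self):
        ped, a, b = fixture_pair("full_sibs")
        K = ib.two_locus_ibd(ped, a, b, 0.5)
        ks = np.array([0.25, 0.5, 0.25])
        assert K.k[2, 2] == pytest.approx(0.0625)
        assert np.abs(K.k - np.outer(ks, ks)).max() < 1e-12

    def test_self_pair(self):
        ped, a, _ = fixture_pair("full_sibs")
        K = ib.two_locus_ibd(ped, a, a, 0.3)
        assert K.k[2, 2] == 1.0 and K.k.sum() == 1.0

    def test_inbred_target_rejected(self):
        ped, a, b = fixture_pair("sib_mating_sibs", 1)
        with pytest.raises(InbredPairError):
            ib.two_locus_ibd(ped, a, b, 0.25)

    @pytest.mark.parametrize("name,params", UNILINEAL)
    @pytest.mark.parametrize("rho", [0.1, 0.3])
    def test_unilineal_route_equals_general_route(self, name, params, rho):
        ped, a, b = fixture_pair(name, *params)
        k1 = ib.two_locus_ibd(ped, a, b, rho, method="unilineal").k
        k2 = ib.two_locus_ibd(ped, a, b, rho, method="general").k
        assert np.abs(k1 - k2).max() < 1e-10

    @pytest.mark.parametrize("name,params", SIX_FIXTURES)
    def test_conservation_and_symmetry(self, name, params):
        """Row and column sums of K(rho) are the single-locus kappa, and
        K is symmetric, at every rho."""
        ped, a, b = fixture_pair(name, *params)
        ks = np.asarray(ib.kappa(ped, a, b), dtype=float)
        for rho in (0.0, 0.1, 0.25, 0.4, 0.5):
            K = ib.two_locus_ibd(ped, a, b, rho).k
            assert np.abs(K.sum(axis=1) - ks).max() < 1e-10
            assert np.abs(K.sum(axis=0) - ks).max() < 1e-10
            assert np.abs(K - K.T).max() < 1e-10

    def test_endpoint_forms_via_general_route(self):
        """The recursion itself (not the endpoint shortcut) must reproduce
        the diagonal form at rho = 0 and the outer product at rho = 1/2."""
        ped, a, b = fixture_pair("full_sibs")
        ks = np.asarray(ib.kappa(ped, a, b), dtype=float)
        K0 = ib.two_locus_ibd(ped, a, b, 0.0, method="general").k
        K5 = ib.two_locus_ibd(ped, a, b, 0.5, method="general").k
        assert np.abs(K0 - np.diag(ks)).max() < 1e-12
        assert np.abs(K5 - np.outer(ks, ks)).max() < 1e-12


class TestPhased:
    def test_parent_offspring_components(self):
        """(cc, ct, tc, tt) = (rbar, 0, rho, 0): the IBD alleles are always
        in cis within the child, and in cis within the parent exactly when
        the transmitted gamete is nonrecombinant."""
        ped, a, b = fixture_pair("parent_offspring")
        ph = ib.two_locus_ibd_phased(ped, a, b, 0.25)
        assert (ph.k11cc, ph.k11ct, ph.k11tc, ph.k11tt) == pytest.approx(
            (0.75, 0.0, 0.25, 0.0), abs=1e-12
        )

    @pytest.mark.parametrize("rho", [0.1, 0.25, 0.4])
    def test_inbred_half_sib_parent_pure_cis(self, halfsib_inbred, rho):
        """H-i: both IBD alleles always ride the shared parent's single
        haplotype class, so cis/cis carries everything, at any rho."""
        ped, (a, b) = halfsib_inbred
        ph = ib.two_locus_ibd_phased(ped, a, b, rho)
        assert ph.k11cc == pytest.approx(1.0, abs=1e-12)
        assert ph.k11ct == ph.k11tc == ph.k11tt == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "name,params",
        [("quad_half_first_cousins", ()), ("full_sibs", ()), ("grandparent", ())],
    )
    @pytest.mark.parametrize("rho", [0.1, 0.3])
    def test_reassembly_recovers_phi11(self, name, params, rho):
        """The phase-weighted sum of the ten components equals phi11."""
        ped, a, b = fixture_pair(name, *params)
        ph = ib.two_locus_ibd_phased(ped, a, b, rho)
        rb = 1 - rho
        R = rho * rho + rb * rb
        reassembled = (
            R / 2 * (ph.k22h + ph.k21h)
            + rho * rb * (ph.k22r + ph.k21r)
            + rb * rb / 4 * ph.k11cc
            + rho * rb / 4 * (ph.k11ct + ph.k11tc)
            + rho * rho / 4 * ph.k11tt
        )
        assert reassembled == pytest.approx(
            ib.two_locus_kinship(ped, a, b, rho), abs=1e-10
        )

    def test_components_aggregate_to_kappa_matrix(self):
        ped, a, b = fixture_pair("full_sibs")
        rho = 0.2
        ph = ib.two_locus_ibd_phased(ped, a, b, rho)
        K = ib.two_locus_ibd(ped, a, b, rho).k
        assert ph.k11cc + ph.k11ct + ph.k11tc + ph.k11tt == pytest.approx(
            K[1, 1], abs=1e-12
        )
        assert ph.k21h + ph.k21r == pytest.approx(K[2, 1], abs=1e-12)
        assert ph.k22h + ph.k22r == pytest.approx(K[2, 2], abs=1e-12)
        assert ph.k12h == ph.k21h and ph.k12r == ph.k21r


class TestIdentityMatrix:
    def test_term_plan(self):
        """Recovering row and column 8 from single-locus sums leaves 121 of
        the 225 grid cells, and no cell involving the four one-IBD detailed
        states remains."""
        plan = ib.plan_identity_terms()
        assert len(plan) == 121
        c_sizes = {i: len(c) for i, c in enumerate(
            ([1], [6], [2, 3], [7], [4, 5], [8], [9, 12], [10, 11, 13, 14], [15]), 1
        )}
        assert sum(c_sizes[i] * c_sizes[j] for i in c_sizes for j in c_sizes) == 225
        eight = {10, 11, 13, 14}
        assert all(r not in eight and s not in eight for r, s in plan)

    def test_rho_zero_is_diagonal(self):
        ped, a, b = fixture_pair("sib_mating_sibs", 1)
        delta = ib.condensed_identity(ped, a, b).delta
        D = ib.two_locus_identity(ped, a, b, 0.0).d
        assert np.abs(D - np.diag(delta)).max() < 1e-12

    def test_noninbred_pair_reduces_to_kappa_matrix(self):
        ped, a, b = fixture_pair("full_sibs")
        rho = 0.3
        D = ib.two_locus_identity(ped, a, b, rho).d
        K = ib.two_locus_ibd(ped, a, b, rho).k
        assert np.abs(D[:6, :]).max() == 0 and np.abs(D[:, :6]).max() == 0
        # states (S7, S8, S9) <-> IBD counts (2, 1, 0)
        assert np.abs(D[6:, 6:][::-1, ::-1] - K).max() < 1e-10

    @pytest.mark.parametrize("rho", [0.2, 0.35])
    def test_sib_mating_marginals_and_symmetry(self, rho):
        ped, a, b = fixture_pair("sib_mating_sibs", 1)
        delta = ib.condensed_identity(ped, a, b).delta
        D = ib.two_locus_identity(ped, a, b, rho).d
        assert np.abs(D.sum(axis=1) - delta).max() < 1e-10
        assert np.abs(D.sum(axis=0) - delta).max() < 1e-10
        assert D.sum() == pytest.approx(1.0, abs=1e-10)
        assert D.min() >= 0
        assert np.abs(D - D.T).max() < 1e-10

    @pytest.mark.parametrize(
        "pair", ["sibs", "child_parent"], ids=["sib-mating sibs", "inbred child vs parent"]
    )
    def test_independence_endpoint_outer_product(self, pair):
        """D(1/2) is the outer product of the single-locus coefficients."""
        ped, a, b = fixture_pair("sib_mating_sibs", 1)
        if pair == "child_parent":
            b = ped.father(a)
        delta = ib.condensed_identity(ped, a, b).delta
        D = ib.two_locus_identity(ped, a, b, 0.5).d
        assert np.abs(D - np.outer(delta, delta)).max() < 1e-10

    def test_self_pair_rejected(self):
        ped, a, _ = fixture_pair("full_sibs")
        with pytest.raises(PedigreeError):
            ib.two_locus_identity(ped, a, a, 0.25)

    def test_completely_inbred_founder_target_rejected(self, halfsib_inbred):
        ped, _ = halfsib_inbred
        with pytest.raises(UnsupportedFounderInbreedingError):
            ib.two_locus_identity(ped, "2", "4", 0.25)

    def test_inbred_founder_elsewhere_supported(self, halfsib_inbred):
        """Complete founder inbreeding away from the targets is fine."""
        ped, (a, b) = halfsib_inbred
        D = ib.two_locus_identity(ped, a, b, 0.25).d
        K = ib.two_locus_ibd(ped, a, b, 0.25).k
        assert np.abs(D[6:, 6:][::-1, ::-1] - K).max() < 1e-10
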