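"""Selection against codon mismatch, κ optimization, fixation probabilities."""

import math

import mpmath
import numpy as np
import pandas as pd
import pytest

from codonmutsel import (
    CodonFamily,
    CodonFamilyTable,
    GenomeCounts,
    MutSelParams,
    delta_s,
    expected_codon_counts,
    gene_selection_cost,
    log10_fixation_probability,
    optimize_kappa,
)
from codonmutsel.simulate import endogenous_like, make_truth, simulate_counts

K_TABLE = CodonFamilyTable((CodonFamily("K", "K", ("AAA", "AAG")),))


def k_genome(rows, phis=None):
    ids = [f"g{i}" for i in range(len(rows))]
    counts = pd.DataFrame(rows, index=ids, columns=["AAA", "AAG"])
    ann = pd.DataFrame({"chromosome": "C", "start": 1}, index=ids)
    return GenomeCounts(K_TABLE, counts, ann)


class TestExpectedCounts:
    def test_symmetric_split(self):
        params = MutSelParams(K_TABLE, np.zeros(2), np.zeros(2))
        assert np.allclose(expected_codon_counts(params, 1.0, {"K": 10}), [5, 5])

    def test_hand_softmax_times_m(self):
        params = MutSelParams(K_TABLE, np.array([-0.5, 0.5]), np.zeros(2))
        expect = expected_codon_counts(params, 0.0, {"K": 100})
        assert np.allclose(expect, [73.11, 26.89], atol=0.005)

    def test_per_family_sum_equals_m(self, table, two_codon_params):
        rng = np.random.default_rng(0)
        m = {f.label: int(rng.integers(0, 40)) for f in table.families}
        for phi in (0.0, 0.7, 4.2):
            expect = expected_codon_counts(two_codon_params, phi, m)
            for fam in table.families:
                assert expect[table.slice(fam.label)].sum() == pytest.approx(m[fam.label])


class TestGeneSelectionCost:
    def test_zero_on_neutral_codons(self):
        params = MutSelParams(K_TABLE, np.array([0.3, -0.3]), np.zeros(2))
        assert gene_selection_cost(params, 1.0, 1.0, np.array([4.0, 6.0])) == 0.0

    def test_hand_value_and_kappa_linearity(self):
        # Δη = (−1, +1), N_e = 10⁷, all 10 codons on codon 2 → s = −10⁻⁶
        params = MutSelParams(K_TABLE, np.zeros(2), np.array([-1.0, 1.0]))
        counts = np.array([0.0, 10.0])
        s1 = gene_selection_cost(params, 1.0, 1.0, counts, ne=1e7)
        assert s1 == pytest.approx(-1e-6, rel=1e-12)
        s2 = gene_selection_cost(params, 2.0, 1.0, counts, ne=1e7)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_linear_in_each_delta_eta_prime(self):
        base = MutSelParams(K_TABLE, np.zeros(2), np.array([-0.5, 0.5]))
        double = MutSelParams(K_TABLE, np.zeros(2), np.array([-1.0, 1.0]))
        counts = np.array([3.0, 7.0])
        assert gene_selection_cost(double, 1.0, 1.0, counts) == pytest.approx(
            2 * gene_selection_cost(base, 1.0, 1.0, counts)
        )


class TestDeltaS:
    def test_zero_when_donor_equals_host(self, table):
        truth = make_truth(n_genes=30, length=150, sigma_phi=1.0, seed=2)
        genes = simulate_counts(truth)
        host = truth.params["endogenous"]
        res = delta_s(host, host, genes, truth.phi, kappa_intro=1.0)
        assert np.allclose(res.per_gene["delta_s"], 0.0, atol=1e-15)
        assert res.total_delta_s == 0.0

    def test_opposed_donor_bias_costs_fitness(self, table):
        """Donor mutation bias pushing against host selection → Δs < 0."""
        rng = np.random.default_rng(4)
        de = rng.normal(0, 0.4, table.n_codons)
        host = MutSelParams(table, np.zeros(table.n_codons), de).recenter()
        # donor mutation favors exactly the codons host selection penalizes
        donor = MutSelParams(table, -2.0 * host.delta_eta, np.zeros(table.n_codons)).recenter()
        truth = make_truth(
            n_genes=40, length=200, sigma_phi=1.0, seed=5, params={"endogenous": host}
        )
        genes = simulate_counts(truth)
        res = delta_s(host, donor, genes, truth.phi, kappa_intro=1.0)
        assert res.total_delta_s < 0

    def test_aligned_donor_bias_exapts_low_expression_gene(self):
        """Donor mutation bias matching host selection on a low-φ gene → Δs > 0."""
        host = MutSelParams(
            K_TABLE, np.array([0.5, -0.5]), np.array([-0.5, 0.5])
        )  # host mutation favors codon 2; host selection favors codon 1
        donor = MutSelParams(
            K_TABLE, np.array([-1.0, 1.0]), np.zeros(2)
        )  # donor mutation favors codon 1, as host selection does
        genes = k_genome([[5, 5]])
        phi = pd.Series([0.2], index=["g0"])
        res = delta_s(host, donor, genes, phi, kappa_intro=1.0)
        assert res.per_gene["delta_s"].iloc[0] > 0
        assert bool(res.per_gene["exapted"].iloc[0])

    def test_missing_phi_skipped_with_warning(self):
        host = MutSelParams(K_TABLE, np.zeros(2), np.array([-0.3, 0.3]))
        genes = k_genome([[5, 5], [2, 8]])
        phi = pd.Series([1.0], index=["g0"])
        with pytest.warns(UserWarning, match="skipped"):
            res = delta_s(host, host, genes, phi)
        assert len(res.per_gene) == 1

    def test_aggregate_is_sum(self, table):
        truth = make_truth(n_genes=20, length=150, sigma_phi=1.0, seed=6)
        genes = simulate_counts(truth)
        host = truth.params["endogenous"]
        donor = endogenous_like(table, np.random.default_rng(9))
        res = delta_s(host, donor, genes, truth.phi, kappa_intro=2.0)
        assert res.total_delta_s == pytest.approx(res.per_gene["delta_s"].sum())


class TestOptimizeKappa:
    def test_degenerate_all_neutral_hits_lower_boundary(self):
        host = MutSelParams(K_TABLE, np.array([0.3, -0.3]), np.zeros(2))
        genes = k_genome([[5, 5], [8, 2]])
        phi = pd.Series([1.0, 1.0], index=["g0", "g1"])
        with pytest.warns(UserWarning, match="boundary"):
            kappa, scan = optimize_kappa(host, host, genes, phi)
        assert kappa == pytest.approx(0.1)
        assert np.allclose(scan["cost"], 0.0)

    def test_five_fold_efficacy_recovered(self, table):
        """Donor = host selection at one-fifth efficacy, orthogonal mutation
        bias → the efficacy conversion κ* ≈ 5 (exact in the weak-selection
        limit)."""
        rng = np.random.default_rng(5)
        h0 = endogenous_like(table, rng)
        host = MutSelParams(table, np.zeros(table.n_codons), h0.delta_eta, "endogenous")
        donor = MutSelParams(table, np.zeros(table.n_codons), host.delta_eta / 5.0, "source")
        truth = make_truth(
            n_genes=200, length=300, sigma_phi=1.0, seed=9, params={"endogenous": host}
        )
        genes = simulate_counts(truth)
        kappa, scan = optimize_kappa(host, donor, genes, truth.phi)
        assert 4.5 <= kappa <= 5.5
        # grid-minimum property
        at = lambda k: float(scan.loc[np.isclose(scan["kappa"], k), "cost"])
        assert at(kappa) <= at(round(kappa - 0.1, 10))
        assert at(kappa) <= at(round(kappa + 0.1, 10))

    def test_signed_total_objective_is_linear_hence_boundary(self, table):
        rng = np.random.default_rng(5)
        h0 = endogenous_like(table, rng)
        host = MutSelParams(table, np.zeros(table.n_codons), h0.delta_eta, "endogenous")
        donor = MutSelParams(table, np.zeros(table.n_codons), host.delta_eta / 5.0, "source")
        truth = make_truth(
            n_genes=50, length=150, sigma_phi=1.0, seed=9, params={"endogenous": host}
        )
        genes = simulate_counts(truth)
        with pytest.warns(UserWarning, match="boundary"):
            kappa, _ = optimize_kappa(host, donor, genes, truth.phi, objective="total")
        assert kappa in (0.1, 10.0)


class TestFixationProbability:
    @pytest.mark.parametrize(
        "ds, ne, expected",
        [(-0.0008, 1e7, -6952), (-0.0003, 1e7, -2609)],
    )
    def test_reported_exponents(self, ds, ne, expected):
        assert round(log10_fixation_probability(ds, ne)) == expected

    def test_neutral_limit_and_continuity(self):
        ne = 1e7
        neutral = log10_fixation_probability(0.0, ne)
        assert neutral == pytest.approx(-math.log10(2 * ne))
        # at |Δs| = 1e-14 the genuine O(Δs·N_e) correction is ≈ 1e-7
        for eps in (1e-14, -1e-14):
            assert log10_fixation_probability(eps, ne) == pytest.approx(neutral, abs=1e-6)

    def test_strictly_increasing_in_ds(self):
        ne = 1e6
        grid = np.linspace(-0.002, 0.002, 41)
        vals = [log10_fixation_probability(float(d), ne) for d in grid]
        assert np.all(np.diff(vals) > 0)

    def test_matches_arbitrary_precision(self):
        """Log-space result vs mpmath direct evaluation, 20 random inputs."""
        rng = np.random.default_rng(12)
        mpmath.mp.dps = 60
        for _ in range(20):
            ds = float(rng.uniform(-0.002, 0.001))
            ne = float(10 ** rng.uniform(5, 7.5))
            if ds == 0:
                continue
            with mpmath.workdps(60):
                pi = (1 - mpmath.e**(-mpmath.mpf(ds))) / (
                    1 - mpmath.e**(-2 * mpmath.mpf(ds) * mpmath.mpf(ne))
                )
                exact = float(mpmath.log10(pi))
            ours = log10_fixation_probability(ds, ne)
            assert ours == pytest.approx(exact, rel=1e-8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            log10_fixation_probability(0.1, -1.0)
        with pytest.raises(ValueError):
            log10_fixation_probability(float("nan"), 1e7)
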