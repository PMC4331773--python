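"""Cell state, update order, division inheritance, phenotype."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from epidrift.cells import (
    ARPDefinition,
    GenomeTables,
    attempt_division,
    daughter_methylation,
    evaluate_phenotype,
    initial_cell,
    partition_histones,
    promoter_occupancies,
    step_cell,
    transcription_theta,
)
from epidrift.genome import make_fixture_genome
from epidrift.regulation import (
    RegulationParams,
    hmt_binding_probability,
    expression_fixed_point,
)


@pytest.fixture(scope="module")
def tables(genome):
    return GenomeTables(genome)


class TestInitialCell:
    def test_chromatin_starts_fully_modified_and_unmethylated(self, tables, params):
        c = initial_cell(tables, params)
        np.testing.assert_array_equal(c.n_hm, tables.n_h)
        assert not c.cpg_meth.any()
        w = tables.unmethylated_fraction(c.cpg_meth)
        assert (w[tables.cpg_counts > 0] == 1.0).all()
        theta = hmt_binding_probability(c.n_hm, tables.n_h, w, params)
        # Theta is at its maximum over reachable chromatin states
        assert (
            theta[tables.has_nuc]
            >= hmt_binding_probability(
                c.n_hm - 1, tables.n_h, w * 0.9, params
            )[tables.has_nuc]
        ).all()

    def test_isolated_gene_fixed_point(self, params):
        g = make_fixture_genome(n_h=[8], seed=3)
        # strip interactions so the promoter sits at its basal occupancy
        g.genes[0].interactions = []
        c = initial_cell(g, params)
        theta = hmt_binding_probability(8, 8, 1.0, params)
        expected = expression_fixed_point(
            params.q_p / (1 + params.q_p), theta, params
        )
        assert c.expression[0] == pytest.approx(expected, rel=1e-9)

    def test_coupled_fixed_point_matches_root_finder(self, params):
        genome = make_fixture_genome(n_h=[2, 4, 4, 6, 8, 8] * 3 + [0, 8], seed=11)
        tables = GenomeTables(genome)
        c = initial_cell(tables, params)
        w = tables.unmethylated_fraction(np.zeros(tables.total_cpgs, bool))
        theta_t = transcription_theta(
            hmt_binding_probability(tables.n_h, tables.n_h, w, params), tables
        )

        def residual(e):
            return (
                params.p_max
                * promoter_occupancies(e, tables, params)
                * theta_t
                / params.delta
                - e
            )

        root = fsolve(residual, np.full(tables.n_genes, 100.0), full_output=False)
        assert np.max(np.abs(c.expression - root) / np.maximum(root, 1e-9)) < 1e-6


class TestStepCell:
    def test_quiescent_cell_never_changes_dna_methylation(self, tables, params, rng):
        c = initial_cell(tables, params)
        before = c.cpg_meth.copy()
        for _ in range(10_000):
            step_cell(c, tables, params, rng)
        np.testing.assert_array_equal(c.cpg_meth, before)

    def test_full_modification_absorbing_without_demodification(self, tables, rng):
        p = RegulationParams(k_d=0.0)
        c = initial_cell(tables, p)
        for _ in range(1000):
            step_cell(c, tables, p, rng)
        np.testing.assert_array_equal(c.n_hm, tables.n_h)

    def test_c3_genes_transcribe_without_chromatin_gate(self, tables, params, rng):
        c = initial_cell(tables, params)
        for _ in range(200):
            step_cell(c, tables, params, rng)
        c3 = np.flatnonzero(~tables.has_nuc)
        # nucleosome-free genes stay expressed at their promoter-set level
        assert (c.expression[c3] > 100).all()


class TestDivision:
    def test_empty_pool_partitions_to_empty(self, rng):
        d1, d2 = partition_histones(np.zeros(5, dtype=int), rng)
        assert not d1.any() and not d2.any()

    def test_histone_conservation_and_symmetry(self, rng):
        n = np.full(2000, 6)
        d1, d2 = partition_histones(n, rng)
        np.testing.assert_array_equal(d1 + d2, n)
        assert np.mean(d1) == pytest.approx(3.0, rel=0.05)

    def test_mean_interdivision_time_about_one_generation(self, tables, params, rng):
        # R = 0.005 per step: mean waiting time 200 steps (~1 generation)
        c = initial_cell(tables, params, environment="omega")
        times, last, t = [], 0, 0
        while len(times) < 300:
            t += 1
            out = attempt_division(c, 0.005, tables, params, rng)
            if out is not None:
                c = out[0]
                c.environment = "omega"
                times.append(t - last)
                last = t
        assert np.mean(times) == pytest.approx(200.0, rel=0.15)

    def test_division_in_niche_is_contract_violation(self, tables, params, rng):
        c = initial_cell(tables, params, environment="alpha")
        with pytest.raises(ValueError):
            attempt_division(c, 0.005, tables, params, rng)

    def test_daughter_generation_and_clone_bookkeeping(self, tables, params, rng):
        c = initial_cell(tables, params, clone_id=7, environment="omega")
        c.generation = 3
        c.division_progress = 1.0
        d1, d2 = attempt_division(c, 0.005, tables, params, rng)
        for d in (d1, d2):
            assert d.generation == 4
            assert d.clone_id == 7
            assert d.division_progress == 0.0

    def test_dilution_opens_methylation_window(self, tables, params, rng):
        # de novo pressure is evaluated on the *post-partition* state: a
        # fully diluted daughter methylates at the full constant
        meth = np.zeros(tables.total_cpgs, dtype=bool)
        gains_low = [
            daughter_methylation(meth, np.zeros_like(tables.n_h), tables, params, rng).sum()
            for _ in range(300)
        ]
        gains_high = [
            daughter_methylation(meth, tables.n_h, tables, params, rng).sum()
            for _ in range(300)
        ]
        assert np.mean(gains_low) > 10 * max(np.mean(gains_high), 0.1)


class TestPhenotype:
    def test_silenced_markers_give_aged(self, tables, params):
        arp = ARPDefinition(marker_gene_ids=(7, 8, 9), ts=2.0)
        c = initial_cell(tables, params)
        c.expression[:] = 0.0
        assert evaluate_phenotype(c, arp) == "aged"

    def test_expressed_markers_give_young(self, tables, params):
        arp = ARPDefinition(marker_gene_ids=(7, 8, 9), ts=2.0)
        c = initial_cell(tables, params)
        assert evaluate_phenotype(c, arp) == "young"

    def test_boundary_mean_exactly_ts_is_young(self, tables, params):
        arp = ARPDefinition(marker_gene_ids=(7, 8, 9), ts=2.0)
        c = initial_cell(tables, params)
        c.expression[:] = 2.0
        assert evaluate_phenotype(c, arp) == "young"

    def test_markers_must_be_bistable(self, genome, params):
        with pytest.raises(ValueError):
            ARPDefinition(marker_gene_ids=(2, 3, 4)).validate_markers(genome, params)
        ARPDefinition(marker_gene_ids=(7, 8, 9)).validate_markers(genome, params)


class TestSilencingStability:
    """Reversibility of C1a silencing vs irreversibility of C2 silencing."""

    def _lineages(self, n_h, n_cpg, params, rng, n_rep, horizon, meth0):
        """Vectorized replicate Omega lineages of a single gene; returns the
        max modified count each lineage reached after burn-in."""
        from epidrift.regulation import (
            denovo_rate,
            replicate_methylation,
            step_histones,
        )

        n = np.zeros(n_rep, dtype=np.int64)
        meth = rng.random((n_rep, n_cpg)) < meth0
        n_h_arr = np.full(n_rep, n_h)
        peak = np.zeros(n_rep, dtype=np.int64)
        for t in range(horizon):
            w = 1.0 - meth.mean(axis=1)
            theta = hmt_binding_probability(n, n_h_arr, w, params)
            n = step_histones(n, n_h_arr, theta, params, rng)
            divide = rng.random(n_rep) < 0.005
            if divide.any():
                n[divide] = rng.binomial(n[divide], 0.5)
                d = denovo_rate(n[divide], n_h, params)
                meth[divide] = replicate_methylation(
                    meth[divide], d[:, None], params, rng
                )
            if t > 500:
                peak = np.maximum(peak, n)
        return peak

    def test_methylated_c2_gene_stays_silenced(self, params, rng):
        peak = self._lineages(4, 10, params, rng, n_rep=100, horizon=5000, meth0=0.6)
        # a monostable gene with methylated DNA never regains the fully
        # modified (actively transcribed) state; brief single-nucleosome
        # flickers are not a reactivation
        assert np.mean(peak >= 4) < 0.01

    def test_silenced_c1a_gene_can_reactivate(self, params, rng):
        peak = self._lineages(8, 18, params, rng, n_rep=60, horizon=30_000, meth0=0.6)
        # imperfect maintenance (D_main < 1) lets some lineages regain the
        # high-modification mode
        assert np.mean(peak >= 7) > 0.05
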