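"""Reduced animal models: reduced designs, solutions, and back-solving."""

import numpy as np
import pandas as pd
import pytest

from ssram import (
    DesignError,
    Pedigree,
    VarianceComponents,
    a_inverse,
    assemble_reduced,
    build_reduced_design,
    classify_animals,
    equivalent_g,
    inbreeding,
    run_ram,
    solve_full,
    subset_inverse,
    tabular_a,
)
from conftest import sim_dataset


@pytest.fixture(scope="module")
def example_sets(example):
    return classify_animals(example.ped, example.genotyped,
                            set(example.records["animal"]))


@pytest.fixture(scope="module")
def example_mv(example):
    return inbreeding(example.ped)


class TestReducedDesign:
    def test_method1_w_and_r_tilde(self, example, example_sets, example_mv, expected):
        rd = build_reduced_design(example.records, example.ped, example_sets,
                                  example_mv, example.vc, 1, fixed=("sex",))
        assert set(rd.kept) == set(expected["m1_kept"])
        cols = [rd.kept.index(k) for k in expected["a_pp_inv_x6_order"]]
        rows = [rd.record_animals.index(a) for a in expected["w_m1_records"]]
        np.testing.assert_allclose(rd.W[np.ix_(rows, cols)], expected["w_m1"])
        got = dict(zip(rd.record_animals, rd.r_tilde_inv))
        for a, v in expected["r_tilde_nn"].items():
            assert got[a] == pytest.approx(v)
        for a in (4, 5, 10):  # kept records keep the raw residual
            assert got[a] == pytest.approx(0.5)
        # animal 8 has no phenotype: no row anywhere in W
        assert all(a != 8 for a in rd.record_animals)

    def test_method3_wq(self, example, example_sets, example_mv, expected):
        rd = build_reduced_design(example.records, example.ped, example_sets,
                                  example_mv, example.vc, 3, fixed=("sex",))
        cols = [rd.kept.index(k) for k in expected["m3_kept"]]
        rows = [rd.record_animals.index(a) for a in expected["w_m1_records"]]
        np.testing.assert_allclose(rd.W[np.ix_(rows, cols)], expected["w_q_m3"])

    def test_w_row_sums(self, example, example_sets, example_mv):
        rd = build_reduced_design(example.records, example.ped, example_sets,
                                  example_mv, example.vc, 1, fixed=("sex",))
        sums = rd.W.sum(axis=1)
        assert set(np.round(sums, 12)) <= {0.0, 0.5, 1.0}

    def test_b_regressions(self, example, example_sets, example_mv, expected):
        rd = build_reduced_design(example.records, example.ped, example_sets,
                                  example_mv, example.vc, 1, fixed=("sex",))
        b = {e.animal: e.B for e in rd.plan.entries}
        for a, v in expected["b_diag"].items():
            assert b[a] == pytest.approx(v, abs=1e-12)

    def test_absorbed_with_unknown_parents_gets_full_ms_inflation(self):
        """D = 1 case: W row all zero, R̃ = (σ_e² + σ_a²)⁻¹."""
        ped = Pedigree.from_records([(1, 0, 0), (2, 0, 0), (3, 1, 0), (9, 0, 0)])
        # make 9 a phenotyped nonparent founder; 1 is a parent
        rec = pd.DataFrame({"animal": [3, 9], "value": [1.0, 2.0]})
        vc = VarianceComponents(sigma_a2=1.0, sigma_e2=2.0)
        sets = classify_animals(ped, {2}, {3, 9})
        mv = inbreeding(ped)
        rd = build_reduced_design(rec, ped, sets, mv, vc, 1)
        i9 = rd.record_animals.index(9)
        np.testing.assert_allclose(rd.W[i9], 0.0)
        assert rd.r_tilde_inv[i9] == pytest.approx(1.0 / 3.0)

    def test_duplicate_absorbed_record_rejected(self, example, example_sets,
                                                example_mv):
        rec = pd.concat([example.records, example.records.iloc[[2]]],
                        ignore_index=True)
        with pytest.raises(DesignError, match="multiple records"):
            build_reduced_design(rec, example.ped, example_sets, example_mv,
                                 example.vc, 1, fixed=("sex",))


class TestSystemOrders:
    def test_example_orders(self, example):
        kw = dict(fixed=example.fixed, g=example.g)
        orders = {
            m: run_ram(example.records, example.ped, example.genotyped,
                       example.vc, m, **kw).diagnostics["order"]
            for m in (1, 2, 3)
        }
        assert orders == {1: 10, 2: 8, 3: 7}

    @pytest.mark.parametrize("seed", range(3))
    def test_order_never_grows(self, seed):
        d = sim_dataset(seed)
        vc = VarianceComponents(sigma_a2=1.0, sigma_e2=2.0,
                                sigma_alpha2=0.5, sigma_delta2=0.5)
        geno = [l for l in d.ped.labels if l in d.genotyped]
        g = equivalent_g(d.markers, tabular_a(d.ped, geno), vc)
        full = solve_full(d.records, d.ped, vc, fixed=("sex",),
                          genotyped=geno, g=g)
        o1 = run_ram(d.records, d.ped, d.genotyped, vc, 1, fixed=("sex",),
                     g=g).diagnostics["order"]
        o3 = run_ram(d.records, d.ped, d.genotyped, vc, 3, fixed=("sex",),
                     g=g).diagnostics["order"]
        assert o3 <= o1 <= full.diagnostics["order"]

    def test_reduction_of_nothing_equals_full_system(self):
        """All animals genotyped: Method 1 keeps everyone; the reduced system
        is the full system."""
        ped = Pedigree.from_records([(1, 0, 0), (2, 0, 0), (3, 2, 1)])
        rec = pd.DataFrame({"animal": [1, 2, 3], "value": [1.0, 2.0, 1.5]})
        vc = VarianceComponents(sigma_a2=1.0, sigma_e2=2.0)
        geno = (1, 2, 3)
        from ssram import LabeledSymMatrix
        g = LabeledSymMatrix(
            np.array([[1.0, 0.1, 0.5], [0.1, 1.1, 0.4], [0.5, 0.4, 1.2]]), geno)
        full = solve_full(rec, ped, vc, genotyped=geno, g=g)
        ram = run_ram(rec, ped, geno, vc, 1, g=g)
        assert ram.diagnostics["order"] == full.diagnostics["order"]
        assert (ram.provenance == "direct").all()
        assert np.abs(ram.animal - full.animal).max() < 1e-12


@pytest.fixture(scope="module")
def sols(example):
    kw = dict(fixed=example.fixed, g=example.g)
    return {m: run_ram(example.records, example.ped, example.genotyped,
                       example.vc, m, **kw) for m in (1, 2, 3)}


class TestExampleSolutions:
    def test_fixed_effects(self, sols, expected):
        for m in (1, 2, 3):
            assert sols[m].fixed["mu"] == pytest.approx(
                expected["b_hat"]["mu"], abs=5e-5)
            assert sols[m].fixed["sex:female"] == pytest.approx(
                expected["b_hat"]["sex:female"], abs=5e-5)

    def test_method1_direct_and_backsolved(self, sols, expected):
        s = sols[1]
        for a, v in expected["m1_a_p"].items():
            assert s.animal[a] == pytest.approx(v, abs=5e-5)
            assert s.provenance[a] == "direct"
        for a, v in expected["m1_a_n"].items():
            assert s.animal[a] == pytest.approx(v, abs=5e-5)
            assert s.provenance[a] == "backsolved"
        adj = s.diagnostics["adjusted_record"]
        for a, v in expected["m1_adjusted"].items():
            assert adj[a] == pytest.approx(v, abs=5e-5)
        # the nonphenotyped absorbed animal gets its parent average assigned
        assert adj[8] == pytest.approx(s.animal[4] / 2, abs=1e-12)

    def test_method2_direct_and_backsolved(self, sols, expected):
        s = sols[2]
        for a, v in expected["m2_a_p"].items():
            assert s.animal[a] == pytest.approx(v, abs=5e-5)
            assert s.provenance[a] == "direct"
        for a, v in expected["m2_a_n"].items():
            assert s.animal[a] == pytest.approx(v, abs=5e-5)
            assert s.provenance[a] == "backsolved"

    def test_method3_direct_and_backsolved(self, sols, expected):
        s = sols[3]
        for a, v in expected["m3_a_q"].items():
            assert s.animal[a] == pytest.approx(v, abs=5e-5)
        for a, v in expected["m3_a_n"].items():
            assert s.animal[a] == pytest.approx(v, abs=5e-5)
        for a, v in expected["m3_a_r"].items():
            assert s.animal[a] == pytest.approx(v, abs=5e-5)
            assert s.provenance[a] == "backsolved"

    def test_all_methods_match_full_model(self, sols, example, expected):
        full = solve_full(example.records, example.ped, example.vc,
                          fixed=example.fixed, genotyped=example.genotyped,
                          g=example.g)
        for m in (1, 2, 3):
            assert np.abs(sols[m].animal - full.animal).max() < 1e-10


class TestBacksolveIsPedigreeOnly:
    def test_method2_backsolve_reproducible_from_tabular_inverse(self, example,
                                                                 expected):
        """Absorbed solutions are a pure function of kept solutions and the
        pedigree inverse; the oracle uses dense tabular A with no genomic
        term anywhere."""
        sol = run_ram(example.records, example.ped, example.genotyped,
                      example.vc, 2, fixed=example.fixed, g=example.g)
        kept = list(expected["m2_kept"])
        absorbed = [1, 2, 3, 6, 7, 8]
        q = np.linalg.inv(tabular_a(example.ped).to_dense())
        labels = list(example.ped.labels)
        pos = {a: labels.index(a) for a in labels}
        qnn = q[np.ix_([pos[a] for a in absorbed], [pos[a] for a in absorbed])]
        qns = q[np.ix_([pos[a] for a in absorbed], [pos[a] for a in kept])]
        want = np.linalg.solve(qnn, -qns @ sol.animal[kept].to_numpy())
        np.testing.assert_allclose(sol.animal[absorbed].to_numpy(), want,
                                   atol=1e-9)

    def test_method3_r_from_app_inverse_blocks(self, example, expected):
        sol = run_ram(example.records, example.ped, example.genotyped,
                      example.vc, 3, fixed=example.fixed, g=example.g)
        app = subset_inverse(a_inverse(example.ped), expected["m1_kept"])
        r, q_set = [1, 2, 3], list(expected["m3_kept"])
        want = np.linalg.solve(
            app.block(r, r), -app.block(r, q_set) @ sol.animal[q_set].to_numpy())
        np.testing.assert_allclose(sol.animal[r].to_numpy(), want, atol=1e-12)


class TestEquivalenceAndLimits:
    @pytest.mark.parametrize("seed", range(4))
    def test_all_methods_equal_full_on_simulated_data(self, seed):
        d = sim_dataset(seed, n_founders=12, n_generations=4,
                        genotyped_fraction=0.25, phenotyped_fraction=0.7)
        vc = VarianceComponents(sigma_a2=1.0, sigma_e2=2.0,
                                sigma_alpha2=0.7, sigma_delta2=0.3)
        geno = [l for l in d.ped.labels if l in d.genotyped]
        g = equivalent_g(d.markers, tabular_a(d.ped, geno), vc)
        full = solve_full(d.records, d.ped, vc, fixed=("sex",),
                          genotyped=geno, g=g)
        for m in (1, 2, 3):
            ram = run_ram(d.records, d.ped, d.genotyped, vc, m,
                          fixed=("sex",), g=g)
            assert np.abs(ram.animal - full.animal).max() < 1e-8, f"method {m}"

    def test_pedigree_only_ram_equals_blup(self):
        d = sim_dataset(5)
        vc = VarianceComponents(sigma_a2=1.0, sigma_e2=2.0)
        full = solve_full(d.records, d.ped, vc, fixed=("sex",))
        for m in (1, 2, 3):
            ram = run_ram(d.records, d.ped, d.genotyped, vc, m, fixed=("sex",))
            assert np.abs(ram.animal - full.animal).max() < 1e-8

    def test_b_shrinks_to_zero_with_vanishing_genetic_variance(self, example,
                                                               example_sets,
                                                               example_mv):
        """B ∈ (0,1); as σ_a² → 0 the regression vanishes and back-solved
        values approach the parent average."""
        for s_a2 in (1.0, 0.1, 1e-6):
            vc = VarianceComponents(sigma_a2=s_a2, sigma_e2=2.0)
            rd = build_reduced_design(example.records, example.ped,
                                      example_sets, example_mv, vc, 1,
                                      fixed=("sex",))
            bs = np.array([e.B for e in rd.plan.entries])
            assert ((bs > 0) & (bs < 1)).all()
        assert bs.max() < 1e-6
        vc = VarianceComponents(sigma_a2=1e-9, sigma_e2=2.0)
        sol = run_ram(example.records, example.ped, example.genotyped, vc, 1,
                      fixed=example.fixed, g=example.g)
        for a in (9, 11, 12):
            s, d = example.ped.parents_of(a)
            pa = (sol.animal[s] + sol.animal[d]) / 2
            assert sol.animal[a] == pytest.approx(pa, abs=1e-8)
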