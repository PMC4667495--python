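import numpy as np
import pytest

from eemkit import (Atom, Bond, EEMParameterSet, FitConfig, Molecule,
                    SparseTypeError, TrainingExample, fit_linear_for_kappa,
                    search_kappa, solve_eem, validate_on_test_set)
from eemkit.errors import FitError
from eemkit.synthetic import GeneratorConfig, make_ground_truth

from conftest import SMALL_POOL

FAST_GRID = FitConfig(kappa_grid=(0.2, 0.8, 0.1), min_atoms_per_type=3)


@pytest.fixture(scope="module")
def small_truth():
    config = GeneratorConfig(seed=41, n_molecules=40, atoms_range=(3, 15),
                             element_pool=SMALL_POOL, kappa=0.44)
    return make_ground_truth(config)


def a_difference_error(fitted, truth):
    keys = sorted(truth.entries)
    anchor = keys[0]
    return max(
        abs((fitted.entries[k][0] - fitted.entries[anchor][0])
            - (truth.entries[k][0] - truth.entries[anchor][0]))
        for k in keys)


class TestLinearFit:
    def test_recovers_parameters_at_true_kappa(self, small_truth):
        truth, examples = small_truth
        fit = fit_linear_for_kappa(examples, 0.44, min_atoms_per_type=3)
        assert fit.residual_rms < 1e-8
        for key, (_, b_true) in truth.entries.items():
            assert fit.entries[key][1] == pytest.approx(b_true, abs=1e-6)
        fitted_set = EEMParameterSet("f", 0.44, fit.entries)
        assert a_difference_error(fitted_set, truth) < 1e-6

    def test_wrong_kappa_recovers_the_scaled_truth(self, small_truth):
        """The parameter scale is a gauge freedom: the fit at a wrong
        kappa is exactly the truth rescaled by kappa/kappa*, and the
        charges it implies are unchanged."""
        truth, examples = small_truth
        kappa = 0.44 + 0.2
        fit = fit_linear_for_kappa(examples, kappa, min_atoms_per_type=3)
        assert fit.residual_rms < 1e-8  # still an exact solution
        scale = kappa / 0.44
        for key, (_, b_true) in truth.entries.items():
            assert fit.entries[key][1] == \
                pytest.approx(scale * b_true, rel=1e-6)
        scaled_set = EEMParameterSet("s", kappa, fit.entries)
        for ex in examples[:5]:
            q = solve_eem(ex.molecule, scaled_set).charges
            assert np.max(np.abs(q - ex.ref_charges)) < 1e-8

    def test_sparse_types_refused_with_type_list(self, small_truth):
        _, examples = small_truth
        with pytest.raises(SparseTypeError) as err:
            fit_linear_for_kappa(examples[:2], 0.44,
                                 min_atoms_per_type=50)
        assert err.value.types  # names the offending types

    def test_degenerate_design_warns_beyond_gauge(self):
        mol = Molecule("h2", [Atom(0, "H", (0, 0, 0)),
                              Atom(1, "H", (0, 0, 0.9))],
                       [Bond(0, 1, 1)])
        example = TrainingExample(mol, np.zeros(2))
        fit = fit_linear_for_kappa([example], 0.5, min_atoms_per_type=1)
        assert fit.rank < fit.expected_rank
        assert any("rank deficiency" in w for w in fit.warnings)
        assert any("H1" in w for w in fit.warnings)

    def test_nonpositive_kappa_rejected(self, small_truth):
        _, examples = small_truth
        with pytest.raises(ValueError):
            fit_linear_for_kappa(examples, 0.0)


@pytest.fixture(scope="module")
def fit_result(small_truth):
    _, examples = small_truth
    return search_kappa(examples, FAST_GRID)


class TestSearchKappa:
    def test_recovers_truth_in_canonical_scale(self, small_truth,
                                               fit_result):
        truth, _ = small_truth
        assert fit_result.params.kappa == pytest.approx(0.44, abs=1e-3)
        for key, (_, b_true) in truth.entries.items():
            assert fit_result.params.entries[key][1] == \
                pytest.approx(b_true, abs=1e-6)
        assert a_difference_error(fit_result.params, truth) < 1e-6
        assert fit_result.quality.r2 >= 0.9999

    def test_quality_is_recomputed_in_charge_space(self, small_truth,
                                                   fit_result):
        _, examples = small_truth
        report = validate_on_test_set(fit_result.params, examples)
        assert report.r2 == pytest.approx(fit_result.quality.r2,
                                          abs=1e-12)
        assert report.rmsd == pytest.approx(fit_result.quality.rmsd,
                                            abs=1e-12)

    def test_trace_has_one_entry_per_grid_point_plus_refinement(
            self, fit_result):
        lo, hi, step = FAST_GRID.kappa_grid
        grid = [lo + k * step for k in range(7)]
        coarse = [k for k, _ in fit_result.kappa_trace[:len(grid)]]
        np.testing.assert_allclose(coarse, grid, atol=1e-12)
        assert len(fit_result.kappa_trace) > len(grid)  # refinement ran

    def test_winning_kappa_is_locally_optimal(self, small_truth,
                                              fit_result):
        """Perturbing the selected kappa must not improve the objective
        (within numerical jitter; the objective is flat along the scale
        gauge, so improvements can only be floating-point noise)."""
        truth, examples = small_truth
        best = fit_result.quality.r2
        step = FAST_GRID.kappa_grid[2]
        for kappa in (fit_result.params.kappa - 5 * step,
                      fit_result.params.kappa + 5 * step):
            if kappa <= 0:
                continue
            from eemkit.param_fit import _Design, _paramset_from
            design = _Design(examples, 3, 0.5)
            candidate = _paramset_from(design.fit(kappa), "probe", "")
            report = validate_on_test_set(candidate, examples)
            assert report.r2 <= best + 1e-9

    def test_determinism(self, small_truth):
        _, examples = small_truth
        r1 = search_kappa(examples, FAST_GRID)
        r2 = search_kappa(examples, FAST_GRID)
        assert r1.params.kappa == r2.params.kappa
        for key in r1.params.entries:
            assert r1.params.entries[key] == r2.params.entries[key]
        assert r1.kappa_trace == r2.kappa_trace

    def test_gauge_anchor_choice_does_not_change_charges(
            self, small_truth, fit_result):
        _, examples = small_truth
        shifted = EEMParameterSet(
            "shifted", fit_result.params.kappa,
            {k: (a + 3.3, b)
             for k, (a, b) in fit_result.params.entries.items()})
        for ex in examples[:5]:
            q0 = solve_eem(ex.molecule, fit_result.params).charges
            q1 = solve_eem(ex.molecule, shifted).charges
            assert np.max(np.abs(q0 - q1)) < 1e-12

    def test_more_data_never_hurts_on_noiseless_input(self):
        config_small = GeneratorConfig(
            seed=42, n_molecules=15, atoms_range=(3, 12),
            element_pool=SMALL_POOL, kappa=0.44)
        config_large = GeneratorConfig(
            seed=42, n_molecules=60, atoms_range=(3, 12),
            element_pool=SMALL_POOL, kappa=0.44)
        _, few = make_ground_truth(config_small)
        _, many = make_ground_truth(config_large)
        rmsd_few = search_kappa(few, FAST_GRID).quality.rmsd
        rmsd_many = search_kappa(many, FAST_GRID).quality.rmsd
        assert rmsd_many <= rmsd_few + 1e-8

    def test_unsolvable_grid_fails_with_diagnostics(self, small_truth):
        _, examples = small_truth
        # a grid of absurdly large kappa drives the system singular
        config = FitConfig(kappa_grid=(9e9, 9.2e9, 1e8),
                           min_atoms_per_type=3)
        with pytest.raises(FitError):
            search_kappa(examples, config)


class TestValidateOnTestSet:
    def test_held_out_molecules_from_same_truth(self, small_truth):
        truth, examples = small_truth
        fitted = search_kappa(examples, FAST_GRID).params
        held_out_cfg = GeneratorConfig(seed=43, n_molecules=20,
                                       atoms_range=(3, 15),
                                       element_pool=SMALL_POOL)
        from eemkit.synthetic import make_molecules
        held_out = [
            TrainingExample(mol, solve_eem(mol, truth).charges)
            for mol in make_molecules(held_out_cfg)]
        report = validate_on_test_set(fitted, held_out)
        assert report.r2 >= 0.99
        assert report.coverage_fraction == 1.0

    def test_uncovered_molecules_reduce_coverage(self, small_truth):
        truth, examples = small_truth
        no_o2 = EEMParameterSet(
            "gap", truth.kappa,
            {k: v for k, v in truth.entries.items() if k != "O2"})
        with_o2 = [ex for ex in examples
                   if any(a.element == "O" for a in ex.molecule.atoms)]
        without = [ex for ex in examples
                   if not any(a.element == "O" for a in ex.molecule.atoms)]
        assert with_o2 and without  # fixture exercises both branches
        report = validate_on_test_set(no_o2, examples)
        expected = len(without) / len(examples)
        assert report.coverage_fraction == pytest.approx(expected,
                                                         abs=1e-12)
        assert report.n_molecules == len(without)

    def test_zero_covered_molecules_is_an_error(self, small_truth):
        truth, examples = small_truth
        empty_cover = EEMParameterSet("none", truth.kappa,
                                      {"Xx1": (1.0, 1.0)})
        with pytest.raises(FitError):
            validate_on_test_set(empty_cover, examples)


class TestTrainingExample:
    def test_reference_charge_drift_rejected(self):
        mol = Molecule("h2", [Atom(0, "H", (0, 0, 0)),
                              Atom(1, "H", (0, 0, 0.9))],
                       [Bond(0, 1, 1)])
        with pytest.raises(ValueError, match="drift"):
            TrainingExample(mol, np.array([0.1, -0.05]))
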