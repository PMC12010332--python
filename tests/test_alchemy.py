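"""TI, MBAR, the solvation cycle and Wang-Landau machinery."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from linkerthermo import synthetic as syn
from linkerthermo import units
from linkerthermo.alchemy import (AlchemicalDataset, FreeEnergyResult,
                                  SoftCoreSpec, WangLandauState,
                                  consistency_check, mbar_solve,
                                  read_alchemical_dataset, solvation_cycle,
                                  ti_integrate, wang_landau_toy,
                                  wang_landau_update,
                                  write_alchemical_dataset)
from linkerthermo.errors import CapabilityError, StructuralError

KBT300 = units.kbt_kj_per_mol(300.0)


def _dhdl_dataset(lam, means, n=200, temperature=300.0, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    origin = np.repeat(np.arange(len(lam)), n)
    dhdl = np.repeat(np.asarray(means, float), n)
    if noise:
        dhdl = dhdl + noise * rng.standard_normal(dhdl.size)
    return AlchemicalDataset(lambda_states=np.asarray(lam, float),
                             temperature=temperature, origin_state=origin,
                             dhdl=dhdl)


class TestTI:
    def test_constant_integrand(self):
        ds = _dhdl_dataset([0.0, 0.5, 1.0], [7.0, 7.0, 7.0])
        res = ti_integrate(ds)
        assert res.delta_A == pytest.approx(7.0, rel=1e-12)
        assert res.per_interval.sum() == pytest.approx(res.delta_A)

    def test_linear_integrand_trapezoid_exact(self):
        lam = np.linspace(0, 1, 6)
        a, b = 2.0, 10.0
        ds = _dhdl_dataset(lam, a + b * lam)
        assert ti_integrate(ds).delta_A == pytest.approx(a + b / 2, rel=1e-12)

    def test_harmonic_toy_within_uncertainty(self):
        toy = syn.harmonic_alchemy(1000.0, 4000.0, 5, 2000, 300.0, seed=5)
        res = ti_integrate(toy.dataset)
        assert abs(res.delta_A - toy.truth["delta_A"]) < 3 * res.uncertainty

    def test_missing_dhdl_redirects(self):
        toy = syn.harmonic_alchemy(1000.0, 2000.0, 3, 50, 300.0, seed=1)
        ds = replace(toy.dataset, dhdl=None)
        with pytest.raises(CapabilityError, match="MBAR"):
            ti_integrate(ds)


class TestMBAR:
    def test_identical_states_zero(self):
        rng = np.random.default_rng(2)
        u_col = 0.5 * rng.standard_normal(400) ** 2
        u = np.column_stack([u_col, u_col])
        ds = AlchemicalDataset(lambda_states=[0.0, 1.0], temperature=300.0,
                               reduced_potentials=u,
                               origin_state=np.repeat([0, 1], 200))
        res = mbar_solve(ds)
        assert abs(res.delta_A) < 1e-10

    def test_harmonic_toy_three_sigma(self):
        for seed in range(5):
            toy = syn.harmonic_alchemy(1000.0, 4000.0, 5, 2000, 300.0, seed=seed)
            res = mbar_solve(toy.dataset)
            assert abs(res.delta_A - toy.truth["delta_A"]) < 3 * res.uncertainty

    def test_offset_states_translation_invariance(self):
        # same force constant, shifted minima: delta A = 0
        rng = np.random.default_rng(3)
        k, kbt = 800.0, KBT300
        shifts = np.array([0.0, 0.05, 0.1])
        xs, origin = [], []
        for i, x0 in enumerate(shifts):
            xs.append(rng.normal(x0, math.sqrt(kbt / k), 2000))
            origin.append(np.full(2000, i))
        x = np.concatenate(xs)
        u = 0.5 * k * (x[:, None] - shifts[None, :]) ** 2 / kbt
        ds = AlchemicalDataset(lambda_states=[0.0, 0.5, 1.0], temperature=300.0,
                               reduced_potentials=u,
                               origin_state=np.concatenate(origin))
        res = mbar_solve(ds)
        assert abs(res.delta_A) < 3 * max(res.uncertainty, 0.01)

    def test_uncertainty_calibrated(self):
        estimates, reported = [], []
        for seed in range(12):
            toy = syn.harmonic_alchemy(1000.0, 4000.0, 5, 500, 300.0, seed=seed)
            r = mbar_solve(toy.dataset)
            estimates.append(r.delta_A)
            reported.append(r.uncertainty)
        emp = np.std(estimates)
        assert np.mean(reported) == pytest.approx(emp, rel=0.8)

    def test_shift_invariance(self):
        toy = syn.harmonic_alchemy(1000.0, 3000.0, 4, 500, 300.0, seed=6)
        shifted = replace(toy.dataset,
                          reduced_potentials=toy.dataset.reduced_potentials + 13.7)
        a = mbar_solve(toy.dataset)
        b = mbar_solve(shifted)
        assert a.delta_A == pytest.approx(b.delta_A, abs=1e-8)

    def test_lambda_reversal_negates(self):
        toy = syn.harmonic_alchemy(1000.0, 3000.0, 4, 500, 300.0, seed=7)
        ds = toy.dataset
        rev = AlchemicalDataset(
            lambda_states=np.sort(1.0 - ds.lambda_states),
            temperature=ds.temperature,
            reduced_potentials=ds.reduced_potentials[:, ::-1],
            origin_state=ds.n_states - 1 - ds.origin_state)
        assert mbar_solve(rev).delta_A == pytest.approx(-mbar_solve(ds).delta_A,
                                                        abs=1e-8)
        # TI sees the sign flip too
        rev_ti = replace(rev, dhdl=-ds.dhdl)
        assert ti_integrate(rev_ti).delta_A == pytest.approx(
            -ti_integrate(ds).delta_A, abs=1e-10)

    def test_bias_shrinks_with_samples(self):
        errs = []
        for n in (200, 2000, 20000):
            per_seed = []
            for seed in range(3):
                toy = syn.harmonic_alchemy(1000.0, 4000.0, 5, n, 300.0,
                                           seed=seed)
                per_seed.append(abs(mbar_solve(toy.dataset).delta_A
                                    - toy.truth["delta_A"]))
            errs.append(np.mean(per_seed))
        assert errs[0] > errs[2]

    def test_low_overlap_warns(self):
        toy = syn.harmonic_alchemy(10.0, 100_000.0, 2, 200, 300.0, seed=8)
        with pytest.warns(UserWarning, match="overlap"):
            mbar_solve(toy.dataset)

    def test_empty_state_rejected(self):
        toy = syn.harmonic_alchemy(1000.0, 2000.0, 3, 100, 300.0, seed=9)
        ds = toy.dataset
        keep = ds.origin_state != 1
        bad = AlchemicalDataset(lambda_states=ds.lambda_states,
                                temperature=ds.temperature,
                                reduced_potentials=ds.reduced_potentials[keep],
                                origin_state=ds.origin_state[keep])
        with pytest.raises(StructuralError, match="at least one sample"):
            mbar_solve(bad)


class TestCycleAndConsistency:
    def test_equal_legs_cancel(self):
        a = FreeEnergyResult(delta_A=-10.0, uncertainty=0.0, method="MBAR")
        assert solvation_cycle(a, a).delta_A == 0.0

    def test_quadrature_arithmetic(self):
        a = FreeEnergyResult(delta_A=5.0, uncertainty=0.3, method="MBAR")
        b = FreeEnergyResult(delta_A=12.0, uncertainty=0.4, method="MBAR")
        res = solvation_cycle(a, b)
        assert res.delta_A == pytest.approx(-7.0)
        assert res.uncertainty == pytest.approx(0.5)

    def test_cycle_from_analytic_legs(self):
        solvent = syn.harmonic_alchemy(1000.0, 4000.0, 5, 2000, 300.0, seed=10)
        vacuum = syn.harmonic_alchemy(1000.0, 2000.0, 5, 2000, 300.0, seed=11)
        cyc = solvation_cycle(mbar_solve(solvent.dataset),
                              mbar_solve(vacuum.dataset))
        expect = solvent.truth["delta_A"] - vacuum.truth["delta_A"]
        assert cyc.delta_A == pytest.approx(expect, abs=3 * cyc.uncertainty + 0.05)

    def test_temperature_mismatch(self):
        a = FreeEnergyResult(delta_A=1.0, uncertainty=0.0, method="TI",
                             temperature=300.0)
        b = FreeEnergyResult(delta_A=1.0, uncertainty=0.0, method="TI",
                             temperature=310.0)
        with pytest.raises(StructuralError, match="temperature"):
            solvation_cycle(a, b)

    def test_consistency_pass_and_fail(self):
        a = FreeEnergyResult(delta_A=1.0, uncertainty=0.05, method="TI")
        b = FreeEnergyResult(delta_A=1.0, uncertainty=0.05, method="MBAR")
        rep = consistency_check(a, b)
        assert rep.passed and rep.discrepancy == 0.0 and rep.conclusive == "MBAR"
        corrupted = FreeEnergyResult(delta_A=50.0, uncertainty=0.05, method="TI")
        rep2 = consistency_check(corrupted, b)
        assert not rep2.passed and rep2.discrepancy == pytest.approx(49.0)

    def test_harmonic_toy_ti_mbar_agree(self):
        toy = syn.harmonic_alchemy(1000.0, 4000.0, 5, 2000, 300.0, seed=12)
        ti = ti_integrate(toy.dataset)
        mb = mbar_solve(toy.dataset)
        assert consistency_check(ti, mb).passed
        assert abs(ti.delta_A - mb.delta_A) < 0.1 * KBT300


class TestWangLandau:
    def test_twenty_scalings_to_converge(self):
        # smallest n with 0.7^n < 0.001
        assert math.ceil(math.log(0.001) / math.log(0.7)) == 20
        st = wang_landau_toy(np.array([0.0, 1.0]), seed=1)
        assert st.n_scalings == 20 and st.converged

    def test_update_mechanics(self):
        st = WangLandauState.initial(2, min_samples_per_state=1)
        st = wang_landau_update(st, 0)
        assert st.log_weights[0] == -1.0 and st.histogram[0] == 1
        st = wang_landau_update(st, 1)  # now flat -> reset + scale
        assert st.wl_delta == pytest.approx(0.7)
        assert st.histogram.sum() == 0 and st.n_scalings == 1

    def test_out_of_range_index(self):
        st = WangLandauState.initial(2)
        with pytest.raises(IndexError):
            wang_landau_update(st, 5)

    def test_symmetric_states_near_zero_gap(self):
        st = wang_landau_toy(np.array([0.0, 0.0]), seed=2)
        assert abs(st.log_weights[1] - st.log_weights[0]) < 0.05

    def test_weight_gap_tracks_beta_delta_a(self):
        for f in ([0.0, 1.0], [0.0, -2.0, 3.0]):
            f = np.array(f)
            st = wang_landau_toy(f, seed=3)
            gaps = st.log_weights - st.log_weights[0]
            np.testing.assert_allclose(gaps, f - f[0], atol=0.05)


class TestDatasetIO:
    def test_u_matrix_round_trip(self, tmp_path):
        toy = syn.harmonic_alchemy(1000.0, 4000.0, 4, 50, 300.0, seed=1)
        ds = replace(toy.dataset, softcore=SoftCoreSpec())
        p = tmp_path / "u.csv"
        write_alchemical_dataset(ds, p)
        back = read_alchemical_dataset(p)
        np.testing.assert_array_equal(back.reduced_potentials,
                                      ds.reduced_potentials)
        np.testing.assert_array_equal(back.lambda_states, ds.lambda_states)
        assert back.temperature == 300.0

    def test_dhdl_round_trip(self, tmp_path):
        toy = syn.harmonic_alchemy(1000.0, 4000.0, 4, 50, 300.0, seed=1)
        ds = replace(toy.dataset, reduced_potentials=None)
        p = tmp_path / "dhdl.csv"
        write_alchemical_dataset(ds, p)
        back = read_alchemical_dataset(p)
        np.testing.assert_array_equal(back.dhdl, ds.dhdl)
        assert ti_integrate(back).delta_A == pytest.approx(
            ti_integrate(toy.dataset).delta_A)

    def test_equilibration_discard(self):
        toy = syn.harmonic_alchemy(1000.0, 2000.0, 3, 100, 300.0, seed=2)
        ds = replace(toy.dataset,
                     times_ps=np.arange(toy.dataset.origin_state.size) * 2.0)
        trimmed = ds.discard_equilibration(100.0)
        assert trimmed.origin_state.size == ds.origin_state.size - 50

    @given(lam_bad=st.floats(-2.0, -0.01))
    def test_bad_lambda_rejected(self, lam_bad):
        with pytest.raises(StructuralError):
            AlchemicalDataset(lambda_states=[lam_bad, 1.0], temperature=300.0,
                              origin_state=np.array([0, 1]),
                              dhdl=np.array([0.0, 0.0]))
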