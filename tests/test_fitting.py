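"""Constrained profile fitting, mechanism classification, global fits."""

import numpy as np
import pandas as pd
import pytest

from cskinetics import core, fitting, reference, simulate
from cskinetics.fitting import (
    arrhenius_result_to_paramset,
    classify_mechanism,
    excess_macromolecule_check,
    fit_arrhenius_global,
    fit_cs_profile,
    fit_lock_and_key,
    report,
)

WT = reference.CS_VARIANTS["wt"]
LIGANDS = np.array([2.5, 5.0, 10.0, 15.0, 25.0, 40.0, 55.0, 70.0])


def closed_form_dataset(rc, ligands=LIGANDS, noise=0.0, seed=0, temperature=288.15):
    """Slow-relaxation dataset straight from the closed-form expression."""
    rng = np.random.default_rng(seed)
    alpha = core.cs_slow_relaxation(ligands, rc.k12, rc.k21, rc.kon, rc.koff)
    obs = alpha * (1.0 + noise * rng.standard_normal(alpha.size))
    err = noise * alpha if noise > 0 else np.full(alpha.size, np.nan)
    return pd.DataFrame(
        {
            "ligand_uM": ligands,
            "temperature_K": temperature,
            "alpha_s1": obs,
            "alpha_err_s1": err,
            "phase": "slow",
        }
    )


class TestCsProfileFit:
    def test_noise_free_self_consistency(self):
        data = closed_form_dataset(WT)
        result, scan = fit_cs_profile(data, koff=0.0)
        assert result.params["k12"] == pytest.approx(56.0, rel=1e-4)
        assert result.params["k21"] == pytest.approx(8.8, rel=1e-2)
        assert result.params["kon"] == pytest.approx(1.5, rel=1e-2)
        assert scan.identifiable

    def test_noisy_recovery_within_reported_uncertainty(self, wt_dataset):
        dataset, _ = wt_dataset
        result, _ = fit_cs_profile(dataset, koff=0.0)
        # truth within ~2 SE of the estimate for the well-determined k12
        assert abs(result.params["k12"] - 56.0) <= max(
            2 * result.stderr["k12"], 6.0
        )
        assert result.constraints["kon_bounds"] == [0.5, 3.0]

    def test_wide_kon_bounds_leave_k21_unidentified(self):
        # alpha2 alone constrains only the asymptote and initial slope:
        # without the independent kon interval the k21 profile is flat
        data = closed_form_dataset(WT, noise=0.05, seed=3)
        result, scan = fit_cs_profile(data, koff=0.0, kon_bounds=(1e-3, 1e3))
        assert not scan.identifiable
        assert "k21_weakly_identified" in result.flags

    def test_requires_five_ligand_points(self):
        data = closed_form_dataset(WT, ligands=np.array([5.0, 10.0, 20.0]))
        with pytest.raises(ValueError):
            fit_cs_profile(data)

    def test_profile_objective_never_beats_optimum(self):
        data = closed_form_dataset(WT, noise=0.05, seed=9)
        result, scan = fit_cs_profile(data, koff=0.0)
        assert np.all(scan.objective >= result.objective - 1e-9)


class TestLockAndKeyFit:
    def test_linear_mutant_slope_recovered(self, e217a_dataset):
        dataset, _ = e217a_dataset
        result = fit_lock_and_key(dataset)
        assert result.params["kon"] == pytest.approx(0.070, rel=0.15)

    def test_two_exact_points_give_exact_line(self):
        data = pd.DataFrame(
            {
                "ligand_uM": [10.0, 20.0],
                "temperature_K": 288.15,
                "alpha_s1": [1.5, 2.5],
                "alpha_err_s1": np.nan,
                "phase": "slow",
            }
        )
        result = fit_lock_and_key(data)
        assert result.params["kon"] == pytest.approx(0.1, rel=1e-9)
        assert result.params["koff"] == pytest.approx(0.5, rel=1e-9)

    def test_hyperbolic_data_leave_residual_trend(self):
        # a runs test needs a reasonably dense titration to have power
        data = closed_form_dataset(WT, ligands=np.linspace(2.5, 70, 16),
                                   noise=0.01, seed=5)
        result = fit_lock_and_key(data)
        assert result.extras["runs_p"] < 0.05


class TestClassifier:
    def test_wild_type_titration_is_conformational_selection(self, wt_dataset):
        dataset, _ = wt_dataset
        label, evidence = classify_mechanism(dataset)
        assert label == "conformational_selection"
        assert evidence["curvature_evident"]

    def test_frozen_mutant_titration_is_lock_and_key(self, e217a_dataset):
        dataset, _ = e217a_dataset
        label, _ = classify_mechanism(dataset, seed=2)
        assert label == "lock_and_key"

    def test_three_noisy_points_are_indeterminate(self):
        rng = np.random.default_rng(0)
        ligands = np.array([5.0, 20.0, 60.0])
        alpha = 0.07 * ligands * (1 + 0.05 * rng.standard_normal(3))
        data = pd.DataFrame(
            {
                "ligand_uM": ligands,
                "temperature_K": 288.15,
                "alpha_s1": alpha,
                "alpha_err_s1": 0.05 * alpha,
                "phase": "slow",
            }
        )
        label, _ = classify_mechanism(data)
        assert label == "indeterminate"

    def test_classifier_calibration_across_seeds(self):
        # verdict rates on simulated designs: both mechanisms >= 95% correct;
        # checked over a fixed seed panel
        wt_hits = lk_hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            data = closed_form_dataset(WT, noise=0.05, seed=100 + seed)
            label, _ = classify_mechanism(data, seed=seed)
            wt_hits += label == "conformational_selection"
            rng = np.random.default_rng(200 + seed)
            alpha = 0.070 * LIGANDS * (1 + 0.05 * rng.standard_normal(LIGANDS.size))
            lk_data = pd.DataFrame(
                {
                    "ligand_uM": LIGANDS,
                    "temperature_K": 288.15,
                    "alpha_s1": alpha,
                    "alpha_err_s1": 0.05 * alpha,
                    "phase": "slow",
                }
            )
            label, _ = classify_mechanism(lk_data, seed=seed)
            lk_hits += label == "lock_and_key"
        assert wt_hits == n_seeds
        assert lk_hits == n_seeds


def temperature_dataset(law, noise=0.0, seed=0, ligands=LIGANDS):
    frames = []
    for i, T in enumerate([278.15, 283.15, 288.15, 293.15, 298.15, 303.15]):
        rc = law.at_temperature(T)
        frames.append(
            closed_form_dataset(rc, ligands=ligands, noise=noise, seed=seed * 101 + i,
                                temperature=T)
        )
    return pd.concat(frames, ignore_index=True)


class TestArrheniusGlobal:
    LAW = reference.TEMPERATURE_GLOBAL_FIT

    def test_refuses_fewer_than_three_temperatures(self):
        data = closed_form_dataset(WT)
        with pytest.raises(ValueError):
            fit_arrhenius_global(data)

    def test_zero_activation_energy_collapses_to_isothermal_fit(self):
        flat_law = core.ArrheniusParameterSet(
            k12=(56.0, 0.0), k21=(8.8, 0.0), kon=(1.5, 0.0)
        )
        data = temperature_dataset(flat_law)
        result = fit_arrhenius_global(data, seed=1)
        assert result.params["k12_0"] == pytest.approx(56.0, rel=1e-3)
        assert result.params["kon_0"] == pytest.approx(1.5, rel=1e-2)
        assert result.params["Ea_12"] == pytest.approx(0.0, abs=0.1)

    def test_noisy_recovery_within_two_standard_errors(self):
        truth = {"k12_0": 45.0, "k21_0": 6.4, "kon_0": 1.1,
                 "Ea_12": 12.0, "Ea_21": 37.0, "Ea_on": 20.0}
        data = temperature_dataset(self.LAW, noise=0.05, seed=1)
        result = fit_arrhenius_global(data, seed=1)
        for name, value in truth.items():
            assert abs(result.params[name] - value) <= 2 * result.stderr[name], name

    def test_extrapolated_closed_fraction_at_body_temperature(self):
        data = temperature_dataset(self.LAW, noise=0.05, seed=2)
        result = fit_arrhenius_global(data, seed=2)
        law = arrhenius_result_to_paramset(result)
        rc = law.at_temperature(310.15)
        fraction_closed = rc.k21 / (rc.k12 + rc.k21)
        assert fraction_closed == pytest.approx(0.75, abs=0.1)

    def test_temperature_data_restore_k21_identifiability(self):
        # the single-temperature profile of k21 is flat without the kon
        # constraint; the multi-temperature objective is not
        single = closed_form_dataset(WT, noise=0.03, seed=7)
        _, scan_single = fit_cs_profile(single, koff=0.0, kon_bounds=(1e-3, 1e3))
        multi = temperature_dataset(self.LAW, noise=0.03, seed=7)
        result = fit_arrhenius_global(multi, seed=7)
        rel_se_multi = result.stderr["k21_0"] / result.params["k21_0"]
        assert not scan_single.identifiable
        assert rel_se_multi < 0.5  # k21 now carries a meaningful uncertainty


class TestExcessMacromolecule:
    PROTEINS = tuple(np.linspace(1.0, 20.0, 12))

    def test_conformational_selection_gives_linear_profile(self):
        design = simulate.TitrationDesign(
            (0.05,), self.PROTEINS, regime="excess_macromolecule"
        )
        traces, _ = simulate.simulate_titration(
            WT, design, simulate.TraceConfig(seed=7)
        )
        result = excess_macromolecule_check(traces)
        assert result["verdict"] == "linear"
        assert result["slope"] == pytest.approx(WT.kon * WT.fraction_open, rel=0.15)

    def test_induced_fit_gives_hyperbolic_profile(self):
        rc = simulate.InducedFitRateConstants(kon=3.0, koff=5.0, kf=15.0, kr=2.0)
        cfg = simulate.TraceConfig(
            seed=9, observable_weights={"E": 1.0, "C1": 1.3, "C2": 1.6}
        )
        streams = np.random.SeedSequence(9).spawn(len(self.PROTEINS))
        traces = []
        for i, protein in enumerate(self.PROTEINS):
            courses = simulate.simulate_induced_fit(
                rc, 0.05, protein, simulate.default_time_grid(5.0)
            )
            traces.append(
                simulate.render_trace(
                    courses,
                    cfg,
                    {"protein_uM": protein, "regime": "excess_macromolecule"},
                    rng=np.random.default_rng(streams[i]),
                )
            )
        result = excess_macromolecule_check(traces)
        assert result["verdict"] == "hyperbolic"

    def test_single_protein_concentration_is_an_error(self):
        table = pd.DataFrame({"protein_uM": [5.0], "alpha_s1": [6.5]})
        with pytest.raises(ValueError):
            excess_macromolecule_check(table)


class TestReport:
    def test_variant_table_with_derived_quantities(self):
        table = report(
            {"wt": WT, "W215A": reference.CS_VARIANTS["W215A"]}, reference="wt"
        )
        wt_row = table[table["variant"] == "wt"].iloc[0]
        mut_row = table[table["variant"] == "W215A"].iloc[0]
        assert wt_row["tau_ms"] == pytest.approx(15.4, abs=0.1)
        assert mut_row["tau_ms"] == pytest.approx(6.2, abs=0.1)
        assert wt_row["estar_to_e"] == "1:6"
        assert mut_row["estar_to_e"] == "2:1"

    def test_single_variant_has_no_fold_change_column(self):
        table = report({"wt": WT}, reference="wt")
        assert not any(c.startswith("kon_fold") for c in table.columns)

    def test_double_mutant_fold_change(self):
        double = reference.variant_rate_constants("W215A/E217A")
        table = report({"wt": WT, "double": double}, reference="wt")
        fold = table.loc[table["variant"] == "double", "kon_fold_vs_wt"].iloc[0]
        assert fold == pytest.approx(7894.7, rel=1e-3)
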