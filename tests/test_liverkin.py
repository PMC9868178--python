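"""Kinetic core: rate laws, steady states, load characteristics, capacities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepamre.liverkin import (
    Metabolite,
    ModelInstance,
    ModelValidationError,
    PlasmaState,
    ProteomeProfile,
    Reaction,
    ReferenceModelSpec,
    build_reference_model,
    capacities,
    fa_of_glucose,
    gamma_of_glucose,
    ghk_flux,
    instantiate,
    load_characteristic,
    steady_state,
)
from hepamre.liverkin.capacity import N_CAPACITIES


class TestTransferFunctions:
    def test_gamma_limits_and_midpoint(self):
        assert gamma_of_glucose(0.0) == pytest.approx(1.0)
        assert gamma_of_glucose(6.0, g_half=6.0) == pytest.approx(0.5)
        assert gamma_of_glucose(1e6) < 1e-3

    @given(st.floats(0.5, 20.0), st.floats(1.0, 8.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_gamma_monotone_decreasing(self, g_half, hill):
        grid = np.linspace(3.0, 12.0, 40)
        vals = gamma_of_glucose(grid, g_half=g_half, hill=hill)
        assert np.all(np.diff(vals) < 0)

    def test_gamma_rejects_negative_glucose(self):
        with pytest.raises(ValueError):
            gamma_of_glucose(-1.0)

    def test_ffa_fasted_above_fed_and_plateaus(self):
        assert fa_of_glucose(3.0) > fa_of_glucose(12.0)
        assert fa_of_glucose(1e9) == pytest.approx(0.2, rel=1e-6)
        # at the transfer midpoint the value is the mean of the plateaus
        assert fa_of_glucose(6.0, g_half=6.0) == pytest.approx((1.0 + 0.2) / 2)

    def test_ffa_monotone_on_grid(self):
        grid = np.linspace(3, 12, 50)
        assert np.all(np.diff(fa_of_glucose(grid)) < 0)


class TestGHK:
    def test_zero_potential_reduces_to_ficks_law(self):
        assert ghk_flux(2.0, 1, 0.0, 5.0, 3.0) == pytest.approx(2.0 * (5.0 - 3.0))
        assert ghk_flux(2.0, 1, 0.0, 4.0, 4.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("v_small", [1e-9, -1e-9])
    def test_continuity_at_zero_potential(self, v_small):
        j0 = ghk_flux(1.5, 1, 0.0, 5.0, 1.0)
        j = ghk_flux(1.5, 1, v_small, 5.0, 1.0)
        assert j == pytest.approx(j0, rel=1e-6)

    def test_series_matches_exact_form_near_singularity(self):
        # exact expression at a u just above the series switch-over
        j_series = ghk_flux(1.0, 1, 2.5e-13, 5.0, 1.0)  # |u| < 1e-8 -> series
        j_exact = ghk_flux(1.0, 1, 2.5e-9, 5.0, 1.0)  # |u| ~ 1e-4 -> exact
        assert j_series == pytest.approx(j_exact, rel=1e-6)

    def test_driven_flux_direction(self):
        # positive potential, cation: outward-positive driving of c_in
        assert ghk_flux(1.0, 1, 0.15, 1.0, 1.0, T=310.0) > 0


def _toy_chain(v1=10.0, v2=25.0, k1=2.0, k2=0.5, s0=5.0):
    """Two-step irreversible Michaelis-Menten chain with one internal pool."""
    spec = ReferenceModelSpec(
        name="toy",
        metabolites=(
            Metabolite("s_e", "plasma", s0),
            Metabolite("x", "internal", 1.0),
            Metabolite("p_e", "plasma", 0.0),
        ),
        reactions=(
            Reaction("r1", "E1", "chain", "mm_irr", v1, {"s_e": -1, "x": 1}, km={"s_e": k1}),
            Reaction("r2", "E2", "chain", "mm_irr", v2, {"x": -1, "p_e": 1}, km={"x": k2}),
        ),
        capacity_defs=(),
        gamma_params={"g_half": 6.0, "hill": 4.0},
        ffa_params={"fed_plateau": 0.2, "fasted_plateau": 1.0, "g_half": 6.0, "hill": 4.0},
        plasma_defaults={},
    )
    inst = ModelInstance(spec=spec, vmax={"r1": v1, "r2": v2}, sample_id="toy")
    plasma = PlasmaState(glucose=5.0, fatty_acids=0.5, gamma=0.5, others={"s_e": s0, "p_e": 0.0})
    return spec, inst, plasma


class TestSteadyState:
    def test_two_step_chain_matches_closed_form(self):
        v1, v2, k1, k2, s0 = 10.0, 25.0, 2.0, 0.5, 5.0
        _, inst, plasma = _toy_chain(v1, v2, k1, k2, s0)
        ss = steady_state(inst, plasma)
        flux = v1 * s0 / (k1 + s0)
        x_expected = k2 * (flux / v2) / (1.0 - flux / v2)
        assert ss.fluxes["r1"] == pytest.approx(flux, rel=1e-10)
        assert ss.fluxes["r2"] == pytest.approx(flux, rel=1e-8)
        assert ss.concentrations["x"] == pytest.approx(x_expected, rel=1e-8)

    def test_zero_uptake_silences_linear_chain(self):
        _, inst, plasma = _toy_chain()
        inst = ModelInstance(spec=inst.spec, vmax={"r1": 1e-12, "r2": 25.0}, sample_id="t")
        ss = steady_state(inst, plasma)
        assert abs(ss.fluxes["r2"]) < 1e-10

    def test_vmax_scaling_scales_fluxes_not_concentrations(self, model, reference_profile):
        inst = instantiate(model, reference_profile)
        from hepamre.liverkin.solver import plasma_state_at

        plasma = plasma_state_at(model, 5.0)
        base = steady_state(inst, plasma)
        alpha = 1.7
        scaled = ModelInstance(
            spec=model, vmax={k: alpha * v for k, v in inst.vmax.items()}, sample_id="a"
        )
        ss = steady_state(scaled, plasma)
        for rid, v in base.fluxes.items():
            assert ss.fluxes[rid] == pytest.approx(alpha * v, rel=1e-7, abs=1e-9)
        for mid, c in base.concentrations.items():
            assert ss.concentrations[mid] == pytest.approx(c, rel=1e-7)

    def test_mass_balance_residual_is_tiny(self, model, reference_load):
        for ss in reference_load.states:
            vmax_flux = max(abs(v) for v in ss.fluxes.values())
            assert ss.residual < 1e-9 * vmax_flux


class TestModelSpec:
    def test_default_model_is_valid_and_complete(self, model):
        assert len(model.capacity_defs) == N_CAPACITIES
        assert len(model.internal_metabolites) >= 8
        # the 20 numbered pathways of the lumped scheme plus the fatty-acid
        # uptake transport group
        pathways = {r.pathway for r in model.reactions}
        assert len(pathways) == 21 and "fatty_acid_uptake" in pathways

    def test_dangling_reference_is_reported(self):
        import yaml
        from importlib import resources

        doc = yaml.safe_load(
            resources.files("hepamre.data").joinpath("reference_model.yaml").read_text()
        )
        doc["reactions"][0]["stoichiometry"]["not_a_metabolite"] = 1
        with pytest.raises(ModelValidationError, match="not_a_metabolite"):
            build_reference_model(doc)

    def test_never_consumed_metabolite_is_reported(self):
        import yaml
        from importlib import resources

        doc = yaml.safe_load(
            resources.files("hepamre.data").joinpath("reference_model.yaml").read_text()
        )
        doc["metabolites"].append(
            {"id": "orphan", "compartment": "internal", "initial_mm": 1.0}
        )
        doc["reactions"][0]["stoichiometry"]["orphan"] = 1  # produced, never consumed
        with pytest.raises(ModelValidationError, match="orphan"):
            build_reference_model(doc)

    def test_nitrogen_imbalanced_reaction_is_reported(self):
        import yaml
        from importlib import resources

        doc = yaml.safe_load(
            resources.files("hepamre.data").joinpath("reference_model.yaml").read_text()
        )
        for r in doc["reactions"]:
            if r["id"] == "urea_syn":
                r["stoichiometry"]["nh4_i"] = -1  # breaks the 2N -> urea balance
        with pytest.raises(ModelValidationError, match="nitrogen"):
            build_reference_model(doc)


class TestInstantiate:
    def test_identity_profile_keeps_reference_vmax(self, model, reference_profile):
        inst = instantiate(model, reference_profile)
        for r in model.reactions:
            assert inst.vmax[r.id] == pytest.approx(r.vmax_ref)

    def test_single_enzyme_scaling_is_local(self, model):
        ratios = {r.enzyme: 1.0 for r in model.reactions}
        ratios["GCK"] = 0.5
        inst = instantiate(model, ProteomeProfile("s", ratios))
        for r in model.reactions:
            expected = 0.5 * r.vmax_ref if r.enzyme == "GCK" else r.vmax_ref
            assert inst.vmax[r.id] == pytest.approx(expected)

    def test_missing_enzymes_default_to_one_with_warnings(self, model, caplog):
        ratios = {r.enzyme: 1.0 for r in model.reactions}
        dropped = ["GCK", "CPS1", "FASN"]
        for e in dropped:
            ratios.pop(e)
        import logging

        with caplog.at_level(logging.WARNING, logger="hepamre.liverkin.model"):
            inst = instantiate(model, ProteomeProfile("s", ratios))
        assert sum("not quantified" in rec.message for rec in caplog.records) == 3
        for r in model.reactions:
            assert inst.vmax[r.id] == pytest.approx(r.vmax_ref)

    def test_non_positive_ratio_is_rejected(self, model):
        with pytest.raises(ValueError, match="GCK"):
            ProteomeProfile("s", {"GCK": -0.1})


class TestLoadCharacteristic:
    def test_glucose_release_fasted_uptake_fed(self, reference_load):
        net = reference_load.flux_series("gk") - reference_load.flux_series("g6pase")
        assert net[0] < 0  # 3 mM: hepatic glucose production
        assert net[-1] > 0  # 12 mM: hepatic glucose uptake

    def test_repeated_grid_point_gives_identical_fluxes(self, model, reference_profile):
        inst = instantiate(model, reference_profile)
        load = load_characteristic(inst, [5.0, 5.0])
        for rid in inst.vmax:
            f = load.flux_series(rid)
            assert f[0] == pytest.approx(f[1], rel=1e-9, abs=1e-12)

    def test_warm_start_agrees_with_cold_start(self, model, reference_profile):
        inst = instantiate(model, reference_profile)
        warm = load_characteristic(inst, [3.0, 7.0, 12.0])
        for g, ss_warm in zip((3.0, 7.0, 12.0), warm.states):
            cold = load_characteristic(inst, [g]).states[0]
            for rid, v in cold.fluxes.items():
                assert ss_warm.fluxes[rid] == pytest.approx(v, rel=1e-7, abs=1e-7)

    def test_grid_outside_range_rejected(self, model, reference_profile):
        inst = instantiate(model, reference_profile)
        with pytest.raises(ValueError):
            load_characteristic(inst, [2.0, 5.0])
        with pytest.raises(ValueError):
            load_characteristic(inst, [5.0, 4.0])


class TestCapacities:
    def test_exactly_sixteen_named_capacities(self, reference_capacities):
        assert len(reference_capacities.values) == 16
        assert reference_capacities.units["max_tag_content"] == "mM"

    def test_gluconeogenesis_sign_and_extremum_location(
        self, model, reference_load, reference_capacities
    ):
        assert reference_capacities.values["gluconeogenesis"] < 0
        # brute-force argmin of net glucose exchange over the grid
        net = reference_load.flux_series("gk") - reference_load.flux_series("g6pase")
        g_at_min = reference_load.glucose_grid[int(np.argmin(net))]
        assert reference_capacities.argmax_glucose["gluconeogenesis"] == g_at_min == 3.0

    @pytest.mark.parametrize("alpha", [0.5, 2.0])
    def test_flux_capacities_scale_with_abundance(
        self, model, reference_capacities, alpha
    ):
        prof = ProteomeProfile("a", {r.enzyme: alpha for r in model.reactions})
        load = load_characteristic(instantiate(model, prof))
        caps = capacities(load, spec=model, sample_id="a")
        for name, value in caps.values.items():
            if name == "max_tag_content":  # a concentration, not a flux
                assert value == pytest.approx(
                    reference_capacities.values[name], rel=1e-8
                )
            else:
                assert value == pytest.approx(
                    alpha * reference_capacities.values[name], rel=1e-8
                )

    def test_nitrogen_conservation_at_steady_state(self, reference_load):
        # N enters via ammonia + amino-acid lumps, leaves via urea + glutamine
        for ss in reference_load.states:
            n_in = (
                ss.fluxes["aa_upt"]
                + ss.fluxes["ala_util"]
                + ss.fluxes["nh3_upt"]
                + 2.0 * ss.fluxes["glnase"]
            )
            n_out = 2.0 * ss.fluxes["urea_syn"] + 2.0 * ss.fluxes["gs"]
            assert n_out == pytest.approx(n_in, rel=1e-8)
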