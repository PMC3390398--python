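"""FBA, FVA, QP flux fitting, ATP-per-flux-norm scan, crowding baseline."""

import pytest

from momentfba import (
    CrowdingParams,
    Medium,
    MetabolicModel,
    Reaction,
    SolverError,
    ValidationError,
    chain_toy,
    fba,
    fba_fixed_growth,
    fbawmc,
    fit_fluxes_qp,
    fva,
    max_atp_per_flux_square,
)
from momentfba.gpr import parse_gpr


@pytest.fixture
def chain_model():
    return chain_toy((100.0,), (1.0,), 0.5)


def two_route_model(yield2=0.5):
    """s -> b via R1 (yield 1) or via R2 (yield2 b per s)."""
    return MetabolicModel(
        "routes",
        [
            Reaction("EX_s", {"s": 1.0}),
            Reaction("R1", {"s": -1.0, "b": 1.0}),
            Reaction("R2", {"s": -1.0, "b": yield2}),
            Reaction("BM", {"b": -1.0}),
        ],
        biomass_reaction="BM",
    )


class TestFBA:
    @pytest.mark.parametrize("bound, growth", [(10.0, 10.0), (20.0, 20.0)])
    def test_growth_linear_in_uptake_bound(self, chain_model, bound, growth):
        res = fba(chain_model.model, chain_model.medium, uptake_bound=bound)
        assert res.objective == pytest.approx(growth, abs=1e-9)
        assert res.biomass_yield == pytest.approx(1.0, abs=1e-9)

    def test_half_yield_stoichiometry(self):
        model = MetabolicModel(
            "half",
            [
                Reaction("EX_s", {"s": 1.0}),
                Reaction("R1", {"s": -1.0, "b": 0.5}),
                Reaction("BM", {"b": -1.0}),
            ],
            biomass_reaction="BM",
        )
        res = fba(model, Medium("m", {"EX_s"}), uptake_bound=10.0)
        assert res.objective == pytest.approx(5.0, abs=1e-9)
        assert res.biomass_yield == pytest.approx(0.5, abs=1e-9)

    def test_unbounded_without_uptake_bound_raises(self, chain_model):
        with pytest.raises(SolverError, match="unbounded"):
            fba(chain_model.model, chain_model.medium)


class TestFBAFixedGrowth:
    def test_chain_uptake_equals_growth(self, chain_model):
        v = fba_fixed_growth(chain_model.model, chain_model.medium, 5.0)
        assert v["EX_src"] == pytest.approx(5.0, abs=1e-9)

    def test_flux_routed_through_high_yield_route(self):
        model = two_route_model(0.5)
        v = fba_fixed_growth(model, Medium("m", {"EX_s"}), 5.0)
        assert v["R1"] == pytest.approx(5.0, abs=1e-6)
        assert v["R2"] == pytest.approx(0.0, abs=1e-6)
        assert v["EX_s"] == pytest.approx(5.0, abs=1e-6)

    def test_zero_growth_gives_zero_fluxes(self, chain_model):
        v = fba_fixed_growth(chain_model.model, chain_model.medium, 0.0)
        assert max(abs(x) for x in v.values()) == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_growth_raises(self, chain_model):
        chain_model.model.reaction("EX_src").ub = 1.0
        with pytest.raises(SolverError):
            fba_fixed_growth(chain_model.model, chain_model.medium, 5.0)


class TestFVA:
    def test_linear_chain_all_unique_at_optimum(self, chain_model):
        df, unique = fva(
            chain_model.model, chain_model.medium, 1.0, uptake_bound=10.0
        )
        assert unique == set(chain_model.model.reaction_ids)

    def test_parallel_equivalent_routes_not_unique(self):
        model = two_route_model(1.0)
        df, unique = fva(model, Medium("m", {"EX_s"}), 1.0, uptake_bound=10.0)
        ranges = {r["reaction"]: (r["min"], r["max"]) for _, r in df.iterrows()}
        assert ranges["R1"] == (pytest.approx(0.0, abs=1e-6), pytest.approx(10.0, abs=1e-6))
        assert ranges["R2"] == (pytest.approx(0.0, abs=1e-6), pytest.approx(10.0, abs=1e-6))
        assert "R1" not in unique and "R2" not in unique
        assert "EX_s" in unique and "BM" in unique

    def test_fraction_zero_gives_raw_cone(self, chain_model):
        df, _ = fva(chain_model.model, chain_model.medium, 0.0, uptake_bound=10.0)
        ranges = {r["reaction"]: (r["min"], r["max"]) for _, r in df.iterrows()}
        # mass balance forces all three fluxes equal, bounded by uptake cap
        for rid in chain_model.model.reaction_ids:
            assert ranges[rid] == (
                pytest.approx(0.0, abs=1e-9),
                pytest.approx(10.0, abs=1e-9),
            )

    def test_base_fluxes_inside_ranges(self, chain_model):
        base = fba(chain_model.model, chain_model.medium, uptake_bound=10.0)
        df, _ = fva(chain_model.model, chain_model.medium, 0.9, uptake_bound=10.0)
        for _, row in df.iterrows():
            v = base.v[row["reaction"]]
            assert row["min"] - 1e-6 <= v <= row["max"] + 1e-6


class TestFitFluxesQP:
    def test_feasible_measurements_returned_exactly(self, chain_model):
        measured = {"EX_src": 4.0, "R1": 4.0, "BM": 4.0}
        res = fit_fluxes_qp(chain_model.model, measured, chain_model.medium)
        assert res.sse == pytest.approx(0.0, abs=1e-8)
        for rid, m in measured.items():
            assert res.v[rid] == pytest.approx(m, abs=1e-5)

    def test_chain_conflict_splits_difference(self, chain_model):
        # mass balance forces v1 = v2; measured (1, 3) -> fitted (2, 2), sse 2
        res = fit_fluxes_qp(
            chain_model.model, {"EX_src": 1.0, "R1": 3.0}, chain_model.medium
        )
        assert res.v["EX_src"] == pytest.approx(2.0, abs=1e-6)
        assert res.v["R1"] == pytest.approx(2.0, abs=1e-6)
        assert res.sse == pytest.approx(2.0, abs=1e-6)

    def test_single_free_measurement_matched(self, chain_model):
        res = fit_fluxes_qp(chain_model.model, {"BM": 7.5}, chain_model.medium)
        assert res.v["BM"] == pytest.approx(7.5, abs=1e-6)
        assert res.sse == pytest.approx(0.0, abs=1e-8)

    def test_no_measurements_rejected(self, chain_model):
        with pytest.raises(ValidationError):
            fit_fluxes_qp(chain_model.model, {}, chain_model.medium)

    def test_unknown_measured_id_rejected(self, chain_model):
        with pytest.raises(ValidationError, match="R99"):
            fit_fluxes_qp(chain_model.model, {"R99": 1.0}, chain_model.medium)


class TestMaxAtpScan:
    def atp_model(self, parallel=False):
        reactions = [
            Reaction("EX_s", {"s": 1.0}),
            Reaction("R1", {"s": -1.0, "atp": 1.0}),
            Reaction("ATPD", {"atp": -1.0}),
        ]
        if parallel:
            reactions.insert(2, Reaction("R2", {"s": -1.0, "atp": 1.0}))
        return MetabolicModel("atp", reactions, biomass_reaction="ATPD")

    def test_single_route_same_flux_every_eps(self):
        model = self.atp_model()
        res = max_atp_per_flux_square(
            model, Medium("m", {"EX_s"}), 10.0, "ATPD", eps_grid=(0.5, 1.5, 7)
        )
        assert res.v["R1"] == pytest.approx(10.0, abs=1e-6)
        assert res.atp_flux == pytest.approx(10.0, abs=1e-6)

    def test_parallel_routes_split_symmetrically(self):
        model = self.atp_model(parallel=True)
        res = max_atp_per_flux_square(
            model, Medium("m", {"EX_s"}), 10.0, "ATPD", eps_grid=(0.5, 1.5, 5)
        )
        assert res.v["R1"] == pytest.approx(5.0, abs=1e-5)
        assert res.v["R2"] == pytest.approx(5.0, abs=1e-5)

    def test_single_grid_point_is_one_qp(self):
        model = self.atp_model()
        res = max_atp_per_flux_square(
            model, Medium("m", {"EX_s"}), 10.0, "ATPD", eps_grid=(1.0, 1.0, 1)
        )
        assert res.eps == pytest.approx(1.0)

    def test_refined_grid_never_worse(self):
        model = self.atp_model(parallel=True)
        args = (model, Medium("m", {"EX_s"}), 10.0, "ATPD")
        coarse = max_atp_per_flux_square(*args, eps_grid=(0.5, 1.5, 3))
        fine = max_atp_per_flux_square(*args, eps_grid=(0.5, 1.5, 9))
        assert fine.ratio >= coarse.ratio - 1e-10

    def test_missing_atp_drain_rejected(self):
        model = self.atp_model()
        with pytest.raises(ValidationError, match="NOPE"):
            max_atp_per_flux_square(model, Medium("m", {"EX_s"}), 10.0, "NOPE")


class TestFBAwMC:
    def test_chain_growth_inverse_of_coefficient(self, chain_model):
        crowding = CrowdingParams(coefficients={"R1": 0.02})
        v, growth = fbawmc(chain_model.model, chain_model.medium, crowding)
        assert growth == pytest.approx(50.0, abs=1e-8)

    def test_no_budget_no_uptake_bound_unbounded(self, chain_model):
        with pytest.raises(SolverError, match="unbounded"):
            fbawmc(chain_model.model, chain_model.medium, CrowdingParams({}))

    def test_doubling_coefficients_halves_growth(self, chain_model):
        g1 = fbawmc(chain_model.model, chain_model.medium, CrowdingParams({"R1": 0.02}))[1]
        g2 = fbawmc(chain_model.model, chain_model.medium, CrowdingParams({"R1": 0.04}))[1]
        assert g2 == pytest.approx(g1 / 2.0, rel=1e-9)

    def test_matches_enzyme_constrained_on_trivial_gpr_chain(self):
        """With a_j = MW/(kcat*C) the crowding and enzyme-capacity
        constraints coincide on single-enzyme chains."""
        from conftest import moment_growth

        toy = chain_toy((90.0, 45.0), (2.0, 1.0), 0.6)
        crowding = CrowdingParams.from_enzyme_params(toy.model, toy.params)
        _, growth_wmc = fbawmc(toy.model, toy.medium, crowding)
        assert growth_wmc == pytest.approx(moment_growth(toy), rel=1e-8)


def test_reversible_split_respected_in_crowding():
    model = MetabolicModel(
        "rev",
        [
            Reaction("EX_s", {"s": 1.0}),
            Reaction("R1", {"b": -1.0, "s": 1.0}, lb=-1e3, gpr=parse_gpr("gA")),
            Reaction("BM", {"b": -1.0}),
        ],
        biomass_reaction="BM",
    )
    v, growth = fbawmc(
        model, Medium("m", {"EX_s"}), CrowdingParams(coefficients={"R1": 0.1})
    )
    # |v_R1| is charged: growth = 1/0.1 even though the flux is negative
    assert growth == pytest.approx(10.0, abs=1e-8)
    assert v["R1"] == pytest.approx(-10.0, abs=1e-6)
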