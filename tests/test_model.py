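"""Model data types, propensities, stoichiometry and jump-channel ordering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rdhybrid as rh
from rdhybrid import (
    CompartmentGrid,
    ModelSpecificationError,
    ReactionDiffusionModel,
    ReactionSpec,
    SpeciesSpec,
    SystemState,
    build_jump_channels,
    reaction_propensity,
    reaction_state_change,
)
from rdhybrid.model import canonical_edges


def state_of(model, **counts_by_species):
    X = np.zeros((model.n_compartments, model.n_species), dtype=np.int64)
    for sp, vals in counts_by_species.items():
        X[:, model.species_index(sp)] = vals
    return SystemState(X)


class TestPropensity:
    def test_linear_degradation_scales_with_count(self):
        model, _ = rh.build_example("example1", K=10)
        state = state_of(model, M=180)
        deg = next(r for r in model.reactions if r.name == "degradation")
        assert reaction_propensity(deg, state, 3, model) == pytest.approx(1.8)

    def test_zero_order_production_rate(self):
        # v_M = 1e-4 uM/s at Lambda_M = 1.8e4 per uM: 1.8 events/s inside
        # the production region, 0 outside
        model, _ = rh.build_example("example1", K=10)
        state = state_of(model, M=0)
        prod = next(r for r in model.reactions if r.name == "production")
        assert reaction_propensity(prod, state, 0, model) == pytest.approx(1.8)
        assert reaction_propensity(prod, state, 9, model) == 0.0

    def test_trimolecular_autocatalysis_falling_factorial(self):
        # S + 2A -> 3A at alpha=1, Lambda=500, X_S=500, X_A=505:
        # a = Lambda * alpha * (X_S/Lambda) * X_A (X_A - 1)/Lambda^2
        #   = 500 * 505 * 504 / 500^2 = 509.04 events/s, which approaches the
        # mean-field rate Lambda*alpha*[S][A]^2 = 510.05 as Lambda grows
        model, _ = rh.build_example("example6_turing")
        auto = next(r for r in model.reactions if r.name == "autocatalysis")
        state = state_of(model, S=500, A=505)
        a = reaction_propensity(auto, state, 0, model)
        assert a == pytest.approx(500 * 505 * 504 / 500**2)
        assert a == pytest.approx(509.04)

    def test_insufficient_copies_give_zero_propensity(self):
        model, _ = rh.build_example("example6_turing")
        auto = next(r for r in model.reactions if r.name == "autocatalysis")
        state = state_of(model, S=500, A=1)
        assert reaction_propensity(auto, state, 0, model) == 0.0

    def test_bad_compartment_rejected(self):
        model, x0 = rh.build_example("example1", K=10)
        with pytest.raises(ModelSpecificationError):
            reaction_propensity(model.reactions[0], x0, 10, model)


class TestStateChange:
    def test_pure_degradation(self):
        model, _ = rh.build_example("example1", K=10)
        deg = next(r for r in model.reactions if r.name == "degradation")
        delta = reaction_state_change(deg, 4, model)
        assert delta[4, model.species_index("M")] == -1
        assert np.count_nonzero(delta) == 1

    def test_turing_autocatalysis(self):
        model, _ = rh.build_example("example6_turing")
        auto = next(r for r in model.reactions if r.name == "autocatalysis")
        delta = reaction_state_change(auto, 0, model)
        assert delta[0, model.species_index("S")] == -1
        assert delta[0, model.species_index("A")] == 1

    def test_mixed_lambda_binding_moves_lambda_ratio(self):
        # Lambda_M / Lambda_R = 1.8e4 / 200 = 90: one binding event removes
        # one R, creates one W and removes 90 M molecules
        model, _ = rh.build_example("example2")
        binding = next(r for r in model.reactions if r.name == "binding")
        delta = reaction_state_change(binding, 7, model)
        assert delta[7, model.species_index("M")] == -90
        assert delta[7, model.species_index("R")] == -1
        assert delta[7, model.species_index("W")] == 1

    def test_non_integer_lambda_ratio_rejected(self):
        with pytest.raises(ModelSpecificationError):
            ReactionDiffusionModel(
                species=[SpeciesSpec("A", 0, 300.0), SpeciesSpec("B", 0, 200.0)],
                grid=CompartmentGrid(extent=(2,), spacing=1.0),
                reactions=[ReactionSpec({"A": 1}, {"B": 1}, 1.0)],
            )


class TestMeanFieldLimit:
    @pytest.mark.parametrize("name", ["example1", "example2", "example3",
                                      "example6_turing"])
    def test_propensities_reproduce_pde_reaction_terms(self, name):
        """Propensity-weighted state changes / Lambda match the macroscopic
        mass-action terms to O(1/Lambda) at several concentration points."""
        model, _ = rh.build_example(name, **({"K": 12} if name != "example4_2d" else {}))
        cm = model.compiled()
        rng = np.random.default_rng(42)
        for _ in range(3):
            conc = rng.uniform(0.5, 2.0, (model.n_compartments, model.n_species))
            X = SystemState(np.round(conc * cm.lam).astype(np.int64))
            conc_eff = X.counts / cm.lam
            # stochastic side: sum_r a_kr * net_ri / Lambda_i
            dc_stoch = np.zeros((cm.K, cm.S))
            for r, rx in enumerate(model.reactions):
                for k in range(cm.K):
                    a = reaction_propensity(rx, X, k, model)
                    dc_stoch[k] += a * cm.net[r] / cm.lam
            # macroscopic side
            dc_pde = np.zeros((cm.K, cm.S))
            for rx in model.reactions:
                rate = np.full(cm.K, rx.rate) if rx.profile is None \
                    else rx.rate * rx.profile
                for sp, s in rx.reactants.items():
                    rate = rate * conc_eff[:, model.species_index(sp)] ** s
                for i in model._changed_species(rx):
                    spn = model.species[i].name
                    net = rx.products.get(spn, 0) - rx.reactants.get(spn, 0)
                    dc_pde[:, i] += net * rate
            # falling factorials differ from powers by O(s^2 / X)
            min_count = max(X.counts.min(), 1)
            tol = 10.0 / min_count + 1e-9
            scale = np.abs(dc_pde).max() + 1e-12
            assert np.abs(dc_stoch - dc_pde).max() / scale < tol


class TestJumpChannels:
    def test_three_compartment_ordering_and_rate(self):
        model, _ = rh.build_example("pure_diffusion", K=3, D=40.0, h=2.0)
        ch = build_jump_channels(model, "X")
        assert [(c.source, c.target) for c in ch] == [(0, 1), (1, 0), (1, 2), (2, 1)]
        assert all(c.rate_constant == pytest.approx(10.0) for c in ch)

    def test_two_compartments_give_two_channels(self):
        model, _ = rh.build_example("pure_diffusion", K=2)
        assert len(build_jump_channels(model, "X")) == 2

    def test_2d_channel_count_matches_edge_enumeration(self):
        # 50 x 5 grid: 2*(49*5) x-edges + 2*(50*4) y-edges = 890
        model, _ = rh.build_example("example4_2d")
        ch = build_jump_channels(model, "M")
        assert len(ch) == 890
        # brute force: directed nearest-neighbour pairs
        count = 0
        for ix in range(50):
            for iy in range(5):
                for jx, jy in ((ix - 1, iy), (ix + 1, iy), (ix, iy - 1), (ix, iy + 1)):
                    if 0 <= jx < 50 and 0 <= jy < 5:
                        count += 1
        assert count == 890
        pairs = {(c.source, c.target) for c in ch}
        assert len(pairs) == 890

    def test_non_diffusive_species_rejected(self):
        model, _ = rh.build_example("example2")
        with pytest.raises(ModelSpecificationError):
            build_jump_channels(model, "R")

    @given(K=st.integers(2, 30))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_1d_position_convention_is_a_bijection(self, K):
        # position of k->k-1 is 2k-2 and of k->k+1 is 2k-1 (1-based)
        grid = CompartmentGrid(extent=(K,), spacing=1.0)
        src, tgt = canonical_edges(grid)
        assert src.size == 2 * K - 2
        seen = set()
        for pos in range(2 * K - 2):
            s, t = src[pos] + 1, tgt[pos] + 1  # 1-based
            onebased = pos + 1
            if t == s - 1:
                assert onebased == 2 * s - 2
            else:
                assert t == s + 1 and onebased == 2 * s - 1
            seen.add((s, t))
        assert len(seen) == 2 * K - 2

    def test_2d_reduces_to_1d_when_one_extent_is_one(self):
        g1 = CompartmentGrid(extent=(6,), spacing=1.0)
        g2 = CompartmentGrid(extent=(6, 1), spacing=1.0)
        assert [tuple(e) for e in zip(*canonical_edges(g1))] == \
            [tuple(e) for e in zip(*canonical_edges(g2))]


class TestValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(rh.InvariantViolationError):
            SystemState(np.array([[-1]]))

    def test_bad_species_parameters_rejected(self):
        with pytest.raises(ModelSpecificationError):
            SpeciesSpec("X", diffusion_coefficient=-1.0)
        with pytest.raises(ModelSpecificationError):
            SpeciesSpec("X", lambda_scale=0.0)

    def test_undeclared_species_rejected(self):
        with pytest.raises(ModelSpecificationError):
            ReactionDiffusionModel(
                species=[SpeciesSpec("A")],
                grid=CompartmentGrid(extent=(2,), spacing=1.0),
                reactions=[ReactionSpec({"Z": 1}, {}, 1.0)],
            )

    def test_duplicate_species_rejected(self):
        with pytest.raises(ModelSpecificationError):
            ReactionDiffusionModel(
                species=[SpeciesSpec("A"), SpeciesSpec("A")],
                grid=CompartmentGrid(extent=(2,), spacing=1.0),
            )


class TestConfigRoundTrip:
    @pytest.mark.parametrize("name", ["example1", "example3", "example4_2d",
                                      "example6_turing"])
    def test_yaml_round_trip_preserves_model(self, name, tmp_path):
        model, _ = rh.build_example(name)
        path = tmp_path / "model.yaml"
        rh.dump_model(model, path)
        back = rh.load_model(path)
        assert back.content_hash() == model.content_hash()
        assert [s.name for s in back.species] == [s.name for s in model.species]
        assert back.grid.extent == model.grid.extent

    def test_initial_concentrations_from_config(self, tmp_path):
        import yaml

        model, _ = rh.build_example("pure_diffusion", K=3, lam=100.0)
        cfg = rh.model_to_config(model)
        cfg["initial_concentrations"] = {"X": [1.0, 0.25, 0.0]}
        path = tmp_path / "m.yaml"
        path.write_text(yaml.safe_dump(cfg))
        back, state = rh.load_problem(path)
        assert back.content_hash() == model.content_hash()
        assert state.counts[:, 0].tolist() == [100, 25, 0]
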