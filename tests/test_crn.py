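"""Core CRN data model: unit conversion, propensities, scaling, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phobr.crn import (
    COPIES_PER_UM,
    ConservationLaw,
    CRNModel,
    Reaction,
    ScalingFactors,
    Species,
    apply_scaling,
    check_conservation,
    concentration_to_counts,
    counts_to_concentration,
    load_model,
    propensity,
    save_model,
)


@pytest.mark.parametrize(
    "conc, volume, expected",
    [
        (0.0, 1.0, 0),
        (1.0, 1.0, 602),
        (1.0, 0.1, 60),
    ],
)
def test_concentration_to_counts(conc, volume, expected):
    assert concentration_to_counts(conc, volume) == expected


@given(
    conc=st.floats(min_value=0.01, max_value=100.0),
    volume=st.floats(min_value=0.1, max_value=10.0),
)
@settings(deadline=None, derandomize=True)
def test_concentration_counts_round_trip_within_one_copy(conc, volume):
    n = concentration_to_counts(conc, volume)
    back = counts_to_concentration(n, volume)
    assert abs(concentration_to_counts(back, volume) - n) <= 1
    assert abs(back - conc) * COPIES_PER_UM * volume <= 0.5 + 1e-9


@pytest.mark.parametrize("conc, volume", [(-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
def test_conversion_rejects_bad_domain(conc, volume):
    with pytest.raises(ValueError):
        concentration_to_counts(conc, volume)


def _toy_model():
    return CRNModel(
        model_id="toy",
        species=[
            Species("A", initial_copies=10),
            Species("B", initial_copies=5),
            Species("C", initial_copies=0),
        ],
        reactions=[
            Reaction("u", {"A": 1}, {"C": 1}, 0.1, "fc"),
            Reaction("b", {"A": 1, "B": 1}, {"C": 1}, 1.0, "bf"),
            Reaction("d", {"A": 2}, {"C": 1}, 1.0, "uf"),
        ],
        volume=1.0,
    )


class TestPropensity:
    def test_first_order(self):
        m = _toy_model()
        state = np.array([10, 5, 0])
        assert propensity(m.reactions[0], state, m.volume, m._index) == pytest.approx(1.0)

    def test_homodimerisation_single_copy_is_zero(self):
        m = _toy_model()
        state = np.array([1, 0, 0])
        assert propensity(m.reactions[2], state, m.volume, m._index) == 0.0

    def test_heterobimolecular_matches_concentration_oracle(self):
        # oracle: convert counts to uM, apply the deterministic rate law,
        # convert the flux back to events per second
        m = _toy_model()
        state = np.array([602, 602, 0])
        conc = 602 / COPIES_PER_UM
        expected_flux_events = 1.0 * conc * conc * COPIES_PER_UM  # k[A][B] * (N_A V)
        got = propensity(m.reactions[1], state, m.volume, m._index)
        assert got == pytest.approx(expected_flux_events, rel=1e-12)
        assert got == pytest.approx(601.8, abs=0.5)

    def test_negative_state_rejected(self):
        m = _toy_model()
        with pytest.raises(ValueError):
            propensity(m.reactions[0], np.array([-1, 0, 0]), m.volume, m._index)


def test_reaction_order_above_two_rejected():
    with pytest.raises(ValueError):
        Reaction("bad", {"A": 3}, {}, 1.0)
    with pytest.raises(ValueError):
        Reaction("bad", {"A": 2, "B": 1}, {}, 1.0)


def test_unknown_species_in_reaction_rejected():
    with pytest.raises(ValueError):
        CRNModel(
            "m",
            species=[Species("A")],
            reactions=[Reaction("r", {"A": 1}, {"Z": 1}, 1.0)],
        )


def test_duplicate_species_names_rejected():
    with pytest.raises(ValueError):
        CRNModel("m", species=[Species("A"), Species("A")], reactions=[])


class TestApplyScaling:
    def test_control_identity(self):
        m = _toy_model()
        out = apply_scaling(m, ScalingFactors(1, 1, 1))
        assert [r.rate_constant for r in out.reactions] == [
            r.rate_constant for r in m.reactions
        ]

    def test_fc_zero_silences_tagged_reactions(self):
        m = _toy_model()
        out = apply_scaling(m, ScalingFactors(0, 1, 1))
        state = np.array([10, 5, 0])
        assert propensity(out.reactions[0], state, m.volume, m._index) == 0.0

    def test_tagged_factors_applied(self):
        m = _toy_model()
        out = apply_scaling(m, ScalingFactors(1.0, 1.5, 0.5))
        assert out.reactions[1].rate_constant == pytest.approx(1.5)
        assert out.reactions[2].rate_constant == pytest.approx(0.5)

    def test_input_not_mutated(self):
        m = _toy_model()
        apply_scaling(m, ScalingFactors(0, 0, 0))
        assert m.reactions[0].rate_constant == 0.1

    @given(
        s1=st.tuples(*[st.floats(0.1, 3.0)] * 3),
        s2=st.tuples(*[st.floats(0.1, 3.0)] * 3),
    )
    @settings(deadline=None, derandomize=True)
    def test_scaling_composes_multiplicatively(self, s1, s2):
        m = _toy_model()
        a = apply_scaling(apply_scaling(m, ScalingFactors(*s1)), ScalingFactors(*s2))
        b = apply_scaling(m, ScalingFactors(*s1).combine(ScalingFactors(*s2)))
        for ra, rb in zip(a.reactions, b.reactions):
            assert ra.rate_constant == pytest.approx(rb.rate_constant, rel=1e-12)


class TestConservation:
    def test_violating_law_rejected_at_construction(self):
        with pytest.raises(ValueError):
            CRNModel(
                "m",
                species=[Species("A", initial_copies=1), Species("B")],
                reactions=[Reaction("r", {"A": 1}, {"B": 2}, 1.0)],
                conservation_laws=[ConservationLaw(("A", "B"), 1)],
            )

    def test_ssa_trajectory_conserves_promoter_total(self, full_model):
        from phobr.simulate import simulate_ssa

        traj = simulate_ssa(full_model, t_end=50.0, seed=3)
        ok, dev = check_conservation(full_model, traj)
        assert ok and dev == 0.0
        idx = [full_model.index("pPhoA"), full_model.index("pPhoAa")]
        assert np.all(traj.states[:, idx].sum(axis=1) == 10)

    def test_hand_built_violation_detected(self, full_model):
        from phobr.simulate import simulate_ssa

        traj = simulate_ssa(full_model, t_end=10.0, seed=3)
        traj.states[-1, full_model.index("pPhoAa")] += 1
        ok, dev = check_conservation(full_model, traj)
        assert not ok and dev >= 1.0

    def test_unknown_species_in_law_errors(self, full_model):
        from phobr.simulate import simulate_ssa

        traj = simulate_ssa(full_model, t_end=5.0, seed=3)
        bad = ConservationLaw(("pPhoA", "nope"), 10)
        model = CRNModel(
            full_model.model_id,
            full_model.species,
            full_model.reactions,
            full_model.volume,
            [],
        )
        model.conservation_laws = [bad]
        with pytest.raises(ValueError):
            check_conservation(model, traj)


def test_model_file_round_trip(tmp_path, full_model):
    path = tmp_path / "model.yaml"
    save_model(full_model, path)
    back = load_model(path)
    assert back.species_names == full_model.species_names
    assert [r.id for r in back.reactions] == [r.id for r in full_model.reactions]
    assert [r.rate_constant for r in back.reactions] == [
        r.rate_constant for r in full_model.reactions
    ]
    assert back.volume == full_model.volume
    assert len(back.conservation_laws) == 2
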