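"""Register enumeration, cleavage bookkeeping, and disproportionation dynamics."""

import numpy as np
import pytest

from gtase import subsites as ss
from gtase.subsites import GlycanSpecies, ReactionState, SubsiteProfile


@pytest.fixture(scope="module")
def gh57():
    return ss.gh57_preset()


@pytest.fixture(scope="module")
def gh77():
    return ss.gh77_contrast_preset()


class TestEnumerateRegisters:
    def test_trisaccharide_placements_and_productive_count(self, gh57):
        regs = ss.enumerate_registers(GlycanSpecies(3), gh57)
        assert len(regs) == 7
        productive = [r for r in regs if r.productive]
        assert len(productive) == 2
        assert sorted(tuple(r.occupied) for r in productive) == [
            (-2, -1, 1), (-1, 1, 2),
        ]

    def test_glucose_cannot_span_the_scissile_bond(self, gh57):
        regs = ss.enumerate_registers(GlycanSpecies(1), gh57)
        assert len(regs) == 9
        assert not any(r.productive for r in regs)

    def test_pentasaccharide_allows_one_acceptor_overhang(self, gh57):
        regs = ss.enumerate_registers(GlycanSpecies(5), gh57)
        inside = [r for r in regs if all(-6 <= s <= 3 for s in r.occupied)]
        assert len(inside) == 5
        productive = [r for r in regs if r.productive]
        assert len(productive) == 4
        spans = sorted((r.occupied[0], r.occupied[-1]) for r in productive)
        assert spans == [(-4, 1), (-3, 2), (-2, 3), (-1, 4)]

    def test_donor_side_overhang_is_unlimited(self, gh57):
        regs = ss.enumerate_registers(GlycanSpecies(9), gh57)
        productive = [r for r in regs if r.productive]
        # d can reach 8 with one unit below -6 overhanging the donor side
        assert max(r.donor_units for r in productive) == 8

    def test_pnp_label_occupies_the_distal_acceptor_slot(self, gh57):
        regs = ss.enumerate_registers(GlycanSpecies(6, "pNP"), gh57)
        for r in regs:
            assert r.pnp_subsite is not None
            assert len(r.occupied) == 6
            assert r.pnp_subsite > r.occupied[-1]


class TestRegisterWeight:
    def test_uniform_affinities_weigh_one(self):
        profile = SubsiteProfile(
            affinities={s: 1.0 for s in (-3, -2, -1, 1, 2, 3)}
        )
        for reg in ss.enumerate_registers(GlycanSpecies(4), profile):
            assert ss.register_weight(reg, profile) == 1.0

    def test_gh77_steric_hindrance_zeroes_plus_two_registers(self, gh77):
        for n in range(2, 8):
            for reg in ss.enumerate_registers(GlycanSpecies(n), gh77):
                occupied = set(reg.occupied)
                if reg.pnp_subsite is not None:
                    occupied.add(reg.pnp_subsite)
                if 2 in occupied:
                    assert ss.register_weight(reg, gh77) == 0.0

    def test_hand_profile_product(self):
        profile = SubsiteProfile(affinities={-1: 2.0, 1: 3.0, 2: 5.0})
        regs = ss.enumerate_registers(GlycanSpecies(2), profile)
        target = next(r for r in regs if tuple(r.occupied) == (-1, 1))
        assert ss.register_weight(target, profile) == 6.0

    def test_overhanging_units_contribute_neutral_factor(self, gh57):
        regs = ss.enumerate_registers(GlycanSpecies(5), gh57)
        overhang = next(r for r in regs if r.occupied[-1] == 4)
        # occupied -1,+1,+2,+3,+4(overhang): affinities 1*6*6*6*1
        assert ss.register_weight(overhang, gh57) == pytest.approx(216.0)


class TestCleaveAndPartition:
    def test_pentaose_register_releases_acceptor_fragment(self, gh57):
        g5 = GlycanSpecies(5)
        state = ReactionState(amounts={g5: 10.0})
        regs = ss.enumerate_registers(g5, gh57)
        # bound -2..+3: release G3, hold G2
        reg = next(r for r in regs if (r.occupied[0], r.occupied[-1]) == (-2, 3))
        out = ss.cleave_and_partition(reg, gh57, state, amount=1.0)
        assert out.amounts[GlycanSpecies(3)] == 1.0
        assert out.intermediate[2] == 1.0
        assert out.amounts[g5] == 9.0
        # bound -1..+4 (overhang): release G4, hold G1
        reg = next(r for r in regs if (r.occupied[0], r.occupied[-1]) == (-1, 4))
        out = ss.cleave_and_partition(reg, gh57, state, amount=1.0)
        assert out.amounts[GlycanSpecies(4)] == 1.0
        assert out.intermediate[1] == 1.0

    def test_nonproductive_register_is_a_noop(self, gh57):
        g3 = GlycanSpecies(3)
        state = ReactionState(amounts={g3: 5.0})
        reg = next(
            r for r in ss.enumerate_registers(g3, gh57) if not r.productive
        )
        out = ss.cleave_and_partition(reg, gh57, state)
        assert out.amounts == state.amounts
        assert out.intermediate == state.intermediate

    def test_pnp_substrate_keeps_label_on_acceptor_fragment(self, gh57):
        pnpg6 = GlycanSpecies(6, "pNP")
        state = ReactionState(amounts={pnpg6: 1.0})
        regs = ss.enumerate_registers(pnpg6, gh57)
        # glucoses on -4..+2, pNP on +3: release pNPG2, hold G4
        reg = next(r for r in regs if r.acceptor_units == 2 and r.productive)
        out = ss.cleave_and_partition(reg, gh57, state, amount=1.0)
        assert out.amounts[GlycanSpecies(2, "pNP")] == 1.0
        assert out.intermediate[4] == 1.0
        # held G4 transferred onto fresh pNPG6 -> pNPG10
        out.amounts[pnpg6] = 1.0
        final = ss.transfer_intermediate(out, 4, pnpg6, amount=1.0)
        assert final.amounts[GlycanSpecies(10, "pNP")] == 1.0

    def test_transfer_concatenates_lengths(self, gh57):
        state = ReactionState(
            amounts={GlycanSpecies(3): 2.0}, intermediate={1: 1.0}
        )
        out = ss.transfer_intermediate(state, 1, GlycanSpecies(3), amount=1.0)
        assert out.amounts[GlycanSpecies(4)] == 1.0
        assert out.intermediate[1] == 0.0

    def test_hydrolysis_releases_held_fragment_free(self):
        state = ReactionState(intermediate={2: 1.0})
        out = ss.hydrolyze_intermediate(state, 2, amount=1.0)
        assert out.amounts[GlycanSpecies(2)] == 1.0

    def test_mass_is_conserved_by_every_event(self, gh57):
        g5 = GlycanSpecies(5)
        state = ReactionState(amounts={g5: 10.0, GlycanSpecies(3): 4.0})
        total = state.total_glucose_units()
        reg = next(
            r for r in ss.enumerate_registers(g5, gh57) if r.productive
        )
        state = ss.cleave_and_partition(reg, gh57, state)
        assert state.total_glucose_units() == pytest.approx(total)
        d = next(iter(state.intermediate))
        state = ss.transfer_intermediate(state, d, GlycanSpecies(3))
        assert state.total_glucose_units() == pytest.approx(total)


class TestSimulation:
    def test_glucose_units_conserved_deterministically(self, gh57):
        state = ReactionState(amounts={GlycanSpecies(5): 10.0})
        result = ss.simulate(state, gh57, duration=120.0)
        mass = result.glucose_units()
        assert np.max(np.abs(mass - mass[0])) / mass[0] < 1e-9

    def test_gh57_early_products_from_pentaose(self, gh57):
        state = ReactionState(amounts={GlycanSpecies(5): 10.0})
        result = ss.simulate(state, gh57, duration=120.0)
        profile = ss.product_profile(result, 2.0).set_index("species")
        for major in ("G4", "G3"):
            for minor in ("G2", "G1"):
                assert profile.loc[major, "amount"] > profile.loc[minor, "amount"]

    def test_gh57_top_product_from_tetraose_is_maltotriose(self, gh57):
        state = ReactionState(amounts={GlycanSpecies(4): 10.0})
        result = ss.simulate(state, gh57, duration=120.0)
        assert ss.top_products(result, 2.0, 1) == ["G3"]
        profile = ss.product_profile(result, 2.0).set_index("species")
        assert profile.loc["G1", "fraction"] < profile.loc["G3", "fraction"]

    def test_short_substrates_turn_over_much_slower(self, gh57):
        def consumed(n):
            sp = GlycanSpecies(n)
            result = ss.simulate(
                ReactionState(amounts={sp: 10.0}), gh57, duration=10.0
            )
            idx, row = result.state_at(10.0)
            return 10.0 - row[result.species.index(sp.name)]

        assert consumed(3) < 0.3 * consumed(5)
        assert consumed(2) < 0.05 * consumed(5)

    def test_gh77_contrast_releases_glucose_first(self, gh77):
        state = ReactionState(amounts={GlycanSpecies(5): 10.0})
        result = ss.simulate(state, gh77, duration=120.0)
        assert "G1" in ss.top_products(result, 2.0, 2)

    def test_stochastic_counts_conserve_mass_exactly(self, gh57):
        state = ReactionState(amounts={GlycanSpecies(5): 5.0})
        result = ss.simulate(
            state, gh57, duration=10.0, mode="stochastic", seed=7,
            system_size=1000.0, n_output=11,
        )
        counts = result.glucose_units() * 1000.0
        assert np.allclose(counts, counts[0], atol=1e-6)

    def test_identical_seeds_reproduce_trajectories_bitwise(self, gh57):
        state = ReactionState(amounts={GlycanSpecies(5): 5.0})
        kwargs = dict(duration=5.0, mode="stochastic", seed=42,
                      system_size=500.0, n_output=6)
        a = ss.simulate(state, gh57, **kwargs)
        b = ss.simulate(state, gh57, **kwargs)
        np.testing.assert_array_equal(a.data, b.data)

    def test_stochastic_tracks_deterministic_at_large_counts(self, gh57):
        state = ReactionState(amounts={GlycanSpecies(5): 10.0})
        omega = 1e4  # 10 mM x 1e4 = 1e5 molecules
        sto = ss.simulate(state, gh57, duration=5.0, mode="stochastic",
                          seed=11, system_size=omega, n_output=6)
        det = ss.simulate(state, gh57, duration=5.0, n_output=6)
        i = 5
        for name in ("G5", "G4", "G3", "G2", "G6"):
            j = det.species.index(name)
            expected = det.data[i, j] * omega
            observed = sto.data[i, j] * omega
            se = max(np.sqrt(expected), 1.0)
            assert abs(observed - expected) <= 3.0 * se, name

    def test_negative_rate_constants_rejected(self):
        with pytest.raises(ValueError):
            ss.gh57_preset(hydrolysis_rate=-1.0)

    def test_zero_duration_rejected(self, gh57):
        with pytest.raises(ValueError):
            ss.simulate(
                ReactionState(amounts={GlycanSpecies(5): 1.0}), gh57, duration=0.0
            )


class TestProductProfile:
    def test_initial_snapshot_equals_initial_amounts(self, gh57):
        state = ReactionState(amounts={GlycanSpecies(5): 10.0})
        result = ss.simulate(state, gh57, duration=10.0)
        profile = ss.product_profile(result, 0.0)
        assert list(profile["species"]) == ["G5"]
        assert profile["amount"].iloc[0] == pytest.approx(10.0)

    def test_fractions_sum_to_one_over_products(self, gh57):
        state = ReactionState(amounts={GlycanSpecies(5): 10.0})
        result = ss.simulate(state, gh57, duration=30.0)
        profile = ss.product_profile(result, 10.0)
        fractions = profile.loc[~profile["is_substrate"], "fraction"]
        assert fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_out_of_range_time_rejected(self, gh57):
        state = ReactionState(amounts={GlycanSpecies(5): 10.0})
        result = ss.simulate(state, gh57, duration=10.0)
        with pytest.raises(ValueError):
            ss.product_profile(result, 99.0)
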