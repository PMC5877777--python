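import math

import numpy as np
import pytest

from allonet.eam import (
    R_KCAL,
    EnsembleModel,
    ToyFoldingSpec,
    alanine_delta,
    enumerate_ensemble,
    make_partition,
    mutation_scan,
    residue_stability,
    susceptible_regions,
    unit_energies_from_structure,
)
from allonet.regions import Interval
from oracles import brute_ensemble

RT25 = R_KCAL * 298.15


class TestPartition:
    def test_164_residues_gives_21_units(self):
        p = make_partition(164, window=8, min_terminal=4)
        sizes = [end - start + 1 for start, end in p.units]
        assert len(sizes) == 21
        assert sizes == [8] * 20 + [4]

    def test_exact_window_is_single_unit(self):
        assert make_partition(8).units == ((1, 8),)

    def test_remainder_of_five_stands_alone(self):
        p = make_partition(13, window=8, min_terminal=4)
        assert [e - s + 1 for s, e in p.units] == [8, 5]

    def test_short_remainder_merges_into_last_unit(self):
        p = make_partition(19, window=8, min_terminal=4)
        assert [e - s + 1 for s, e in p.units] == [8, 11]

    def test_shift_produces_leading_unit(self):
        p = make_partition(20, window=8, min_terminal=4, shift=4)
        assert [e - s + 1 for s, e in p.units] == [4, 8, 8]

    def test_short_shift_merges_forward(self):
        p = make_partition(20, window=8, min_terminal=4, shift=2)
        # lead 2 merges into the first window, trailing 2 into the last
        assert [e - s + 1 for s, e in p.units] == [10, 10]

    def test_units_tile_without_gaps(self):
        for n in (8, 13, 30, 164):
            p = make_partition(n)
            covered = [r for s, e in p.units for r in range(s, e + 1)]
            assert covered == list(range(1, n + 1))

    def test_window_below_terminal_minimum_rejected(self):
        with pytest.raises(ValueError, match="min_terminal"):
            make_partition(20, window=3, min_terminal=4)

    def test_unit_lookup(self):
        p = make_partition(13)
        assert p.unit_of(8) == 0 and p.unit_of(9) == 1
        with pytest.raises(KeyError):
            p.unit_of(14)


class TestEnsemble:
    def test_two_units_probabilities_normalize(self):
        m = enumerate_ensemble(make_partition(16), energies=np.array([2.0, 3.0]))
        assert m.state_probabilities.size == 4
        assert abs(m.state_probabilities.sum() - 1.0) <= 1e-12

    def test_single_unit_boltzmann_ratio(self):
        m = enumerate_ensemble(make_partition(8), energies=np.array([5.0]))
        # P(folded)/P(unfolded) = exp(5/RT) ~ 4.6e3 at 25 C
        assert m.kappa_units[0] == pytest.approx(math.exp(5.0 / RT25), rel=1e-12)
        assert m.kappa_units[0] == pytest.approx(4.63e3, rel=0.01)

    def test_uniform_default_calibrates_to_overall_stability(self):
        m = enumerate_ensemble(make_partition(40), overall_dg=5.0)
        assert m.partition.n_units == 5
        np.testing.assert_allclose(m.unit_energies, 1.0)

    def test_unit_cap_refused_loudly(self):
        with pytest.raises(ValueError, match="coarser window"):
            enumerate_ensemble(make_partition(8 * 25))

    def test_toy_spec_input(self):
        spec = ToyFoldingSpec(16, unit_energies=np.array([1.0, 4.0]))
        m = enumerate_ensemble(spec)
        assert m.n_units == 2

    def test_enumeration_chunk_order_invariant(self):
        from allonet.eam import _accumulate
        g = np.array([0.5, 1.5, 2.0, 0.7])
        z1, f1, _ = _accumulate(g, RT25, False)
        z2, f2, _ = _accumulate(g, RT25, False, chunk=1)
        assert z1 == pytest.approx(z2, rel=1e-12)
        np.testing.assert_allclose(f1, f2, rtol=1e-12)


class TestResidueStability:
    def test_symmetric_two_state_system(self):
        m = enumerate_ensemble(make_partition(8), energies=np.array([0.0]))
        table = residue_stability(m)
        np.testing.assert_allclose(table["kappa_f"], 1.0)
        np.testing.assert_allclose(table["dG_f"], 0.0, atol=1e-15)

    def test_single_unit_closed_form(self):
        m = enumerate_ensemble(make_partition(8), energies=np.array([5.0]))
        table = residue_stability(m)
        np.testing.assert_allclose(table["dG_f"], -5.0, atol=1e-10)

    def test_identity_dg_equals_minus_rt_log_kappa(self):
        spec = ToyFoldingSpec(24, unit_energies=np.array([0.3, 2.0, 1.2]))
        m = enumerate_ensemble(spec)
        table = residue_stability(m)
        np.testing.assert_allclose(
            table["dG_f"], -m.rt * np.log(table["kappa_f"]), rtol=1e-14)

    def test_same_unit_residues_share_values(self):
        m = enumerate_ensemble(make_partition(13), energies=np.array([1.0, 2.0]))
        table = residue_stability(m)
        assert table["kappa_f"][:8].nunique() == 1
        assert table["kappa_f"][8:].nunique() == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        u = int(rng.integers(1, 7))
        g = rng.uniform(-1.0, 3.0, size=u)
        m = enumerate_ensemble(make_partition(8 * u), energies=g)
        kappa_b, dg_b, z_b = brute_ensemble(g, 298.15)
        np.testing.assert_allclose(m.kappa_units, kappa_b, rtol=1e-10)
        np.testing.assert_allclose(m.dg_units(), dg_b, rtol=1e-10, atol=1e-12)
        assert m.z == pytest.approx(z_b, rel=1e-10)

    def test_monotone_in_unit_energy(self):
        lo = enumerate_ensemble(make_partition(16), energies=np.array([1.0, 1.0]))
        hi = enumerate_ensemble(make_partition(16), energies=np.array([2.0, 1.0]))
        assert hi.kappa_units[0] > lo.kappa_units[0]


class TestMutationScan:
    def test_zero_perturbation_is_identity(self):
        m = enumerate_ensemble(make_partition(24))
        scan = mutation_scan(m, site=5, delta=0.0)
        np.testing.assert_allclose(scan["ddG"], 0.0, atol=1e-14)

    def test_single_unit_stabilization_closed_form(self):
        m = enumerate_ensemble(make_partition(8), energies=np.array([5.0]))
        scan = mutation_scan(m, site=1, delta=1.0)  # g: 5 -> 6
        np.testing.assert_allclose(scan["ddG"], -1.0, atol=1e-10)

    def test_two_unit_toy_matches_brute_force(self):
        g = np.array([1.3, 0.8])
        m = enumerate_ensemble(make_partition(16), energies=g)
        scan = mutation_scan(m, site=2, delta=-0.5)
        g_mut = g.copy()
        g_mut[0] += -0.5
        _, dg_wt, _ = brute_ensemble(g, 298.15)
        _, dg_mut, _ = brute_ensemble(g_mut, 298.15)
        expected = np.concatenate([
            np.full(8, dg_mut[0] - dg_wt[0]),
            np.full(8, dg_mut[1] - dg_wt[1]),
        ])
        np.testing.assert_allclose(scan["ddG"], expected, atol=1e-10)

    def test_site_outside_chain_rejected(self):
        m = enumerate_ensemble(make_partition(8))
        with pytest.raises(KeyError):
            mutation_scan(m, site=9, delta=1.0)

    def test_results_scale_with_residue_type_table(self):
        assert alanine_delta("ALA") == 0.0
        assert alanine_delta("GLY") > 0.0  # smaller than Ala
        assert alanine_delta("TRP") < alanine_delta("LEU") < 0.0


class TestSusceptibleRegions:
    def test_all_zero_profile_is_empty(self):
        assert not susceptible_regions(np.zeros(10), cutoff=0.2)

    def test_hand_thresholded_profile(self):
        profile = np.array([0.1, 0.25, 0.3, 0.1])
        rs = susceptible_regions(profile, cutoff=0.2)
        assert rs.intervals == [Interval(2, 3, "susceptible")]

    def test_high_cutoff_empties_the_set(self):
        profile = np.array([0.1, 0.25, 0.3, 0.1])
        assert not susceptible_regions(profile, cutoff=1.0)

    def test_absolute_vs_signed_mode(self):
        profile = np.array([-0.9, 0.1, 0.9])
        assert susceptible_regions(profile, 0.5).residues() == {1, 3}
        assert susceptible_regions(profile, 0.5, mode="signed").residues() == {3}

    def test_mutated_site_optionally_excluded(self):
        profile = np.array([0.9, 0.9, 0.0])
        rs = susceptible_regions(profile, 0.5, exclude_site=1)
        assert rs.residues() == {2}


def test_structure_derived_energies_rescale_to_overall(bundle30):
    partition = make_partition(bundle30.n_residues)
    g = unit_energies_from_structure(bundle30, partition, overall_dg=5.0)
    assert g.sum() == pytest.approx(5.0)
    assert (g > 0).all()
    m = enumerate_ensemble(partition, energies=g)
    assert isinstance(m, EnsembleModel)
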