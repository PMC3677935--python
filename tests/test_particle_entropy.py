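"""Particle-system estimators: half-space rule, neighbourhood states,
conditional entropy limits and invariances."""
import numpy as np
import pytest

from mixentropy import (NeighbourhoodSpec, ParticleSnapshot, Trajectory,
                        binned_shannon_entropy, composition_entropy,
                        conditional_entropy_particles, entropy_time_series,
                        generate_demixed, generate_mixed,
                        half_space_neighbours, max_mixing_entropy,
                        nb_state_cutoff, nb_state_shell, nb_state_weight)
from mixentropy.particle_entropy import (InsufficientNeighboursError,
                                         neighbourhood_states)
from mixentropy.particle_sim import box_for_density

LN2 = np.log(2.0)


class TestMaxMixing:
    def test_binary_equimolar(self):
        assert max_mixing_entropy([0.5, 0.5]) == pytest.approx(LN2)

    def test_pure(self):
        assert max_mixing_entropy([1.0]) == 0.0

    def test_four_components(self):
        assert max_mixing_entropy([0.25] * 4) == pytest.approx(np.log(4))

    def test_rejects_bad_simplex(self):
        with pytest.raises(ValueError):
            max_mixing_entropy([0.7, 0.7])


class TestBinnedShannon:
    def test_demixed_halves_pure_regions(self):
        snap = generate_demixed(2000, box_for_density(2000), seed=1)
        assert binned_shannon_entropy(snap, 2).value < 0.05

    def test_uniform_random_near_ln2(self):
        snap = generate_mixed(10000, box_for_density(10000), seed=2)
        assert binned_shannon_entropy(snap, 4).value == pytest.approx(LN2, abs=0.02)

    def test_oversubdivision_warns_not_errors(self):
        snap = generate_mixed(100, box_for_density(100), seed=3)
        est = binned_shannon_entropy(snap, 20)
        assert est.warnings and est.undersampled


class TestHalfSpaceRule:
    def test_ordering_and_exclusion(self):
        # i at origin; (0.5,0.5) is nearer than (0,1); (0,-1) is below
        snap = ParticleSnapshot([[0, 0], [0, 1], [0.5, 0.5], [0, -1]],
                                list("XABA"), (10.0, 10.0), periodic=False)
        idx, dist = half_space_neighbours(snap, 0)
        assert idx.tolist() == [2, 1]
        assert dist == pytest.approx([np.sqrt(0.5), 1.0])

    def test_tie_break_asymmetry_on_boundary(self):
        # same y: only the particle at dx > 0 sees the other
        snap = ParticleSnapshot([[1, 2], [3, 2]], list("AB"), (10.0, 10.0),
                                periodic=False)
        assert half_space_neighbours(snap, 0)[0].tolist() == [1]
        assert half_space_neighbours(snap, 1)[0].tolist() == []

    def test_minimum_image_across_boundary(self):
        snap = ParticleSnapshot([[0, 9.8], [0, 0.1]], list("AB"),
                                (10.0, 10.0), periodic=True)
        idx, dist = half_space_neighbours(snap, 0)
        assert idx.tolist() == [1]
        assert dist[0] == pytest.approx(0.3)


class TestNeighbourhoodStates:
    def test_cutoff_ordered_types(self):
        snap = ParticleSnapshot([[0, 0], [0, 1], [0.5, 0.5], [0, -1]],
                                list("XABA"), (10.0, 10.0), periodic=False)
        assert nb_state_cutoff(snap, 0, 2) == ("B", "A")
        with pytest.raises(InsufficientNeighboursError):
            nb_state_cutoff(snap, 0, 3)

    def test_cutoff_pure_system(self):
        snap = generate_mixed(100, box_for_density(100), composition=1.0, seed=1)
        assert nb_state_cutoff(snap, 0, 3) == ("A", "A", "A")

    def test_shell_order_within_shell_ignored(self):
        # two neighbours at distinct distances: (B nearer, A farther) pools
        # to the same single-shell state as (A nearer, B farther)
        s1 = ParticleSnapshot([[5, 5], [5, 5.9], [5, 6.2]], list("ABA"),
                              (10.0, 10.0), periodic=False)
        s2 = ParticleSnapshot([[5, 5], [5, 5.9], [5, 6.2]], list("AAB"),
                              (10.0, 10.0), periodic=False)
        assert nb_state_shell(s1, 0, (2,)) == nb_state_shell(s2, 0, (2,))
        assert nb_state_shell(s1, 0, (2,)) == ((1, 1),)  # {A:1, B:1}

    def test_shell_two_shells(self):
        pos = [[5, 5], [5, 5.5], [5.2, 5.5], [5, 6.2], [4.8, 6.4]]
        snap = ParticleSnapshot(pos, list("BAABA"), (10.0, 10.0), periodic=False)
        state = nb_state_shell(snap, 0, (2, 2))
        assert state == ((2, 0), (1, 1))  # ({A:2}, {A:1,B:1})

    def test_weight_single_neighbour_top_bin(self):
        snap = ParticleSnapshot([[5, 5], [5, 5.8]], list("BA"), (10.0, 10.0),
                                periodic=False)
        assert nb_state_weight(snap, 0, lam=1.0, n_bins=8) == (7,)

    def test_weight_hand_value(self):
        """A at r=lambda, B at 2*lambda: f(A) = e^-1/(e^-1+e^-2) = 0.7311,
        landing in bin 5 of 8."""
        snap = ParticleSnapshot([[5, 5], [5, 6], [5, 7]], list("BAB"),
                                (20.0, 20.0), periodic=False)
        assert nb_state_weight(snap, 0, lam=1.0, n_bins=8) == (5,)
        f = np.exp(-1) / (np.exp(-1) + np.exp(-2))
        assert int(f * 8) == 5

    def test_weight_equal_distances_middle_bin(self):
        snap = ParticleSnapshot([[5, 5], [4.3, 5.7], [5.7, 5.7]], list("BAB"),
                                (20.0, 20.0), periodic=False)
        assert nb_state_weight(snap, 0, lam=0.5, n_bins=8) == (4,)

    def test_bulk_path_matches_per_particle(self):
        snap = generate_mixed(300, box_for_density(300), seed=4)
        for spec in (NeighbourhoodSpec("cutoff", k=4),
                     NeighbourhoodSpec("shell", shell_sizes=(3, 4)),
                     NeighbourhoodSpec("weight", n_bins=8)):
            sigma, states, skipped = neighbourhood_states(snap, spec)
            assert skipped == 0
            for i in range(snap.n):
                if spec.variant == "cutoff":
                    ref = nb_state_cutoff(snap, i, spec.k)
                elif spec.variant == "shell":
                    ref = nb_state_shell(snap, i, spec.shell_sizes)
                else:
                    ref = nb_state_weight(snap, i, spec.resolve_lambda(snap),
                                          spec.n_bins)
                assert states[i] == ref


class TestConditionalEntropy:
    def test_demixed_near_zero(self):
        snap = generate_demixed(4096, box_for_density(4096), seed=5)
        est = conditional_entropy_particles(snap, NeighbourhoodSpec("cutoff", k=6))
        assert est.value < 0.05

    def test_mixed_near_ln2(self):
        snap = generate_mixed(4096, box_for_density(4096), seed=6)
        for spec in (NeighbourhoodSpec("cutoff", k=6),
                     NeighbourhoodSpec("weight", n_bins=8)):
            est = conditional_entropy_particles(snap, spec)
            assert est.value == pytest.approx(LN2, abs=0.03)

    def test_bounded_by_composition_entropy(self):
        snap = generate_mixed(2000, box_for_density(2000), composition=0.3, seed=7)
        cond = conditional_entropy_particles(snap, NeighbourhoodSpec("cutoff", k=6))
        assert cond.value <= composition_entropy(snap).value + 1e-12

    def test_translation_and_label_permutation_invariance(self):
        snap = generate_demixed(500, box_for_density(500), seed=8)
        spec = NeighbourhoodSpec("cutoff", k=4)
        base = conditional_entropy_particles(snap, spec).value
        shifted = snap.translated([3.7, -1.2])
        assert conditional_entropy_particles(shifted, spec).value == \
            pytest.approx(base, abs=1e-12)
        swapped = ParticleSnapshot(snap.positions,
                                   np.where(snap.labels == "A", "B", "A"),
                                   snap.box, snap.periodic)
        assert conditional_entropy_particles(swapped, spec).value == \
            pytest.approx(base, abs=1e-12)

    def test_all_skipped_raises(self):
        snap = ParticleSnapshot([[0, 0], [0, 1]], list("AB"), (10.0, 10.0),
                                periodic=False)
        with pytest.raises(ValueError):
            # particle 1 has no upper neighbour, particle 0 has only one
            conditional_entropy_particles(snap, NeighbourhoodSpec("cutoff", k=2))


class TestTimeSeries:
    def test_constant_trajectory_constant_series(self):
        snap = generate_mixed(500, box_for_density(500), seed=9)
        traj = Trajectory([ParticleSnapshot(snap.positions, snap.labels,
                                            snap.box, True, float(t))
                           for t in range(4)])
        ser = entropy_time_series(traj, NeighbourhoodSpec("cutoff", k=4))
        assert len(ser) == 4
        assert np.ptp(ser.values) == 0.0

    def test_window_pooling_stationary(self):
        rng = np.random.default_rng(10)
        box = box_for_density(1000)
        snaps = [generate_mixed(1000, box, seed=int(rng.integers(2**31)))
                 for _ in range(6)]
        traj = Trajectory([ParticleSnapshot(s.positions, s.labels, s.box,
                                            True, float(t))
                           for t, s in enumerate(snaps)])
        spec = NeighbourhoodSpec("cutoff", k=4)
        w1 = entropy_time_series(traj, spec, window=1)
        w3 = entropy_time_series(traj, spec, window=3)
        assert abs(w1.values.mean() - w3.values.mean()) < 0.03

    def test_window_validation(self):
        snap = generate_mixed(100, box_for_density(100), seed=11)
        traj = Trajectory([snap])
        with pytest.raises(ValueError):
            entropy_time_series(traj, NeighbourhoodSpec("cutoff", k=4), window=2)
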