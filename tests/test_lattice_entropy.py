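"""Lattice entropy estimators: frozen examples, limits and invariances."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mixentropy import (LatticeEnsemble, LatticeNeighbourhood,
                        bethe_entropy_1d, cluster_entropies,
                        conditional_entropy_chain, conditional_entropy_lattice,
                        kikuchi_entropy, mean_field_entropy)
from mixentropy.lattice_entropy import half_plane_offsets

LN2 = np.log(2.0)


def ens_of(frames, alphabet=(-1, 1)):
    return LatticeEnsemble(frames=np.asarray(frames), alphabet=alphabet)


def all_up(n_frames=3, L=6):
    return ens_of(np.ones((n_frames, L, L), dtype=np.int8))


class TestOffsets:
    def test_r1_is_half_the_four_neighbourhood(self):
        assert set(half_plane_offsets(1)) == {(1, 0), (0, 1)}

    def test_rsqrt2_adds_upper_diagonals(self):
        assert set(half_plane_offsets(np.sqrt(2))) == {(1, 0), (0, 1), (1, 1), (-1, 1)}

    def test_offsets_exclude_origin_and_lower_half(self):
        for r in (1, np.sqrt(2), 2, 2.5):
            offs = half_plane_offsets(r)
            assert (0, 0) not in offs
            for dx, dy in offs:
                assert dy > 0 or (dy == 0 and dx > 0)
                assert dx * dx + dy * dy <= r * r + 1e-6

    def test_nesting(self):
        assert set(half_plane_offsets(1)) <= set(half_plane_offsets(np.sqrt(2)))


class TestMeanField:
    def test_single_state(self):
        assert mean_field_entropy(all_up()).value == 0.0

    def test_balanced(self):
        f = np.array([np.ones((4, 4)), -np.ones((4, 4))], dtype=np.int8)
        assert mean_field_entropy(ens_of(f)).value == pytest.approx(LN2, abs=1e-12)

    def test_quarter_three_quarter(self):
        f = np.ones((1, 4, 4), dtype=np.int8)
        f[0, 0] = -1  # 4 of 16 sites down
        expected = -(0.25 * np.log(0.25) + 0.75 * np.log(0.75))
        assert mean_field_entropy(ens_of(f)).value == pytest.approx(expected, abs=1e-12)
        assert mean_field_entropy(ens_of(f)).value == pytest.approx(0.5623, abs=5e-5)


class TestClusterEntropies:
    def test_all_up_zero(self):
        assert cluster_entropies(all_up()) == (0.0, 0.0, 0.0, 0.0)

    def test_iid_independence_limit(self, iid_ensemble):
        s1, s2h, s2v, s_sq = cluster_entropies(iid_ensemble)
        assert s1 == pytest.approx(LN2, abs=0.02)
        assert s2h == pytest.approx(2 * LN2, abs=0.02)
        assert s2v == pytest.approx(2 * LN2, abs=0.02)
        assert s_sq == pytest.approx(4 * LN2, abs=0.02)

    def test_checkerboard_all_ln2(self, checkerboard_frame):
        """Two site states, two pair states and two block states, each
        equiprobable over positions."""
        s1, s2h, s2v, s_sq = cluster_entropies(ens_of(checkerboard_frame[None]))
        for s in (s1, s2h, s2v, s_sq):
            assert s == pytest.approx(LN2, abs=1e-12)


class TestBethe1D:
    def test_constant_chains(self):
        assert bethe_entropy_1d(ens_of(np.ones((5, 32), np.int8))).value == 0.0

    def test_iid_limit(self):
        r = np.random.default_rng(2)
        ens = ens_of(r.choice([-1, 1], size=(50, 512)).astype(np.int8))
        assert bethe_entropy_1d(ens).value == pytest.approx(LN2, abs=0.02)
        assert conditional_entropy_chain(ens, 1).value == pytest.approx(LN2, abs=0.02)

    def test_bethe_equals_order_one_conditional(self):
        r = np.random.default_rng(3)
        ens = ens_of(r.choice([-1, 1], size=(10, 64)).astype(np.int8))
        assert bethe_entropy_1d(ens).value == pytest.approx(
            conditional_entropy_chain(ens, 1).value, abs=1e-12)

    def test_conditional_chain_monotone_in_order(self):
        r = np.random.default_rng(4)
        # correlated chains: smoothed random walk signs
        raw = np.cumsum(r.normal(size=(20, 256)), axis=1)
        ens = ens_of(np.where(np.sign(raw) >= 0, 1, -1).astype(np.int8))
        values = [conditional_entropy_chain(ens, m).value for m in (1, 2, 3)]
        assert values[0] + 1e-12 >= values[1] >= values[2] - 1e-12

    def test_requires_chain(self):
        with pytest.raises(ValueError):
            bethe_entropy_1d(all_up())


class TestKikuchi:
    def test_all_up(self):
        assert kikuchi_entropy(all_up()).value == 0.0

    def test_iid_limit(self, iid_ensemble):
        assert kikuchi_entropy(iid_ensemble).value == pytest.approx(LN2, abs=0.02)


class TestConditionalLattice:
    def test_all_up(self):
        assert conditional_entropy_lattice(all_up(), 1.0).value == 0.0

    def test_checkerboard_fully_determined(self, checkerboard_frame):
        """The neighbourhood state determines the site state exactly."""
        est = conditional_entropy_lattice(ens_of(checkerboard_frame[None]), 1.0)
        assert est.value == 0.0

    def test_iid_limit(self, iid_ensemble):
        est = conditional_entropy_lattice(iid_ensemble, np.sqrt(2))
        assert est.value == pytest.approx(LN2, abs=0.02)

    def test_cutoff_wrap_guard(self):
        with pytest.raises(ValueError):
            conditional_entropy_lattice(ens_of(np.ones((1, 4, 4), np.int8)), 2.5)

    def test_undersampling_flag(self):
        r = np.random.default_rng(5)
        small = ens_of(r.choice([-1, 1], size=(1, 6, 6)).astype(np.int8))
        est = conditional_entropy_lattice(small, np.sqrt(2))
        assert est.undersampled


# ---------------------------------------------------------------------------
# properties on random ensembles

random_ensembles = hnp.arrays(
    dtype=np.int8,
    shape=st.tuples(st.integers(1, 4), st.just(6), st.just(6)),
    elements=st.sampled_from([-1, 1]),
)


@settings(max_examples=40, deadline=None)
@given(random_ensembles)
def test_conditioning_inequalities(frames):
    """Nested neighbourhoods: H(s|b_big) <= H(s|b_small) <= H(s); the
    monotone limit of the entropy per symbol of an information source."""
    ens = ens_of(frames)
    mf = mean_field_entropy(ens).value
    c1 = conditional_entropy_lattice(ens, 1.0).value
    c2 = conditional_entropy_lattice(ens, np.sqrt(2)).value
    assert c2 <= c1 + 1e-12
    assert c1 <= mf + 1e-12


@settings(max_examples=25, deadline=None)
@given(random_ensembles, st.integers(0, 5), st.integers(0, 5))
def test_translation_invariance(frames, dx, dy):
    ens = ens_of(frames)
    rolled = ens_of(np.roll(frames, (dx, dy), axis=(1, 2)))
    for est in (mean_field_entropy, kikuchi_entropy,
                lambda e: conditional_entropy_lattice(e, np.sqrt(2))):
        assert est(ens).value == pytest.approx(est(rolled).value, abs=1e-12)


@settings(max_examples=25, deadline=None)
@given(random_ensembles)
def test_spin_flip_invariance(frames):
    ens = ens_of(frames)
    flipped = ens_of(-frames)
    for est in (mean_field_entropy, kikuchi_entropy,
                lambda e: conditional_entropy_lattice(e, 1.0)):
        assert est(ens).value == pytest.approx(est(flipped).value, abs=1e-12)


def test_conditional_matches_pairwise_route(rng):
    """Cross-route check: the radix-encoded estimator equals the generic
    pair-based conditional entropy on the same observations."""
    from mixentropy.estimate import conditional_entropy_from_pairs
    frames = rng.choice([-1, 1], size=(3, 6, 6)).astype(np.int8)
    ens = ens_of(frames)
    nb = LatticeNeighbourhood(np.sqrt(2))
    sigma, neigh = [], []
    for f in frames:
        for x in range(6):
            for y in range(6):
                sigma.append(f[x, y])
                neigh.append(tuple(f[(x + dx) % 6, (y + dy) % 6]
                                   for dx, dy in nb.offsets))
    direct = conditional_entropy_from_pairs(sigma, neigh)
    fast = conditional_entropy_lattice(ens, nb)
    assert fast.value == pytest.approx(direct.value, abs=1e-12)
    assert fast.n_states_observed == direct.n_states_observed
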