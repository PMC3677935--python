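"""Exact reference entropies for validating the estimators.

* Onsager's closed-form solution of the 2D square-lattice Ising model
  (free energy by quadrature of the single-integral representation,
  internal energy via the complete elliptic integral), giving
  S(T) = (u - f)/T per site in nats.
* The 1D nearest-neighbour chain via the 2x2 transfer matrix.
* Exhaustive enumeration of small periodic lattices (L <= 4), including the
  exact conditional entropy for a given neighbourhood cut-off, which no
  closed form provides.

Units: J = k_B = 1 throughout; entropies per site in nats.
"""
from __future__ import annotations

import numpy as np
from scipy import integrate, special

__all__ = [
    "onsager_free_energy",
    "onsager_internal_energy",
    "onsager_entropy",
    "onsager_curve",
    "transfer_matrix_entropy_1d",
    "enumeration_entropy",
    "enumeration_conditional_entropy",
]

_QUAD_KW = dict(epsabs=1e-10, epsrel=1e-10, limit=200)


def _check_T(T: float) -> float:
    T = float(T)
    if T <= 0:
        raise ValueError("temperature must be positive")
    return T


def onsager_free_energy(T: float) -> float:
    """Free energy per site f(T) of the 2D Ising model (J=1, h=0).

    Uses the reduction of Onsager's double integral to a single integral:
    the inner angular integral of ln(a - b cos t) has the closed form
    2*pi*ln((a + sqrt(a^2 - b^2))/2), leaving one quadrature with an
    integrable logarithmic singularity at the origin exactly at T_c.
    """
    T = _check_T(T)
    K = 1.0 / T
    c2 = np.cosh(2 * K)
    s2 = np.sinh(2 * K)

    def integrand(theta):
        a = c2 * c2 - s2 * np.cos(theta)
        inner = a * a - s2 * s2
        inner = max(inner, 0.0)
        return np.log(0.5 * (a + np.sqrt(inner)))

    val, _ = integrate.quad(integrand, 0.0, np.pi, points=[0.0], **_QUAD_KW)
    minus_beta_f = np.log(2.0) + val / (2.0 * np.pi)
    return float(-T * minus_beta_f)


def onsager_internal_energy(T: float) -> float:
    """Internal energy per site u(T), elliptic-integral form."""
    T = _check_T(T)
    K = 1.0 / T
    c2 = np.cosh(2 * K)
    s2 = np.sinh(2 * K)
    k = 2.0 * s2 / (c2 * c2)          # modulus, k <= 1, = 1 at T_c
    m = min(k * k, 1.0 - 1e-16)       # scipy.ellipk takes m = k^2
    factor = 2.0 * np.tanh(2 * K) ** 2 - 1.0
    # the factor vanishes exactly at T_c, suppressing the log divergence of K(m)
    return float(-1.0 / np.tanh(2 * K) * (1.0 + (2.0 / np.pi) * factor * special.ellipk(m)))


def onsager_entropy(T: float) -> float:
    """Exact entropy per site S(T) = (u(T) - f(T))/T, in nats."""
    T = _check_T(T)
    return (onsager_internal_energy(T) - onsager_free_energy(T)) / T


def onsager_curve(temperatures) -> np.ndarray:
    """Vectorised S(T) over a temperature grid (returns an array of nats)."""
    return np.array([onsager_entropy(t) for t in np.asarray(temperatures, float)])


def transfer_matrix_entropy_1d(T: float, J: float = 1.0) -> float:
    """Exact entropy per site of the 1D nearest-neighbour Ising chain.

    From the largest transfer-matrix eigenvalue lambda = 2 cosh(J/T):
    f = -T ln lambda, u = -J tanh(J/T), S = (u - f)/T.
    """
    T = _check_T(T)
    beta_j = J / T
    return float(np.log(2.0 * np.cosh(beta_j)) - beta_j * np.tanh(beta_j))


# ---------------------------------------------------------------------------
# exhaustive enumeration of small periodic lattices


def _enumerate_states(L: int) -> tuple[np.ndarray, np.ndarray]:
    """All 2^(L*L) spin configurations and their total energies.

    Returns (spins, energies) with spins of shape (2^n, L, L) in {-1, +1}.
    Guarded at L <= 4 (65536 states) against combinatorial blow-up.
    """
    if not 2 <= L <= 4:
        raise ValueError("exhaustive enumeration supports 2 <= L <= 4 only")
    n = L * L
    codes = np.arange(2 ** n, dtype=np.uint32)
    bits = ((codes[:, None] >> np.arange(n)) & 1).astype(np.int8)
    spins = (2 * bits - 1).reshape(-1, L, L)
    e = -(spins * np.roll(spins, -1, axis=1)).sum(axis=(1, 2)) \
        - (spins * np.roll(spins, -1, axis=2)).sum(axis=(1, 2))
    return spins, e.astype(float)


def _boltzmann_weights(energies: np.ndarray, T: float) -> np.ndarray:
    x = -(energies - energies.min()) / T
    w = np.exp(x)
    return w / w.sum()


def enumeration_entropy(L: int, T: float) -> float:
    """Exact entropy per site of the periodic L x L Ising model, L <= 4.

    Computed from the full partition function: S = (U - F)/(T N).
    """
    T = _check_T(T)
    _, e = _enumerate_states(L)
    shift = e.min()
    log_z = special.logsumexp(-(e - shift) / T)
    w = _boltzmann_weights(e, T)
    U = float((w * e).sum())
    F = float(shift - T * log_z)
    return (U - F) / (T * L * L)


def enumeration_conditional_entropy(L: int, T: float, cutoff_r: float = np.sqrt(2)) -> float:
    """Exact conditional entropy H(s | half-plane neighbourhood) on L x L.

    The exact analogue of the plug-in conditional-entropy estimator: the
    joint distribution of a site's state and the states at the half-plane
    offsets is accumulated over all configurations with their Boltzmann
    weights (and over all sites, by translation invariance).
    """
    from .lattice_entropy import LatticeNeighbourhood
    from .estimate import conditional_entropy_from_pairs

    T = _check_T(T)
    spins, e = _enumerate_states(L)
    w = _boltzmann_weights(e, T)
    nb = LatticeNeighbourhood(cutoff_r)
    sigma, neigh, weights = [], [], []
    for dx, dy in nb.offsets:
        if abs(dx) > L // 2 or abs(dy) > L // 2:
            raise ValueError("cutoff too large for this lattice")
    for i in range(L):
        for j in range(L):
            sigma.append(spins[:, i, j])
            neigh.append(np.stack([spins[:, (i + dx) % L, (j + dy) % L]
                                   for dx, dy in nb.offsets], axis=1))
            weights.append(w)
    est = conditional_entropy_from_pairs(
        np.concatenate(sigma), np.concatenate(neigh, axis=0),
        weights=np.concatenate(weights))
    return est.value
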