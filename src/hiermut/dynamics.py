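"""Deterministic dynamics of expected one-hit mutant numbers.

The expected change in the mutant count of each compartment over one update
(removal of ``2^n`` mature cells plus the full replacement cascade) is a
tree-probability-weighted sum of per-tree contributions.  With ``mu_k =
m_k / N_k`` the mutant fraction, a tree ``a`` with self-renewal counts
``s_k = a_k - 2 a_{k-1}`` contributes (sampling with replacement):

* ``C_0`` gains ``2 u a_0 (1 - mu_0)`` (net of the ``a_0 mu_0`` mutants that
  differentiate out and return via its own backfilling self-renewals);
* ``C_k`` (interior) gains ``2 a_{k-1} (mu_{k-1} + u (1 - mu_{k-1}))`` from
  arriving differentiated daughters, ``s_k (mu_k + 2 u (1 - mu_k))`` from
  self-renewals, and loses ``a_k mu_k`` mutants that differentiate out;
* ``C_n`` gains ``2 a_{n-1} (mu_{n-1} + u (1 - mu_{n-1}))`` and loses the
  ``2^n mu_n`` expected mutants among the removed cells.

Because every term is linear in ``m``, the weighted sum collapses onto the
expected differentiation counts ``E[a_k]``; the ``u = 0`` system is the
lower-triangular "clonal" system ``m'_k = K_k (mu_{k-1} - mu_k)`` with
flush-out rates ``K_k = 2 E[a_{k-1}]``.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy.integrate import solve_ivp

from .architecture import TissueArchitecture
from .trees import DivisionTree, enumerate_trees, expected_differentiations, tree_distribution

__all__ = [
    "per_tree_delta",
    "rhs",
    "printed_rhs",
    "integrate",
    "generation_probabilities",
    "flush_out_rates",
    "clonal_matrix",
    "clonal_integrate",
    "clonal_steady_state",
    "flush_out_exponent",
]


def _mu(m, N):
    m = np.asarray(m, dtype=float)
    N = np.asarray(N, dtype=float)
    if m.shape != N.shape:
        raise ValueError(f"state has shape {m.shape}, sizes have shape {N.shape}")
    return m / N


def _binom_pmf(k, n, p):
    return comb(n, k) * p**k * (1.0 - p) ** (n - k)


def _brute_gain_diff(a_k, mu_parent, u):
    """E[2 i + l] over i mutant dividers and l de-novo daughters.

    ``i ~ Binomial(a_k, mu_parent)`` mutant cells differentiate (two mutant
    daughters each); the ``2 (a_k - i)`` wild-type daughters each mutate with
    probability ``u``.
    """
    total = 0.0
    for i in range(a_k + 1):
        pi = _binom_pmf(i, a_k, mu_parent)
        for l in range(2 * (a_k - i) + 1):
            pl = _binom_pmf(l, 2 * (a_k - i), u)
            total += (2 * i + l) * pi * pl
    return total


def _brute_gain_pro(s_k, mu_k, u):
    """E[i + l] for ``s_k`` self-renewal divisions in a compartment."""
    total = 0.0
    for i in range(s_k + 1):
        pi = _binom_pmf(i, s_k, mu_k)
        for l in range(2 * (s_k - i) + 1):
            pl = _binom_pmf(l, 2 * (s_k - i), u)
            total += (i + l) * pi * pl
    return total


def _brute_loss_removed(count, mu):
    """Expected mutants among ``count`` removed cells (binomial mean)."""
    return sum(i * _binom_pmf(i, count, mu) for i in range(count + 1))


def per_tree_delta(tree: DivisionTree, m, u, arch: TissueArchitecture,
                   method: str = "closed") -> np.ndarray:
    """Expected per-update mutant change in each compartment for one tree.

    ``method="brute"`` evaluates the full double binomial sums;
    ``method="closed"`` uses the collapsed linear form (they agree to 1e-12).
    ``method="printed_beta"`` instead charges the differentiating compartment
    the full ``2 i + l`` gain of its downstream neighbor — kept only for
    comparison with the displayed loss term; it does not reproduce the
    printed low-``n`` systems.
    """
    n = arch.n
    if tree.n != n:
        raise ValueError(f"tree n={tree.n} does not match architecture n={n}")
    mu = _mu(m, arch.N)
    a = tree.a
    s = tree.self_renewals
    dm = np.zeros(n + 1)

    if method == "closed":
        dm[0] = 2.0 * u * a[0] * (1.0 - mu[0])
        for k in range(1, n):
            dm[k] = (2.0 * a[k - 1] * (mu[k - 1] + u * (1.0 - mu[k - 1]))
                     + s[k] * (mu[k] + 2.0 * u * (1.0 - mu[k]))
                     - a[k] * mu[k])
        dm[n] = 2.0 * a[n - 1] * (mu[n - 1] + u * (1.0 - mu[n - 1])) - 2**n * mu[n]
        return dm

    if method not in ("brute", "printed_beta"):
        raise ValueError(f"unknown method {method!r}")

    # gains: differentiated daughters arriving in C_{k+1}, self-renewals in C_k
    for k in range(n):
        dm[k + 1] += _brute_gain_diff(a[k], mu[k], u)
    for k in range(n + 1):
        if s[k] > 0:
            dm[k] += _brute_gain_pro(s[k], mu[k], u)
    # losses
    if method == "brute":
        # expected number of mutant cells differentiating out of C_k
        for k in range(n):
            dm[k] -= _brute_loss_removed(a[k], mu[k])
    else:  # printed_beta: charge the upstream compartment the downstream gain
        for k in range(n):
            dm[k] -= _brute_gain_diff(a[k], mu[k], u)
    dm[n] -= _brute_loss_removed(2**n, mu[n])
    return dm


def rhs(m, arch: TissueArchitecture, u, method: str = "closed") -> np.ndarray:
    """Per-update derivative of expected mutant counts (tree-weighted sum)."""
    dm = np.zeros(arch.n + 1)
    for tree, p in tree_distribution(arch):
        dm += p * per_tree_delta(tree, m, u, arch, method=method)
    return dm


def _rhs_fast(m, Ea, N, u, n):
    """Closed-form derivative using precomputed ``E[a_k]`` (linear in m)."""
    mu = np.asarray(m, dtype=float) / N
    dm = np.empty(n + 1)
    dm[0] = 2.0 * u * Ea[0] * (1.0 - mu[0])
    for k in range(1, n):
        Es = Ea[k] - 2.0 * Ea[k - 1]
        dm[k] = (2.0 * Ea[k - 1] * (mu[k - 1] + u * (1.0 - mu[k - 1]))
                 + Es * (mu[k] + 2.0 * u * (1.0 - mu[k]))
                 - Ea[k] * mu[k])
    dm[n] = 2.0 * Ea[n - 1] * (mu[n - 1] + u * (1.0 - mu[n - 1])) - 2**n * mu[n]
    return dm


def printed_rhs(n: int, m, v: float, u, N=None, corrected: bool = True) -> np.ndarray:
    """Hard-coded transcription of the reference closed-form systems.

    Supports ``n in {1, 2, 3}`` with constant interior self-renewal ``v``.
    The reference ``n = 1`` system lacks the overall factor 2 of the generic
    construction; ``corrected=True`` (default) restores it, ``corrected=False``
    returns the system exactly as displayed.
    """
    if n not in (1, 2, 3):
        raise ValueError(f"printed systems exist for n in {{1, 2, 3}}, got {n}")
    if N is None:
        N = np.ones(n + 1)
    mu = _mu(m, N)
    if n == 1:
        dm1 = u + mu[0] * (1 - u) - mu[1]
        if corrected:
            dm1 *= 2.0
        return np.array([2 * u * (1 - mu[0]), dm1])
    if n == 2:
        return np.array([
            2 * u * (1 - v) ** 2 * (1 - mu[0]),
            2 * (1 - v) ** 2 * (u + mu[0] * (1 - u) - mu[1])
            + 4 * u * (2 - v) * v * (1 - mu[1]),
            4 * (u + mu[1] * (1 - u) - mu[2]),
        ])
    return np.array([
        2 * u * (1 - v) ** 6 * (1 - mu[0]),
        2 * (1 - v) ** 6 * (u + mu[0] * (1 - u) - mu[1])
        + 4 * u * (2 - v) * (1 - v) ** 4 * v * (1 - mu[1])
        + 4 * u * v * (2 - 3 * v + v**3) * (1 - mu[1]),
        4 * (u * (1 - mu[1] + v * (2 - 3 * v + 4 * v**2 - 2 * v**3)
                  * (1 + mu[1] - 2 * mu[2]))
             + (1 - v) ** 2 * (1 + 2 * v**2) * (mu[1] - mu[2])),
        8 * (u + mu[2] * (1 - u) - mu[3]),
    ])


def integrate(arch: TissueArchitecture, u, m_init, t_grid, rtol: float = 1e-8):
    """Integrate the expected-mutant system on a grid of update times.

    Returns an array of shape ``(len(t_grid), n + 1)``.  Time is measured in
    update steps; the derivative is the expected per-update change.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    m_init = np.asarray(m_init, dtype=float)
    N = arch.N.astype(float)
    if np.any(m_init < 0) or np.any(m_init > N):
        raise ValueError("initial mutant counts must lie in [0, N_i]")
    Ea = expected_differentiations(arch)
    n = arch.n

    sol = solve_ivp(
        lambda t, m: _rhs_fast(m, Ea, N, u, n),
        (t_grid[0], t_grid[-1]), m_init, t_eval=t_grid,
        method="LSODA", rtol=rtol, atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y.T


def generation_probabilities(arch: TissueArchitecture, u: float = 1e-3) -> np.ndarray:
    """Probability that a de-novo mutant arises in each compartment.

    The right-hand side at the mutant-free state, normalized to sum to 1.
    Independent of ``u`` and of the compartment sizes (every source term is
    proportional to ``u`` and size-free).
    """
    if not (0 < u <= 1):
        raise ValueError(f"u must lie in (0, 1], got {u}")
    src = rhs(np.zeros(arch.n + 1), arch, u)
    return src / src.sum()


def flush_out_rates(arch: TissueArchitecture) -> np.ndarray:
    """Flush-out rates ``K_k = 2 E[a_{k-1}]`` for k = 1..n.

    For constant interior ``v``, ``K_1 = 2 (1 - v)^(2^n - 2)``.
    """
    return 2.0 * expected_differentiations(arch)


def clonal_matrix(arch: TissueArchitecture) -> np.ndarray:
    """Matrix ``A`` of the linear clonal system ``m' = A m`` (u = 0)."""
    n = arch.n
    K = flush_out_rates(arch)
    N = arch.N.astype(float)
    A = np.zeros((n + 1, n + 1))
    for k in range(1, n + 1):
        A[k, k - 1] = K[k - 1] / N[k - 1]
        A[k, k] = -K[k - 1] / N[k]
    return A


def clonal_integrate(arch: TissueArchitecture, m_init, t_grid) -> np.ndarray:
    """Clonal (u = 0) trajectories; ``m_0`` is conserved for all time."""
    t_grid = np.asarray(t_grid, dtype=float)
    m_init = np.asarray(m_init, dtype=float)
    A = clonal_matrix(arch)
    sol = solve_ivp(
        lambda t, m: A @ m, (t_grid[0], t_grid[-1]), m_init,
        t_eval=t_grid, method="LSODA", rtol=1e-10, atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"clonal integration failed: {sol.message}")
    return sol.y.T


def clonal_steady_state(arch: TissueArchitecture, m0: float) -> np.ndarray:
    """Steady state ``m_k = m_0 N_k / N_0`` of the clonal system."""
    N = arch.N.astype(float)
    return m0 * N / N[0]


def flush_out_exponent(n: int, i: int, v_grid=(0.99, 0.999)) -> float:
    """Leading exponent of ``K_i`` in ``1 - v`` near ``v = 1``.

    Estimated as the log-log slope of ``K_i(v)`` against ``1 - v`` on
    ``v_grid``; the exact value is ``gamma_i = 2^(n - i + 1) - 2`` (so the
    top rate ``K_n`` stays bounded away from zero).
    """
    if not (1 <= i <= n):
        raise ValueError(f"compartment index i must lie in 1..{n}, got {i}")
    sizes = (10,) * (n + 1)  # K does not depend on sizes
    logs = []
    for v in v_grid:
        from .architecture import make_architecture

        K = flush_out_rates(make_architecture(n, sizes, v))
        logs.append(np.log(K[i - 1]))
    x = np.log1p([-v for v in v_grid])
    return float(np.polyfit(x, logs, 1)[0])
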