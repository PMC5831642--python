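"""Discrete-update stochastic simulation of the renewal process.

Each update removes ``2^n`` cells from the terminal compartment and resolves
the replacement cascade downstream-to-upstream: openings in ``C_k`` are
filled by self-renewal with probability ``v_k`` (an odd differentiation
leftover gets one extra self-renewal) and the rest by differentiation
divisions from ``C_{k-1}``.  Dividing-cell identities are drawn without
replacement (default) from the compartment composition at the start of that
compartment's replacement phase; newly created cells never divide within the
same update.  Wild-type divisions mutate each daughter independently with
probability ``u`` (``per_daughter`` default) or once per division
(``per_division``).  In two-hit mode divisions of one-hit parents trigger
the second hit with probability ``u`` once per division (default) or per
daughter, and the run stops at the first such event.

The inner loop is compiled with numba when available; the same code runs in
pure Python otherwise.  Replicate ``r`` of an ensemble uses seed
``seed + r``, making runs bit-reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .architecture import TissueArchitecture

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "SimConfig",
    "SimState",
    "TwoHitResult",
    "initial_state",
    "update_step",
    "run_trajectory",
    "run_two_hit",
    "run_ensemble",
    "run_two_hit_ensemble",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a stochastic run."""

    arch: TissueArchitecture
    u: float
    sampling: str = "without_replacement"
    mutation_model: str = "per_daughter"
    second_hit_model: str = "per_division"
    two_hit: bool = False
    max_updates: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.u <= 1.0):
            raise ValueError(f"u must lie in [0, 1], got {self.u}")
        if self.sampling not in ("without_replacement", "with_replacement"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")
        for model in (self.mutation_model, self.second_hit_model):
            if model not in ("per_daughter", "per_division"):
                raise ValueError(f"unknown mutation model {model!r}")
        if self.max_updates < 1:
            raise ValueError("max_updates must be >= 1")

    @property
    def _with_replacement(self) -> bool:
        return self.sampling == "with_replacement"

    @property
    def _per_division(self) -> bool:
        return self.mutation_model == "per_division"

    @property
    def _per_division_second(self) -> bool:
        return self.second_hit_model == "per_division"


@dataclass
class SimState:
    """Per-compartment wild-type and one-hit mutant counts plus update counter."""

    wild: np.ndarray
    mutant: np.ndarray
    t: int = 0

    def copy(self) -> "SimState":
        return SimState(self.wild.copy(), self.mutant.copy(), self.t)


@dataclass(frozen=True)
class TwoHitResult:
    """First-passage record of a two-hit simulation."""

    t2: int  # update index of the first two-hit creation (valid when not censored)
    origin: int  # compartment where the two-hit daughter appeared
    censored: bool


def initial_state(arch: TissueArchitecture, mutants=None) -> SimState:
    """All-wild-type state, optionally seeding one-hit mutant counts."""
    wild = arch.N.copy()
    mut = np.zeros(arch.n + 1, dtype=np.int64)
    if mutants is not None:
        mut = np.asarray(mutants, dtype=np.int64).copy()
        if np.any(mut < 0) or np.any(mut > wild):
            raise ValueError("mutant counts must lie in [0, N_i]")
        wild = wild - mut
    return SimState(wild=wild, mutant=mut, t=0)


# ---------------------------------------------------------------------------
# compiled kernels


@njit(cache=False)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=False)
def _draw_good(ngood, nbad, nsample, with_replacement):
    """Number of 'good' cells among ``nsample`` dividers drawn from a pool."""
    if nsample <= 0 or ngood <= 0:
        return 0
    if nbad <= 0:
        return nsample
    if with_replacement:
        x = np.random.binomial(nsample, ngood / (ngood + nbad))
        if x > ngood:
            x = ngood
        if nsample - x > nbad:
            x = nsample - nbad
        return x
    return np.random.hypergeometric(ngood, nbad, nsample)


@njit(cache=False)
def _n_new_mutant_daughters(wild_divs, u, per_division):
    if wild_divs <= 0 or u <= 0.0:
        return 0
    if per_division:
        return np.random.binomial(wild_divs, u)
    return np.random.binomial(2 * wild_divs, u)


@njit(cache=False)
def _n_second_hits(mut_divs, u, per_division):
    if mut_divs <= 0 or u <= 0.0:
        return 0
    if per_division:
        return np.random.binomial(mut_divs, u)
    return np.random.binomial(2 * mut_divs, u)


@njit(cache=False)
def _one_update(wild, mut, v, u, two_hit, with_repl, per_division, per_div2):
    """Advance one update in place.

    Returns the compartment where the first two-hit daughter appeared, or -1
    if none was created (always -1 when ``two_hit`` is False).
    """
    n = len(wild) - 1
    top = 2**n
    # removal from C_n (without/with replacement per mode)
    rm = _draw_good(mut[n], wild[n], top, with_repl)
    mut[n] -= rm
    wild[n] -= top - rm

    openings = top
    for k in range(n, 0, -1):
        # split the openings in C_k into self-renewals and differentiations
        if v[k] >= 1.0:
            nself = openings
        elif v[k] <= 0.0:
            nself = 0
        else:
            nself = np.random.binomial(openings, v[k])
        ndiff = openings - nself
        if ndiff % 2 == 1:
            nself += 1
            ndiff -= 1
        ndiv = ndiff // 2

        # self-renewal divisions in C_k, dividers from the current survivors
        ms = _draw_good(mut[k], wild[k], nself, with_repl)
        ws = nself - ms
        if two_hit:
            if _n_second_hits(ms, u, per_div2) > 0:
                return k
        new1 = _n_new_mutant_daughters(ws, u, per_division)
        mut[k] += ms + new1
        wild[k] += ws - new1

        # differentiation divisions performed by C_{k-1}
        md = _draw_good(mut[k - 1], wild[k - 1], ndiv, with_repl)
        wd = ndiv - md
        mut[k - 1] -= md
        wild[k - 1] -= wd
        if two_hit:
            if _n_second_hits(md, u, per_div2) > 0:
                return k
        new1 = _n_new_mutant_daughters(wd, u, per_division)
        mut[k] += 2 * md + new1
        wild[k] += 2 * wd - new1

        openings = ndiv

    # stem compartment: openings filled purely by self-renewal (v_0 = 1)
    ms = _draw_good(mut[0], wild[0], openings, with_repl)
    ws = openings - ms
    if two_hit:
        if _n_second_hits(ms, u, per_div2) > 0:
            return 0
    new1 = _n_new_mutant_daughters(ws, u, per_division)
    mut[0] += ms + new1
    wild[0] += ws - new1
    return -1


@njit(cache=False)
def _run_trajectory(seed, N, v, u, wild0, mut0, n_updates, record_every,
                    with_repl, per_division):
    np.random.seed(seed)
    wild = wild0.copy()
    mut = mut0.copy()
    n_rec = n_updates // record_every
    out = np.zeros((n_rec, len(N)), dtype=np.int64)
    r = 0
    for t in range(1, n_updates + 1):
        _one_update(wild, mut, v, u, False, with_repl, per_division, False)
        if t % record_every == 0:
            out[r] = mut
            r += 1
    return out


@njit(cache=False)
def _run_two_hit(seed, N, v, u, max_updates, with_repl, per_division, per_div2):
    np.random.seed(seed)
    wild = N.copy()
    mut = np.zeros(len(N), dtype=np.int64)
    for t in range(1, max_updates + 1):
        org = _one_update(wild, mut, v, u, True, with_repl, per_division, per_div2)
        if org >= 0:
            return t, org
    return -1, -1


# ---------------------------------------------------------------------------
# python-level API


def update_step(state: SimState, config: SimConfig, seed: int) -> SimState:
    """Apply one update to a copy of ``state`` (one-hit bookkeeping)."""
    new = state.copy()
    _seed_rng(int(seed))
    _one_update(new.wild, new.mutant, config.arch.v, config.u, False,
                config._with_replacement, config._per_division, False)
    new.t += 1
    if np.any(new.wild + new.mutant != config.arch.N):
        raise RuntimeError("internal error: compartment occupancy not conserved")
    return new


def run_trajectory(config: SimConfig, n_updates: int, record_every: int = 1,
                   m_init=None):
    """One-hit mutant counts recorded every ``record_every`` updates.

    Returns ``(times, counts)`` with ``counts`` of shape
    ``(n_updates // record_every, n + 1)``.
    """
    state = initial_state(config.arch, m_init)
    out = _run_trajectory(
        int(config.seed), config.arch.N, config.arch.v, config.u,
        state.wild, state.mutant, int(n_updates), int(record_every),
        config._with_replacement, config._per_division,
    )
    times = np.arange(1, out.shape[0] + 1) * record_every
    return times, out


def run_two_hit(config: SimConfig, seed=None) -> TwoHitResult:
    """Simulate from an all-wild-type start until the first two-hit daughter.

    Censoring at ``max_updates`` is reported explicitly via the result's
    ``censored`` flag.
    """
    s = int(config.seed if seed is None else seed)
    t2, org = _run_two_hit(
        s, config.arch.N, config.arch.v, config.u, int(config.max_updates),
        config._with_replacement, config._per_division, config._per_division_second,
    )
    return TwoHitResult(t2=int(t2), origin=int(org), censored=t2 < 0)


def run_ensemble(config: SimConfig, n_replicates: int, n_updates: int = None,
                 record_every: int = 1, m_init=None):
    """Replicate runs with seeds ``config.seed + r``.

    In two-hit mode returns a DataFrame (replicate, t2_updates, censored,
    origin_compartment); otherwise returns ``(times, counts)`` with counts of
    shape ``(n_replicates, n_recorded, n + 1)``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if config.two_hit:
        return run_two_hit_ensemble(config, n_replicates)
    if n_updates is None:
        raise ValueError("n_updates is required for one-hit ensembles")
    all_out = []
    for r in range(n_replicates):
        rep = replace(config, seed=config.seed + r)
        times, out = run_trajectory(rep, n_updates, record_every, m_init)
        all_out.append(out)
    return times, np.stack(all_out)


def run_two_hit_ensemble(config: SimConfig, n_replicates: int) -> pd.DataFrame:
    """Two-hit first-passage times for ``n_replicates`` independent runs."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = np.empty((n_replicates, 3), dtype=np.int64)
    for r in range(n_replicates):
        res = run_two_hit(config, seed=config.seed + r)
        rows[r] = (res.t2, res.censored, res.origin)
    return pd.DataFrame({
        "replicate": np.arange(n_replicates),
        "t2_updates": rows[:, 0],
        "censored": rows[:, 1].astype(bool),
        "origin_compartment": rows[:, 2],
    })
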