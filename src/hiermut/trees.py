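"""Division trees: enumeration, probabilities, sampling and statistics.

Removing ``2^n`` terminally differentiated cells triggers a cascade of
``2^n`` divisions distributed over the hierarchy.  A cascade is uniquely
characterized by the differentiation counts ``a = (a_0, ..., a_{n-1})``,
where ``a_i`` is the number of differentiation divisions performed by
``C_i``.  Validity requires ``a_{n-1} = 2^{n-1}`` (terminal cells never
divide, so all ``2^n`` removed cells are replaced by differentiation) and
``0 <= 2 a_{i-1} <= a_i`` (the ``a_i`` openings in ``C_i`` are filled by
``2 a_{i-1}`` differentiated daughters plus ``s_i = a_i - 2 a_{i-1} >= 0``
self-renewals).

Openings are resolved independently: each of the ``a_{i+1}`` openings in
``C_{i+1}`` self-renews with probability ``v_{i+1}``, and if the leftover
differentiation demand is odd one extra self-renewal is added.  Hence the
number of differentiation-filled openings ``X ~ Binomial(a_{i+1}, 1 - v_{i+1})``
and ``a_i`` differentiations occur iff ``X ∈ {2 a_i, 2 a_i + 1}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from .architecture import TissueArchitecture

__all__ = [
    "DivisionTree",
    "enumerate_trees",
    "conditional_prob",
    "tree_probability",
    "tree_distribution",
    "sample_tree",
    "expected_differentiations",
    "tree_statistics",
    "distribution_to_frame",
]


@dataclass(frozen=True)
class DivisionTree:
    """Differentiation-count string ``(a_0, ..., a_{n-1})`` of one cascade."""

    a: tuple

    def __post_init__(self):
        a = tuple(int(x) for x in self.a)
        object.__setattr__(self, "a", a)
        n = len(a)
        if n < 1:
            raise ValueError("a tree needs at least one compartment level")
        if a[-1] != 2 ** (n - 1):
            raise ValueError(f"a_(n-1) must equal 2^(n-1)={2 ** (n - 1)}, got {a[-1]}")
        prev = 0
        for i, ai in enumerate(a):
            if not (2 * prev <= ai):
                raise ValueError(f"invalid tree {a}: need 2*a_{i - 1} <= a_{i}")
            prev = ai

    @property
    def n(self) -> int:
        return len(self.a)

    @property
    def self_renewals(self) -> tuple:
        """``s_i = a_i - 2 a_{i-1}`` for i = 0..n, with ``a_{-1} = 0, a_n = 2^n``.

        ``s_0 = a_0`` counts the stem-compartment self-renewals that backfill
        its differentiated-out cells; ``s_n = 0`` always.
        """
        ext = (0,) + self.a + (2 ** self.n,)
        return tuple(ext[i + 1] - 2 * ext[i] for i in range(self.n + 1))

    @property
    def length(self) -> int:
        """Number of compartments with nonzero differentiation counts."""
        return sum(1 for x in self.a if x > 0)

    @property
    def total_divisions(self) -> int:
        """All divisions of the cascade: differentiations plus self-renewals."""
        return sum(self.a) + sum(self.self_renewals)


def enumerate_trees(n: int) -> list:
    """All valid trees for an ``n + 1``-compartment hierarchy, lexicographic.

    Counts for n = 1..4 are 1, 2, 4, 10.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    # build from the top: admissible a_i given a_{i+1} satisfy 0 <= 2 a_i <= a_{i+1}
    suffixes = [(2 ** (n - 1),)]
    for _ in range(n - 1):
        new = []
        for suf in suffixes:
            a_next = suf[0]
            for ai in range(a_next // 2 + 1):
                new.append((ai,) + suf)
        suffixes = new
    return [DivisionTree(a) for a in sorted(suffixes)]


def conditional_prob(a_i: int, a_next: int, v_next: float):
    """P(a_i differentiations in ``C_i`` | a_next openings in ``C_{i+1}``).

    Equals the Binomial(``a_next``, ``1 - v_next``) mass at
    ``{2 a_i, 2 a_i + 1}`` — the odd leftover opening receives one extra
    self-renewal.  Accepts floats or exact :class:`~fractions.Fraction`
    probabilities.
    """
    a_i, a_next = int(a_i), int(a_next)
    if a_i < 0 or a_next < 0 or 2 * a_i > a_next:
        raise ValueError(f"invalid combination a_i={a_i}, a_next={a_next}")
    if not (0 <= v_next <= 1):
        raise ValueError(f"v must lie in [0, 1], got {v_next}")
    one = v_next ** 0  # preserves Fraction arithmetic
    q = one - v_next
    k = 2 * a_i
    p = comb(a_next, k) * q**k * v_next ** (a_next - k)
    if k + 1 <= a_next:
        p += comb(a_next, k + 1) * q ** (k + 1) * v_next ** (a_next - k - 1)
    return p


def tree_probability(tree: DivisionTree, arch: TissueArchitecture, exact: bool = False):
    """Probability of a division tree: product of the per-level conditionals."""
    if tree.n != arch.n:
        raise ValueError(f"tree has n={tree.n} but architecture has n={arch.n}")
    v = [Fraction(x).limit_denominator(10**12) for x in arch.selfrenewal] if exact \
        else list(arch.selfrenewal)
    ext = tree.a + (2 ** arch.n,)
    p = Fraction(1) if exact else 1.0
    for i in range(arch.n):
        p *= conditional_prob(ext[i], ext[i + 1], v[i + 1])
    return p


def tree_distribution(arch: TissueArchitecture, exact: bool = False) -> list:
    """All (tree, probability) pairs for an architecture; probabilities sum to 1."""
    return [(t, tree_probability(t, arch, exact=exact)) for t in enumerate_trees(arch.n)]


def distribution_to_frame(dist) -> pd.DataFrame:
    """Tabulate a tree distribution: columns ``a_0..a_{n-1}``, probability, length."""
    n = dist[0][0].n
    rows = [
        {**{f"a_{i}": t.a[i] for i in range(n)},
         "probability": float(p), "length": t.length}
        for t, p in dist
    ]
    return pd.DataFrame(rows)


def sample_tree(arch: TissueArchitecture, rng) -> DivisionTree:
    """Draw one division tree by resolving openings top-down.

    Each of the ``a_{i+1}`` openings self-renews independently with
    probability ``v_{i+1}``; an odd differentiation leftover is rounded down
    by one extra self-renewal.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = arch.n
    a = [0] * n
    a[n - 1] = 2 ** (n - 1)
    for i in range(n - 2, -1, -1):
        d = rng.binomial(a[i + 1], 1.0 - arch.selfrenewal[i + 1])
        a[i] = d // 2  # odd leftover -> extra self-renewal
    return DivisionTree(tuple(a))


def expected_differentiations(arch: TissueArchitecture) -> np.ndarray:
    """``E[a_k]`` for k = 0..n-1, the exact sum over the tree distribution."""
    dist = tree_distribution(arch)
    out = np.zeros(arch.n)
    for t, p in dist:
        out += p * np.asarray(t.a, dtype=float)
    return out


def tree_statistics(arch: TissueArchitecture) -> dict:
    """Mean tree length and mean division position over the distribution.

    The mean division position of a single tree is
    ``2^{-n} * sum_{i=0}^{n} 2^i (a_i - a_{i-1})`` with ``a_{-1} = 0`` and
    ``a_n = 2^n``, implemented verbatim.
    """
    n = arch.n
    mean_length = 0.0
    mean_pos = 0.0
    for t, p in tree_distribution(arch):
        ext = (0,) + t.a + (2**n,)
        pos = sum(2**i * (ext[i + 1] - ext[i]) for i in range(n + 1)) / 2**n
        mean_length += p * t.length
        mean_pos += p * pos
    return {"mean_length": mean_length, "mean_division_position": mean_pos}
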