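"""Tissue architectures: compartment sizes and self-renewal probabilities.

A hierarchical tissue is modelled as ``n + 1`` well-mixed compartments
``C_0 .. C_n`` arranged from the stem-cell pool (``C_0``) to the terminally
differentiated pool (``C_n``).  Each compartment has a fixed size ``N_i`` and a
self-renewal probability ``v_i`` — the probability that an opening in ``C_i``
is filled by a symmetric self-renewal division inside ``C_i`` rather than by a
differentiation division from ``C_{i-1}``.  Two constraints are structural:
removed stem cells can only be replaced by self-renewal, so ``v_0 = 1``, and
terminally differentiated cells do not divide, so ``v_n = 0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import yaml

__all__ = [
    "TissueArchitecture",
    "ScenarioPreset",
    "make_architecture",
    "preset",
    "preset_names",
    "architecture_to_dict",
    "architecture_from_dict",
]


@dataclass(frozen=True)
class TissueArchitecture:
    """Sizes and self-renewal probabilities of a compartment hierarchy.

    Parameters
    ----------
    n : int
        Number of non-terminal levels; compartments are ``C_0 .. C_n``.
    sizes : tuple of int
        Compartment sizes ``N_0 .. N_n`` (cells), all >= 1.
    selfrenewal : tuple of float
        Self-renewal probabilities ``v_0 .. v_n`` with ``v_0 = 1``,
        ``v_n = 0`` and every entry in [0, 1].
    """

    n: int
    sizes: tuple
    selfrenewal: tuple

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if len(self.sizes) != self.n + 1:
            raise ValueError(
                f"sizes must have length n+1={self.n + 1}, got {len(self.sizes)}"
            )
        if len(self.selfrenewal) != self.n + 1:
            raise ValueError(
                f"selfrenewal must have length n+1={self.n + 1}, "
                f"got {len(self.selfrenewal)}"
            )
        if any(int(N) != N or N < 1 for N in self.sizes):
            raise ValueError(f"all compartment sizes must be integers >= 1: {self.sizes}")
        if any(not (0.0 <= v <= 1.0) for v in self.selfrenewal):
            raise ValueError(f"self-renewal probabilities must lie in [0, 1]: {self.selfrenewal}")
        if self.selfrenewal[0] != 1.0:
            raise ValueError("v_0 must equal 1 (stem cells are replaced by self-renewal only)")
        if self.selfrenewal[-1] != 0.0:
            raise ValueError("v_n must equal 0 (terminally differentiated cells do not divide)")
        object.__setattr__(self, "sizes", tuple(int(N) for N in self.sizes))
        object.__setattr__(self, "selfrenewal", tuple(float(v) for v in self.selfrenewal))

    @property
    def N(self) -> np.ndarray:
        """Compartment sizes as an integer array."""
        return np.asarray(self.sizes, dtype=np.int64)

    @property
    def v(self) -> np.ndarray:
        """Self-renewal probabilities as a float array."""
        return np.asarray(self.selfrenewal, dtype=np.float64)

    @property
    def total_cells(self) -> int:
        return int(sum(self.sizes))


def make_architecture(n, sizes, v_spec) -> TissueArchitecture:
    """Build a :class:`TissueArchitecture` from a self-renewal specification.

    ``v_spec`` may be

    * a scalar ``v`` applied to the interior compartments ``C_1 .. C_{n-1}``;
    * an explicit vector of length ``n + 1`` (its first and last entries are
      overridden to 1 and 0);
    * the string ``"size_coupled"``, which sets
      ``v_i = N_i / (N_i + N_{i-1})`` for ``1 <= i <= n - 1`` so that
      differentiation from large into small compartments is disfavored.

    The boundary values ``v_0 = 1`` and ``v_n = 0`` are always forced, so a
    scalar spec like ``v=0.9`` means ``v = (1, 0.9, ..., 0.9, 0)``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    sizes = tuple(sizes)
    if len(sizes) != n + 1:
        raise ValueError(f"sizes must have length n+1={n + 1}, got {len(sizes)}")

    if isinstance(v_spec, str):
        if v_spec != "size_coupled":
            raise ValueError(f"unknown v_spec rule: {v_spec!r}")
        v = [1.0] + [sizes[i] / (sizes[i] + sizes[i - 1]) for i in range(1, n)] + [0.0]
    elif np.ndim(v_spec) == 0:
        v_scalar = float(v_spec)
        if not (0.0 <= v_scalar <= 1.0):
            raise ValueError(f"v must lie in [0, 1], got {v_scalar}")
        v = [1.0] + [v_scalar] * (n - 1) + [0.0]
    else:
        v = [float(x) for x in v_spec]
        if len(v) != n + 1:
            raise ValueError(f"v vector must have length n+1={n + 1}, got {len(v)}")
        if any(not (0.0 <= x <= 1.0) for x in v):
            raise ValueError(f"self-renewal probabilities must lie in [0, 1]: {v}")
        v[0], v[-1] = 1.0, 0.0
    return TissueArchitecture(n=n, sizes=sizes, selfrenewal=tuple(v))


@dataclass(frozen=True)
class ScenarioPreset:
    """A named parameterization (architecture plus mutation probability)."""

    name: str
    architecture: TissueArchitecture
    u: float
    notes: str = ""

    def __post_init__(self):
        if not (0.0 <= self.u <= 1.0):
            raise ValueError(f"u must lie in [0, 1], got {self.u}")


_SIZES_CONSTANT = (65, 65, 65, 65)
_SIZES_INCREASING = (20, 40, 80, 120)
# The decreasing profile is the reversal of the increasing one; it preserves
# the total cell count (260), making the two directly comparable.
_SIZES_DECREASING = (120, 80, 40, 20)


def _presets() -> dict:
    table = {}

    def add(name, n, sizes, v_spec, u, notes):
        table[name] = ScenarioPreset(
            name=name, architecture=make_architecture(n, sizes, v_spec), u=u, notes=notes
        )

    add("fig3", 3, (1063, 10_000, 100_000, 1_000_000), 0.9, 1e-3,
        "ODE-vs-simulation comparison; N_0 = 1063 as printed (1000 is the "
        "plausible intended value, kept as an alternative only); v = 0.9 panel")
    add("fig3_v01", 3, (1063, 10_000, 100_000, 1_000_000), 0.1, 1e-3,
        "ODE-vs-simulation comparison, v = 0.1 panel")
    add("fig4", 4, (40, 80, 120, 160, 200), 0.1, 1e-3,
        "generation-probability and clonal-dynamics analyses; v is swept in "
        "the source figure, stored here at 0.1")
    add("fig5_constant", 3, _SIZES_CONSTANT, 0.9, 1e-3,
        "one-hit ensemble, constant architecture (total 260 cells)")
    add("fig5_increasing", 3, _SIZES_INCREASING, 0.9, 1e-3,
        "one-hit ensemble, increasing architecture (total 260 cells)")
    add("fig6_constant_v09", 3, _SIZES_CONSTANT, 0.9, 1e-3,
        "two-hit waiting times, constant sizes, high self-renewal")
    add("fig6_increasing_v09", 3, _SIZES_INCREASING, 0.9, 1e-3,
        "two-hit waiting times, increasing sizes, high self-renewal")
    add("fig6_constant_v01", 3, _SIZES_CONSTANT, 0.1, 1e-3,
        "two-hit waiting times, constant sizes, low self-renewal")
    add("fig6_increasing_v01", 3, _SIZES_INCREASING, 0.1, 1e-3,
        "two-hit waiting times, increasing sizes, low self-renewal")
    add("fig7_constant", 3, _SIZES_CONSTANT, "size_coupled", 1e-3,
        "two-hit waiting times, size-coupled self-renewal, constant sizes "
        "(v interior = 0.5)")
    add("fig7_increasing", 3, _SIZES_INCREASING, "size_coupled", 1e-3,
        "two-hit waiting times, size-coupled self-renewal, increasing sizes")
    add("fig7_decreasing", 3, _SIZES_DECREASING, "size_coupled", 1e-3,
        "two-hit waiting times, size-coupled self-renewal, decreasing sizes "
        "(reversal of the increasing profile; not printed in the source)")
    # aliases for the four two-hit comparison panels
    table["fig6a_constant"] = table["fig6_constant_v09"]
    table["fig6a_increasing"] = table["fig6_increasing_v09"]
    table["fig6b_constant"] = table["fig6_constant_v01"]
    table["fig6b_increasing"] = table["fig6_increasing_v01"]
    return table


_PRESET_TABLE = _presets()


def preset_names() -> list:
    """Names of all registered scenario presets."""
    return sorted(_PRESET_TABLE)


def preset(name: str, v=None) -> ScenarioPreset:
    """Look up a named scenario preset.

    Parameters
    ----------
    name : str
        One of :func:`preset_names`.
    v : optional
        Override the interior self-renewal probability (scalar, vector, or
        ``"size_coupled"``) while keeping the preset's sizes and ``u``.
    """
    try:
        p = _PRESET_TABLE[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
    if v is not None:
        arch = make_architecture(p.architecture.n, p.architecture.sizes, v)
        p = replace(p, architecture=arch, notes=p.notes + f" (v overridden to {v!r})")
    return p


# ---------------------------------------------------------------------------
# serialization


def architecture_to_dict(arch: TissueArchitecture, u=None) -> dict:
    d = {"n": arch.n, "sizes": list(arch.sizes), "v": list(arch.selfrenewal)}
    if u is not None:
        d["u"] = float(u)
    return d


def architecture_from_dict(d: dict) -> TissueArchitecture:
    """Build an architecture from a mapping with keys n, sizes, v.

    ``v`` may be a scalar, a list, or the string ``"size_coupled"``.
    """
    unknown = set(d) - {"n", "sizes", "v", "u"}
    if unknown:
        raise ValueError(f"unknown architecture keys: {sorted(unknown)}")
    return make_architecture(int(d["n"]), d["sizes"], d["v"])


def save_architecture(arch: TissueArchitecture, path, u=None):
    path = str(path)
    d = architecture_to_dict(arch, u=u)
    with open(path, "w") as fh:
        if path.endswith((".yml", ".yaml")):
            yaml.safe_dump(d, fh)
        else:
            json.dump(d, fh, indent=1)


def load_architecture(path):
    path = str(path)
    with open(path) as fh:
        d = yaml.safe_load(fh)  # YAML is a superset of JSON
    return architecture_from_dict(d)
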