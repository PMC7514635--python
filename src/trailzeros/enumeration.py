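"""Exact enumeration of trails and the shared coefficient-table container.

:func:`enumerate_trails` walks the full tree of legal trails up to a small
maximum length by depth-first search and returns the exact integer counts
``c_{N, n_coll, n_cross, n_straight, n_surface}`` — the microcanonical
coefficients of the canonical partition function.  It is the oracle against
which the stochastic (FlatPERM) estimates are validated.

:class:`CountTable` holds either exact integer counts or real-valued
FlatPERM estimates, keyed by the full feature tuple, with provenance
metadata, and round-trips bit-exactly through a plain-text TSV format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .walks import ModelWeights

FeatureKey = tuple[int, int, int, int, int]  # (N, n_coll, n_cross, n_straight, n_surface)

_TSV_MAGIC = "# trailzeros count-table v1"
_COLUMNS = ("N", "n_coll", "n_cross", "n_straight", "n_surface", "value")


@dataclass
class CountTable:
    """Microcanonical coefficients, exact or estimated.

    ``counts`` maps ``(N, n_coll, n_cross, n_straight, n_surface)`` to a
    nonnegative value: an exact integer in ``"exact"`` mode, a real FlatPERM
    estimate in ``"flatperm"`` mode.  ``meta`` records provenance (seed,
    tours, replicate, carried weights, flat axes ...).  In FlatPERM mode
    features outside the flattened axes are folded into the estimate and
    their columns read zero.
    """

    counts: dict[FeatureKey, float]
    weights: ModelWeights
    mode: str = "exact"  # "exact" | "flatperm"
    n_max: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "flatperm"):
            raise ValueError(f"unknown table mode {self.mode!r}")
        for key, v in self.counts.items():
            if v < 0:
                raise ValueError(f"negative count at {key}")
            if self.mode == "exact" and v != int(v):
                raise ValueError(f"non-integer exact count at {key}")

    # -- queries ----------------------------------------------------------

    def lengths(self) -> list[int]:
        return sorted({k[0] for k in self.counts})

    def total(self, n: int) -> float:
        """Total number (or estimate) of n-step trails."""
        return sum(v for k, v in self.counts.items() if k[0] == n)

    def slice(self, n: int) -> dict[FeatureKey, float]:
        return {k: v for k, v in self.counts.items() if k[0] == n}

    def marginal_interactions(self, n: int) -> dict[int, float]:
        """Counts at length n grouped by NI = n_coll + n_cross."""
        out: dict[int, float] = {}
        for k, v in self.slice(n).items():
            out[k[1] + k[2]] = out.get(k[1] + k[2], 0.0) + v
        return out

    def marginal_surface(self, n: int) -> dict[int, float]:
        """Counts at length n grouped by the surface-contact number."""
        out: dict[int, float] = {}
        for k, v in self.slice(n).items():
            out[k[4]] = out.get(k[4], 0.0) + v
        return out

    # -- serialization ----------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(_TSV_MAGIC + "\n")
            fh.write("# model: " + json.dumps(self.weights.to_dict(), sort_keys=True) + "\n")
            fh.write("# mode: " + self.mode + "\n")
            fh.write("# n_max: " + str(self.n_max) + "\n")
            fh.write("# meta: " + json.dumps(self.meta, sort_keys=True) + "\n")
            fh.write("\t".join(_COLUMNS) + "\n")
            for key in sorted(self.counts):
                v = self.counts[key]
                if self.mode == "exact":
                    sval = str(int(v))
                else:
                    sval = repr(float(v))
                fh.write("\t".join(str(x) for x in key) + "\t" + sval + "\n")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        with open(path) as fh:
            lines = fh.read().splitlines()
        if not lines or lines[0] != _TSV_MAGIC:
            raise ValueError(f"{path}: not a trailzeros count-table")
        model = mode = meta = None
        n_max = 0
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("# model: "):
                model = json.loads(line[len("# model: "):])
            elif line.startswith("# mode: "):
                mode = line[len("# mode: "):]
            elif line.startswith("# n_max: "):
                n_max = int(line[len("# n_max: "):])
            elif line.startswith("# meta: "):
                meta = json.loads(line[len("# meta: "):])
            elif not line.startswith("#"):
                body_start = i
                break
        if lines[body_start] != "\t".join(_COLUMNS):
            raise ValueError(f"{path}: unexpected column header")
        counts: dict[FeatureKey, float] = {}
        for line in lines[body_start + 1:]:
            if not line:
                continue
            parts = line.split("\t")
            key = tuple(int(x) for x in parts[:5])
            counts[key] = float(parts[5])
        return cls(
            counts=counts,
            weights=ModelWeights.from_dict(model),
            mode=mode,
            n_max=n_max,
            meta=meta or {},
        )


def symmetry_factor(weights: ModelWeights) -> int:
    """Multiplicity of a fixed-first-step enumeration.

    The free lattice is four-fold rotation symmetric, so fixing the first
    step and multiplying by 4 reproduces the unreduced totals.  A wall
    breaks the rotational symmetry, so surface enumerations carry factor 1.
    """
    return 1 if weights.surface else 4


def enumerate_trails(
    weights: ModelWeights,
    n_max: int,
    reduce_symmetry: bool = False,
    node_budget: Optional[int] = None,
) -> CountTable:
    """Exact counts of all distinct trails of length 1..n_max.

    All four first steps are enumerated by default; with
    ``reduce_symmetry`` (bulk only) the first step is fixed and counts are
    multiplied by :func:`symmetry_factor`.  Deterministic.  ``node_budget``
    raises a resource error beyond roughly that many trails (estimated a
    priori from the 4 * 3^(N-1) upper bound).
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if node_budget is not None and 4 * 3 ** (n_max - 1) > node_budget:
        raise ResourceWarning(
            f"enumeration to N={n_max} may exceed the node budget {node_budget}"
        )
    visaw = weights.variant == "visaw"
    mc = n_max // 2 + 1
    ms = max(n_max, 1)
    msu = n_max + 1 if weights.surface else 1
    site_conv = weights.surface_convention == "sites"
    factor = 1
    first_dir = -1
    if reduce_symmetry:
        if weights.surface:
            raise ValueError("symmetry reduction is a bulk-only optimization")
        first_dir = 0
        factor = symmetry_factor(weights)
    counts = np.zeros((n_max + 1, mc, mc, ms, msu), dtype=np.int64)
    _kernels.enumerate_kernel(
        n_max, visaw, weights.surface, site_conv, first_dir, counts
    )
    sparse: dict[FeatureKey, float] = {}
    nz = np.argwhere(counts)
    for n, a, b, c, s in nz:
        if n == 0:
            continue
        sparse[(int(n), int(a), int(b), int(c), int(s))] = float(
            counts[n, a, b, c, s] * factor
        )
    return CountTable(
        counts=sparse,
        weights=weights,
        mode="exact",
        n_max=n_max,
        meta={"reduced": bool(reduce_symmetry), "symmetry_factor": factor},
    )
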