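"""Flat-histogram pruned-and-enriched Rosenbluth (FlatPERM) sampling.

FlatPERM grows trails step by step from the anchored start.  At length
``n`` a walk with atmosphere ``a_n`` (number of legal continuations)
carries a Rosenbluth weight that is multiplied by ``a_n`` per step, times
any carried Boltzmann factor for the feature the step just created.  Every
visit to a histogram cell ``(n, m)`` — where ``m`` is the flattened feature
bin — adds the current weight to a running accumulator ``C`` and one to a
visit counter ``S``; after ``T`` tours the estimate of the microcanonical
coefficient is ``c_{n,m} ~= C[n,m] / T``.  Pruning and enrichment keep the
histogram of visits flat: with ``r = W / Wbar`` (``Wbar = C[n,m]/T`` the
running mean weight), a branch with ``r < 1`` survives with probability
``r`` at weight ``Wbar``, and a branch with ``r > 1`` splits into
``min(ceil(r), a_n)`` copies of weight ``W/c``.  A cell's very first visit
neither prunes nor enriches.  The scheme is unbiased; the test suite checks
the estimates against exact enumeration.

Estimating the *effective* surface coefficients — the partition-polynomial
coefficients in the surface weight at fixed bulk weights — is the same
algorithm flattening in (n, surface contacts) while carrying ``tau`` and
``p`` as growth weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import _kernels
from .enumeration import CountTable, FeatureKey
from .walks import ModelWeights

FLAT_AXES = ("ni", "surface", "coll_cross")

_FLAT_CODE = {"ni": _kernels.FLAT_NI, "surface": _kernels.FLAT_NS,
              "coll_cross": _kernels.FLAT_CC}


@dataclass(frozen=True)
class FlatPermConfig:
    """Run configuration for FlatPERM sampling.

    ``flat_axes`` selects the histogram bin: ``"ni"`` flattens in the total
    number of doubly visited sites (collisions + crossings), ``"surface"``
    in the surface-contact number (with ``tau`` and ``p`` carried as growth
    weights — the effective-coefficient mode), ``"coll_cross"`` in the
    (collision, crossing) pair.  ``tours`` is the iteration budget per
    replicate; replicate sub-seeds are derived from ``seed`` by NumPy's
    SeedSequence spawning and recorded in the output metadata.
    """

    n_max: int
    tours: int
    flat_axes: str = "ni"
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.tours < 1:
            raise ValueError("tours must be >= 1")
        if self.flat_axes not in FLAT_AXES:
            raise ValueError(f"unknown flat_axes {self.flat_axes!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def bin_shape(self) -> tuple[int, int]:
        """(number of bins M, secondary stride m2_cap) for the kernel."""
        half = self.n_max // 2 + 1
        if self.flat_axes == "ni":
            return half, 1
        if self.flat_axes == "surface":
            return self.n_max + 1, 1
        return half * half, half

    def replicate_seeds(self) -> list[int]:
        """Distinct sub-seeds, one per replicate (kept below 2^31)."""
        state = np.random.SeedSequence(self.seed).generate_state(self.replicates)
        seeds = [int(s % (2**31 - 1)) for s in state]
        if len(set(seeds)) != len(seeds):  # pragma: no cover - astronomically rare
            seeds = [(s + i) % (2**31 - 1) for i, s in enumerate(seeds)]
        return seeds

    def to_dict(self) -> dict:
        return {
            "n_max": self.n_max,
            "tours": self.tours,
            "flat_axes": self.flat_axes,
            "seed": self.seed,
            "replicates": self.replicates,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FlatPermConfig":
        return cls(**d)


@dataclass
class HistogramState:
    """Accumulated FlatPERM histogram of one replicate.

    ``C[n, m]`` is the summed visit weight, ``S[n, m]`` the visit count;
    ``Wbar = C / tours`` is the running mean weight.  ``steps`` counts
    growth steps (one per appended walk step, over all branches).
    """

    config: FlatPermConfig
    weights: ModelWeights
    C: np.ndarray
    S: np.ndarray
    tours: int = 0
    steps: int = 0

    @classmethod
    def fresh(cls, weights: ModelWeights, config: FlatPermConfig) -> "HistogramState":
        _check_model(weights, config)
        m, _ = config.bin_shape()
        return cls(
            config=config,
            weights=weights,
            C=np.zeros((config.n_max + 1, m)),
            S=np.zeros((config.n_max + 1, m), dtype=np.int64),
        )

    def wbar(self) -> np.ndarray:
        """Running mean weight per cell (NaN where never visited)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(self.S > 0, self.C / max(self.tours, 1), np.nan)
        return out

    def coverage(self, n: int) -> int:
        """Number of visited bins at length n."""
        return int((self.S[n] > 0).sum())

    def save(self, path) -> None:
        np.savez(path, C=self.C, S=self.S, tours=self.tours, steps=self.steps)

    def restore(self, path) -> None:
        data = np.load(path)
        self.C = data["C"]
        self.S = data["S"]
        self.tours = int(data["tours"])
        self.steps = int(data["steps"])


@dataclass
class RunEstimate:
    """Estimated coefficient table of one replicate, with diagnostics."""

    table: CountTable
    replicate: int
    seed: int
    tours: int
    steps: int
    coverage: dict[int, int]


def _check_model(weights: ModelWeights, config: FlatPermConfig) -> None:
    if config.flat_axes == "surface" and not weights.surface:
        raise ValueError("surface flattening requires a surface-mode model")
    if config.flat_axes == "ni" and weights.variant == "generalized" \
            and weights.tau_c != weights.tau_x:
        raise ValueError(
            "flattening in NI conflates collisions and crossings; the "
            "generalized model with tau_c != tau_x needs flat_axes='coll_cross'"
        )


def grow_tour(
    state: HistogramState,
    weights: ModelWeights,
    config: FlatPermConfig,
    rng: np.random.Generator,
) -> HistogramState:
    """Run one complete FlatPERM tour, updating the histogram in place.

    The tour's random stream is seeded from ``rng``; a sequence of calls
    with the same generator state reproduces bit for bit.
    """
    seed = int(rng.integers(0, 2**31 - 1))
    _run_tours(state, weights, config, seed, 1)
    return state


def _run_tours(state: HistogramState, weights: ModelWeights,
               config: FlatPermConfig, seed: int, tours: int) -> None:
    _, m2_cap = config.bin_shape()
    steps_out = np.zeros(1, dtype=np.int64)
    _kernels.flatperm_kernel(
        config.n_max,
        tours,
        weights.variant == "visaw",
        weights.surface,
        weights.surface_convention == "sites",
        _FLAT_CODE[config.flat_axes],
        weights.tau_c,
        weights.tau_x,
        weights.p,
        m2_cap,
        state.C,
        state.S,
        seed,
        state.tours,
        steps_out,
    )
    state.tours += tours
    state.steps += int(steps_out[0])


def state_to_table(state: HistogramState, replicate: int = 0,
                   seed: Optional[int] = None) -> CountTable:
    """Convert an accumulated histogram into a CountTable estimate.

    Features outside the flattened axes are folded into the estimate (and,
    in surface mode, carry the fixed ``tau``/``p`` growth weights); their
    key columns read zero.  Lengths with no coverage are truncated with a
    warning.
    """
    config = state.config
    if state.tours < 1:
        raise ValueError("empty histogram state")
    est = state.C / state.tours
    counts: dict[FeatureKey, float] = {}
    half = config.n_max // 2 + 1
    covered_max = 0
    for n in range(1, config.n_max + 1):
        cells = np.nonzero(state.S[n])[0]
        if cells.size:
            covered_max = n
        for m in cells:
            m = int(m)
            if config.flat_axes == "ni":
                key = (n, m, 0, 0, 0)
            elif config.flat_axes == "surface":
                key = (n, 0, 0, 0, m)
            else:
                key = (n, m // half, m % half, 0, 0)
            counts[key] = float(est[n, m])
    if covered_max < config.n_max:
        warnings.warn(
            f"no bin coverage beyond N={covered_max}; table truncated",
            stacklevel=2,
        )
    meta = {
        "flat_axes": config.flat_axes,
        "tours": state.tours,
        "steps": state.steps,
        "seed": seed if seed is not None else config.seed,
        "replicate": replicate,
        "carried": {"tau_c": state.weights.tau_c, "tau_x": state.weights.tau_x,
                    "p": state.weights.p}
        if config.flat_axes == "surface"
        else {"p": state.weights.p},
    }
    return CountTable(
        counts=counts,
        weights=state.weights,
        mode="flatperm",
        n_max=covered_max,
        meta=meta,
    )


def run_flatperm(weights: ModelWeights, config: FlatPermConfig) -> list[RunEstimate]:
    """Run independent FlatPERM replicates; one estimate table each.

    Replicates use distinct sub-seeds derived from ``config.seed`` and are
    bit-for-bit reproducible given (seed, config).
    """
    _check_model(weights, config)
    estimates = []
    for rep, seed in enumerate(config.replicate_seeds()):
        state = HistogramState.fresh(weights, config)
        _run_tours(state, weights, config, seed, config.tours)
        table = state_to_table(state, replicate=rep, seed=seed)
        estimates.append(
            RunEstimate(
                table=table,
                replicate=rep,
                seed=seed,
                tours=state.tours,
                steps=state.steps,
                coverage={n: state.coverage(n) for n in range(config.n_max + 1)},
            )
        )
    return estimates


def effective_coefficients(
    weights: ModelWeights, config: FlatPermConfig
) -> list[CountTable]:
    """Effective surface coefficients at fixed ``tau`` and ``p``.

    Runs surface-mode FlatPERM flattening in (N, surface contacts) while
    carrying ``tau`` and ``p`` as growth weights; the returned tables hold
    ``ctilde_{N_S}(N) = sum over bulk features of c_{N,.,N_S} tau^{N_I}
    p^{n_straight}`` — the coefficients of the surface partition polynomial
    in ``omega``.
    """
    if not weights.surface:
        raise ValueError("effective coefficients require surface mode")
    if config.flat_axes != "surface":
        config = replace(config, flat_axes="surface")
    return [est.table for est in run_flatperm(weights, config)]
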