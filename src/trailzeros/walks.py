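"""Square-lattice trail geometry and vertex bookkeeping.

A *trail* is a lattice path that may not traverse any lattice bond twice but
may visit a site up to twice (the maximum on the square lattice, which has
four bonds per site).  A doubly visited site hosts two passages of the walk
and is classified either as a *collision* (the two passages touch and
deflect) or a *crossing* (both passages run straight through, transversally).
The interacting self-avoiding trail (ISAT) weights both alike,
``tau_c == tau_x``; the vertex-interacting self-avoiding walk (VISAW)
forbids crossings outright and weights collisions with ``tau_c``.  A
stiffness weight ``p`` is attached to singly visited vertices where the walk
continues straight, and in the half-plane (adsorption) geometry a weight
``omega`` is attached to surface contacts with the wall ``y = 0``.

This module is the reference implementation of the model rules: everything
here recomputes from scratch and is deliberately simple.  The enumeration
and sampling kernels keep their own incremental state and are checked
against these functions in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional, Sequence, Union


class WalkError(ValueError):
    """A walk or vertex configuration violates the trail constraints."""


class Direction(Enum):
    """One of the four unit steps on the square lattice."""

    E = (1, 0)
    N = (0, 1)
    W = (-1, 0)
    S = (0, -1)

    @property
    def dx(self) -> int:
        return self.value[0]

    @property
    def dy(self) -> int:
        return self.value[1]

    @property
    def opposite(self) -> "Direction":
        return _OPPOSITE[self]

    @property
    def axis(self) -> str:
        """'x' for E/W, 'y' for N/S."""
        return "x" if self.value[0] != 0 else "y"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Direction.{self.name}"


_OPPOSITE = {
    Direction.E: Direction.W,
    Direction.W: Direction.E,
    Direction.N: Direction.S,
    Direction.S: Direction.N,
}

#: Canonical direction order used by the kernels and serialization.
DIRECTIONS = (Direction.E, Direction.N, Direction.W, Direction.S)


def steps_from_string(text: str) -> tuple[Direction, ...]:
    """Parse a direction string over the alphabet ``EWNS``."""
    try:
        return tuple(Direction[ch] for ch in text.strip().upper())
    except KeyError as exc:
        raise WalkError(f"invalid direction character in {text!r}") from exc


def steps_to_string(steps: Iterable[Direction]) -> str:
    return "".join(d.name for d in steps)


VARIANTS = ("isat", "visaw", "generalized")
SURFACE_CONVENTIONS = ("steps", "sites")


@dataclass(frozen=True)
class ModelWeights:
    """Boltzmann weights and variant flags of the generalized trail model.

    Parameters
    ----------
    tau_c, tau_x :
        Weights per collision and per crossing site.  ISAT requires
        ``tau_c == tau_x``; VISAW requires ``tau_x == 0`` and treats any
        crossing-creating step as an illegal move rather than a weight-0
        configuration.
    p :
        Stiffness weight per singly visited straight vertex.  Doubly
        visited sites carry only ``tau_c``/``tau_x`` (one weight per vertex
        configuration; the straight passages of a crossing acquire no extra
        ``p``).
    omega :
        Surface-contact weight (half-plane geometry only).
    surface :
        Confine the walk to ``y >= 0`` with the start anchored on the wall.
    surface_convention :
        ``"steps"`` counts steps with both endpoints on the wall;
        ``"sites"`` counts distinct visited wall sites excluding the
        anchored start.
    """

    tau_c: float = 1.0
    tau_x: float = 1.0
    p: float = 1.0
    omega: float = 1.0
    variant: str = "isat"
    surface: bool = False
    surface_convention: str = "steps"

    def __post_init__(self) -> None:
        for name in ("tau_c", "tau_x", "p", "omega"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.surface_convention not in SURFACE_CONVENTIONS:
            raise ValueError(
                f"unknown surface convention {self.surface_convention!r}"
            )
        if self.variant == "isat" and self.tau_c != self.tau_x:
            raise ValueError("ISAT requires tau_c == tau_x")
        if self.variant == "visaw" and self.tau_x != 0.0:
            raise ValueError("VISAW requires tau_x == 0 (crossings forbidden)")

    @classmethod
    def isat(cls, tau: float = 1.0, **kw) -> "ModelWeights":
        return cls(tau_c=tau, tau_x=tau, variant="isat", **kw)

    @classmethod
    def visaw(cls, tau: float = 1.0, **kw) -> "ModelWeights":
        return cls(tau_c=tau, tau_x=0.0, variant="visaw", **kw)

    def with_(self, **kw) -> "ModelWeights":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "tau_c": self.tau_c,
            "tau_x": self.tau_x,
            "p": self.p,
            "omega": self.omega,
            "variant": self.variant,
            "surface": self.surface,
            "surface_convention": self.surface_convention,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelWeights":
        return cls(**d)


@dataclass(frozen=True)
class FeatureCounts:
    """Microcanonical features of a single walk.

    ``n`` is the number of steps, ``n_coll``/``n_cross`` the collision and
    crossing sites, ``n_straight`` the singly visited straight vertices and
    ``n_surface`` the surface contacts (under the configured convention;
    zero in bulk geometry).
    """

    n: int
    n_coll: int = 0
    n_cross: int = 0
    n_straight: int = 0
    n_surface: int = 0

    def __post_init__(self) -> None:
        if min(self.n, self.n_coll, self.n_cross, self.n_straight, self.n_surface) < 0:
            raise ValueError("feature counts must be >= 0")
        if self.n_coll + self.n_cross > self.n // 2:
            raise ValueError("too many doubly visited sites for this length")
        if self.n > 0 and self.n_straight > self.n - 1:
            raise ValueError("too many straight vertices for this length")
        if self.n_surface > self.n:
            raise ValueError("too many surface contacts for this length")

    @property
    def n_interactions(self) -> int:
        """Total doubly visited sites, the ISAT interaction count."""
        return self.n_coll + self.n_cross

    def as_key(self) -> tuple[int, int, int, int, int]:
        return (self.n, self.n_coll, self.n_cross, self.n_straight, self.n_surface)


Passage = tuple[Optional[Direction], Optional[Direction]]


def _passage_bonds(passage: Passage) -> frozenset:
    """Incident bond directions of one passage through a site.

    A passage is an ``(in, out)`` pair of step directions; either may be
    ``None`` when the site is a walk endpoint.  The bond toward the
    predecessor site points opposite to the incoming step.
    """
    in_dir, out_dir = passage
    bonds = set()
    if in_dir is not None:
        bonds.add(in_dir.opposite)
    if out_dir is not None:
        bonds.add(out_dir)
    if in_dir is not None and out_dir is not None and len(bonds) == 1:
        raise WalkError("passage enters and leaves through the same bond")
    return frozenset(bonds)


def classify_doubly_visited_site(passage_a: Passage, passage_b: Passage) -> str:
    """Classify a doubly visited site as ``"collision"`` or ``"crossing"``.

    A crossing requires both passages to run straight through transversally:
    one occupies the two x-axis bonds, the other the two y-axis bonds.  Any
    other pairing — including endpoint-degenerate passages with fewer than
    four distinct incident bonds (a closed-loop touch, or the walk's head
    resting on the site) — is a collision.
    """
    bonds_a = _passage_bonds(passage_a)
    bonds_b = _passage_bonds(passage_b)
    if bonds_a & bonds_b:
        raise WalkError("the two passages share a lattice bond")
    if len(bonds_a | bonds_b) > 4:  # pragma: no cover - defensive
        raise WalkError("more than four incident bonds at one site")
    x_pair = frozenset({Direction.E, Direction.W})
    y_pair = frozenset({Direction.N, Direction.S})
    if {bonds_a, bonds_b} == {x_pair, y_pair}:
        return "crossing"
    return "collision"


class LatticeWalk:
    """A bond-self-avoiding path on the square lattice.

    Invariants checked at construction: no bond used twice, no site visited
    (occupied) more than twice, and in surface mode all sites at ``y >= 0``
    with the start on the wall ``y = 0``.
    """

    __slots__ = ("start", "steps", "surface", "_sites")

    def __init__(
        self,
        steps: Union[str, Sequence[Direction]] = (),
        start: tuple[int, int] = (0, 0),
        surface: bool = False,
    ) -> None:
        if isinstance(steps, str):
            steps = steps_from_string(steps)
        self.steps: tuple[Direction, ...] = tuple(steps)
        self.start = (int(start[0]), int(start[1]))
        self.surface = bool(surface)
        sites = [self.start]
        x, y = self.start
        for d in self.steps:
            x, y = x + d.dx, y + d.dy
            sites.append((x, y))
        self._sites = tuple(sites)
        self._validate()

    def _validate(self) -> None:
        if self.surface and self.start[1] != 0:
            raise WalkError("surface walks must start on the wall y = 0")
        bonds = set()
        visits: dict[tuple[int, int], int] = {}
        visits[self.start] = 1
        for a, b in zip(self._sites, self._sites[1:]):
            bond = frozenset((a, b))
            if bond in bonds:
                raise WalkError(f"bond {a}-{b} used twice")
            bonds.add(bond)
            visits[b] = visits.get(b, 0) + 1
            if visits[b] > 2:
                raise WalkError(f"site {b} visited more than twice")
            if self.surface and b[1] < 0:
                raise WalkError(f"site {b} below the wall")

    # -- basic views ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def sites(self) -> tuple[tuple[int, int], ...]:
        """Visited sites in walk order (length N + 1, with repeats)."""
        return self._sites

    @property
    def head(self) -> tuple[int, int]:
        return self._sites[-1]

    def visit_counts(self) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for s in self._sites:
            counts[s] = counts.get(s, 0) + 1
        return counts

    def used_bonds(self) -> set:
        return {frozenset(pair) for pair in zip(self._sites, self._sites[1:])}

    def extended(self, d: Direction) -> "LatticeWalk":
        """The walk with one step appended (re-validates)."""
        return LatticeWalk(self.steps + (d,), start=self.start, surface=self.surface)

    def reversed(self) -> "LatticeWalk":
        """The same path traversed from the other end (bulk only)."""
        rev = tuple(d.opposite for d in reversed(self.steps))
        return LatticeWalk(rev, start=self.head, surface=False)

    def to_string(self) -> str:
        return steps_to_string(self.steps)

    @classmethod
    def from_string(cls, text: str, **kw) -> "LatticeWalk":
        return cls(steps_from_string(text), **kw)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"LatticeWalk({self.to_string()!r}, start={self.start}, "
            f"surface={self.surface})"
        )

    # -- passage structure -------------------------------------------------

    def passages(self) -> dict[tuple[int, int], list[Passage]]:
        """Per-site list of (in, out) passages, ``None`` at walk endpoints."""
        result: dict[tuple[int, int], list[Passage]] = {}
        n = len(self.steps)
        for i, site in enumerate(self._sites):
            in_dir = self.steps[i - 1] if i > 0 else None
            out_dir = self.steps[i] if i < n else None
            result.setdefault(site, []).append((in_dir, out_dir))
        return result


def count_features(walk: LatticeWalk, weights: ModelWeights) -> FeatureCounts:
    """Count collisions, crossings, straight vertices and surface contacts.

    This is the from-scratch reference counter; deterministic and
    direction-reversal invariant.  In VISAW mode a crossing in the walk is a
    structural error (crossings are illegal moves there, so no legally grown
    walk can contain one).
    """
    n_coll = n_cross = n_straight = 0
    for site, passes in walk.passages().items():
        if len(passes) == 2:
            kind = classify_doubly_visited_site(passes[0], passes[1])
            if kind == "crossing":
                n_cross += 1
            else:
                n_coll += 1
        else:
            in_dir, out_dir = passes[0]
            if in_dir is not None and out_dir is not None and in_dir == out_dir:
                n_straight += 1
    if weights.variant == "visaw" and n_cross > 0:
        raise WalkError("crossing present in a VISAW walk")
    n_surface = 0
    if weights.surface:
        if not walk.surface:
            raise WalkError("surface feature counting requires a surface walk")
        if weights.surface_convention == "steps":
            n_surface = sum(
                1
                for a, b in zip(walk.sites, walk.sites[1:])
                if a[1] == 0 and b[1] == 0
            )
        else:
            wall_sites = {s for s in walk.sites if s[1] == 0}
            wall_sites.discard(walk.start)
            n_surface = len(wall_sites)
    return FeatureCounts(
        n=len(walk),
        n_coll=n_coll,
        n_cross=n_cross,
        n_straight=n_straight,
        n_surface=n_surface,
    )


def legal_continuations(walk: LatticeWalk, weights: ModelWeights) -> set[Direction]:
    """The atmosphere: directions whose added step keeps the walk legal.

    A step is legal when it (i) reuses no bond, (ii) creates no triply
    visited site, (iii) in VISAW mode creates no crossing at the departure
    site, and (iv) in surface mode stays in the half-plane ``y >= 0``.  An
    empty set is a valid return (trapped walk).
    """
    atmosphere = set()
    base_cross = None
    for d in DIRECTIONS:
        try:
            ext = walk.extended(d)
        except WalkError:
            continue
        if weights.variant == "visaw":
            # crossing creation check at the departure site
            if base_cross is None:
                base_cross = _crossing_count(walk)
            if _crossing_count(ext) > base_cross:
                continue
        atmosphere.add(d)
    return atmosphere


def _crossing_count(walk: LatticeWalk) -> int:
    n = 0
    for passes in walk.passages().values():
        if len(passes) == 2:
            if classify_doubly_visited_site(passes[0], passes[1]) == "crossing":
                n += 1
    return n
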