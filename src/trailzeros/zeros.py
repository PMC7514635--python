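"""Partition polynomials and their complex (Fisher) zeros.

The canonical partition function of an N-step trail ensemble is a
polynomial in the temperature-like variable: ``Z_N(tau) = sum_NI c_{N,NI}
tau^NI`` in the bulk, ``P_N(omega) = sum_NS ctilde_NS omega^NS`` against a
wall.  Its complex zeros pinch the positive real axis at the transition
point as N grows; all physics downstream is read off the *leading* zero,
the one closest to the positive real axis.

Numerically the coefficients are huge (they grow exponentially with N) but
the polynomials are low-degree (degree <= N) with strictly positive
coefficients, so the zeros stay off the nonnegative real axis.  The
production solver normalizes the coefficients, rescales the variable to
balance the two ends, and runs the balanced companion-matrix eigensolver;
every root is then certified with a relative backward-error residual
evaluated in extended precision, and refined (Newton, then full Aberth at
escalating precision) if the certificate fails.  An independent Aberth
simultaneous-iteration backend in extended precision is available for
cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import mpmath as mp
import numpy as np

from .enumeration import CountTable
from .walks import ModelWeights

VARIABLES = ("tau", "omega")


class SolverError(RuntimeError):
    """Root finding failed to certify at maximum precision."""


@dataclass
class PartitionPolynomial:
    """A canonical partition polynomial in one complex variable.

    ``coeffs[k]`` is the (nonnegative, finite) coefficient of the k-th
    power of the variable; remaining model weights are fixed and recorded.
    """

    variable: str
    n: int
    coeffs: np.ndarray
    fixed: Optional[ModelWeights] = None

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 1 or self.coeffs.size == 0:
            raise ValueError("coefficient vector must be 1-D and nonempty")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coefficients must be finite")
        if np.any(self.coeffs < 0):
            raise ValueError("negative coefficient (corrupt estimate?)")
        if not np.any(self.coeffs > 0):
            raise ValueError("polynomial has no positive coefficient")

    @property
    def degree(self) -> int:
        return int(np.nonzero(self.coeffs)[0][-1])

    @property
    def log10_range(self) -> float:
        """log10 of max/min nonzero coefficient magnitude (scale metadata)."""
        nz = self.coeffs[self.coeffs > 0]
        return float(np.log10(nz.max() / nz.min()))

    def __call__(self, z: complex) -> complex:
        return complex(np.polyval(self.coeffs[::-1], z))


@dataclass
class RootSet:
    """All complex roots of a partition polynomial, with certificates.

    ``residuals[i]`` is the relative backward error ``|P(z_i)| /
    sum_k |c_k| |z_i|^k`` evaluated in extended precision.
    """

    roots: np.ndarray
    residuals: np.ndarray
    precision_dps: int
    variable: str
    n: int

    def leading_candidates(self) -> np.ndarray:
        """Roots in the upper half plane, sorted by imaginary part."""
        upper = self.roots[self.roots.imag > 0]
        return upper[np.argsort(upper.imag)]


@dataclass(frozen=True)
class LeadingZero:
    """The zero closest to the positive real axis at one walk length."""

    value: complex
    n: int
    variable: str
    rule: str = "min_im"

    def __post_init__(self) -> None:
        if not (self.value.imag > 0 and self.value.real > 0):
            raise ValueError("leading zero must have Re > 0 and Im > 0")


def build_polynomial(
    table: CountTable,
    n: int,
    variable: str,
    fixed: Optional[ModelWeights] = None,
) -> PartitionPolynomial:
    """Assemble Z_N(tau) or P_N(omega) from a coefficient table.

    The coefficient of power k sums all table entries whose variable power
    is k, each multiplied by the remaining fixed weights raised to their
    feature counts.  For ``variable="tau"`` the power is the total number
    of doubly visited sites NI = n_coll + n_cross, which requires ``tau_c
    == tau_x`` (ISAT) unless the table has no crossings (VISAW).  Tables
    from FlatPERM record folded features as zero columns, so fixed weights
    are never applied twice.
    """
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    fixed = fixed if fixed is not None else table.weights
    entries = table.slice(n)
    if not entries:
        raise ValueError(f"table has no entries at N={n}")
    if variable == "tau":
        has_cross = any(k[2] > 0 for k in entries)
        if has_cross and fixed.tau_c != fixed.tau_x:
            raise ValueError(
                "a single-variable polynomial in tau needs tau_c == tau_x "
                "(or a crossing-free table)"
            )
        max_pow = max(k[1] + k[2] for k in entries)
    else:
        max_pow = max(k[4] for k in entries)
    coeffs = np.zeros(max_pow + 1)
    for (nn, nc, nx, nstr, nsurf), v in entries.items():
        if variable == "tau":
            power = nc + nx
            w = v * fixed.p**nstr * fixed.omega**nsurf
        else:
            power = nsurf
            w = v * fixed.tau_c**nc * fixed.tau_x**nx * fixed.p**nstr
        coeffs[power] += w
    return PartitionPolynomial(variable=variable, n=n, coeffs=coeffs, fixed=fixed)


# ---------------------------------------------------------------------------
# root solving


def _working_dps(poly: PartitionPolynomial) -> int:
    return max(50, int(poly.log10_range) + 20)


def _residuals_mp(coeffs: Sequence, roots, dps: int) -> np.ndarray:
    """Relative backward error of each root, evaluated at dps digits."""
    out = np.empty(len(roots))
    with mp.workdps(dps):
        cs = [mp.mpf(float(c)) for c in coeffs]
        for i, z in enumerate(roots):
            zz = mp.mpc(complex(z))
            az = abs(zz)
            acc = mp.mpc(0)
            denom = mp.mpf(0)
            pw = mp.mpc(1)
            apw = mp.mpf(1)
            for c in cs:
                acc += c * pw
                denom += abs(c) * apw
                pw *= zz
                apw *= az
            out[i] = float(abs(acc) / denom) if denom > 0 else float("inf")
    return out


def _newton_polish(coeffs, roots, dps: int, iters: int = 6):
    with mp.workdps(dps):
        cs = [mp.mpf(float(c)) for c in coeffs]
        dcs = [k * c for k, c in enumerate(cs)][1:]
        polished = []
        for z in roots:
            zz = mp.mpc(complex(z))
            for _ in range(iters):
                p = _horner(cs, zz)
                dp = _horner(dcs, zz)
                if dp == 0:
                    break
                step = p / dp
                zz -= step
                if abs(step) < mp.mpf(10) ** (-dps + 5) * (1 + abs(zz)):
                    break
            polished.append(complex(zz))
    return np.array(polished, dtype=complex)


def _horner(cs, z):
    acc = mp.mpc(0)
    for c in reversed(cs):
        acc = acc * z + c
    return acc


def _companion_roots(coeffs: np.ndarray) -> np.ndarray:
    """Balanced companion eigensolve after coefficient/variable rescaling."""
    d = int(np.nonzero(coeffs)[0][-1])
    lo = int(np.nonzero(coeffs)[0][0])
    c = coeffs[: d + 1].astype(float)
    # factor out roots at the origin (positive-coefficient tables have lo=0,
    # but estimated tables can in principle miss the constant term)
    zero_roots = np.zeros(lo, dtype=complex)
    c = c[lo:]
    d = d - lo
    if d == 0:
        return zero_roots
    s = (c[0] / c[d]) ** (1.0 / d) if c[0] > 0 and c[d] > 0 else 1.0
    q = c * s ** np.arange(d + 1)
    q = q / np.abs(q).max()
    u = np.roots(q[::-1])
    return np.concatenate([zero_roots, u * s])


def _aberth_roots(coeffs: np.ndarray, dps: int, maxiter: int = 400) -> np.ndarray:
    """Aberth simultaneous iteration in extended precision.

    Independent of the companion backend: starts from a perturbed circle
    with radius set by the geometric mean root modulus.
    """
    d = int(np.nonzero(coeffs)[0][-1])
    lo = int(np.nonzero(coeffs)[0][0])
    zero_roots = [0j] * lo
    c = coeffs[lo : d + 1].astype(float)
    deg = d - lo
    if deg == 0:
        return np.array(zero_roots, dtype=complex)
    with mp.workdps(dps):
        cs = [mp.mpf(float(x)) for x in c]
        dcs = [k * x for k, x in enumerate(cs)][1:]
        r0 = mp.mpf(float(c[0] / c[deg])) ** (mp.mpf(1) / deg) if c[0] > 0 else mp.mpf(1)
        z = [
            r0 * mp.exp(mp.mpc(0, 2 * mp.pi * (j + 0.35) / deg + 0.4))
            for j in range(deg)
        ]
        tol = mp.mpf(10) ** (-dps + 8)
        for _ in range(maxiter):
            moved = mp.mpf(0)
            for j in range(deg):
                p = _horner(cs, z[j])
                dp = _horner(dcs, z[j])
                if dp == 0:
                    z[j] += tol
                    continue
                newton = p / dp
                ssum = mp.mpc(0)
                for k in range(deg):
                    if k != j:
                        diff = z[j] - z[k]
                        if diff != 0:
                            ssum += 1 / diff
                denom = 1 - newton * ssum
                corr = newton / denom if denom != 0 else newton
                z[j] -= corr
                moved = max(moved, abs(corr) / (1 + abs(z[j])))
            if moved < tol:
                break
        roots = [complex(x) for x in z]
    return np.array(zero_roots + roots, dtype=complex)


def _check_conjugate_symmetry(roots: np.ndarray, rtol: float = 1e-10) -> bool:
    scale = np.abs(roots).max() if roots.size else 1.0
    upper = roots[roots.imag > rtol * scale]
    lower = roots[roots.imag < -rtol * scale]
    if len(upper) != len(lower):
        return False
    for z in upper:
        if not np.any(np.abs(lower - z.conjugate()) <= 1e-8 * (1 + abs(z))):
            return False
    return True


def solve_roots(
    poly: PartitionPolynomial,
    backend: str = "companion",
    residual_tol: float = 1e-10,
    max_escalations: int = 4,
) -> RootSet:
    """All complex roots of the polynomial, with backward-error certificates.

    Every returned root satisfies ``|P(z)| / sum_k |c_k||z|^k <
    residual_tol``; the working precision is raised (Newton polish, then a
    full Aberth solve at doubled digits) until the residual and
    conjugate-symmetry checks pass, else :class:`SolverError` is raised.
    """
    if poly.degree < 1:
        raise ValueError("degree must be >= 1")
    coeffs = poly.coeffs[: poly.degree + 1]
    dps = _working_dps(poly)
    if backend == "companion":
        roots = _companion_roots(coeffs)
    elif backend == "aberth":
        roots = _aberth_roots(coeffs, dps)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    res = _residuals_mp(coeffs, roots, dps)
    if np.any(res >= residual_tol) or not _check_conjugate_symmetry(roots):
        roots = _newton_polish(coeffs, roots, dps)
        res = _residuals_mp(coeffs, roots, dps)
    esc = 0
    while (np.any(res >= residual_tol) or not _check_conjugate_symmetry(roots)) \
            and esc < max_escalations:
        esc += 1
        dps *= 2
        roots = _aberth_roots(coeffs, dps)
        res = _residuals_mp(coeffs, roots, dps)
    if np.any(res >= residual_tol):
        raise SolverError(
            f"roots of Z_{poly.n}({poly.variable}) failed the "
            f"{residual_tol:g} residual certificate at {dps} digits"
        )
    if not _check_conjugate_symmetry(roots):
        raise SolverError(
            f"root set of Z_{poly.n}({poly.variable}) is not conjugate-"
            f"symmetric at {dps} digits"
        )
    return RootSet(
        roots=roots,
        residuals=res,
        precision_dps=dps,
        variable=poly.variable,
        n=poly.n,
    )


def select_leading(
    roots: RootSet,
    rule: str = "min_im",
    window: tuple[float, float] = (0.0, 20.0),
    prev: Optional[LeadingZero] = None,
) -> Optional[LeadingZero]:
    """Select the leading zero: closest to the positive real axis.

    ``"min_im"`` returns the root of minimal imaginary part among those
    with ``Im > 0`` and ``Re`` inside the positive window; ``"continuity"``
    returns the qualifying root nearest to the previous length's leading
    zero.  Returns ``None`` when no root qualifies.
    """
    lo, hi = window
    cand = roots.roots[
        (roots.roots.imag > 0)
        & (roots.roots.real > lo)
        & (roots.roots.real < hi)
    ]
    if cand.size == 0:
        return None
    if rule == "min_im":
        z = cand[np.argmin(cand.imag)]
    elif rule == "continuity":
        if prev is None:
            z = cand[np.argmin(cand.imag)]
        else:
            z = cand[np.argmin(np.abs(cand - prev.value))]
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return LeadingZero(value=complex(z), n=roots.n, variable=roots.variable,
                       rule=rule)
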