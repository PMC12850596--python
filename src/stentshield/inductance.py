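"""Self- and mutual inductances of stent loops and the coupled-system matrix.

All loops are treated as perfect electric conductors carrying a surface
current (skin depth at MR frequencies is orders of magnitude below the strut
radius), so the closed forms below are the *external* inductances:

* circular loop of wire radius ``rho``:  ``L_c = mu0 R (ln(8R/rho) - 2)``
* rectangle ``L x w`` of round wire (external Grover/Rosa form)::

      L = (mu0/pi) [ L ln(2Lw / (rho (L + b))) + w ln(2Lw / (rho (w + b)))
                     + 2b - 2(L + w) + 2 rho ],      b = sqrt(L^2 + w^2)

* coaxial rings, Maxwell's formula in terms of the complete elliptic
  integrals ``K`` and ``E`` with modulus ``k = 2R / sqrt((2R)^2 + d^2)``::

      M = mu0 R [ (2/k - k) K(k) - (2/k) E(k) ]

Mutual inductances of rectangular loops are evaluated numerically from the
Neumann double integral.  The same Neumann kernel doubles as an independent
oracle for the closed forms: the self-inductance of a loop is obtained as
the mutual inductance between the loop and a copy displaced by the wire's
geometric mean distance (``rho`` for a surface current).

Note ``scipy.special.ellipk/ellipe`` are parametrized by ``m = k**2``; the
wrappers here accept the modulus ``k`` to avoid that silent-error trap.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.constants import mu_0 as MU0
from scipy.special import ellipe, ellipk

from .geometry import LoopSet, SpecError, StentSpec

#: condition-number threshold above which the coupled system is rejected
COND_LIMIT = 1e12


class NumericalError(RuntimeError):
    """Raised when the coupled-loop system cannot be solved reliably."""


def self_inductance_circular(radius: float, strut_radius: float) -> float:
    """External self-inductance of a circular loop of round wire."""
    if not 0 < strut_radius < radius:
        raise SpecError("self-inductance requires 0 < rho < R")
    return MU0 * radius * (np.log(8.0 * radius / strut_radius) - 2.0)


def mutual_inductance_rings(radius: float, separation) -> float | np.ndarray:
    """Mutual inductance of two coaxial rings of equal radius.

    Maxwell's closed form with modulus ``k = 2R / sqrt((2R)^2 + d^2)``.
    ``separation`` may be an array; the sign of the separation is ignored.
    """
    d = np.abs(np.asarray(separation, dtype=float))
    if np.any(d == 0):
        raise SpecError("coincident rings: mutual-inductance integral diverges")
    k2 = 4.0 * radius**2 / (4.0 * radius**2 + d**2)
    k = np.sqrt(k2)
    out = MU0 * radius * ((2.0 / k - k) * ellipk(k2) - (2.0 / k) * ellipe(k2))
    return float(out) if np.isscalar(separation) else out


def self_inductance_rectangle(
    length: float, width: float, strut_radius: float
) -> float:
    """External self-inductance of a rectangular loop of round wire."""
    if width <= 0:
        raise SpecError("degenerate rectangle: width must be positive")
    if length <= 0:
        raise SpecError("degenerate rectangle: length must be positive")
    if strut_radius <= 0 or strut_radius >= min(length, width) / 2.0:
        raise SpecError("wire radius must satisfy 0 < rho << min(L, w)")
    b = np.hypot(length, width)
    val = (
        length * np.log(2.0 * length * width / (strut_radius * (length + b)))
        + width * np.log(2.0 * length * width / (strut_radius * (width + b)))
        + 2.0 * b
        - 2.0 * (length + width)
        + 2.0 * strut_radius
    )
    return MU0 / np.pi * val


def mutual_inductance_neumann(
    loop_a: np.ndarray, loop_b: np.ndarray
) -> float:
    """Neumann double integral between two discretized closed loops.

    ``M = mu0/(4 pi) sum_ij (dl_i . dl_j) / |r_i - r_j|`` over the segment
    midpoints.  Symmetric in its arguments.  Loops sharing wire (distance
    collapsing to zero) are rejected -- this is the reason the middle bar is
    omitted from odd-N cages.
    """
    d1 = np.diff(loop_a, axis=0)
    d2 = np.diff(loop_b, axis=0)
    m1 = 0.5 * (loop_a[:-1] + loop_a[1:])
    m2 = 0.5 * (loop_b[:-1] + loop_b[1:])
    dist = np.linalg.norm(m1[:, None, :] - m2[None, :, :], axis=2)
    scale = max(np.abs(d1).max(), np.abs(d2).max())
    if dist.min() < 1e-9 * max(scale, 1e-12):
        raise SpecError(
            "loops share wire segments: Neumann integral diverges"
        )
    return MU0 / (4.0 * np.pi) * float(np.sum((d1 @ d2.T) / dist))


def neumann_self_inductance(
    loop: np.ndarray, strut_radius: float, surface_current: bool = True
) -> float:
    """Self-inductance via the Neumann integral with a GMD displacement.

    The loop's self-inductance equals the mutual inductance between the
    filament loop and a copy displaced by the wire's geometric mean distance
    (``rho`` for a surface current on a PEC, ``rho * exp(-1/4)`` for a
    uniform volume current).  Used as an independent oracle for the closed
    forms; production code uses the closed forms.
    """
    gmd = strut_radius if surface_current else strut_radius * np.exp(-0.25)
    area = _polyline_area_normal(loop)
    shifted = loop + gmd * area
    return mutual_inductance_neumann(loop, shifted)


def _polyline_area_normal(poly: np.ndarray) -> np.ndarray:
    d = np.diff(poly, axis=0)
    mid = 0.5 * (poly[:-1] + poly[1:])
    a = 0.5 * np.cross(mid, d).sum(axis=0)
    return a / np.linalg.norm(a)


@dataclasses.dataclass
class InductanceSystem:
    """Symmetric coupled-inductance matrix of one loop family.

    ``matrix`` is ``diag(self-inductances) + M`` in henry.  ``flux`` and
    ``currents`` are attached by the field solver (per unit incident B1).
    """

    matrix: np.ndarray
    kind: str
    flux: np.ndarray | None = None
    currents: np.ndarray | None = None

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def export_csv(self, path) -> None:
        np.savetxt(path, self.matrix, delimiter=",")


def assemble_system(loops: LoopSet, spec: StentSpec) -> InductanceSystem:
    """Assemble the symmetric inductance matrix of one loop family.

    Circular family: diagonal from the ring closed form, off-diagonal from
    Maxwell's coaxial-ring formula.  Rectangular family: diagonal from the
    rectangle closed form, off-diagonal from the Neumann integral over the
    chord-plane rectangles.  No cross-family terms exist; the two families
    are solved independently.
    """
    n = len(loops)
    if n < 1:
        raise SpecError("cannot assemble a system without loops")
    mat = np.zeros((n, n))
    if loops.kind == "circular":
        x = loops.ring_positions
        for i in range(n):
            mat[i, i] = self_inductance_circular(spec.radius, spec.strut_radius)
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = mutual_inductance_rings(
                    spec.radius, abs(x[i] - x[j])
                )
    elif loops.kind == "rectangular":
        for i in range(n):
            mat[i, i] = self_inductance_rectangle(
                spec.length, loops.widths[i], spec.strut_radius
            )
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = mutual_inductance_neumann(
                    loops.loops[i], loops.loops[j]
                )
    else:
        raise SpecError(f"unknown loop kind {loops.kind!r}")
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise NumericalError(
            f"inductance matrix ill-conditioned (cond = {cond:.3e})"
        )
    return InductanceSystem(matrix=mat, kind=loops.kind)
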