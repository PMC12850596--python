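"""Fluxes, coupled-current solution and Biot-Savart mapping of the induced field.

For a perfectly conducting loop the flux is frozen: ``Phi = L I`` with the
incident flux on the left, so the induced currents of a coupled family solve

    I = - Lmat \\ Phi

per unit incident B1 (quasi-static: the RF carrier is factored out and the
currents are real amplitudes).  Each loop's current then sources a magnetic
field by Biot-Savart; straight wire pieces use the exact analytic
finite-segment field, rings the polygonal quadrature of their discretized
polyline.  Only the field component along the driving B1 component is
accumulated, and the stored scalar is the *shielding fraction*

    beta(r) = - B_ind(r) . e_B1 / B1

so positive values mean the induced field opposes (shields) the transmit
field, per Lenz's law.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.constants import mu_0 as MU0

from .geometry import LoopSet, SpecError, StentSpec
from .inductance import InductanceSystem, NumericalError

#: maximum acceptable relative residual of the linear solve
RESIDUAL_LIMIT = 1e-10

#: unit vectors of the component each loop family shields (model frame)
FAMILY_COMPONENT = {
    "circular": np.array([1.0, 0.0, 0.0]),  # B1x, along the stent axis
    "rectangular": np.array([0.0, 1.0, 0.0]),  # B1y, radial
}


@dataclasses.dataclass(frozen=True)
class TransmitField:
    """Incident transmit field, normalized to unit amplitude per component.

    ``polarization`` is ``"linear"`` (a single component) or ``"circular"``
    (two equal-amplitude orthogonal components in phase quadrature).  The
    carrier frequency never enters the quasi-static calculation.
    """

    polarization: str = "circular"
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.polarization not in ("linear", "circular"):
            raise SpecError("polarization must be 'linear' or 'circular'")
        if self.amplitude <= 0:
            raise SpecError("amplitude must be positive")


@dataclasses.dataclass
class FieldMap:
    """Shielding fraction ``beta(x, t)`` on the central slice.

    ``values[i, j]`` is the shielding at in-slice coordinates
    ``(x[j], t[i])`` where ``x`` runs along the stent axis and ``t`` is the
    transverse in-slice coordinate.  ``mask`` flags points inside the
    wire-exclusion radius where the thin-wire field diverges; masking is
    cosmetic and never applied on the axis where beta is extracted.
    """

    values: np.ndarray
    x: np.ndarray
    t: np.ndarray
    resolution: float
    mask: np.ndarray
    kind: str

    @property
    def masked_fraction(self) -> float:
        return float(self.mask.mean())


def flux_circular(spec: StentSpec, b1: float = 1.0) -> np.ndarray:
    """Flux of the axial B1 component through every ring: ``pi R^2 B1``."""
    return np.full(spec.n_rings, np.pi * spec.radius**2 * b1)


def flux_rectangular(loops: LoopSet, b1: float = 1.0) -> np.ndarray:
    """Flux through the projected rectangles: ``Phi_i = B1 w_i L``."""
    if loops.kind != "rectangular" or loops.widths is None:
        raise SpecError("flux_rectangular requires a rectangular loop set")
    length = loops.loops[0][:, 0].max() - loops.loops[0][:, 0].min()
    return b1 * loops.widths * length


def solve_currents(
    system: InductanceSystem, flux: np.ndarray, loops: LoopSet | None = None
) -> np.ndarray:
    """Solve ``I = -Lmat \\ Phi`` and verify the residual.

    The currents are stored back on the system (and on ``loops`` when
    given).  Units: ampere per tesla of incident B1.
    """
    flux = np.asarray(flux, dtype=float)
    if flux.shape != (system.matrix.shape[0],):
        raise SpecError("flux vector does not match the system size")
    currents = -np.linalg.solve(system.matrix, flux)
    norm = np.linalg.norm(flux)
    if norm > 0:
        residual = np.linalg.norm(system.matrix @ currents + flux) / norm
        if residual > RESIDUAL_LIMIT:
            raise NumericalError(
                f"linear-solve residual {residual:.3e} exceeds "
                f"{RESIDUAL_LIMIT:.0e} (cond = {system.condition_number:.3e})"
            )
    system.flux = flux
    system.currents = currents
    if loops is not None:
        loops.currents = currents
    return currents


def segment_field(
    starts: np.ndarray,
    ends: np.ndarray,
    points: np.ndarray,
    current: float,
) -> np.ndarray:
    """Exact magnetic field of finite straight segments at given points.

    Implements the closed-form integral of the Biot-Savart kernel along each
    segment (valid off the segment's carrier line).  ``starts``/``ends`` have
    shape ``(ns, 3)``, ``points`` ``(np, 3)``; returns ``(np, 3)``.
    """
    starts = np.atleast_2d(starts)
    ends = np.atleast_2d(ends)
    points = np.atleast_2d(points)
    u = ends - starts  # (ns, 3)
    # ra/rb point from the observation point to the segment ends; the
    # Biot-Savart kernel uses dl x s_hat with s_hat from source to point,
    # hence the cross product with -ra below.
    ra = starts[None, :, :] - points[:, None, :]  # (np, ns, 3)
    rb = ends[None, :, :] - points[:, None, :]
    na = np.linalg.norm(ra, axis=2)
    nb = np.linalg.norm(rb, axis=2)
    cr = np.cross(np.broadcast_to(u[None, :, :], ra.shape), -ra)
    c2 = np.einsum("psk,psk->ps", cr, cr)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.einsum("sk,psk->ps", u, rb) / nb - np.einsum(
            "sk,psk->ps", u, ra
        ) / na
        contrib = cr * (t / c2)[:, :, None]
    contrib[~np.isfinite(contrib)] = 0.0  # points on a segment's line
    return MU0 * current / (4.0 * np.pi) * contrib.sum(axis=1)


def loop_field(
    loop: np.ndarray, current: float, points: np.ndarray
) -> np.ndarray:
    """Field of one closed polyline loop at the given points."""
    return segment_field(loop[:-1], loop[1:], points, current)


def shielding_at_points(loops: LoopSet, points: np.ndarray) -> np.ndarray:
    """Shielding fraction ``-B_ind . e / B1`` at arbitrary points.

    ``e`` is the component the family shields (axial for rings, radial for
    rectangles); currents must have been solved for unit incident B1.
    """
    if loops.currents is None:
        raise SpecError("loop currents not solved yet")
    comp = FAMILY_COMPONENT[loops.kind]
    points = np.atleast_2d(np.asarray(points, dtype=float))
    total = np.zeros(len(points))
    for poly, cur in zip(loops.loops, loops.currents):
        total += loop_field(poly, cur, points) @ comp
    return -total


def _min_distance_to_wires(loops: LoopSet, points: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest wire segment midpoint chain."""
    best = np.full(len(points), np.inf)
    for poly in loops.loops:
        mids = 0.5 * (poly[:-1] + poly[1:])
        # chunk to bound memory on fine grids
        for lo in range(0, len(points), 4096):
            sl = slice(lo, lo + 4096)
            d = np.linalg.norm(
                points[sl, None, :] - mids[None, :, :], axis=2
            ).min(axis=1)
            best[sl] = np.minimum(best[sl], d)
    return best


def biot_savart_map(
    loops: LoopSet,
    spec: StentSpec,
    extent: float = 45e-3,
    resolution: float = 0.5e-3,
) -> FieldMap:
    """Map the shielding fraction on the central slice through the axis.

    The slice contains the stent axis and is orthogonal to the shielded B1
    component: the ``x``-``y`` plane for the circular family and the
    ``x``-``z`` plane for the rectangular family (whose chord rectangles lie
    at ``z = +/- w_i / 2`` in-slice).  Points closer than ``2 rho`` to a wire
    are masked.
    """
    n = int(round(2 * extent / resolution)) + 1
    xs = np.linspace(-extent, extent, n)
    ts = np.linspace(-extent, extent, n)
    gx, gt = np.meshgrid(xs, ts)
    if loops.kind == "circular":
        points = np.column_stack(
            [gx.ravel(), gt.ravel(), np.zeros(gx.size)]
        )
    else:
        points = np.column_stack(
            [gx.ravel(), np.zeros(gx.size), gt.ravel()]
        )
    values = shielding_at_points(loops, points).reshape(n, n)
    mask = (
        _min_distance_to_wires(loops, points) < 2.0 * spec.strut_radius
    ).reshape(n, n)
    return FieldMap(
        values=values,
        x=xs,
        t=ts,
        resolution=resolution,
        mask=mask,
        kind=loops.kind,
    )


def beta_axis_samples(spec: StentSpec, n_samples: int = 51) -> np.ndarray:
    """On-axis sample points for the circular-family shielding average.

    The induced field of a ring stack is inhomogeneous along the axis, so
    the shielding is averaged along the axis from the central loop plane to
    the midpoint (``l2 / 2``) of its nearest neighbour.  By the stack's
    mirror symmetry this window is ``x in [0, l2/2]`` regardless of the
    parity of the ring count.
    """
    if spec.cell_length is None:
        raise SpecError("axis averaging requires a cell length l2")
    xs = np.linspace(0.0, spec.cell_length / 2.0, n_samples)
    return np.column_stack([xs, np.zeros(n_samples), np.zeros(n_samples)])


def beta_from_loops(
    loops: LoopSet, spec: StentSpec, n_samples: int = 51
) -> float:
    """Centre shielding of one solved family.

    Rectangular loops: the value at the stent centre.  Circular loops: the
    mean of the on-axis values over ``x in [0, l2/2]`` (see
    :func:`beta_axis_samples`).
    """
    if loops.kind == "rectangular":
        return float(shielding_at_points(loops, np.zeros((1, 3)))[0])
    points = beta_axis_samples(spec, n_samples)
    return float(shielding_at_points(loops, points).mean())


def beta_from_map(fmap: FieldMap, spec: StentSpec) -> float:
    """Extract the centre shielding from a computed map.

    Mirrors :func:`beta_from_loops` but interpolates on the map grid:
    the centre-point value for rectangular loops, the on-axis average over
    ``[0, l2/2]`` for circular loops.  Requested sample points falling in
    the masked region are an error.
    """
    mid = np.argmin(np.abs(fmap.t))
    if fmap.kind == "rectangular":
        jc = np.argmin(np.abs(fmap.x))
        if fmap.mask[mid, jc]:
            raise SpecError("centre point is masked; cannot extract beta")
        return float(fmap.values[mid, jc])
    if spec.cell_length is None:
        raise SpecError("circular-family extraction requires l2")
    sel = (fmap.x >= 0.0) & (fmap.x <= spec.cell_length / 2.0)
    if not sel.any():
        raise SpecError("map extent does not cover the averaging window")
    if fmap.mask[mid, sel].any():
        raise SpecError("averaging window intersects the masked region")
    return float(fmap.values[mid, sel].mean())
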