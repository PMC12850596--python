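"""Geometric decomposition of laser-cut stents into conducting loop families.

A laser-cut stent with cell width ``l1`` (orthogonal to the long axis) and
cell length ``l2`` (parallel to it) is idealized as two orthogonal families of
closed conducting loops on a cylinder of radius ``R``:

* **circular loops** -- ``m`` coaxial rings spaced by ``l2`` along the long
  axis, with surface normals parallel to the axis;
* **rectangular loops** -- pairs of the ``N`` longitudinal bars closed across
  the end rings, with surface normals pointing radially.

The model frame places the stent long axis along ``+x``.  The transmit-field
component shielded by the circular family is then ``B1x`` (along the axis)
and the component shielded by the rectangular family is ``B1y``.  Orientation
of the stent relative to the scanner frame (the angle ``delta`` to B0) is
handled downstream by combination weights, never by rotating the geometry.

Rectangular loop ``i`` pairs the two bars at azimuths ``+/- gamma_i`` from the
``y`` axis, ``gamma_i = (i - 1/2) * 2*pi/N``, and is represented by the planar
chord rectangle through those bars: length ``L`` along ``x``, projected width
``w_i = 2 R sin(gamma_i)`` along ``z``, lying in the plane
``y = R cos(gamma_i)``.  Its projection along the field direction has area
``w_i * L``, which is the area that enters the flux.  For an odd number of
bars the middle bar (index ``ceil(N/2)``) has no partner and is omitted; a
loop built from it would share a bar with an existing loop and the Neumann
mutual-inductance integral would diverge on the shared wire.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from typing import Sequence

import numpy as np

#: default number of discretization segments per wire piece
DEFAULT_SEGMENTS = 100

_LOOP_TYPES = ("circular", "rectangular")


class SpecError(ValueError):
    """Raised for stent specifications that violate the model's domain."""


@dataclasses.dataclass(frozen=True)
class StentSpec:
    """Geometric and electrical description of one stent model.

    Parameters
    ----------
    radius:
        Loop radius ``R`` in metres (typical venous stent: 8 mm).
    strut_radius:
        Strut/wire radius ``rho`` in metres.
    length:
        Stent length ``L`` in metres.
    cell_length:
        Cell length ``l2`` (ring spacing) in metres; required when circular
        loops are requested.
    n_bars:
        Number of longitudinal bars ``N`` (>= 3); required when rectangular
        loops are requested.
    angle_to_b0_deg:
        Orientation angle ``delta`` of the stent long axis to B0 in the
        coronal plane, degrees.  0 means parallel to B0.
    loop_types:
        Which loop families the model builds, subset of
        ``("circular", "rectangular")``.
    """

    radius: float
    strut_radius: float
    length: float
    cell_length: float | None = None
    n_bars: int | None = None
    angle_to_b0_deg: float = 0.0
    loop_types: tuple[str, ...] = _LOOP_TYPES

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise SpecError("loop radius R must be positive")
        if self.strut_radius <= 0:
            raise SpecError("strut radius rho must be positive")
        if self.strut_radius >= self.radius:
            raise SpecError("strut radius rho must be smaller than loop radius R")
        if self.length <= 0:
            raise SpecError("stent length must be positive")
        if not self.loop_types or any(t not in _LOOP_TYPES for t in self.loop_types):
            raise SpecError(f"loop_types must be a non-empty subset of {_LOOP_TYPES}")
        if not 0.0 <= self.angle_to_b0_deg <= 90.0:
            raise SpecError("orientation angle delta must lie in [0, 90] degrees")
        if "circular" in self.loop_types:
            if self.cell_length is None or self.cell_length <= 0:
                raise SpecError("circular loops require a positive cell length l2")
            if self.n_rings < 2:
                raise SpecError(
                    "cell length l2 too large: fewer than two rings fit the stent"
                )
        if "rectangular" in self.loop_types:
            if self.n_bars is None or self.n_bars < 3:
                raise SpecError("rectangular loops require at least N = 3 bars")

    @property
    def n_rings(self) -> int:
        """Number of circular loops ``m = floor(L / l2) + 1``.

        When ``l2`` divides ``L`` exactly this reproduces the convention
        ``L = (m - 1) l2``; otherwise the ring stack spans ``(m - 1) l2``
        centred on the stent.
        """
        if self.cell_length is None:
            raise SpecError("spec has no cell length l2")
        return int(math.floor(self.length / self.cell_length + 1e-9)) + 1

    @property
    def l1_chord(self) -> float:
        """Cell width as the chord between adjacent bars, ``2 R sin(pi/N)``."""
        if self.n_bars is None:
            raise SpecError("spec has no bar count N")
        return 2.0 * self.radius * math.sin(math.pi / self.n_bars)

    @property
    def l1_arc(self) -> float:
        """Cell width as the circumferential arc between bars, ``2 pi R / N``."""
        if self.n_bars is None:
            raise SpecError("spec has no bar count N")
        return 2.0 * math.pi * self.radius / self.n_bars

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-ready dict with explicit SI unit suffixes in the keys."""
        d = {
            "radius_m": self.radius,
            "strut_radius_m": self.strut_radius,
            "length_m": self.length,
            "angle_to_b0_deg": self.angle_to_b0_deg,
            "loop_types": list(self.loop_types),
        }
        if self.cell_length is not None:
            d["cell_length_m"] = self.cell_length
        if self.n_bars is not None:
            d["n_bars"] = self.n_bars
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StentSpec":
        known = {
            "radius_m",
            "strut_radius_m",
            "length_m",
            "cell_length_m",
            "n_bars",
            "angle_to_b0_deg",
            "loop_types",
        }
        unknown = set(d) - known
        if unknown:
            raise SpecError(f"unknown stent-spec keys: {sorted(unknown)}")
        return cls(
            radius=float(d["radius_m"]),
            strut_radius=float(d["strut_radius_m"]),
            length=float(d["length_m"]),
            cell_length=(
                float(d["cell_length_m"]) if "cell_length_m" in d else None
            ),
            n_bars=int(d["n_bars"]) if "n_bars" in d else None,
            angle_to_b0_deg=float(d.get("angle_to_b0_deg", 0.0)),
            loop_types=tuple(d.get("loop_types", _LOOP_TYPES)),
        )

    def content_hash(self) -> str:
        """Short stable hash of the spec, used as provenance in outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclasses.dataclass
class LoopSet:
    """A family of closed, discretized wire loops with solver metadata.

    ``loops`` holds closed polylines (arrays of shape ``(n + 1, 3)`` with the
    first point repeated at the end).  ``currents`` is filled in by the
    solver, in ampere per tesla of incident B1.
    """

    loops: list[np.ndarray]
    kind: str  # "circular" | "rectangular"
    axis: np.ndarray
    segments: int
    #: projected widths w_i (rectangular loops only)
    widths: np.ndarray | None = None
    #: chord-plane offsets y_i = R cos(gamma_i) (rectangular loops only)
    plane_offsets: np.ndarray | None = None
    #: axial ring positions (circular loops only)
    ring_positions: np.ndarray | None = None
    #: azimuths of the longitudinal bars (rectangular loops only), radians
    bar_azimuths: np.ndarray | None = None
    #: 1-based index of the omitted middle bar for odd N, else None
    omitted_bar: int | None = None
    currents: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.loops)


def loop_area_vector(poly: np.ndarray) -> np.ndarray:
    """Vector area of a closed polyline, ``0.5 * sum(r x dl)``."""
    d = np.diff(poly, axis=0)
    mid = 0.5 * (poly[:-1] + poly[1:])
    return 0.5 * np.cross(mid, d).sum(axis=0)


def _ring_polyline(radius: float, x0: float, segments: int) -> np.ndarray:
    phi = np.linspace(0.0, 2.0 * np.pi, segments + 1)
    pts = np.column_stack(
        [np.full(segments + 1, x0), radius * np.cos(phi), radius * np.sin(phi)]
    )
    pts[-1] = pts[0]
    return pts


def _rect_polyline(
    length: float, width: float, y0: float, segments: int
) -> np.ndarray:
    # corner order chosen so the area vector points along +y
    corners = np.array(
        [
            [-length / 2.0, y0, -width / 2.0],
            [-length / 2.0, y0, +width / 2.0],
            [+length / 2.0, y0, +width / 2.0],
            [+length / 2.0, y0, -width / 2.0],
        ]
    )
    pieces = []
    for a, b in zip(corners, np.roll(corners, -1, axis=0)):
        t = np.linspace(0.0, 1.0, segments + 1)[:-1, None]
        pieces.append(a + t * (b - a))
    pieces.append(corners[:1])
    return np.vstack(pieces)


def build_circular_stack(
    spec: StentSpec, segments: int = DEFAULT_SEGMENTS
) -> LoopSet:
    """Build the stack of ``m`` coaxial rings with spacing ``l2``.

    The rings are centred on the stent mid-plane: for ``L = 100 mm`` and
    ``l2 = 10 mm`` this yields 11 rings at axial positions -50, -40, ...,
    +50 mm.  Ring normals point along the axis (+x); the flux of the axial
    B1 component through every ring is ``pi R^2 B1``.
    """
    if spec.cell_length is None or spec.cell_length <= 0:
        raise SpecError("circular stack requires a positive cell length l2")
    m = spec.n_rings
    if m < 2:
        raise SpecError("circular stack requires at least two rings (l2 < L)")
    half_span = (m - 1) * spec.cell_length / 2.0
    positions = np.linspace(-half_span, half_span, m)
    loops = [_ring_polyline(spec.radius, x0, segments) for x0 in positions]
    return LoopSet(
        loops=loops,
        kind="circular",
        axis=np.array([1.0, 0.0, 0.0]),
        segments=segments,
        ring_positions=positions,
    )


def build_rectangular_cage(
    spec: StentSpec, segments: int = DEFAULT_SEGMENTS
) -> LoopSet:
    """Build the planar rectangular loops formed by paired longitudinal bars.

    Loop ``i`` (``i = 1 .. floor(N/2)``) pairs the bars at azimuths
    ``+/- gamma_i``, ``gamma_i = (i - 1/2) 2 pi / N``, giving projected width
    ``w_i = 2 R sin(gamma_i)`` and chord-plane offset ``R cos(gamma_i)``.
    For odd ``N`` the unpaired middle bar ``ceil(N/2)`` is omitted.
    """
    if spec.n_bars is None or spec.n_bars < 3:
        raise SpecError("rectangular cage requires at least N = 3 bars")
    n = spec.n_bars
    n_loops = n // 2
    idx = np.arange(1, n_loops + 1)
    gamma = (idx - 0.5) * 2.0 * np.pi / n
    widths = 2.0 * spec.radius * np.sin(gamma)
    offsets = spec.radius * np.cos(gamma)
    loops = [
        _rect_polyline(spec.length, w, y0, segments)
        for w, y0 in zip(widths, offsets)
    ]
    # all N bar azimuths, measured from +y; pairs are (+gamma_i, -gamma_i)
    azimuths = np.concatenate([gamma, -gamma])
    omitted = (n + 1) // 2 if n % 2 == 1 else None
    if omitted is not None:
        azimuths = np.sort(azimuths)
    return LoopSet(
        loops=loops,
        kind="rectangular",
        axis=np.array([1.0, 0.0, 0.0]),
        segments=segments,
        widths=widths,
        plane_offsets=offsets,
        bar_azimuths=azimuths,
        omitted_bar=omitted,
    )


def build_grid_stent(
    spec: StentSpec, segments: int = DEFAULT_SEGMENTS
) -> tuple[LoopSet, LoopSet]:
    """Build both loop families of a grid stent.

    The families are returned as two independent loop sets; the induced
    fields of the two families superpose linearly and no cross-family
    coupling terms exist in the model (each family shields an orthogonal
    B1 component).
    """
    circular = (
        build_circular_stack(spec, segments)
        if "circular" in spec.loop_types
        else LoopSet([], "circular", np.array([1.0, 0.0, 0.0]), segments)
    )
    rectangular = (
        build_rectangular_cage(spec, segments)
        if "rectangular" in spec.loop_types
        else LoopSet([], "rectangular", np.array([1.0, 0.0, 0.0]), segments)
    )
    return circular, rectangular


def catalogue_to_specs(catalogue: dict) -> dict[str, StentSpec]:
    """Parse a {name: spec-dict} catalogue mapping into StentSpec objects."""
    return {name: StentSpec.from_dict(d) for name, d in catalogue.items()}


def load_spec(path) -> StentSpec:
    """Read a single stent spec from a JSON file."""
    with open(path) as fh:
        return StentSpec.from_dict(json.load(fh))


def save_spec(spec: StentSpec, path) -> None:
    """Write a stent spec to a JSON file with SI-unit key suffixes."""
    with open(path, "w") as fh:
        json.dump(spec.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
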