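"""Whole-stent shielding: per-family solutions and orientation combination.

A circularly polarized transmit field has two equal-amplitude orthogonal
components.  With the stent orthogonal to B0 (``delta = 90``), one component
is shielded by the rectangular loops and the other by the circular loops,
so the combined shielding is the average

    beta = (beta_rect + beta_circ) / 2 .

With the stent parallel to B0 (``delta = 0``) both components see the
rectangular loops and the circular loops carry no flux: ``beta = beta_rect``.
At an oblique angle ``delta`` in the coronal plane the axial flux scales with
``sin^2(delta)`` and the combination interpolates between the two cases:

    beta = 1/2 [ beta_rect + cos^2(delta) beta_rect + sin^2(delta) beta_circ ]
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import __version__ as _pkg_version
from .fields import (
    FieldMap,
    beta_from_loops,
    biot_savart_map,
    flux_circular,
    flux_rectangular,
    solve_currents,
)
from .geometry import (
    DEFAULT_SEGMENTS,
    SpecError,
    StentSpec,
    build_circular_stack,
    build_rectangular_cage,
)
from .inductance import assemble_system


@dataclasses.dataclass
class ShieldingResult:
    """Shielding of one stent model at a given orientation.

    ``beta`` is a fraction; format with ``beta_percent`` for reporting.
    ``combination`` records which orientation rule produced it.
    """

    beta: float
    angle_to_b0_deg: float
    combination: str  # "parallel" | "orthogonal" | "oblique"
    beta_rect: float | None = None
    beta_circ: float | None = None
    map: FieldMap | None = None
    map_rect: FieldMap | None = None
    map_circ: FieldMap | None = None
    provenance: dict | None = None

    @property
    def beta_percent(self) -> float:
        return 100.0 * self.beta

    def to_dict(self) -> dict:
        d = {
            "beta": self.beta,
            "beta_percent": self.beta_percent,
            "angle_to_b0_deg": self.angle_to_b0_deg,
            "combination": self.combination,
            "beta_rect": self.beta_rect,
            "beta_circ": self.beta_circ,
        }
        if self.provenance:
            d["provenance"] = self.provenance
        return d


def _combination_name(delta_deg: float) -> str:
    if delta_deg == 0.0:
        return "parallel"
    if delta_deg == 90.0:
        return "orthogonal"
    return "oblique"


def combine_orthogonal(
    beta_rect: float,
    beta_circ: float,
    map_rect: FieldMap | None = None,
    map_circ: FieldMap | None = None,
) -> ShieldingResult:
    """Combine the families for a stent orthogonal to B0.

    Each family shields one of the two circular-polarization components, so
    scalars and maps combine with weight 1/2 each.
    """
    beta = 0.5 * (beta_rect + beta_circ)
    combined = None
    if map_rect is not None and map_circ is not None:
        combined = FieldMap(
            values=0.5 * (map_rect.values + map_circ.values),
            x=map_rect.x,
            t=map_rect.t,
            resolution=map_rect.resolution,
            mask=map_rect.mask | map_circ.mask,
            kind="combined",
        )
    return ShieldingResult(
        beta=beta,
        angle_to_b0_deg=90.0,
        combination="orthogonal",
        beta_rect=beta_rect,
        beta_circ=beta_circ,
        map=combined,
        map_rect=map_rect,
        map_circ=map_circ,
    )


def combine_oblique(
    beta_rect: float, beta_circ: float, delta_deg: float
) -> ShieldingResult:
    """Combine the families for a stent at angle ``delta`` to B0.

    Reduces exactly to the parallel rule at ``delta = 0`` and to the
    orthogonal rule at ``delta = 90``.
    """
    if not 0.0 <= delta_deg <= 90.0:
        raise SpecError("delta must lie in [0, 90] degrees")
    delta = np.deg2rad(delta_deg)
    beta = 0.5 * (
        beta_rect
        + np.cos(delta) ** 2 * beta_rect
        + np.sin(delta) ** 2 * beta_circ
    )
    return ShieldingResult(
        beta=float(beta),
        angle_to_b0_deg=delta_deg,
        combination=_combination_name(delta_deg),
        beta_rect=beta_rect,
        beta_circ=beta_circ,
    )


def beta_from_cp_magnitude(ratio, clamp: bool = True):
    """Single-component shielding from a circularly polarized magnitude ratio.

    If only the ``y`` component is shielded, the magnitude ratio is
    ``B1ROI/B1 = sqrt(1 + (1 - beta)^2) / sqrt(2)``, inverted as

        beta = 1 - sqrt(2 (B1ROI/B1)^2 - 1)

    Valid ratios lie in ``[1/sqrt(2), 1]``.  Noise can push measured ratios
    outside; such values are clamped to the boundary with a warning (beta
    capped at 1), matching the behaviour of noisy measurements where
    intensity ratios near 0.5 drive the apparent shielding to 1.
    """
    r = np.asarray(ratio, dtype=float)
    lo = 1.0 / np.sqrt(2.0)
    invalid = (r < lo - 1e-12) | (r > 1.0 + 1e-12)
    if invalid.any():
        if not clamp:
            raise SpecError("magnitude ratio outside [1/sqrt(2), 1]")
        warnings.warn(
            f"{int(invalid.sum())} magnitude ratio(s) outside "
            "[1/sqrt(2), 1]; clamped (noise-dominated pixels)",
            stacklevel=2,
        )
    r = np.clip(r, lo, 1.0)
    beta = 1.0 - np.sqrt(np.maximum(2.0 * r**2 - 1.0, 0.0))
    return float(beta) if np.isscalar(ratio) else beta


def cp_magnitude_from_beta(beta):
    """Forward relation of :func:`beta_from_cp_magnitude` (for round trips)."""
    b = np.asarray(beta, dtype=float)
    out = np.sqrt(1.0 + (1.0 - b) ** 2) / np.sqrt(2.0)
    return float(out) if np.isscalar(beta) else out


def beta_rectangular_family(
    spec: StentSpec, segments: int = DEFAULT_SEGMENTS
) -> float:
    """Shielding of the rectangular-loop family alone (centre value)."""
    loops = build_rectangular_cage(spec, segments)
    system = assemble_system(loops, spec)
    solve_currents(system, flux_rectangular(loops), loops)
    return beta_from_loops(loops, spec)


def beta_circular_family(
    spec: StentSpec,
    segments: int = DEFAULT_SEGMENTS,
    n_samples: int = 51,
) -> float:
    """Shielding of the circular-loop family alone (on-axis average)."""
    loops = build_circular_stack(spec, segments)
    system = assemble_system(loops, spec)
    solve_currents(system, flux_circular(spec), loops)
    return beta_from_loops(loops, spec, n_samples)


def compute_stent_beta(
    spec: StentSpec,
    segments: int = DEFAULT_SEGMENTS,
    n_samples: int = 51,
    make_maps: bool = False,
    map_extent: float = 45e-3,
    map_resolution: float = 0.5e-3,
) -> ShieldingResult:
    """Full pipeline: loops -> inductances -> currents -> fields -> beta.

    Builds the families requested by ``spec.loop_types``, solves each
    coupled system for unit incident B1, extracts the per-family centre
    shielding and applies the orientation combination selected by
    ``spec.angle_to_b0_deg``.  A family that is absent (or, for the circular
    family at ``delta = 0``, carries no flux) contributes zero.
    """
    delta = spec.angle_to_b0_deg
    beta_rect = None
    beta_circ = None
    map_rect = None
    map_circ = None

    if "rectangular" in spec.loop_types:
        loops = build_rectangular_cage(spec, segments)
        system = assemble_system(loops, spec)
        solve_currents(system, flux_rectangular(loops), loops)
        beta_rect = beta_from_loops(loops, spec)
        if make_maps:
            map_rect = biot_savart_map(loops, spec, map_extent, map_resolution)

    needs_circular = "circular" in spec.loop_types and delta > 0.0
    if needs_circular:
        loops = build_circular_stack(spec, segments)
        system = assemble_system(loops, spec)
        solve_currents(system, flux_circular(spec), loops)
        beta_circ = beta_from_loops(loops, spec, n_samples)
        if make_maps:
            map_circ = biot_savart_map(loops, spec, map_extent, map_resolution)

    br = beta_rect if beta_rect is not None else 0.0
    bc = beta_circ if beta_circ is not None else 0.0
    result = combine_oblique(br, bc, delta)
    result.beta_rect = beta_rect
    result.beta_circ = beta_circ
    result.map_rect = map_rect
    result.map_circ = map_circ
    if make_maps and map_rect is not None and map_circ is not None:
        delta_rad = np.deg2rad(delta)
        result.map = FieldMap(
            values=0.5
            * (
                (1.0 + np.cos(delta_rad) ** 2) * map_rect.values
                + np.sin(delta_rad) ** 2 * map_circ.values
            ),
            x=map_rect.x,
            t=map_rect.t,
            resolution=map_rect.resolution,
            mask=map_rect.mask | map_circ.mask,
            kind="combined",
        )
    result.provenance = {
        "spec": spec.to_dict(),
        "spec_hash": spec.content_hash(),
        "segments_per_piece": segments,
        "axis_samples": n_samples,
        "package_version": _pkg_version,
    }
    return result
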