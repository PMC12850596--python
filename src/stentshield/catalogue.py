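"""The model catalogue: parameter sweeps over cell geometry and stent length.

The catalogue mirrors the study conditions of the analytical sweeps: stent
radius ``R = 8 mm`` and strut radius ``rho = 0.2 mm`` throughout, circular
loop stacks with cell lengths ``l2`` from 0.6 to 30 mm, rectangular cages
with ``N`` from 3 to 30 bars, each repeated for the three typical stent
lengths 60, 80 and 100 mm.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import StentSpec
from .shielding import beta_circular_family, beta_rectangular_family

#: cell lengths l2 of the circular-loop models (mm)
CIRCULAR_L2_MM: tuple[float, ...] = (
    0.6, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0,
    18.0, 20.0, 22.0, 24.0, 26.0, 28.0, 30.0,
)

#: bar counts N of the rectangular-loop models
RECTANGULAR_N: tuple[int, ...] = tuple(range(3, 31))

#: typical stent lengths (mm)
LENGTHS_MM: tuple[float, ...] = (60.0, 80.0, 100.0)

DEFAULT_RADIUS_MM = 8.0
DEFAULT_STRUT_RADIUS_MM = 0.2


def sweep_table(
    lengths_mm: Sequence[float] = LENGTHS_MM,
    l2_values_mm: Sequence[float] = CIRCULAR_L2_MM,
    n_values: Sequence[int] = RECTANGULAR_N,
    radius_mm: float = DEFAULT_RADIUS_MM,
    strut_radius_mm: float = DEFAULT_STRUT_RADIUS_MM,
) -> pd.DataFrame:
    """Compute per-family shielding for every catalogued model.

    Returns a deterministic table with one row per model per length:
    columns ``model``, ``family``, ``N``, ``l1_chord_mm``, ``l1_arc_mm``,
    ``l2_mm``, ``length_mm``, ``beta`` (fraction) and ``beta_percent``.
    ``l1`` is reported both as the chord between adjacent bars (used for
    labelling) and as the circumferential arc.
    """
    rows = []
    for length in lengths_mm:
        for l2 in l2_values_mm:
            spec = StentSpec(
                radius=radius_mm * 1e-3,
                strut_radius=strut_radius_mm * 1e-3,
                length=length * 1e-3,
                cell_length=l2 * 1e-3,
                loop_types=("circular",),
            )
            beta = beta_circular_family(spec)
            rows.append(
                {
                    "model": f"circ_l2_{l2:g}mm_L{length:g}mm",
                    "family": "circular",
                    "N": np.nan,
                    "l1_chord_mm": np.nan,
                    "l1_arc_mm": np.nan,
                    "l2_mm": l2,
                    "length_mm": length,
                    "beta": beta,
                }
            )
        for n in n_values:
            spec = StentSpec(
                radius=radius_mm * 1e-3,
                strut_radius=strut_radius_mm * 1e-3,
                length=length * 1e-3,
                n_bars=n,
                loop_types=("rectangular",),
            )
            beta = beta_rectangular_family(spec)
            rows.append(
                {
                    "model": f"rect_N{n}_L{length:g}mm",
                    "family": "rectangular",
                    "N": n,
                    "l1_chord_mm": spec.l1_chord * 1e3,
                    "l1_arc_mm": spec.l1_arc * 1e3,
                    "l2_mm": np.nan,
                    "length_mm": length,
                    "beta": beta,
                }
            )
    df = pd.DataFrame(rows)
    df["beta_percent"] = 100.0 * df["beta"]
    return df


def max_length_spread_pp(table: pd.DataFrame) -> float:
    """Largest per-model shielding spread across stent lengths, in points.

    For every catalogued model the shielding is compared across the swept
    lengths; returns the maximum absolute difference in percentage points.
    """
    def model_key(row):
        if row["family"] == "circular":
            return ("circular", row["l2_mm"])
        return ("rectangular", row["N"])

    t = table.copy()
    t["key"] = t.apply(model_key, axis=1)
    spread = t.groupby("key")["beta_percent"].agg(lambda s: s.max() - s.min())
    return float(spread.max())
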