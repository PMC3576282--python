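"""Shape classification of exon-position profiles.

Within multi-exon genes, codon-usage statistics are not uniform along the
gene: plotted against exon position they tend to arch up (a cap-shaped
profile, where interstitial exons exceed the two terminal ones) or arch down
(cup-shaped).  The classifier here operationalizes that qualitative notion:
a profile is a *cap* when the mean over interstitial exons exceeds the mean
of the first and last exon by more than a relative tolerance (default 2% of
the terminal mean), a *cup* when it falls below by more than the tolerance,
*flat* within the tolerance, and *mixed* when undefined (fewer than three
exons, or missing values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_TOLERANCE = 0.02

SHAPES = ("cap", "cup", "flat", "mixed")


@dataclass(frozen=True)
class ExonProfile:
    """One statistic evaluated at every exon position of an exon-total group."""

    exon_total: int
    values: tuple[float, ...]
    shape: str
    terminal_mean: float
    interstitial_mean: float


def classify_shape(
    values: Sequence[float], tolerance: float = DEFAULT_TOLERANCE
) -> str:
    """Label a per-exon profile cap / cup / flat / mixed.

    ``tolerance`` is relative to the magnitude of the terminal mean, so the
    label is invariant to positive rescaling of the statistic; it is also
    invariant to adding a constant when the tolerance is zero (and nearly so
    otherwise, since the band tracks the terminal mean).
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 3 or not np.all(np.isfinite(vals)):
        return "mixed"
    terminal = (vals[0] + vals[-1]) / 2.0
    interstitial = float(vals[1:-1].mean())
    band = tolerance * abs(terminal)
    if interstitial > terminal + band:
        return "cap"
    if interstitial < terminal - band:
        return "cup"
    return "flat"


def make_exon_profile(
    exon_total: int,
    values: Sequence[float],
    tolerance: float = DEFAULT_TOLERANCE,
) -> ExonProfile:
    vals = tuple(float(v) for v in values)
    if len(vals) != exon_total:
        raise ValueError("values length must equal exon_total")
    shape = classify_shape(vals, tolerance=tolerance)
    terminal = (vals[0] + vals[-1]) / 2.0
    interstitial = (
        float(np.mean(vals[1:-1])) if exon_total >= 3 else float("nan")
    )
    return ExonProfile(
        exon_total=exon_total,
        values=vals,
        shape=shape,
        terminal_mean=terminal,
        interstitial_mean=interstitial,
    )


def first_exon_conservation(
    profiles: dict[int, Sequence[float]],
) -> pd.DataFrame:
    """Dispersion of a statistic across exon-total groups, by position class.

    For each position class (first exon, last exon, interstitial mean), the
    coefficient of variation of the statistic's value across the exon-total
    groups is reported.  A small CV for the first exon relative to the other
    classes indicates that first-exon codon usage is conserved regardless of
    how many exons a gene carries.
    """
    if len(profiles) < 2:
        raise ValueError("first_exon_conservation needs >= 2 exon-total groups")
    rows = {}
    for total, values in profiles.items():
        vals = np.asarray(values, dtype=float)
        if len(vals) != total:
            raise ValueError(f"group {total}: expected {total} values")
        rows[total] = {
            "first": vals[0],
            "last": vals[-1],
            "interstitial": float(vals[1:-1].mean()) if total >= 3 else np.nan,
        }
    frame = pd.DataFrame(rows).T
    out = []
    for cls in frame.columns:
        col = frame[cls].dropna()
        mean = col.mean()
        cv = float(col.std(ddof=1) / abs(mean)) if len(col) >= 2 and mean != 0 else np.nan
        out.append((cls, mean, cv, len(col)))
    return pd.DataFrame(out, columns=["position_class", "mean", "cv", "n_groups"]).set_index(
        "position_class"
    )


def shape_matrix(
    values_by_cell: dict[tuple[str, int], Sequence[float]],
    tolerance: float = DEFAULT_TOLERANCE,
) -> pd.DataFrame:
    """Classify every (statistic, exon_total) cell; rows = statistic."""
    stats_names = sorted({k[0] for k in values_by_cell})
    totals = sorted({k[1] for k in values_by_cell})
    frame = pd.DataFrame(index=stats_names, columns=totals, dtype=object)
    for (stat, total), values in values_by_cell.items():
        frame.loc[stat, total] = classify_shape(values, tolerance=tolerance)
    return frame
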