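"""Reference-band quantification and between-lane normalization.

Silver-stained 1D gel lanes are summarized as intensity profiles; each
reference band is quantified as the *peak volume*: the trapezoidal
integral of the raw profile over a fixed window around the band's nominal
migration position, with no background subtraction.  Between-lane
intensity differences (staining, loading) are then removed with either
quantile normalization (used for the ISm line) or cyclic-loess
normalization on the log2 scale (used for the ISy line).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import BandMatrix, LaneProfile, ReferenceBand

__all__ = [
    "quantify_reference_bands",
    "quantify_lanes",
    "quantile_normalize",
    "cyclic_loess_normalize",
    "total_band_intensity",
]


def _integrate_window(positions: np.ndarray, intensities: np.ndarray,
                      lo: float, hi: float) -> float:
    """Trapezoidal integral of the sampled profile over [lo, hi].

    The window edges are included as linearly interpolated points so the
    integral does not depend on whether a sample falls exactly on an edge.
    """
    inside = (positions > lo) & (positions < hi)
    xs = np.concatenate(([lo], positions[inside], [hi]))
    ys = np.concatenate((
        [np.interp(lo, positions, intensities)],
        intensities[inside],
        [np.interp(hi, positions, intensities)],
    ))
    return float(np.trapezoid(ys, xs))


def quantify_reference_bands(
    profile: LaneProfile,
    bands: Sequence[ReferenceBand],
    background_mode: str = "none",
    quantity: str = "peak_volume",
) -> np.ndarray:
    """Quantify each reference band of one lane as its peak volume.

    Parameters
    ----------
    profile
        The lane's intensity trace.
    bands
        Reference bands; every window must lie inside the profile range.
    background_mode
        Only ``"none"`` is supported: nothing is subtracted.
    quantity
        Only ``"peak_volume"`` (windowed trapezoidal integral).

    Returns
    -------
    One intensity per band, in the order given.
    """
    if background_mode != "none":
        raise ValueError(f"unsupported background_mode {background_mode!r}; only 'none'")
    if quantity != "peak_volume":
        raise ValueError(f"unsupported quantity {quantity!r}; only 'peak_volume'")
    pmin, pmax = profile.positions[0], profile.positions[-1]
    windows = [b.window for b in bands]
    for b, (lo, hi) in zip(bands, windows):
        if lo < pmin or hi > pmax:
            raise ValueError(
                f"band {b.band_id!r} window [{lo:g}, {hi:g}] lies outside the "
                f"profile range [{pmin:g}, {pmax:g}]"
            )
    order = np.argsort([w[0] for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if windows[a][1] > windows[b][0]:
            warnings.warn(
                f"windows of bands {bands[a].band_id!r} and {bands[b].band_id!r} "
                "overlap; both are integrated as specified",
                stacklevel=2,
            )
    return np.array([
        _integrate_window(profile.positions, profile.intensities, lo, hi)
        for (lo, hi) in windows
    ])


def quantify_lanes(
    profiles: Sequence[LaneProfile],
    bands: Sequence[ReferenceBand],
    background_mode: str = "none",
    quantity: str = "peak_volume",
) -> BandMatrix:
    """Quantify a set of lanes against a common reference-band set."""
    vols = np.vstack([
        quantify_reference_bands(p, bands, background_mode, quantity)
        for p in profiles
    ])
    return BandMatrix.from_profiles(profiles, vols, [b.band_id for b in bands])


def quantile_normalize(matrix: BandMatrix) -> BandMatrix:
    """Force every lane (row) to share one common intensity distribution.

    The reference distribution is the across-row mean of the row-sorted
    values; each row is mapped onto it by rank.  Ties receive the mean of
    the reference values at the tied ranks, so row-wise rank order is
    preserved and, after normalization, every row holds the identical
    multiset of values.
    """
    if matrix.n_individuals < 2:
        raise ValueError("quantile normalization requires at least two rows")
    vals = matrix.values
    n = vals.shape[1]
    reference = np.sort(vals, axis=1).mean(axis=0)
    out = np.empty_like(vals)
    for i in range(vals.shape[0]):
        row = vals[i]
        order = np.argsort(row, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # tied values share the mean of their tied reference quantiles
        _, inverse = np.unique(row, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        counts = np.bincount(inverse)
        out[i] = (sums / counts)[inverse]
    return matrix.with_intensities(out)


def cyclic_loess_normalize(
    matrix: BandMatrix,
    span: float = 0.7,
    max_iterations: int = 3,
    offset: float = 1.0,
) -> BandMatrix:
    """Cyclic-loess normalization of lanes on the log2 scale.

    For every pair of rows a loess curve is fitted to M = log2 difference
    versus A = log2 average across bands, and half of the fitted trend is
    removed from each row (so the pair's A values are untouched and the
    grand log2 mean is preserved exactly).  The cycle over all pairs is
    repeated ``max_iterations`` times, then values are mapped back to the
    intensity scale and clipped at zero.

    Parameters
    ----------
    span
        Loess smoothing fraction in (0, 1].
    offset
        Added before taking log2; must make all values positive.
    """
    if matrix.n_individuals < 2:
        raise ValueError("cyclic loess normalization requires at least two rows")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    vals = matrix.values
    if np.any(vals + offset <= 0):
        raise ValueError(
            "log2 transform undefined: increase `offset` so all intensities + offset > 0"
        )
    log = np.log2(vals + offset)
    n_rows = log.shape[0]
    for _ in range(max_iterations):
        for i in range(n_rows - 1):
            for j in range(i + 1, n_rows):
                m = log[i] - log[j]
                a = 0.5 * (log[i] + log[j])
                fit = lowess(m, a, frac=span, return_sorted=False)
                log[i] -= fit / 2.0
                log[j] += fit / 2.0
    out = np.clip(np.exp2(log) - offset, 0.0, None)
    return matrix.with_intensities(out)


def total_band_intensity(matrix: BandMatrix) -> pd.DataFrame:
    """Per-individual total intensity: the sum over all reference bands.

    Used as a proxy for the total amount of protein in the venom.
    Returns a table with the metadata columns and a ``total_intensity``
    column.
    """
    out = matrix.meta.copy()
    out["total_intensity"] = matrix.values.sum(axis=1)
    return out
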