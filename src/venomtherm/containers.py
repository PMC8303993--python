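"""Core data containers shared across the pipeline.

The central object is :class:`BandMatrix`: a table of reference-band
intensities (one row per individual wasp, one column per reference band)
together with the metadata needed by the statistical analyses (parasitoid
line, rearing temperature, replicate).  Lane-level data enter the pipeline
as :class:`LaneProfile` objects (a densitometric intensity trace along the
migration axis of one gel lane) and are reduced to a ``BandMatrix`` by
integrating over :class:`ReferenceBand` windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: metadata columns of the on-disk band-matrix CSV layout, in order
META_COLUMNS = ("individual_id", "line", "temperature", "replicate")


@dataclass
class LaneProfile:
    """Densitometric intensity trace of a single gel lane.

    Parameters
    ----------
    positions
        Strictly increasing migration coordinates (arbitrary units).
    intensities
        Non-negative staining intensities, one per position.
    individual_id, line, temperature, replicate
        Metadata of the individual the lane belongs to.
    """

    positions: np.ndarray
    intensities: np.ndarray
    individual_id: str = "lane"
    line: str = "ISm"
    temperature: float = 25.0
    replicate: str = "r1"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("positions and intensities must be 1-D")
        if len(self.positions) != len(self.intensities):
            raise ValueError("positions and intensities must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class ReferenceBand:
    """A quantification landmark: a band of known molecular weight.

    Each band is integrated over a fixed window
    ``[nominal_position - window_halfwidth, nominal_position + window_halfwidth]``.
    """

    band_id: str
    nominal_position: float
    window_halfwidth: float

    def __post_init__(self) -> None:
        if self.window_halfwidth <= 0:
            raise ValueError("window_halfwidth must be positive")

    @property
    def window(self) -> tuple[float, float]:
        return (
            self.nominal_position - self.window_halfwidth,
            self.nominal_position + self.window_halfwidth,
        )


@dataclass
class BandMatrix:
    """Individuals x reference-band intensity matrix with metadata.

    ``intensities`` holds one row per individual and one column per band;
    ``meta`` is indexed identically and carries ``line``, ``temperature``
    and ``replicate``.  Raw (pre-normalization) intensities are
    non-negative; normalized or replicate-centered values may not be.
    """

    intensities: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.meta.index):
            raise ValueError("intensities and meta must share the same index")
        missing = [c for c in ("line", "temperature", "replicate") if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta lacks required columns: {missing}")
        if self.intensities.isna().any().any():
            raise ValueError("band matrix contains missing values")
        if not all(np.issubdtype(dt, np.number) for dt in self.intensities.dtypes):
            raise ValueError("band intensities must be numeric")

    # -- basic properties -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.intensities)

    @property
    def n_bands(self) -> int:
        return self.intensities.shape[1]

    @property
    def band_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def values(self) -> np.ndarray:
        return self.intensities.to_numpy(dtype=float)

    @property
    def temperatures(self) -> np.ndarray:
        return np.sort(self.meta["temperature"].unique())

    def with_intensities(self, values: np.ndarray | pd.DataFrame) -> "BandMatrix":
        """Return a copy of this matrix with new intensity values."""
        if isinstance(values, pd.DataFrame):
            new = values.copy()
        else:
            new = pd.DataFrame(
                np.asarray(values, dtype=float),
                index=self.intensities.index,
                columns=self.intensities.columns,
            )
        return BandMatrix(intensities=new, meta=self.meta.copy())

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Flatten to the CSV layout (metadata columns then band columns)."""
        out = self.meta.copy()
        out.insert(0, "individual_id", self.meta.index)
        return pd.concat([out.reset_index(drop=True),
                          self.intensities.reset_index(drop=True)], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BandMatrix":
        missing = [c for c in META_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"band matrix table lacks columns: {missing}")
        frame = frame.set_index("individual_id")
        meta = frame[["line", "temperature", "replicate"]].copy()
        bands = frame.drop(columns=["line", "temperature", "replicate"])
        return cls(intensities=bands.astype(float), meta=meta)

    @classmethod
    def from_csv(cls, path) -> "BandMatrix":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def from_profiles(
        cls,
        profiles: Sequence[LaneProfile],
        quantified: np.ndarray,
        band_ids: Sequence[str],
    ) -> "BandMatrix":
        """Assemble a matrix from per-lane quantification results."""
        quantified = np.asarray(quantified, dtype=float)
        idx = pd.Index([p.individual_id for p in profiles], name="individual_id")
        meta = pd.DataFrame(
            {
                "line": [p.line for p in profiles],
                "temperature": [p.temperature for p in profiles],
                "replicate": [p.replicate for p in profiles],
            },
            index=idx,
        )
        intens = pd.DataFrame(quantified, index=idx, columns=list(band_ids))
        return cls(intensities=intens, meta=meta)
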