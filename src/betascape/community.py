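"""Shared spatial containers: the grid of sites and the site-by-species matrix."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Grid", "CommunityMatrix"]


@dataclass
class Grid:
    """Ordered grid cells with planar coordinates, unit label and elevation.

    Coordinates are projected kilometres.  ``unit`` is a categorical label
    (e.g. a geomorphological unit); ``elevation_m`` is metres above sea
    level and must be non-negative.
    """

    cell_ids: np.ndarray
    x_km: np.ndarray
    y_km: np.ndarray
    unit: np.ndarray
    elevation_m: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids)
        self.x_km = np.asarray(self.x_km, dtype=float)
        self.y_km = np.asarray(self.y_km, dtype=float)
        self.unit = np.asarray(self.unit)
        self.elevation_m = np.asarray(self.elevation_m, dtype=float)
        n = len(self.cell_ids)
        if not (len(self.x_km) == len(self.y_km) == len(self.unit) == len(self.elevation_m) == n):
            raise ValueError("all Grid columns must have the same length")
        if len(np.unique(self.cell_ids)) != n:
            raise ValueError("cell_ids must be unique")
        if np.any(self.elevation_m < 0):
            raise ValueError("elevation_m must be non-negative")

    def __len__(self) -> int:
        return len(self.cell_ids)

    @property
    def coords(self) -> np.ndarray:
        """n x 2 array of (x_km, y_km)."""
        return np.column_stack([self.x_km, self.y_km])

    def subset(self, mask: np.ndarray) -> "Grid":
        """Return a new Grid restricted to the boolean/index mask, order kept."""
        return Grid(
            self.cell_ids[mask],
            self.x_km[mask],
            self.y_km[mask],
            self.unit[mask],
            self.elevation_m[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "x_km": self.x_km,
                "y_km": self.y_km,
                "unit": self.unit,
                "elevation_m": self.elevation_m,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Grid":
        return cls(
            df["cell_id"].to_numpy(),
            df["x_km"].to_numpy(float),
            df["y_km"].to_numpy(float),
            df["unit"].to_numpy(),
            df["elevation_m"].to_numpy(float),
        )


@dataclass
class CommunityMatrix:
    """Site-by-species matrix: 0/1 when raw, real after transforms.

    ``transform_tag`` records the processing state: ``raw``, ``hellinger``
    or ``detrended``.
    """

    cell_ids: np.ndarray
    species: np.ndarray
    values: np.ndarray
    transform_tag: str = "raw"

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids)
        self.species = np.asarray(self.species)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.species)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.cell_ids)} cells, {len(self.species)} species)"
            )
        if len(np.unique(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicated cell_ids")
        if len(np.unique(self.species)) != len(self.species):
            raise ValueError("duplicated species names")
        if self.transform_tag == "raw" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("raw incidence values must be 0 or 1")

    @property
    def n_sites(self) -> int:
        return len(self.cell_ids)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def with_values(self, values: np.ndarray, tag: str) -> "CommunityMatrix":
        return CommunityMatrix(self.cell_ids, self.species, values, tag)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.cell_ids, name="cell_id"),
                            columns=self.species)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, transform_tag: str = "raw") -> "CommunityMatrix":
        return cls(df.index.to_numpy(), df.columns.to_numpy(), df.to_numpy(float), transform_tag)
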