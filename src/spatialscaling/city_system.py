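"""Spatial units (populations, token counts, centroids) and geodesic distances.

A *city system* is a set of N spatial units — municipalities, metropolitan
areas, or any other partition of a territory — each with a population
``x_i > 0`` and an observed count ``y_i >= 0`` of tokens (dollars of GDP,
deaths, miles of road, ...).  Distances between unit centroids are
great-circle distances on a sphere of radius 6371 km unless the user supplies
their own distance matrix (e.g. commuting times expressed in km-equivalents).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: canonical column names of the unit-table CSV schema
UNIT_COLUMNS = ("unit_id", "lat", "lon", "population", "count")


def haversine_matrix(
    lat: Sequence[float], lon: Sequence[float], radius_km: float = EARTH_RADIUS_KM
) -> np.ndarray:
    """Great-circle distance matrix (km) between points on a sphere.

    Parameters
    ----------
    lat, lon
        Coordinates in decimal degrees.
    radius_km
        Sphere radius; the default is the Earth's mean radius.

    Returns
    -------
    ndarray of shape (n, n), symmetric with zero diagonal.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = (
        np.sin(dphi / 2.0) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    )
    d = 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass(frozen=True)
class CitySystem:
    """The N spatial units: identifiers, centroids, populations and counts.

    ``y`` may be ``None`` for a system whose counts have not been observed
    (or not yet simulated).  Coordinates may be ``None`` when the user
    supplies a precomputed :class:`DistanceMatrix` instead.
    """

    unit_id: np.ndarray
    x: np.ndarray
    y: Optional[np.ndarray] = None
    lat: Optional[np.ndarray] = None
    lon: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit_id", np.asarray(self.unit_id, dtype=object))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        n = self.unit_id.shape[0]
        if n < 1:
            raise ValueError("a city system needs at least one unit")
        if self.x.shape != (n,):
            raise ValueError("x must have one entry per unit")
        if not np.all(np.isfinite(self.x)) or np.any(self.x <= 0):
            bad = self.unit_id[~(np.isfinite(self.x) & (self.x > 0))]
            raise ValueError(
                f"populations must be positive and finite; offending unit(s): {list(bad)}"
            )
        if self.y is not None:
            object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
            if self.y.shape != (n,):
                raise ValueError("y must have one entry per unit")
            if not np.all(np.isfinite(self.y)) or np.any(self.y < 0):
                bad = self.unit_id[~(np.isfinite(self.y) & (self.y >= 0))]
                raise ValueError(
                    f"counts must be non-negative and finite; offending unit(s): {list(bad)}"
                )
        if (self.lat is None) != (self.lon is None):
            raise ValueError("lat and lon must be supplied together")
        if self.lat is not None:
            object.__setattr__(self, "lat", np.asarray(self.lat, dtype=float))
            object.__setattr__(self, "lon", np.asarray(self.lon, dtype=float))
            if self.lat.shape != (n,) or self.lon.shape != (n,):
                raise ValueError("lat/lon must have one entry per unit")
            bad_lat = ~(np.isfinite(self.lat) & (self.lat >= -90) & (self.lat <= 90))
            bad_lon = ~(np.isfinite(self.lon) & (self.lon >= -180) & (self.lon <= 180))
            if np.any(bad_lat | bad_lon):
                bad = self.unit_id[bad_lat | bad_lon]
                raise ValueError(
                    "coordinates out of range (lat in [-90, 90], lon in [-180, 180]); "
                    f"offending unit(s): {list(bad)}"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_units(self) -> int:
        return int(self.unit_id.shape[0])

    @property
    def total_population(self) -> float:
        """X = sum of unit populations."""
        return float(self.x.sum())

    @property
    def total_tokens(self) -> float:
        """Y = sum of observed counts."""
        if self.y is None:
            raise ValueError("this system has no observed counts")
        return float(self.y.sum())

    @property
    def has_coordinates(self) -> bool:
        return self.lat is not None

    def subset(self, index: Sequence[int]) -> "CitySystem":
        """Return the system restricted/permuted to ``index`` (integer positions)."""
        idx = np.asarray(index, dtype=int)
        return CitySystem(
            unit_id=self.unit_id[idx],
            x=self.x[idx],
            y=None if self.y is None else self.y[idx],
            lat=None if self.lat is None else self.lat[idx],
            lon=None if self.lon is None else self.lon[idx],
        )

    def with_counts(self, y: Sequence[float]) -> "CitySystem":
        """Return a copy of the system with counts ``y`` attached."""
        return CitySystem(unit_id=self.unit_id, x=self.x, y=np.asarray(y, dtype=float),
                          lat=self.lat, lon=self.lon)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, drop_nonpositive_population: bool = True
                       ) -> "CitySystem":
        """Build a system from a table with the canonical column schema.

        Required columns: ``unit_id``, ``population``; optional: ``count``,
        and the pair ``lat``/``lon``.  Rows with non-positive population are
        dropped with a warning (their log-population is undefined in the
        likelihood); pass ``drop_nonpositive_population=False`` to raise
        instead.
        """
        for col in ("unit_id", "population"):
            if col not in df.columns:
                raise KeyError(f"missing required column '{col}'")
        if ("lat" in df.columns) != ("lon" in df.columns):
            raise KeyError("columns 'lat' and 'lon' must be supplied together")
        df = df.copy()
        bad = ~(pd.to_numeric(df["population"], errors="coerce") > 0)
        if bad.any():
            if not drop_nonpositive_population:
                raise ValueError(
                    f"{int(bad.sum())} unit(s) with non-positive population: "
                    f"{list(df.loc[bad, 'unit_id'])}"
                )
            warnings.warn(
                f"dropped {int(bad.sum())} unit(s) with non-positive population",
                UserWarning,
                stacklevel=2,
            )
            df = df.loc[~bad]
        return cls(
            unit_id=df["unit_id"].to_numpy(),
            x=df["population"].to_numpy(dtype=float),
            y=df["count"].to_numpy(dtype=float) if "count" in df.columns else None,
            lat=df["lat"].to_numpy(dtype=float) if "lat" in df.columns else None,
            lon=df["lon"].to_numpy(dtype=float) if "lon" in df.columns else None,
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CitySystem":
        return cls.from_dataframe(pd.read_csv(path), **kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"unit_id": self.unit_id}
        if self.lat is not None:
            data["lat"] = self.lat
            data["lon"] = self.lon
        data["population"] = self.x
        if self.y is not None:
            data["count"] = self.y
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric N x N matrix of pairwise distances in km, zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("distances must be finite and non-negative")
        if not np.allclose(v, v.T, rtol=0, atol=1e-6):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("distance matrix must have a zero diagonal")
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        object.__setattr__(self, "values", v)

    @property
    def n_units(self) -> int:
        return int(self.values.shape[0])

    @property
    def max_distance(self) -> float:
        """Diameter of the system in km."""
        return float(self.values.max())

    @classmethod
    def from_system(cls, system: CitySystem, radius_km: float = EARTH_RADIUS_KM
                    ) -> "DistanceMatrix":
        """Geodesic (haversine) distances between unit centroids."""
        if not system.has_coordinates:
            raise ValueError(
                "system has no coordinates; supply a precomputed distance matrix"
            )
        return cls(haversine_matrix(system.lat, system.lon, radius_km=radius_km))

    @classmethod
    def from_csv(cls, path, unit_ids: Optional[Sequence[str]] = None) -> "DistanceMatrix":
        """Read a square distance-matrix CSV keyed by unit_id in row and column.

        If ``unit_ids`` is given, rows and columns are re-ordered to match;
        a missing id raises ``KeyError``.
        """
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if unit_ids is not None:
            ids = [str(u) for u in unit_ids]
            missing = [u for u in ids if u not in df.index or u not in df.columns]
            if missing:
                raise KeyError(f"unit id(s) missing from distance matrix: {missing}")
            df = df.loc[ids, ids]
        return cls(df.to_numpy(dtype=float))

    def to_csv(self, path, unit_ids: Sequence[str]) -> None:
        ids = [str(u) for u in unit_ids]
        pd.DataFrame(self.values, index=ids, columns=ids).to_csv(path)

    def subset(self, index: Sequence[int]) -> "DistanceMatrix":
        idx = np.asarray(index, dtype=int)
        return DistanceMatrix(self.values[np.ix_(idx, idx)])


def build_distance_matrix(system: CitySystem, radius_km: float = EARTH_RADIUS_KM
                          ) -> DistanceMatrix:
    """Geodesic distance matrix between unit centroids (haversine, spherical)."""
    return DistanceMatrix.from_system(system, radius_km=radius_km)
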