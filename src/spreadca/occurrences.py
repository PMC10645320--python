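"""Occurrence records: thinning, pseudo-absence sampling, autocorrelation.

Presence-only species records (e.g. GBIF downloads) need cleaning before a
suitability model can be fitted: records with large coordinate uncertainty
are dropped, records closer together than a minimum spacing are thinned to
one, and pseudo-absence (background) points are placed far from every
presence so their environments genuinely differ. The defaults mirror the
study this package re-implements: uncertainty > 100 m removed, presences
thinned to >= 30 km spacing, pseudo-absences >= 110 km from all other
points, 800 pseudo-absences.

Distances are great-circle (haversine, meters) when the coordinate tag is
geographic and Euclidean otherwise; thresholds are always in meters.

Moran's I with inverse-distance row-standardized weights and a permutation
test is provided to check residual spatial autocorrelation after thinning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CapacityError, DegenerateInputError, SpreadcaError
from .raster import RasterLayer

__all__ = [
    "LABEL_PRESENCE", "LABEL_PSEUDO_ABSENCE",
    "OccurrenceSet", "ThinningConfig",
    "thin_occurrences", "sample_pseudo_absences", "morans_i", "MoransIResult",
    "point_distances",
]

LABEL_PRESENCE = "presence"
LABEL_PSEUDO_ABSENCE = "pseudo_absence"

_GEOGRAPHIC_TAGS = {"wgs84", "epsg:4326", "geographic", "lonlat", "latlon"}
_EARTH_RADIUS_M = 6_371_000.0


def _is_geographic(crs_tag: str) -> bool:
    return crs_tag.strip().lower() in _GEOGRAPHIC_TAGS


def point_distances(ax, ay, bx, by, crs_tag: str = "local-m") -> np.ndarray:
    """Distances in meters between broadcastable point arrays.

    Haversine great-circle distances for geographic tags (x = longitude,
    y = latitude, degrees), Euclidean otherwise.
    """
    ax, ay, bx, by = (np.asarray(v, dtype=float) for v in (ax, ay, bx, by))
    if _is_geographic(crs_tag):
        lon1, lat1, lon2, lat2 = map(np.radians, (ax, ay, bx, by))
        dlat = lat2 - lat1
        dlon = lon2 - lon1
        a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
        return 2 * _EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return np.hypot(ax - bx, ay - by)


@dataclass
class OccurrenceSet:
    """Presence / pseudo-absence point records with coordinate uncertainty."""

    x: np.ndarray
    y: np.ndarray
    uncertainty: np.ndarray
    label: np.ndarray
    crs_tag: str = "local-m"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.uncertainty = np.asarray(self.uncertainty, dtype=float)
        self.label = np.asarray(self.label, dtype=object)
        n = len(self.x)
        if not (len(self.y) == len(self.uncertainty) == len(self.label) == n):
            raise ValueError("all occurrence columns must share length")
        if np.any(self.uncertainty < 0):
            raise ValueError("uncertainty must be non-negative")
        bad = set(self.label) - {LABEL_PRESENCE, LABEL_PSEUDO_ABSENCE}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.x)

    def subset(self, mask) -> "OccurrenceSet":
        mask = np.asarray(mask)
        return OccurrenceSet(self.x[mask], self.y[mask], self.uncertainty[mask],
                             self.label[mask], self.crs_tag)

    def presences(self) -> "OccurrenceSet":
        return self.subset(self.label == LABEL_PRESENCE)

    def pseudo_absences(self) -> "OccurrenceSet":
        return self.subset(self.label == LABEL_PSEUDO_ABSENCE)

    def concat(self, other: "OccurrenceSet") -> "OccurrenceSet":
        if other.crs_tag != self.crs_tag:
            raise ValueError("cannot concatenate occurrence sets with different CRS tags")
        return OccurrenceSet(
            np.concatenate([self.x, other.x]),
            np.concatenate([self.y, other.y]),
            np.concatenate([self.uncertainty, other.uncertainty]),
            np.concatenate([self.label, other.label]),
            self.crs_tag,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.x, "y": self.y,
            "uncertainty_m": self.uncertainty, "label": self.label,
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, crs_tag: str = "local-m") -> "OccurrenceSet":
        return cls(
            x=frame["x"].to_numpy(), y=frame["y"].to_numpy(),
            uncertainty=frame.get("uncertainty_m", pd.Series(np.zeros(len(frame)))).to_numpy(),
            label=frame.get("label", pd.Series([LABEL_PRESENCE] * len(frame))).to_numpy(),
            crs_tag=crs_tag,
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, crs_tag: str = "local-m") -> "OccurrenceSet":
        return cls.from_frame(pd.read_csv(path), crs_tag=crs_tag)


@dataclass
class ThinningConfig:
    """Cleaning and pseudo-absence sampling parameters (defaults per study)."""

    max_uncertainty: float = 100.0
    min_interpoint: float = 30_000.0
    pa_min_dist: float = 110_000.0
    n_pseudo_absence: int = 800
    seed: int = 0
    max_attempts_factor: int = 1000

    def __post_init__(self):
        if min(self.max_uncertainty, self.min_interpoint, self.pa_min_dist) <= 0:
            raise ValueError("all distances must be positive")
        if self.n_pseudo_absence < 1:
            raise ValueError("n_pseudo_absence must be >= 1")


def thin_occurrences(occ: OccurrenceSet, cfg: ThinningConfig) -> OccurrenceSet:
    """Greedy spatial thinning in input order.

    Points with coordinate uncertainty above ``cfg.max_uncertainty`` are
    dropped; the remainder is scanned in input order and a point is kept
    iff it lies at least ``cfg.min_interpoint`` from every already-kept
    point. Deterministic and idempotent.
    """
    precise = occ.subset(occ.uncertainty <= cfg.max_uncertainty)
    kept: list[int] = []
    for i in range(len(precise)):
        if not kept:
            kept.append(i)
            continue
        d = point_distances(precise.x[kept], precise.y[kept],
                            precise.x[i], precise.y[i], occ.crs_tag)
        if np.all(d >= cfg.min_interpoint):
            kept.append(i)
    return precise.subset(np.array(kept, dtype=int)) if kept else precise.subset(
        np.zeros(0, dtype=int))


def sample_pseudo_absences(region_mask: RasterLayer, presences: OccurrenceSet,
                           cfg: ThinningConfig) -> OccurrenceSet:
    """Rejection-sample pseudo-absence points inside a region mask.

    Candidate points are uniform over the nonzero, non-nodata cells of the
    mask (uniform within the cell); a candidate is accepted iff it lies at
    least ``cfg.pa_min_dist`` from every presence and every
    already-accepted pseudo-absence. Raises :class:`CapacityError` naming
    the achieved count if ``cfg.max_attempts_factor * n`` candidates do
    not suffice.
    """
    valid = (region_mask.values != 0) & region_mask.valid_mask
    rows, cols = np.nonzero(valid)
    if rows.size == 0:
        raise SpreadcaError("region mask is empty")
    crs = presences.crs_tag if len(presences) else region_mask.crs_tag
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((cfg.seed, 0x9A))))

    n = cfg.n_pseudo_absence
    max_attempts = cfg.max_attempts_factor * n
    accepted_x: list[float] = []
    accepted_y: list[float] = []
    for _ in range(max_attempts):
        k = rng.integers(rows.size)
        x = region_mask.x_of(cols[k]) + rng.uniform(-0.5, 0.5) * region_mask.cell_size
        y = region_mask.y_of(rows[k]) + rng.uniform(-0.5, 0.5) * region_mask.cell_size
        if len(presences):
            if point_distances(presences.x, presences.y, x, y, crs).min() < cfg.pa_min_dist:
                continue
        if accepted_x:
            if point_distances(np.array(accepted_x), np.array(accepted_y),
                               x, y, crs).min() < cfg.pa_min_dist:
                continue
        accepted_x.append(float(x))
        accepted_y.append(float(y))
        if len(accepted_x) == n:
            break
    if len(accepted_x) < n:
        raise CapacityError(
            f"placed only {len(accepted_x)} of {n} pseudo-absences within "
            f"{max_attempts} attempts", achieved=len(accepted_x))
    m = len(accepted_x)
    return OccurrenceSet(
        x=np.array(accepted_x), y=np.array(accepted_y),
        uncertainty=np.zeros(m),
        label=np.array([LABEL_PSEUDO_ABSENCE] * m),
        crs_tag=crs,
    )


@dataclass
class MoransIResult:
    i: float
    p_value: float
    expected: float
    n_perm: int
    weights: str = "inverse-distance, row-standardized"


def morans_i(values, coords, n_perm: int = 999, seed: int = 0,
             crs_tag: str = "local-m") -> MoransIResult:
    """Moran's I with inverse-distance weights and a permutation test.

    Weights are ``1/d`` between distinct points, row-standardized. The
    p-value is two-sided from ``n_perm`` random permutations of the values
    over the locations: the fraction of permuted |I - E[I]| at least as
    large as observed (with the +1 correction), where
    ``E[I] = -1/(n-1)`` is the null expectation.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(values)
    if n < 4:
        raise ValueError("need at least 4 points")
    if np.ptp(values) == 0:
        raise DegenerateInputError("values are constant; Moran's I undefined")

    d = point_distances(coords[:, None, 0], coords[:, None, 1],
                        coords[None, :, 0], coords[None, :, 1], crs_tag)
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    if not np.isfinite(w).all():
        raise DegenerateInputError("duplicate coordinates give infinite weights")
    w /= w.sum(axis=1, keepdims=True)

    def stat(v):
        z = v - v.mean()
        return float((z @ w @ z) / (z @ z))  # S0 = n after row standardization

    i_obs = stat(values)
    expected = -1.0 / (n - 1)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 0x305A))))
    count = 0
    for _ in range(n_perm):
        i_perm = stat(rng.permutation(values))
        if abs(i_perm - expected) >= abs(i_obs - expected):
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MoransIResult(i=i_obs, p_value=p, expected=expected, n_perm=n_perm)
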