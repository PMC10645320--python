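"""Cellular-automaton invasion spread simulator.

The model is an annual-step stochastic cellular automaton on a projected
grid, in the MigClim tradition: occupied cells produce propagules that
colonize empty cells through two channels,

* **short-distance dispersal (SDD)** — every empty candidate cell within
  ``sdd_max`` of one or more mature occupied cells is colonized with
  probability ``1 - prod_i (1 - D(d_i))`` where ``D(d) = exp(-lambda*d)``
  is the negative-exponential dispersal kernel and the product runs over
  all mature sources within range (independent-source complement rule);
* **long-distance dispersal (LDD)** — each mature occupied cell
  independently triggers a jump event with annual probability
  ``ldd_freq``; the jump direction is uniform on [0, 2pi) and the distance
  uniform on (``ldd_min``, ``ldd_max``]; the landing cell is colonized iff
  it is inside the grid, currently colonizable, and passes the
  invasibility rule.

Land-cover constraints: *barrier* cells (forest) and *unsuitable* cells
(built-up, rice paddy, water) can never be colonized. By default barriers
are "weak": propagules may fly over them in a straight line but cannot
establish on them. A "strong" mode in which any barrier cell on the
source-to-target segment blocks the flight is available via
``strong_barriers=True``.

Invasibility: a cell is colonizable iff its habitat suitability is at
least ``invasibility_threshold`` (default 0.5). A continuous alternative
(colonization probability multiplied by suitability) is available via
``continuous=True``.

Determinism: every stochastic routine takes a ``numpy.random.Generator``
and consumes draws in a fixed order (the full SDD uniform field in raster
scan order, then per-source LDD Bernoulli draws in raster-scan order, then
per-event angle/distance pairs), so identical seeds give bit-identical
trajectories. Replicate ``r`` of a simulation uses a generator seeded from
``SeedSequence((master_seed, r))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, InvalidSpecError, SpreadcaError
from .raster import RasterLayer, require_aligned

__all__ = [
    "STATUS_EMPTY",
    "STATUS_OCCUPIED",
    "STATUS_DECOLONIZED",
    "STATUS_BARRIER",
    "STATUS_UNSUITABLE",
    "DispersalParams",
    "CellStateGrid",
    "SuitabilityStack",
    "SimulationResult",
    "kernel_prob",
    "build_initial_distribution",
    "sdd_colonization_prob",
    "ldd_events",
    "step_year",
    "update_suitability",
    "run_simulation",
    "percent_colonized",
]

STATUS_EMPTY = 0
STATUS_OCCUPIED = 1
STATUS_DECOLONIZED = 2
STATUS_BARRIER = 3
STATUS_UNSUITABLE = 4


@dataclass
class DispersalParams:
    """Dispersal-model parameters.

    Defaults follow the published *Andropogon virginicus* parameterization:
    negative-exponential kernel rate ``lam`` = 0.005 m^-1, SDD capped at
    600 m (the kernel retains exp(-3) ~ 5% at the cap, i.e. ~99% of seeds
    travel shorter), LDD jumps in (600 m, 10 km], one-year maturity and 10
    replicates. ``ldd_freq`` is a per-occupied-mature-cell annual Bernoulli
    probability, so the study's "0.05%" frequency is 0.0005.
    """

    lam: float = 0.005
    sdd_max: float = 600.0
    ldd_min: float = 600.0
    ldd_max: float = 10_000.0
    ldd_freq: float = 0.0005
    maturity_age: int = 1
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.lam <= 0:
            raise InvalidSpecError("lambda must be positive")
        if not (0 < self.sdd_max <= self.ldd_min < self.ldd_max):
            raise InvalidSpecError(
                "need 0 < sdd_max <= ldd_min < ldd_max, got "
                f"sdd_max={self.sdd_max}, ldd_min={self.ldd_min}, ldd_max={self.ldd_max}"
            )
        if not 0.0 <= self.ldd_freq <= 1.0:
            raise InvalidSpecError("ldd_freq must be a probability")
        if self.maturity_age < 1:
            raise InvalidSpecError("maturity_age must be >= 1")
        if self.n_replicates < 1:
            raise InvalidSpecError("n_replicates must be >= 1")


def kernel_prob(d, lam: float):
    """Negative-exponential dispersal kernel ``D(d; lambda) = exp(-lambda d)``.

    Accepts scalars or arrays of distances in meters; raises on negative
    distances. Monotone decreasing in ``d`` with ``D(0) = 1``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = np.exp(-lam * d)
    return float(out) if out.ndim == 0 else out


@dataclass
class CellStateGrid:
    """Per-cell CA state: a status code grid plus ages since colonization.

    Status codes: 0 empty, 1 occupied, 2 decolonized, 3 barrier,
    4 unsuitable land cover. Barrier and unsuitable cells are never
    occupied; ``age`` is meaningful only on occupied cells.
    """

    status: np.ndarray
    age: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 200.0
    crs_tag: str = "local-m"

    def __post_init__(self):
        self.status = np.asarray(self.status, dtype=np.uint8)
        self.age = np.asarray(self.age, dtype=np.int32)
        if self.status.shape != self.age.shape:
            raise ValueError("status and age must share shape")

    @classmethod
    def open_grid(cls, nrows: int, ncols: int, cell_size: float = 200.0,
                  origin_x: float = 0.0, origin_y: float | None = None) -> "CellStateGrid":
        """An all-empty grid with no barriers (convenience for tests/demos)."""
        if origin_y is None:
            origin_y = nrows * cell_size
        return cls(
            status=np.zeros((nrows, ncols), dtype=np.uint8),
            age=np.zeros((nrows, ncols), dtype=np.int32),
            origin_x=origin_x, origin_y=origin_y, cell_size=cell_size,
        )

    @classmethod
    def from_landcover(cls, landcover: RasterLayer, forest_class: int = 1,
                       unsuitable_classes: Sequence[int] = (2, 3, 4)) -> "CellStateGrid":
        """Initialize statuses from an integer land-cover raster.

        Forest becomes a barrier; built-up/paddy/water become unsuitable;
        everything else (and nodata, conservatively treated as unsuitable)
        starts empty.
        """
        lc = landcover.values
        status = np.zeros(lc.shape, dtype=np.uint8)
        status[lc == forest_class] = STATUS_BARRIER
        status[np.isin(lc, list(unsuitable_classes))] = STATUS_UNSUITABLE
        if landcover.nodata is not None:
            status[lc == landcover.nodata] = STATUS_UNSUITABLE
        return cls(
            status=status,
            age=np.zeros(lc.shape, dtype=np.int32),
            origin_x=landcover.origin_x,
            origin_y=landcover.origin_y,
            cell_size=landcover.cell_size,
            crs_tag=landcover.crs_tag,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.status.shape

    @property
    def geotransform(self):
        return (self.origin_x, self.origin_y, self.cell_size, *self.shape)

    def occupied(self) -> np.ndarray:
        return self.status == STATUS_OCCUPIED

    def mature(self, maturity_age: int) -> np.ndarray:
        return self.occupied() & (self.age >= maturity_age)

    def colonizable(self) -> np.ndarray:
        """Cells a propagule may establish on (empty or previously decolonized)."""
        return (self.status == STATUS_EMPTY) | (self.status == STATUS_DECOLONIZED)

    def occupancy_layer(self) -> RasterLayer:
        return RasterLayer(
            values=self.occupied().astype(np.int64),
            origin_x=self.origin_x, origin_y=self.origin_y,
            cell_size=self.cell_size, crs_tag=self.crs_tag,
        )

    def seed_occupancy(self, occupancy: RasterLayer, age: int = 1) -> None:
        """Occupy cells flagged in ``occupancy`` (skipping barrier/unsuitable)."""
        self._require_layer_aligned(occupancy)
        mask = (occupancy.values > 0) & self.colonizable()
        self.status[mask] = STATUS_OCCUPIED
        self.age[mask] = age

    def copy(self) -> "CellStateGrid":
        return CellStateGrid(
            status=self.status.copy(), age=self.age.copy(),
            origin_x=self.origin_x, origin_y=self.origin_y,
            cell_size=self.cell_size, crs_tag=self.crs_tag,
        )

    def _require_layer_aligned(self, layer: RasterLayer) -> None:
        if (layer.origin_x, layer.origin_y, layer.cell_size, layer.nrows, layer.ncols) \
                != self.geotransform:
            raise AlignmentError(
                f"layer geotransform {layer.geotransform} does not match "
                f"state grid {self.geotransform}"
            )


@dataclass
class SuitabilityStack:
    """Time-ordered habitat-suitability layers with an invasibility threshold.

    ``periods`` maps each period start year to its suitability layer; the
    layer active in a given year is the latest one whose start year is not
    after that year (periods switch exactly at their start years).
    """

    periods: list[tuple[int, RasterLayer]]
    invasibility_threshold: float = 0.5

    def __post_init__(self):
        if not self.periods:
            raise InvalidSpecError("suitability stack needs at least one period")
        starts = [s for s, _ in self.periods]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise InvalidSpecError("period start years must be strictly increasing")
        require_aligned(*[layer for _, layer in self.periods])

    @property
    def start_year(self) -> int:
        return self.periods[0][0]

    def layer_for(self, year: int) -> RasterLayer:
        if year < self.periods[0][0]:
            raise SpreadcaError(f"year {year} precedes first period {self.periods[0][0]}")
        active = self.periods[0][1]
        for start, layer in self.periods:
            if start <= year:
                active = layer
        return active


# -- initial distribution ---------------------------------------------------


def build_initial_distribution(points, grid: CellStateGrid,
                               buffer_radius: float = 5000.0,
                               merge_dist: float = 10_000.0,
                               maturity_age: int = 1):
    """Rasterize point populations into an initial occupancy layer.

    Every colonizable cell whose center lies within ``buffer_radius`` of any
    point is occupied with ``age = maturity_age`` (immediately reproductive);
    barrier and unsuitable cells are skipped. Separately, points closer than
    ``merge_dist`` are merged by single linkage and the number of resulting
    population regions is reported.

    Parameters
    ----------
    points : OccurrenceSet or (n, 2) array of (x, y)

    Returns
    -------
    (occupancy, n_regions) : (RasterLayer, int)
    """
    if hasattr(points, "x"):
        xy = np.column_stack([np.asarray(points.x, float), np.asarray(points.y, float)])
    else:
        xy = np.atleast_2d(np.asarray(points, dtype=float))
    if xy.size == 0:
        raise SpreadcaError("no points supplied")

    nrows, ncols = grid.shape
    xmin = grid.origin_x
    ymax = grid.origin_y
    xmax = xmin + ncols * grid.cell_size
    ymin = ymax - nrows * grid.cell_size
    inside = (xy[:, 0] >= xmin) & (xy[:, 0] <= xmax) & (xy[:, 1] >= ymin) & (xy[:, 1] <= ymax)
    if not inside.any():
        raise SpreadcaError("all points fall outside the grid extent")

    occ = np.zeros(grid.shape, dtype=bool)
    cs = grid.cell_size
    for x, y in xy:
        c0 = max(0, int(np.floor((x - buffer_radius - xmin) / cs)) - 1)
        c1 = min(ncols, int(np.ceil((x + buffer_radius - xmin) / cs)) + 1)
        r0 = max(0, int(np.floor((ymax - (y + buffer_radius)) / cs)) - 1)
        r1 = min(nrows, int(np.ceil((ymax - (y - buffer_radius)) / cs)) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        cols = np.arange(c0, c1)
        rows = np.arange(r0, r1)
        cx = xmin + (cols + 0.5) * cs
        cy = ymax - (rows + 0.5) * cs
        d2 = (cx[None, :] - x) ** 2 + (cy[:, None] - y) ** 2
        occ[r0:r1, c0:c1] |= d2 <= buffer_radius**2

    occ &= grid.colonizable()

    # single-linkage merge of populations closer than merge_dist
    n = len(xy)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < merge_dist:
                parent[find(i)] = find(j)
    n_regions = len({find(i) for i in range(n)})

    layer = RasterLayer(
        values=occ.astype(np.int64), origin_x=grid.origin_x, origin_y=grid.origin_y,
        cell_size=grid.cell_size, crs_tag=grid.crs_tag,
    )
    return layer, n_regions


# -- SDD --------------------------------------------------------------------

_KERNEL_CACHE: dict[tuple, np.ndarray] = {}
_D_CLIP = 1.0 - 1e-12  # keeps log1p(-D) finite when lambda*d -> 0


def _sdd_log_kernel(lam: float, sdd_max: float, cell_size: float) -> np.ndarray:
    """Square window of log(1 - D(d)) at cell-center offsets within sdd_max.

    The center cell and offsets beyond sdd_max contribute 0, so convolving
    the mature-occupancy indicator with this window yields
    ``sum_i log(1 - D(d_i))`` at every cell — the log-complement of the
    propagule-pressure colonization probability.
    """
    key = (lam, sdd_max, cell_size)
    cached = _KERNEL_CACHE.get(key)
    if cached is not None:
        return cached
    r = int(np.floor(sdd_max / cell_size))
    offs = np.arange(-r, r + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    d = np.hypot(dy, dx) * cell_size
    D = np.clip(np.exp(-lam * d), 0.0, _D_CLIP)
    w = np.log1p(-D)
    w[(d > sdd_max) | (d == 0)] = 0.0
    _KERNEL_CACHE[key] = w
    return w


def sdd_colonization_prob(target: tuple[int, int], state: CellStateGrid,
                          params: DispersalParams) -> float:
    """Colonization probability of one empty cell from SDD alone.

    ``p = 1 - prod_i (1 - D(d_i; lambda))`` over all mature occupied cells
    within ``sdd_max`` of the target (cell-center Euclidean distances);
    0 when no source is in range.
    """
    r, c = target
    mature = state.mature(params.maturity_age)
    rows, cols = np.nonzero(mature)
    if rows.size == 0:
        return 0.0
    d = np.hypot(rows - r, cols - c) * state.cell_size
    in_range = (d > 0) & (d <= params.sdd_max)
    if not in_range.any():
        return 0.0
    D = np.clip(kernel_prob(d[in_range], params.lam), 0.0, _D_CLIP)
    return float(1.0 - np.exp(np.log1p(-D).sum()))


def _sdd_prob_field(state: CellStateGrid, params: DispersalParams,
                    strong_barriers: bool) -> np.ndarray:
    """Per-cell SDD colonization probability for every cell of the grid."""
    mature = state.mature(params.maturity_age)
    w = _sdd_log_kernel(params.lam, params.sdd_max, state.cell_size)
    if not strong_barriers:
        logq = ndimage.convolve(mature.astype(float), w, mode="constant", cval=0.0)
        return 1.0 - np.exp(logq)

    # strong mode: drop sources whose straight flight crosses a barrier cell
    barrier = state.status == STATUS_BARRIER
    nrows, ncols = state.shape
    logq = np.zeros(state.shape)
    r_off = (w.shape[0] - 1) // 2
    src_rows, src_cols = np.nonzero(mature)
    for sr, sc in zip(src_rows, src_cols):
        for dr in range(-r_off, r_off + 1):
            tr = sr + dr
            if not 0 <= tr < nrows:
                continue
            for dc in range(-r_off, r_off + 1):
                tc = sc + dc
                if not 0 <= tc < ncols:
                    continue
                wv = w[dr + r_off, dc + r_off]
                if wv == 0.0:
                    continue
                if _line_blocked(barrier, sr, sc, tr, tc):
                    continue
                logq[tr, tc] += wv
    return 1.0 - np.exp(logq)


def _line_blocked(barrier: np.ndarray, r0: int, c0: int, r1: int, c1: int) -> bool:
    """True if any strictly intermediate cell on the segment is a barrier.

    The segment between cell centers is sampled at quarter-cell steps and
    mapped back to cell indices; endpoint cells do not block.
    """
    steps = int(4 * max(abs(r1 - r0), abs(c1 - c0))) + 1
    t = np.linspace(0.0, 1.0, steps + 1)
    rr = np.rint(r0 + t * (r1 - r0)).astype(int)
    cc = np.rint(c0 + t * (c1 - c0)).astype(int)
    hit = barrier[rr, cc]
    hit[0] = hit[-1] = False
    return bool(hit.any())


# -- LDD --------------------------------------------------------------------


def ldd_events(state: CellStateGrid, params: DispersalParams,
               rng: np.random.Generator, suitability: RasterLayer | None = None,
               invasibility_threshold: float = 0.5, continuous: bool = False,
               strong_barriers: bool = False) -> list[tuple[int, int]]:
    """Draw this year's long-distance jump events and return landing cells.

    Each mature occupied cell independently triggers an event with
    probability ``ldd_freq``; direction ~ U[0, 2pi), distance ~
    U(ldd_min, ldd_max]. A landing colonizes its cell iff the cell is
    inside the grid, colonizable (empty/decolonized, never barrier or
    unsuitable) and passes the invasibility rule. Draw order is fixed:
    Bernoulli draws for all mature cells in raster-scan order, then the
    angle/distance (and, in continuous mode, acceptance) draws per event.
    """
    mature = state.mature(params.maturity_age)
    src = np.flatnonzero(mature.ravel())
    if src.size == 0:
        return []
    fire = rng.random(src.size) < params.ldd_freq
    src = src[fire]
    if src.size == 0:
        return []
    nrows, ncols = state.shape
    sr, sc = np.divmod(src, ncols)
    theta = rng.uniform(0.0, 2.0 * np.pi, src.size)
    dist = params.ldd_min + rng.random(src.size) * (params.ldd_max - params.ldd_min)
    dx = dist * np.cos(theta)
    dy = dist * np.sin(theta)
    accept_draws = rng.random(src.size) if (continuous and suitability is not None) else None

    landings: list[tuple[int, int]] = []
    colonizable = state.colonizable()
    suit = suitability.values if suitability is not None else None
    barrier = state.status == STATUS_BARRIER
    for k in range(src.size):
        tc = int(np.floor(sc[k] + 0.5 + dx[k] / state.cell_size))
        tr = int(np.floor(sr[k] + 0.5 - dy[k] / state.cell_size))
        if not (0 <= tr < nrows and 0 <= tc < ncols):
            continue
        if not colonizable[tr, tc]:
            continue
        if suit is not None:
            if continuous:
                if accept_draws[k] >= suit[tr, tc]:
                    continue
            elif suit[tr, tc] < invasibility_threshold:
                continue
        if strong_barriers and _line_blocked(barrier, int(sr[k]), int(sc[k]), tr, tc):
            continue
        landings.append((tr, tc))
    return landings


# -- annual step ------------------------------------------------------------


def step_year(state: CellStateGrid, suitability: RasterLayer | None,
              params: DispersalParams, rng: np.random.Generator, *,
              invasibility_threshold: float = 0.5, continuous: bool = False,
              strong_barriers: bool = False) -> CellStateGrid:
    """Advance the automaton by one year, in place.

    Order of operations: (1) increment ages of occupied cells; (2) SDD —
    every colonizable candidate cell passing the invasibility gate is
    colonized with its propagule-pressure probability; (3) LDD events.
    New colonists enter with age 0, so with a one-year maturity they start
    dispersing the following year.
    """
    if suitability is not None:
        state._require_layer_aligned(suitability)

    occ = state.occupied()
    state.age[occ] += 1

    p = _sdd_prob_field(state, params, strong_barriers)
    candidates = state.colonizable()
    if suitability is not None:
        if continuous:
            p = p * np.clip(suitability.values, 0.0, 1.0)
        else:
            candidates &= suitability.values >= invasibility_threshold
    draws = rng.random(state.shape)
    new_sdd = candidates & (draws < p)

    for tr, tc in ldd_events(state, params, rng, suitability,
                             invasibility_threshold, continuous, strong_barriers):
        new_sdd[tr, tc] = True

    new_sdd &= state.colonizable()  # paranoia: never overwrite barrier/unsuitable
    state.status[new_sdd] = STATUS_OCCUPIED
    state.age[new_sdd] = 0
    return state


def update_suitability(state: CellStateGrid, stack: SuitabilityStack,
                       year: int, decolonize: bool = True) -> CellStateGrid:
    """Apply the suitability layer active in ``year`` to the state.

    When decolonization is enabled (MigClim-like), occupied cells whose new
    suitability falls below the stack's invasibility threshold become
    decolonized (status 2, recolonizable later). Returns the state.
    """
    layer = stack.layer_for(year)
    state._require_layer_aligned(layer)
    if decolonize:
        doomed = state.occupied() & (layer.values < stack.invasibility_threshold)
        state.status[doomed] = STATUS_DECOLONIZED
        state.age[doomed] = 0
    return state


# -- full simulation --------------------------------------------------------


@dataclass
class SimulationResult:
    """Trajectories of a replicated dispersal simulation.

    ``occupancy`` has shape (n_replicates, horizon+1, nrows, ncols) and
    stores the occupied mask after each year (index 0 = initial state).
    ``pct_suitable`` is the percentage of currently-suitable colonizable
    cells that are colonized, per replicate and year.
    """

    years: np.ndarray
    occupancy: np.ndarray
    colonized_counts: np.ndarray
    pct_suitable: np.ndarray
    params: DispersalParams
    master_seed: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = "local-m"

    @property
    def n_replicates(self) -> int:
        return self.occupancy.shape[0]

    def final_occupancy(self, replicate: int) -> RasterLayer:
        return RasterLayer(
            values=self.occupancy[replicate, -1].astype(np.int64),
            origin_x=self.origin[0], origin_y=self.origin[1],
            cell_size=self.cell_size, crs_tag=self.crs_tag,
        )

    def summary(self) -> "np.ndarray":
        """Mean percent-colonized trajectory across replicates."""
        return self.pct_suitable.mean(axis=0)


def _replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((master_seed, replicate))))


def run_simulation(init: RasterLayer, stack: SuitabilityStack,
                   landcover: RasterLayer | None, params: DispersalParams,
                   horizon_years: int = 60, *, master_seed: int | None = None,
                   decolonize: bool = True, continuous: bool = False,
                   strong_barriers: bool = False) -> SimulationResult:
    """Run ``params.n_replicates`` seeded replicates of the annual CA.

    Parameters
    ----------
    init : RasterLayer
        Initial occupancy (nonzero = occupied); typically from
        :func:`build_initial_distribution`. Initial cells start mature.
    stack : SuitabilityStack
        Suitability layers by period start year; also carries the
        invasibility threshold.
    landcover : RasterLayer or None
        Integer class raster (forest barrier, built-up/paddy/water
        unsuitable); None means an unconstrained open grid.
    horizon_years : int
        Number of annual steps after the initial year.
    master_seed : int, optional
        Defaults to ``params.seed``; replicate r uses
        ``SeedSequence((master_seed, r))``.
    """
    if landcover is not None:
        require_aligned(init, landcover, stack.periods[0][1])
    else:
        require_aligned(init, stack.periods[0][1])
    if master_seed is None:
        master_seed = params.seed

    def base_state() -> CellStateGrid:
        st = (CellStateGrid.from_landcover(landcover) if landcover is not None
              else CellStateGrid(
                  status=np.zeros(init.shape, dtype=np.uint8),
                  age=np.zeros(init.shape, dtype=np.int32),
                  origin_x=init.origin_x, origin_y=init.origin_y,
                  cell_size=init.cell_size, crs_tag=init.crs_tag))
        st.seed_occupancy(init, age=params.maturity_age)
        return st

    year0 = stack.start_year
    years = np.arange(year0, year0 + horizon_years + 1)
    nrows, ncols = init.shape
    nrep = params.n_replicates
    occupancy = np.zeros((nrep, horizon_years + 1, nrows, ncols), dtype=bool)
    counts = np.zeros((nrep, horizon_years + 1), dtype=np.int64)
    pct = np.zeros((nrep, horizon_years + 1), dtype=float)

    for r in range(nrep):
        rng = _replicate_rng(master_seed, r)
        state = base_state()
        # decolonization applies only at period switches, never to the
        # surveyed initial distribution itself
        active = stack.layer_for(year0)

        def record(t):
            occ = state.occupied()
            occupancy[r, t] = occ
            counts[r, t] = occ.sum()
            suit_mask = (active.values >= stack.invasibility_threshold) & \
                (state.status != STATUS_BARRIER) & (state.status != STATUS_UNSUITABLE)
            nsuit = suit_mask.sum()
            pct[r, t] = 100.0 * (occ & suit_mask).sum() / nsuit if nsuit else 0.0

        record(0)
        for t in range(1, horizon_years + 1):
            year = year0 + t
            new_active = stack.layer_for(year)
            if new_active is not active:
                active = new_active
                update_suitability(state, stack, year, decolonize=decolonize)
            step_year(state, active, params, rng,
                      invasibility_threshold=stack.invasibility_threshold,
                      continuous=continuous, strong_barriers=strong_barriers)
            record(t)

    return SimulationResult(
        years=years, occupancy=occupancy, colonized_counts=counts,
        pct_suitable=pct, params=params, master_seed=master_seed,
        cell_size=init.cell_size, origin=(init.origin_x, init.origin_y),
        crs_tag=init.crs_tag,
    )


def percent_colonized(result: SimulationResult, suitable_mask: RasterLayer):
    """Percent of suitable cells colonized per year: mean and 95% CI.

    ``100 * |colonized ∩ suitable| / |suitable|`` per replicate and year,
    summarized across replicates with a normal-approximation confidence
    interval (mean ± 1.96 sd / sqrt(n)).

    Returns a pandas DataFrame with columns year, mean, ci_low, ci_high.
    """
    import pandas as pd

    mask = np.asarray(suitable_mask.values) > 0
    if suitable_mask.nodata is not None:
        mask &= suitable_mask.valid_mask
    nsuit = int(mask.sum())
    if nsuit == 0:
        raise SpreadcaError("suitable mask is empty")
    frac = 100.0 * (result.occupancy & mask).sum(axis=(2, 3)) / nsuit
    mean = frac.mean(axis=0)
    n = frac.shape[0]
    sd = frac.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    half = 1.96 * sd / np.sqrt(n)
    return pd.DataFrame({
        "year": result.years, "mean": mean,
        "ci_low": mean - half, "ci_high": mean + half,
    })
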