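"""Desk-scale spatially explicit individual-based population engine.

Population dynamics emerge from per-individual rules on the patch mosaic.
The annual cycle is breed -> disperse -> overwinter -> census:

1. *Breeding*: each adult on habitat type ``h`` produces offspring drawn
   Poisson with mean ``r_max * fecundity[h] * w_y * max(0, 1 - n/(kappa[h] *
   patch_area))`` where ``n`` is the patch's current adult count —
   emergent logistic density dependence.  Avoidance-archetype adults
   (skylark) within the avoidance radius of trees do not breed.
   Semelparous adults (beetle, spider) die after breeding.
2. *Dispersal*: every juvenile draws a uniform direction and a uniform
   distance on [0, d_max].  Short dispersers stop at the cell before the
   first barrier cell on the straight (cell-center rasterized) path;
   fliers/ballooners cross barriers freely but settle on the last
   non-barrier cell of the path.  Each disperser dies with probability
   ``dispersal_mortality``.
3. *Overwinter*: each individual survives with the probability attached
   to its cell's habitat type; complementation-archetype individuals
   (beetle) survive only if habitat of the complementation types lies
   within the complementation radius.  Survivors are next year's adults.

All stochastic draws are seeded; extinction is a valid state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .landscape import Landscape
from .species import SpeciesParams

__all__ = ["Population", "SimulationContext", "init_population", "step_year", "census"]

_JUVENILE, _ADULT = 0, 1


@dataclass
class Population:
    """Individuals with cell locations and age classes, as flat arrays."""

    rows: np.ndarray
    cols: np.ndarray
    ages: np.ndarray  # 0 = juvenile, 1 = adult

    @classmethod
    def empty(cls) -> "Population":
        z = np.empty(0, dtype=np.int32)
        return cls(z, z.copy(), z.copy())

    def __len__(self) -> int:
        return int(self.rows.size)

    def to_frame(self) -> pd.DataFrame:
        """Debug dump: one row per individual (id, row, col, age)."""
        return pd.DataFrame(
            {
                "id": np.arange(len(self)),
                "row": self.rows,
                "col": self.cols,
                "age": np.where(self.ages == _ADULT, "adult", "juvenile"),
            }
        )


class SimulationContext:
    """Per-(landscape, species) precomputation reused across yearly steps."""

    def __init__(self, landscape: Landscape, species: SpeciesParams):
        self.landscape = landscape
        self.species = species
        grid = landscape.grid
        ids = landscape.patches.index.to_numpy()
        maxid = int(ids.max()) + 1

        self.patch_grid = grid
        self.barrier = landscape.barrier_mask()
        types = landscape.patches["type_code"]

        def cell_map(per_type: dict, default=0.0) -> np.ndarray:
            lut = np.zeros(maxid, dtype=float)
            lut[ids] = types.map(lambda t: per_type.get(t, default)).to_numpy(float)
            return lut[grid]

        self.fecundity = cell_map(dict(species.fecundity_multiplier))
        self.survival = cell_map(dict(species.overwinter_survival))
        self.capacity = cell_map(dict(species.capacity_density))
        self.fecundity[self.barrier] = 0.0
        self.survival[self.barrier] = 0.0

        area_lut = np.zeros(maxid, dtype=float)
        area_lut[ids] = landscape.patches["area_cells"].to_numpy(float)
        self.patch_area = area_lut
        kappa_lut = np.zeros(maxid, dtype=float)
        kappa_lut[ids] = types.map(
            lambda t: dict(species.capacity_density).get(t, 0.0)
        ).to_numpy(float)
        self.patch_kappa_area = kappa_lut * area_lut  # kappa[h] * patch_area

        self.breed_ok = ~self.barrier
        if species.avoidance_types and species.avoidance_radius > 0:
            avoid_src = np.isin(grid, ids[types.isin(species.avoidance_types).to_numpy()])
            d = ndimage.distance_transform_edt(~avoid_src)
            self.breed_ok &= d > species.avoidance_radius

        self.winter_ok = np.ones(grid.shape, bool)
        if species.complementation_types and species.complementation_radius > 0:
            comp_src = np.isin(grid, ids[types.isin(species.complementation_types).to_numpy()])
            d = ndimage.distance_transform_edt(~comp_src)
            self.winter_ok = d <= species.complementation_radius

        self.habitable = (self.fecundity > 0) & ~self.barrier


def init_population(
    landscape: Landscape,
    species: SpeciesParams,
    initial_density: float,
    seed: int = 0,
    ctx: SimulationContext | None = None,
) -> Population:
    """Place adults uniformly at random on habitable cells.

    ``initial_density`` is individuals per habitable cell (cells whose
    type has a positive fecundity multiplier); the total is rounded to
    nearest.  Deterministic given ``seed``.
    """
    if initial_density < 0:
        raise ValueError("initial_density must be >= 0")
    ctx = ctx or SimulationContext(landscape, species)
    cells = np.flatnonzero(ctx.habitable.ravel())
    if cells.size == 0:
        raise ValueError(f"no habitable cell for species {species.name!r}")
    n = int(np.rint(initial_density * cells.size))
    if n == 0:
        return Population.empty()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen = rng.choice(cells, size=n, replace=True)
    r, c = np.divmod(chosen, landscape.shape[1])
    return Population(r.astype(np.int32), c.astype(np.int32), np.full(n, _ADULT, np.int32))


def census(population: Population) -> int:
    """Total individual count (taken at year start, post-overwinter)."""
    return len(population)


def _disperse(
    rows: np.ndarray,
    cols: np.ndarray,
    ctx: SimulationContext,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized straight-line dispersal; returns settled positions."""
    sp = ctx.species
    n = rows.size
    if n == 0 or sp.d_max == 0:
        return rows, cols
    nrows, ncols = ctx.patch_grid.shape
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    dist = rng.uniform(0.0, float(sp.d_max), n)
    dr = dist * np.sin(theta)
    dc = dist * np.cos(theta)
    if not sp.barriers_block:
        # fliers: jump straight to the endpoint; only those landing out of
        # bounds or on a barrier need the path walked back
        tr = np.rint(rows + dr).astype(np.int64)
        tc = np.rint(cols + dc).astype(np.int64)
        inb = (tr >= 0) & (tr < nrows) & (tc >= 0) & (tc < ncols)
        good = inb.copy()
        good[inb] = ~ctx.barrier[tr[inb], tc[inb]]
        out_r = np.where(good, tr, rows).astype(np.int32)
        out_c = np.where(good, tc, cols).astype(np.int32)
        bad = np.flatnonzero(~good)
        if bad.size:
            br, bc = _walk_paths(rows[bad], cols[bad], dr[bad], dc[bad], ctx, sticky=False)
            out_r[bad] = br
            out_c[bad] = bc
        return out_r, out_c
    return _walk_paths(rows, cols, dr, dc, ctx, sticky=True)


def _walk_paths(rows, cols, dr, dc, ctx, sticky: bool):
    """Walk rasterized straight paths; settle on the last valid cell.

    ``sticky`` (short dispersers): stop permanently at the cell before the
    first barrier or edge.  Non-sticky (fliers): skip invalid samples and
    keep the last in-bounds non-barrier cell of the path.
    """
    nrows, ncols = ctx.patch_grid.shape
    n = rows.size
    nsteps = np.maximum(1, np.ceil(np.maximum(np.abs(dr), np.abs(dc)))).astype(int)
    kmax = int(nsteps.max())
    cur_r = rows.astype(np.int64).copy()
    cur_c = cols.astype(np.int64).copy()
    blocked = np.zeros(n, bool)
    r0 = rows.astype(float)
    c0 = cols.astype(float)
    for k in range(1, kmax + 1):
        act = (k <= nsteps) & ~blocked
        if not act.any():
            break
        frac = k / nsteps[act]
        rr = np.rint(r0[act] + frac * dr[act]).astype(np.int64)
        cc = np.rint(c0[act] + frac * dc[act]).astype(np.int64)
        inb = (rr >= 0) & (rr < nrows) & (cc >= 0) & (cc < ncols)
        hit_barrier = np.zeros(rr.shape, bool)
        hit_barrier[inb] = ctx.barrier[rr[inb], cc[inb]]
        ok = inb & ~hit_barrier
        ai = np.flatnonzero(act)
        cur_r[ai[ok]] = rr[ok]
        cur_c[ai[ok]] = cc[ok]
        if sticky:
            blocked[ai[~ok]] = True
    return cur_r.astype(np.int32), cur_c.astype(np.int32)


def step_year(
    population: Population,
    landscape: Landscape,
    species: SpeciesParams,
    w_y: float = 1.0,
    seed: int = 0,
    ctx: SimulationContext | None = None,
) -> Population:
    """Advance the population one year: breed, disperse, overwinter.

    ``w_y`` is the weather-year fecundity multiplier (> 0).  Passing a
    prebuilt :class:`SimulationContext` avoids recomputing per-landscape
    masks inside multi-year loops.
    """
    if w_y <= 0:
        raise ValueError("weather multiplier w_y must be positive")
    ctx = ctx or SimulationContext(landscape, species)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    adults = population.ages == _ADULT
    ar, ac = population.rows[adults], population.cols[adults]

    # --- breeding -----------------------------------------------------
    if ar.size:
        pid = ctx.patch_grid[ar, ac]
        n_patch = np.bincount(pid, minlength=ctx.patch_area.size)
        cap = ctx.patch_kappa_area[pid]
        with np.errstate(divide="ignore", invalid="ignore"):
            room = np.where(cap > 0, 1.0 - n_patch[pid] / cap, 0.0)
        rate = species.r_max * ctx.fecundity[ar, ac] * w_y * np.clip(room, 0.0, None)
        rate[~ctx.breed_ok[ar, ac]] = 0.0
        n_off = rng.poisson(rate)
        jr = np.repeat(ar, n_off).astype(np.int32)
        jc = np.repeat(ac, n_off).astype(np.int32)
    else:
        jr = jc = np.empty(0, np.int32)

    # --- dispersal of juveniles ---------------------------------------
    jr, jc = _disperse(jr, jc, ctx, rng)
    if jr.size and species.dispersal_mortality > 0:
        alive = rng.random(jr.size) >= species.dispersal_mortality
        jr, jc = jr[alive], jc[alive]

    # --- overwinter ---------------------------------------------------
    if species.semelparous:
        wr, wc = jr, jc
    else:
        wr = np.concatenate([ar, jr]).astype(np.int32)
        wc = np.concatenate([ac, jc]).astype(np.int32)
    if wr.size:
        p = ctx.survival[wr, wc] * ctx.winter_ok[wr, wc]
        alive = rng.random(wr.size) < p
        wr, wc = wr[alive], wc[alive]
    return Population(wr, wc, np.full(wr.size, _ADULT, np.int32))
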