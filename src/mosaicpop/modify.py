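"""Complexity-reduction transforms producing landscape variants B, C, D.

Starting from a structured variant-A mosaic, landscape complexity is
progressively removed:

* B — *shape homogenization*: every habitat patch is re-grown as a compact
  blob from its original centroid, conserving identifier, type and (up to
  an enclosure-deadlock correction) area.  Elongated corridor patches are
  thereby destroyed while patch sizes and locations are retained.
* C — *arrangement randomization*: type labels are permuted uniformly at
  random among habitat patches within each quarter-decade size class, so
  configuration is scrambled while composition (relative cover) is
  conserved up to within-class area spread.
* D — *size randomization*: type labels are permuted over all habitat
  patches irrespective of size, so the expected cover of a type becomes
  proportional to its patch-count frequency and composition changes.

Barrier patches (roads, rivers, buildings, lakes, railways) are never
touched by any transform.
"""

from __future__ import annotations

import logging

import numpy as np

from ._rebalance import rebalance_areas
from ._rng import child_rng
from .landscape import (
    Landscape,
    _areas_from_grid,
    _centroids_from_grid,
    grow_patches,
    patch_table,
)

__all__ = [
    "homogenize_shapes",
    "randomize_arrangement",
    "randomize_sizes",
    "make_variants",
]

logger = logging.getLogger(__name__)


class PatchSeedError(RuntimeError):
    """A patch's growth seed cell could not be claimed."""


def homogenize_shapes(landscape: Landscape, seed: int = 0) -> Landscape:
    """Variant-B transform: re-grow every habitat patch compactly in place.

    Each non-barrier patch is seeded at its original centroid (snapped to
    the nearest original member cell) and the free space is re-tiled by
    stochastic region growing: at every step a patch is selected with
    probability proportional to the fraction it remains to grow and claims
    one uniformly chosen unclaimed adjacent cell, so patches near their
    original size grow slowly.  Patch identifiers, types and areas are
    conserved; barrier cells are bit-identical to the input.  Patches
    enclosed before reaching their target are frozen; a rebalancing pass
    then shifts surplus cells back to deficit patches along the
    patch-adjacency graph, so areas are conserved exactly except for the
    rare patch sealed away from any surplus (residual reported in
    ``meta['area_deficit_cells']``).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    barrier = landscape.barrier_mask()
    free = ~barrier
    hab = landscape.patches[~landscape.patches["barrier"]]

    seeds: dict[int, tuple] = {}
    taken = set()
    for pid, rec in hab.iterrows():
        member = np.flatnonzero((landscape.grid == pid).ravel())
        rr, cc = np.unravel_index(member, landscape.shape)
        d2 = (rr - rec["centroid_row"]) ** 2 + (cc - rec["centroid_col"]) ** 2
        order = np.argsort(d2, kind="stable")
        cell = None
        for j in order:
            cand = (int(rr[j]), int(cc[j]))
            if cand not in taken:
                cell = cand
                break
        if cell is None:
            raise PatchSeedError(
                f"patch {pid}: all centroid-adjacent space exhausted, seed unclaimable"
            )
        taken.add(cell)
        seeds[int(pid)] = cell

    targets = hab["area_cells"].astype(int).to_dict()
    owner, _ = grow_patches(free, seeds, targets, rng)
    grid = np.where(owner >= 0, owner, landscape.grid)
    # growth deadlocks leave some patches short; shift surplus cells back
    # toward deficit patches along the patch-adjacency graph
    deficit = rebalance_areas(grid, free, targets)

    tab = landscape.patches[["type_code", "barrier"]].copy()
    ids = tab.index.to_numpy()
    tab["area_cells"] = _areas_from_grid(grid, ids)
    cent = _centroids_from_grid(grid, ids)
    tab["centroid_row"] = cent[:, 0]
    tab["centroid_col"] = cent[:, 1]
    out = Landscape(grid, tab, landscape.cell_size, dict(landscape.meta))
    out.meta.update(
        {
            "variant": "B",
            "homogenize_seed": int(seed),
            "area_deficit_cells": int(sum(abs(v) for v in deficit.values())),
        }
    )
    return out


def _permute_types(landscape: Landscape, perm_groups, seed: int, variant: str) -> Landscape:
    """Permute type labels among habitat patches within each given id group."""
    rng = child_rng(seed, "type-permutation", variant)
    tab = landscape.patches.copy()
    types = tab["type_code"].copy()
    for ids in perm_groups:
        if len(ids) < 2:
            if len(ids) == 1:
                logger.info("variant %s: singleton group, patch %s keeps its type", variant, ids[0])
            continue
        ids = np.asarray(ids)
        perm = rng.permutation(len(ids))
        types.loc[ids] = types.loc[ids].to_numpy()[perm]
    tab["type_code"] = types
    out = Landscape(landscape.grid.copy(), tab, landscape.cell_size, dict(landscape.meta))
    out.meta.update({"variant": variant, f"permutation_seed_{variant}": int(seed)})
    return out


def randomize_arrangement(
    landscape: Landscape, seed: int = 0, cover_tolerance: float = 0.05
) -> Landscape:
    """Variant-C transform: interchange types among same-size-class patches.

    The grid (patch geometry and identifiers) is unchanged; only type
    labels move, permuted uniformly at random within each quarter-decade
    size class of habitat patches.  Barrier patches never participate.
    Size classes holding a single habitat patch keep their type (logged,
    not an error).  Relative cover per type is conserved only up to the
    within-class area spread; a per-type relative change beyond
    ``cover_tolerance`` is logged as a warning.
    """
    from .landscape import relative_cover

    tab = patch_table(landscape)
    hab = tab[~tab["barrier"]]
    groups = [sub.index.to_numpy() for _, sub in hab.groupby("size_class", sort=True)]
    out = _permute_types(landscape, groups, seed, "C")
    before, after = relative_cover(landscape), relative_cover(out)
    for t, f in before.items():
        if f > 0 and abs(after.get(t, 0.0) - f) / f > cover_tolerance:
            logger.warning(
                "variant C: cover of %s changed by %.1f%% (tolerance %.0f%%)",
                t, 100 * abs(after.get(t, 0.0) - f) / f, 100 * cover_tolerance,
            )
    return out


def randomize_sizes(landscape: Landscape, seed: int = 0) -> Landscape:
    """Variant-D transform: interchange types among all habitat patches.

    As :func:`randomize_arrangement` but ignoring size classes, so the
    expected cover of each type becomes its patch-count frequency times
    the habitat area.
    """
    hab = landscape.patches[~landscape.patches["barrier"]]
    return _permute_types(landscape, [hab.index.to_numpy()], seed, "D")


def make_variants(landscape_A: Landscape, seed: int = 0) -> dict:
    """Build the full variant chain {A, B, C, D} from a variant-A landscape.

    B = homogenize_shapes(A); C = randomize_arrangement(B);
    D = randomize_sizes(C).  Each stage gets an independent sub-seed
    derived from ``seed`` by stage name, so stages are independently
    replayable.
    """
    from ._rng import child_seed

    A = landscape_A
    B = homogenize_shapes(A, seed=child_seed(seed, "homogenize"))
    C = randomize_arrangement(B, seed=child_seed(seed, "arrangement"))
    D = randomize_sizes(C, seed=child_seed(seed, "sizes"))
    return {"A": A, "B": B, "C": C, "D": D}
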