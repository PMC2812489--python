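"""Perturbation–recovery protocol: schedule, removal, trajectories, designs.

A run simulates 181 annual cycles.  The first 11 years are burn-in and
flagged as excluded from analysis; the remaining 170 years form the
analyzed window.  Under a perturbed schedule, a fraction of all
individuals is removed at random immediately after the census of years
11, 28, …, 164 (every 17th year), so the first post-perturbation census
(time-since-perturbation t = 1) is the next year's and the analyzed
window splits into exactly 10 recovery segments of 17 years — the
population recovers 10 times.  A perturbation year's recorded census is
therefore always pre-removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_seed
from .ibm import Population, SimulationContext, census, init_population, step_year
from .landscape import Landscape
from .modify import homogenize_shapes, randomize_arrangement, randomize_sizes
from .species import SpeciesParams, WeatherSequence, make_archetype

__all__ = [
    "Schedule",
    "Trajectory",
    "ExperimentDesign",
    "RunResult",
    "perturb",
    "run_experiment",
    "segment_trajectory",
    "run_design",
    "replicate_landscapes",
]

STANDARD_FRACTIONS = (0.0, 0.80, 0.95)


@dataclass(frozen=True)
class Schedule:
    """Perturbation–recording design.

    Defaults: 181 total years, 11 burn-in years, removal every 17th year,
    so the analyzed window holds 170 yearly censuses and 10 complete
    recovery windows.
    """

    total_years: int = 181
    burn_in_years: int = 11
    perturbation_interval: int = 17
    removal_fraction: float = 0.95

    def __post_init__(self):
        if not 0.0 <= self.removal_fraction <= 1.0:
            raise ValueError("removal_fraction must be in [0, 1]")
        if self.removal_fraction > 0:
            span = self.total_years - self.burn_in_years
            if span % self.perturbation_interval != 0:
                raise ValueError(
                    "analyzed span (total - burn_in) must be divisible by the "
                    f"perturbation interval; got {span} / {self.perturbation_interval}"
                )

    @property
    def n_perturbations(self) -> int:
        if self.removal_fraction == 0:
            return 0
        return (self.total_years - self.burn_in_years) // self.perturbation_interval

    @property
    def perturbation_years(self) -> tuple:
        """Years whose census is immediately followed by a removal."""
        return tuple(
            self.burn_in_years + k * self.perturbation_interval
            for k in range(self.n_perturbations)
        )


@dataclass
class Trajectory:
    """Yearly census series with weather labels and recovery bookkeeping.

    ``records`` has one row per simulated year: year, N, weather_label,
    perturbed (removal applied right after this census), analyzed
    (outside burn-in), segment (0-based recovery-window index, -1 during
    burn-in or for unperturbed runs) and t (years since the last
    perturbation, 1..interval; NaN outside segments).
    """

    records: pd.DataFrame
    schedule: Schedule
    extinct: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def analyzed(self) -> pd.DataFrame:
        return self.records[self.records["analyzed"]]

    @property
    def n_perturbations(self) -> int:
        """Perturbation events whose recovery window lies in the analyzed period."""
        return int(self.records["perturbed"].sum())


def perturb(population: Population, fraction: float, seed: int = 0) -> Population:
    """Remove a fraction of all individuals at random.

    Exactly ``round((1 - fraction) * N)`` survivors are retained, chosen
    uniformly without replacement, so removal intensity is not itself a
    noise source; the survivors are spatially unbiased.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n = len(population)
    keep = int(np.rint((1.0 - fraction) * n))
    if keep >= n:
        return population
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx = rng.choice(n, size=keep, replace=False)
    idx.sort()
    return Population(population.rows[idx], population.cols[idx], population.ages[idx])


def run_experiment(
    landscape: Landscape,
    species: SpeciesParams,
    schedule: Schedule,
    seed: int = 0,
    weather: WeatherSequence | None = None,
    initial_density: float = 0.5,
    ctx: SimulationContext | None = None,
) -> Trajectory:
    """Simulate the full perturbation–recovery protocol on one landscape.

    Census is taken at the start of each year; on perturbation years the
    removal is applied immediately after the census (the recorded N is
    pre-removal).  Extinction completes the trajectory with zeros and is
    flagged.
    """
    weather = weather or WeatherSequence.lognormal(seed=child_seed(seed, "weather"))
    ctx = ctx or SimulationContext(landscape, species)
    pop = init_population(landscape, species, initial_density, child_seed(seed, "init"), ctx=ctx)
    pert_years = set(schedule.perturbation_years)
    events = sorted(pert_years)
    rows = []
    for year in range(1, schedule.total_years + 1):
        n = census(pop)
        is_pert = year in pert_years
        analyzed = year > schedule.burn_in_years
        seg, t = -1, np.nan
        past = [e for e in events if e < year]
        if past and analyzed:
            seg = len(past) - 1
            t = year - past[-1]
            if t > schedule.perturbation_interval:
                seg, t = -1, np.nan
        rows.append((year, n, weather.label_for_year(year), is_pert, analyzed, seg, t))
        if is_pert:
            pop = perturb(pop, schedule.removal_fraction, child_seed(seed, "perturb", year))
        pop = step_year(
            pop, landscape, species, weather.multiplier_for_year(year),
            seed=child_seed(seed, "step", year), ctx=ctx,
        )
    rec = pd.DataFrame(
        rows, columns=["year", "N", "weather_label", "perturbed", "analyzed", "segment", "t"]
    )
    extinct = bool((rec.loc[rec["analyzed"], "N"] == 0).any())
    return Trajectory(rec, schedule, extinct=extinct, meta={"seed": int(seed), "species": species.name})


def segment_trajectory(trajectory: Trajectory) -> list:
    """Split the analyzed trajectory into per-perturbation recovery segments.

    Each segment is a DataFrame with columns t (1..interval), N, lnN and
    weather_label; zero-count years keep their row with lnN = NaN (an
    undefined-log marker counted, never silently dropped).
    """
    if trajectory.schedule.removal_fraction == 0:
        raise ValueError(
            "trajectory is unperturbed; use the unperturbed equilibrium fit instead"
        )
    segs = []
    rec = trajectory.records
    for k in sorted(rec.loc[rec["segment"] >= 0, "segment"].unique()):
        sub = rec[rec["segment"] == k].copy()
        with np.errstate(divide="ignore"):
            sub["lnN"] = np.where(sub["N"] > 0, np.log(sub["N"].astype(float)), np.nan)
        segs.append(sub[["t", "N", "lnN", "weather_label", "year"]].reset_index(drop=True))
    return segs


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial of species x removal intensity x landscape variant."""

    species: tuple = ("beetle", "vole", "skylark", "spider")
    intensities: tuple = STANDARD_FRACTIONS
    variants: tuple = ("A", "B", "C", "D")
    master_seed: int = 0
    total_years: int = 181
    burn_in_years: int = 11
    perturbation_interval: int = 17

    def cells(self) -> list:
        """Enumerate every design cell exactly once, with its sub-seed."""
        out = []
        for sp in self.species:
            for frac in self.intensities:
                for var in self.variants:
                    out.append(
                        {
                            "species": sp,
                            "intensity": float(frac),
                            "variant": var,
                            "seed": child_seed(self.master_seed, "cell", sp, f"{frac:.2f}", var),
                        }
                    )
        return out

    @property
    def n_cells(self) -> int:
        return len(self.species) * len(self.intensities) * len(self.variants)


@dataclass
class RunResult:
    descriptor: dict
    trajectory: Trajectory


def run_design(
    design: ExperimentDesign,
    landscapes: dict,
    weather: WeatherSequence | None = None,
    initial_density: float = 0.5,
) -> list:
    """Run every design cell; failures are recorded per cell, not raised.

    ``landscapes`` maps variant labels to Landscape objects.  One weather
    sequence (derived from the master seed unless given) is shared by all
    cells so weather years are comparable across the design.
    """
    weather = weather or WeatherSequence.lognormal(seed=child_seed(design.master_seed, "weather"))
    ctx_cache: dict = {}
    results = []
    for cell in design.cells():
        try:
            ls = landscapes[cell["variant"]]
            key = (cell["variant"], cell["species"])
            if key not in ctx_cache:
                ctx_cache[key] = SimulationContext(ls, make_archetype(cell["species"]))
            ctx = ctx_cache[key]
            sched = Schedule(
                design.total_years,
                design.burn_in_years,
                design.perturbation_interval,
                cell["intensity"],
            )
            traj = run_experiment(
                ls, ctx.species, sched, seed=cell["seed"], weather=weather,
                initial_density=initial_density, ctx=ctx,
            )
            results.append(RunResult({**cell, "error": None}, traj))
        except Exception as exc:  # noqa: BLE001 — per-cell isolation is the contract
            results.append(RunResult({**cell, "error": str(exc)}, None))
    return results


def replicate_landscapes(
    landscape_A: Landscape, variant: str, n_replicates: int, seed: int = 0
) -> list:
    """Independently seeded replicate landscapes of one variant (B, C or D)."""
    if variant not in ("B", "C", "D"):
        raise ValueError("replicates exist only for variants B, C, D (A is deterministic)")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    out = []
    for i in range(n_replicates):
        # stage labels match make_variants, so replicate i of variant X equals
        # make_variants(A, child_seed(seed, "rep", i))[X]
        rep_seed = child_seed(seed, "rep", i)
        ls = homogenize_shapes(landscape_A, seed=child_seed(rep_seed, "homogenize"))
        if variant in ("C", "D"):
            ls = randomize_arrangement(ls, seed=child_seed(rep_seed, "arrangement"))
        if variant == "D":
            ls = randomize_sizes(ls, seed=child_seed(rep_seed, "sizes"))
        out.append(ls)
    return out
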