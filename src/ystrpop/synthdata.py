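"""Synthetic Y-STR data under the stepwise mutation model (SMM).

Generates integer repeat-count haplotypes descending from founders, with
single-step symmetric mutations (each mutation changes a repeat count by
±1 with equal probability).  Three generators are provided:

* star genealogies (every sampled lineage independent back to the founder
  at time t) — the shape assumed by ρ/TD founder dating;
* Kingman-coalescent genealogies (tree simulated with msprime, SMM
  mutations dropped on branches here) — for testing estimators off the
  star assumption;
* a full multi-population diaspora scenario: deep "source" expansions
  (hundreds of generations, high diversity) plus "focal" populations each
  founded from the source a few dozen generations ago (founder-effect
  bottleneck, low diversity), with the ground truth (founders, times)
  returned alongside.

All generators are fully deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .strdata import Dataset, LocusPanel, PopulationSample, STRHaplotype, YFILER_15_ANALYSIS

__all__ = [
    "SourceSpec",
    "FocalSpec",
    "SimulationConfig",
    "ScenarioTruth",
    "DEFAULT_FOUNDER",
    "simulate_star_population",
    "simulate_coalescent_population",
    "simulate_roma_scenario",
]

#: A plausible modal 15-locus Yfiler-style haplotype used as the default
#: ancestral state (DYS389II already scored minus DYS389I).
DEFAULT_FOUNDER = STRHaplotype((15, 13, 22, 17, 16, 15, 12, 10, 11, 21, 11, 11, 14, 10, 19))


def _smm_displacements(rng: np.random.Generator, mu: float, t: float, shape) -> np.ndarray:
    """Net displacement of a symmetric ±1 random walk with Poisson(mu*t) steps."""
    k = rng.poisson(mu * t, size=shape)
    up = rng.binomial(k, 0.5)
    return 2 * up - k


def _to_sample(name: str, group: str, matrix: np.ndarray, panel: LocusPanel | None) -> PopulationSample:
    if (matrix < 1).any():
        warnings.warn(
            f"population {name!r}: {(matrix < 1).sum()} repeat count(s) drifted "
            "below 1; floored at 1 in the output", stacklevel=3)
        matrix = np.maximum(matrix, 1)
    haps = Counter(STRHaplotype(tuple(int(x) for x in row)) for row in matrix)
    return PopulationSample(name, haps, group=group, panel=panel)


def simulate_star_population(n: int, t_gens: float, founder: STRHaplotype = DEFAULT_FOUNDER,
                             mu: float = 6.9e-4, seed: int | np.random.Generator = 0,
                             name: str = "star", group: str = "",
                             panel: LocusPanel | None = None) -> PopulationSample:
    """Sample n haplotypes from a star genealogy of depth ``t_gens``.

    Each individual's haplotype is the founder plus, at every locus, an
    independent SMM random walk of Poisson(mu * t_gens) steps.
    """
    if n < 1 or t_gens < 0 or mu < 0:
        raise ValueError("need n >= 1, t_gens >= 0 and mu >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = np.asarray(founder.repeats, dtype=np.int64)
    disp = _smm_displacements(rng, mu, t_gens, (n, base.shape[0]))
    return _to_sample(name, group, base[None, :] + disp, panel)


def simulate_coalescent_population(n: int, Ne: float, founder: STRHaplotype = DEFAULT_FOUNDER,
                                   mu: float = 6.9e-4, seed: int | np.random.Generator = 0,
                                   name: str = "coalescent", group: str = "",
                                   panel: LocusPanel | None = None) -> PopulationSample:
    """Sample n haplotypes from a Kingman coalescent of haploid size Ne.

    The genealogy is simulated with msprime (haploid, no recombination);
    SMM mutations are then dropped on each branch, Poisson(mu * branch
    length) per locus, starting from the founder haplotype at the root.
    """
    import msprime

    if n < 2 or Ne <= 0 or mu < 0:
        raise ValueError("need n >= 2, Ne > 0 and mu >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ms_seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(samples=n, ploidy=1, population_size=Ne,
                              random_seed=ms_seed)
    tree = ts.first()
    L = len(founder)
    haps = {tree.root: np.asarray(founder.repeats, dtype=np.int64)}
    for node in tree.nodes(order="preorder"):
        if node == tree.root:
            continue
        branch = tree.branch_length(node)
        haps[node] = haps[tree.parent(node)] + _smm_displacements(rng, mu, branch, L)
    matrix = np.vstack([haps[s] for s in ts.samples()])
    return _to_sample(name, group, matrix, panel)


# ---------------------------------------------------------------------------
# diaspora scenario

@dataclass(frozen=True)
class SourceSpec:
    """A deep source population: star expansion at ``t_expansion_gens``."""

    name: str
    n: int
    t_expansion_gens: float
    divergence_gens: float = 300.0  # drift of the regional founder from the ancestral state


@dataclass(frozen=True)
class FocalSpec:
    """A recently founded focal population (founder-effect bottleneck)."""

    name: str
    n: int
    n_founders: int = 1
    t_found_gens: float = 56.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the diaspora scenario.

    Defaults emulate the structure inferred for the Romani paternal
    lineage: three Indian-like source populations expanding 640–1000
    generations ago (16–25 KYA at 25 y/generation) and three Roma-like
    focal populations each founded by a single haplotype drawn from the
    designated source 56 generations (1400 y) ago.
    """

    L: int = 15
    mu: float = 6.9e-4
    generation_years: float = 25.0
    ancestral: STRHaplotype = DEFAULT_FOUNDER
    sources: tuple[SourceSpec, ...] = (
        SourceSpec("source_1", 40, 720.0),
        SourceSpec("source_2", 30, 640.0),
        SourceSpec("source_3", 30, 1000.0),
    )
    focal: tuple[FocalSpec, ...] = (
        FocalSpec("focal_1", 20),
        FocalSpec("focal_2", 30),
        FocalSpec("focal_3", 40),
    )
    source_of_focal: str = "source_1"

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.generation_years <= 0:
            raise ValueError("mu and generation_years must be positive")
        if len(self.ancestral) != self.L:
            raise ValueError("ancestral haplotype length must equal L")
        names = [s.name for s in self.sources] + [f.name for f in self.focal]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        if self.source_of_focal not in {s.name for s in self.sources}:
            raise ValueError(f"unknown source population {self.source_of_focal!r}")
        for s in self.sources:
            if s.n < 2 or s.t_expansion_gens <= 0:
                raise ValueError(f"bad source spec {s}")
        for f in self.focal:
            if f.n < 1 or f.n_founders < 1 or f.t_found_gens < 0:
                raise ValueError(f"bad focal spec {f}")


@dataclass
class ScenarioTruth:
    """Ground truth emitted next to a simulated scenario."""

    config: SimulationConfig
    source_founders: dict = field(default_factory=dict)    # source name -> repeat tuple
    focal_founders: dict = field(default_factory=dict)     # focal name -> list of repeat tuples
    founding_times_gens: dict = field(default_factory=dict)
    founding_times_years: dict = field(default_factory=dict)
    expansion_times_gens: dict = field(default_factory=dict)
    founder_assignment: dict = field(default_factory=dict)  # focal name -> founder idx per individual

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        cfg = d.pop("config")
        cfg["ancestral"] = list(self.config.ancestral.repeats)
        d["config"] = cfg
        d["source_founders"] = {k: list(v) for k, v in self.source_founders.items()}
        d["focal_founders"] = {k: [list(f) for f in v] for k, v in self.focal_founders.items()}
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=list)


def simulate_roma_scenario(config: SimulationConfig | None = None,
                           seed: int = 0) -> tuple[Dataset, ScenarioTruth]:
    """Simulate the multi-population founder scenario.

    Source populations are star expansions from regional founders (the
    ancestral haplotype plus regional drift); each focal population is
    founded by haplotype(s) drawn from the designated source population's
    sampled individuals and expands as a star from the founding time.
    Returns the dataset and the ground truth.
    """
    cfg = config or SimulationConfig()
    panel = YFILER_15_ANALYSIS if cfg.L == 15 else LocusPanel(
        tuple(f"L{i + 1}" for i in range(cfg.L)))
    ss = np.random.SeedSequence(seed)
    streams = {name: np.random.default_rng(child) for name, child in zip(
        [s.name for s in cfg.sources] + [f.name for f in cfg.focal] + ["founders"],
        ss.spawn(len(cfg.sources) + len(cfg.focal) + 1))}

    truth = ScenarioTruth(config=cfg)
    populations: list[PopulationSample] = []
    base = np.asarray(cfg.ancestral.repeats, dtype=np.int64)

    for s in cfg.sources:
        rng = streams[s.name]
        regional = base + _smm_displacements(rng, cfg.mu, s.divergence_gens, cfg.L)
        regional_hap = STRHaplotype(tuple(int(max(x, 1)) for x in regional))
        pop = simulate_star_population(s.n, s.t_expansion_gens, regional_hap, cfg.mu,
                                       seed=rng, name=s.name, group="source", panel=panel)
        populations.append(pop)
        truth.source_founders[s.name] = tuple(regional_hap.repeats)
        truth.expansion_times_gens[s.name] = s.t_expansion_gens

    source_pool = [h for h, c in populations[
        [s.name for s in cfg.sources].index(cfg.source_of_focal)].haplotypes.items()
        for _ in range(c)]
    frng = streams["founders"]

    for f in cfg.focal:
        rng = streams[f.name]
        founders = [source_pool[int(frng.integers(len(source_pool)))]
                    for _ in range(f.n_founders)]
        sizes = np.full(f.n_founders, f.n // f.n_founders)
        sizes[: f.n % f.n_founders] += 1
        mats, assign = [], []
        for k, (fh, sz) in enumerate(zip(founders, sizes)):
            if sz == 0:
                continue
            disp = _smm_displacements(rng, cfg.mu, f.t_found_gens,
                                      (int(sz), cfg.L))
            mats.append(np.asarray(fh.repeats, dtype=np.int64)[None, :] + disp)
            assign.extend([k] * int(sz))
        pop = _to_sample(f.name, "focal", np.vstack(mats), panel)
        populations.append(pop)
        truth.focal_founders[f.name] = [tuple(fh.repeats) for fh in founders]
        truth.founding_times_gens[f.name] = f.t_found_gens
        truth.founding_times_years[f.name] = f.t_found_gens * cfg.generation_years
        truth.founder_assignment[f.name] = assign

    return Dataset(panel, populations), truth
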