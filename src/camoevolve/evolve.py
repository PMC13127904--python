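"""Experiment orchestration: the genetic algorithm across habitats,
lighting treatments and generations.

Each of ``n_habitats x len(treatments)`` populations of 24 genomes plays
generations 0..20 in lock step: every individual is rendered into a scene
of its habitat (all scenes of the set used once per generation; MIXED
treatments split 12 direct / 12 diffuse), measured, and assigned a
survival time by the synthetic observer.  After each play the lowest 50%
die - except that the previous generation's top four carry a lifeline -
and the survivors produce offspring by random pairing, uniform
recombination and reflected Gaussian mutation.

All randomness flows from one master seed through named child streams, so
identical seeds give byte-identical evolution records.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
import pandas as pd
import yaml

from . import genome as ge
from . import observer as ob
from .metrics import measure_stimulus
from .pattern_gen import skin_from_genome
from .renderer import composite_target, place_target
from .scene_synth import habitat_library, make_scene_set

TREATMENTS = ("DIRECT", "DIFFUSE", "MIXED")


@dataclasses.dataclass
class ExperimentConfig:
    n_habitats: int = 28
    treatments: tuple[str, ...] = TREATMENTS
    population_size: int = 24
    generations: int = 20  # populations play generations 0..generations
    mortality: float = 0.5
    lifeline: int = 4
    scenes_per_population: int = 24
    scene_size: tuple[int, int] = (744, 952)
    target_diameter: int = 80
    skin_size: int = 256
    rd_grid: int = 128
    rd_max_steps: int = 3000
    mutation_rate: float = 0.10
    mutation_sigma: float = 0.05
    calibration_genomes: int = 100
    master_seed: int = 0
    observer: dict = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        deaths = self.mortality * self.population_size
        if abs(deaths - round(deaths)) > 1e-9:
            raise ValueError("mortality x population size must be an integer")
        if self.lifeline >= self.population_size - int(round(deaths)):
            raise ValueError("lifeline count must be below the survivor count")
        for t in self.treatments:
            if t not in TREATMENTS:
                raise ValueError(f"unknown treatment {t!r}")

    @property
    def n_deaths(self) -> int:
        return int(round(self.mortality * self.population_size))

    @property
    def n_survivors(self) -> int:
        return self.population_size - self.n_deaths

    @classmethod
    def reduced(cls, master_seed: int = 0, **overrides) -> "ExperimentConfig":
        """Desk-scale configuration: 3 habitats, small scenes and skins.

        Used for the property runs; the evolutionary design (24 targets,
        20 generations, 50% mortality, top-4 lifeline) is unchanged.
        """
        kw = dict(
            n_habitats=3, scene_size=(288, 352), target_diameter=40,
            skin_size=64, rd_grid=64, rd_max_steps=800,
            calibration_genomes=100, master_seed=master_seed,
        )
        kw.update(overrides)
        return cls(**kw)

    def to_yaml(self, path: str | pathlib.Path) -> None:
        d = dataclasses.asdict(self)
        d["treatments"] = list(d["treatments"])
        d["scene_size"] = list(d["scene_size"])
        pathlib.Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "ExperimentConfig":
        d = yaml.safe_load(pathlib.Path(path).read_text())
        d["treatments"] = tuple(d.get("treatments", TREATMENTS))
        d["scene_size"] = tuple(d["scene_size"])
        return cls(**d)


def design_summary(config: ExperimentConfig) -> dict[str, int]:
    """Design arithmetic for a configuration, without running anything.

    A population plays once per generation 0..generations; each play
    presents every member once.
    """
    config.validate()
    n_pops = config.n_habitats * len(config.treatments)
    plays = n_pops * (config.generations + 1)
    return {
        "populations": n_pops,
        "plays": plays,
        "trials": plays * config.population_size,
        "deaths_per_generation": config.n_deaths,
        "survivors_per_generation": config.n_survivors,
    }


# ---------------------------------------------------------------------------
# selection and reproduction

def select(
    members: list[ge.Genome],
    fitness: np.ndarray,
    lifeline_indices: set[int],
    n_survivors: int,
    rng: np.random.Generator,
) -> list[int]:
    """Indices of the survivors, best rank first.

    Members are ranked by fitness (longer survival = fitter); the previous
    generation's top-``lifeline`` members (given by index) are immortal;
    the lowest-ranked mortal members die until exactly ``n_survivors``
    remain.  Ties are broken by the seeded RNG.
    """
    n = len(members)
    if len(fitness) != n:
        raise ValueError("fitness length does not match population size")
    order = np.lexsort((rng.random(n), -np.asarray(fitness, dtype=float)))
    deaths_needed = n - n_survivors
    dead: set[int] = set()
    for idx in order[::-1]:  # worst first
        if len(dead) == deaths_needed:
            break
        if int(idx) in lifeline_indices:
            continue
        dead.add(int(idx))
    return [int(i) for i in order if int(i) not in dead]


def next_generation(
    survivors: list[ge.Genome],
    n_offspring: int,
    rng: np.random.Generator,
    mutation_rate: float = 0.10,
    mutation_sigma: float = 0.05,
) -> list[ge.Genome]:
    """Offspring from random pairing + recombination + mutation of the
    survivors."""
    kids = []
    for _ in range(n_offspring):
        i, j = rng.choice(len(survivors), size=2, replace=False)
        child = ge.recombine(survivors[i], survivors[j], rng)
        kids.append(ge.mutate(child, mutation_rate, mutation_sigma, rng))
    return kids


# ---------------------------------------------------------------------------
# the experiment

@dataclasses.dataclass
class EvolutionRecord:
    trials: pd.DataFrame
    config: dict

    def save(self, out_dir: str | pathlib.Path) -> pathlib.Path:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(out / "trials.csv", index=False)
        (out / "config.json").write_text(json.dumps(self.config, sort_keys=True,
                                                    indent=1, default=str))
        return out

    @classmethod
    def load(cls, out_dir: str | pathlib.Path) -> "EvolutionRecord":
        out = pathlib.Path(out_dir)
        return cls(trials=pd.read_csv(out / "trials.csv"),
                   config=json.loads((out / "config.json").read_text()))


_SCENE_CACHE: dict[tuple, list] = {}


def _scene_set(params, lighting, cfg: ExperimentConfig):
    """Scene sets are a property of the habitat (fixed across master
    seeds), so they are cached per process."""
    key = (params.habitat_id, lighting, cfg.scenes_per_population,
           cfg.scene_size, cfg.target_diameter)
    if key not in _SCENE_CACHE:
        _SCENE_CACHE[key] = make_scene_set(
            params, lighting, n_scenes=cfg.scenes_per_population,
            size=cfg.scene_size, target_diameter=cfg.target_diameter, seed=0)
    return _SCENE_CACHE[key]


def _render_and_measure(genm: ge.Genome, scene, cfg: ExperimentConfig,
                        rng: np.random.Generator, provenance: dict):
    skin = skin_from_genome(genm, size=cfg.skin_size, rd_grid=cfg.rd_grid,
                            rd_max_steps=cfg.rd_max_steps)
    centre = place_target(scene, rng)
    if scene.lighting == "DIRECT":
        rotation = float(scene.azimuth)  # skin "up" faces the light
    else:
        rotation = float(rng.uniform(0.0, 360.0))
    stim = composite_target(scene, skin, centre, rotation_deg=rotation,
                            provenance=provenance)
    return stim, measure_stimulus(stim)


def _observer_params(cfg: ExperimentConfig) -> ob.ObserverParams:
    return ob.ObserverParams(**cfg.observer)


def calibrate_observer(cfg: ExperimentConfig,
                       seed_seq: np.random.SeedSequence) -> ob.ObserverParams:
    """Measure a batch of random genomes across the scene library and fix
    the observer's z-normalization reference."""
    rng = np.random.default_rng(seed_seq)
    habitats = habitat_library(cfg.n_habitats)
    lightings = set()
    for t in cfg.treatments:
        lightings |= {"DIRECT", "DIFFUSE"} if t == "MIXED" else {t}
    rows = []
    for i in range(cfg.calibration_genomes):
        genm = ge.Genome(rng.random(ge.N_GENES))
        hp = habitats[int(rng.integers(len(habitats)))]
        lighting = sorted(lightings)[int(rng.integers(len(lightings)))]
        scenes = _scene_set(hp, lighting, cfg)
        scene = scenes[int(rng.integers(len(scenes)))]
        _, m = _render_and_measure(genm, scene, cfg, rng, {"calibration": i})
        rows.append(m)
    return ob.calibrate(_observer_params(cfg), pd.DataFrame(rows))


def _population_lightings(treatment: str, n: int,
                          rng: np.random.Generator) -> list[str]:
    if treatment == "MIXED":
        # exactly half direct, half diffuse, randomized assignment
        lst = ["DIRECT"] * (n // 2) + ["DIFFUSE"] * (n - n // 2)
        rng.shuffle(lst)
        return lst
    return [treatment] * n


def run_population(
    cfg: ExperimentConfig,
    treatment: str,
    habitat_params,
    params: ob.ObserverParams,
    seed_seq: np.random.SeedSequence,
    rows: list[dict],
) -> None:
    rng = np.random.default_rng(seed_seq)
    pop_id = f"{treatment.lower()}-{habitat_params.habitat_id}"
    pop = ge.init_population(
        cfg.population_size, ge.N_GENES, seed=rng,
        population_id=pop_id, treatment=treatment,
        habitat_id=habitat_params.habitat_id)
    ids = [f"{pop_id}-i{k}" for k in range(cfg.population_size)]
    next_id = cfg.population_size
    prev_top: set[int] = set()

    scene_sets = {}
    for lighting in ({"DIRECT", "DIFFUSE"} if treatment == "MIXED" else {treatment}):
        scene_sets[lighting] = _scene_set(habitat_params, lighting, cfg)

    for gen in range(cfg.generations + 1):
        lightings = _population_lightings(treatment, cfg.population_size, rng)
        scene_order = {
            lighting: list(rng.permutation(cfg.scenes_per_population))
            for lighting in scene_sets
        }
        used = {lighting: 0 for lighting in scene_sets}
        fitness = np.empty(cfg.population_size)
        for i, member in enumerate(pop.members):
            lighting = lightings[i]
            scene = scene_sets[lighting][scene_order[lighting][used[lighting]]
                                         % cfg.scenes_per_population]
            used[lighting] += 1
            prov = {"population_id": pop_id, "individual": ids[i],
                    "generation": gen}
            _, m = _render_and_measure(member, scene, cfg, rng, prov)
            trial = ob.detect(m, params, rng)
            fitness[i] = trial.fitness
            row = {
                "treatment": treatment,
                "habitat_id": habitat_params.habitat_id,
                "population_id": pop_id,
                "generation": gen,
                "individual": ids[i],
                "scene_id": scene.scene_id,
                "lighting": lighting,
                "survival_time_ms": trial.survival_time,
                "timed_out": trial.timed_out,
                "fitness": trial.fitness,
            }
            row.update({k: float(m[k]) for k in sorted(m)})
            row.update({f"g{j:02d}": float(member.genes[j])
                        for j in range(len(member))})
            rows.append(row)

        if gen == cfg.generations:
            break
        surv_idx = select(pop.members, fitness, prev_top, cfg.n_survivors, rng)
        survivors = [pop.members[i] for i in surv_idx]
        surv_ids = [ids[i] for i in surv_idx]
        for rank, member in enumerate(survivors):
            member.lifeline_rank = rank
        offspring = next_generation(survivors, cfg.n_deaths, rng,
                                    cfg.mutation_rate, cfg.mutation_sigma)
        off_ids = [f"{pop_id}-i{next_id + k}" for k in range(len(offspring))]
        next_id += len(offspring)
        pop = ge.Population(members=survivors + offspring,
                            generation=gen + 1, population_id=pop_id,
                            treatment=treatment,
                            habitat_id=habitat_params.habitat_id)
        ids = surv_ids + off_ids
        # lifeline: the top 4 of the generation just played, by new index
        prev_top = set(range(min(cfg.lifeline, len(survivors))))


def run_experiment(cfg: ExperimentConfig) -> EvolutionRecord:
    """Run the full design and return the complete trial ledger."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.master_seed)
    n_pops = cfg.n_habitats * len(cfg.treatments)
    children = ss.spawn(n_pops + 1)
    params = calibrate_observer(cfg, children[0])
    habitats = habitat_library(cfg.n_habitats)
    rows: list[dict] = []
    k = 1
    for treatment in cfg.treatments:
        for hp in habitats:
            run_population(cfg, treatment, hp, params, children[k], rows)
            k += 1
    trials = pd.DataFrame(rows)
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["treatments"] = list(cfg.treatments)
    cfg_dict["scene_size"] = list(cfg.scene_size)
    return EvolutionRecord(trials=trials, config=cfg_dict)
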