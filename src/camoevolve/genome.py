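"""Haploid decimal chromosome: representation, initialization, recombination, mutation.

The unit of evolution is a vector of 36 genes in [0, 1] (34 base loci
controlling reaction-diffusion markings, colours, countershading and edge
enhancement, plus 2 gloss loci).  Populations are initialised with a
per-locus stratified uniform sample so that no two starting individuals
cluster at a locus; crossover is free per-locus recombination of the
haploid chromosome; mutation is a reflected Gaussian step.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

N_GENES = 36  # 34 base loci + 2 gloss loci


@dataclasses.dataclass
class Genome:
    """An individual's chromosome.

    Parameters
    ----------
    genes:
        Vector of gene values, each in [0, 1].
    lifeline_rank:
        Fitness rank in the previous generation (0 = best), if the
        individual survived from it.  Used for lifeline protection.
    """

    genes: np.ndarray
    lifeline_rank: int | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=float)
        if self.genes.ndim != 1:
            raise ValueError("genes must be a 1-D vector")
        if np.any(~np.isfinite(self.genes)):
            raise ValueError("genes must be finite")
        if self.genes.min() < 0.0 or self.genes.max() > 1.0:
            raise ValueError("gene values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.genes.size

    def copy(self) -> "Genome":
        return Genome(self.genes.copy(), self.lifeline_rank)


@dataclasses.dataclass
class Population:
    """A fixed-size group of genomes evolving against one habitat."""

    members: list[Genome]
    generation: int = 0
    population_id: str = "pop0"
    treatment: str = "DIRECT"
    habitat_id: str = "hab0"

    def __len__(self) -> int:
        return len(self.members)

    def gene_matrix(self) -> np.ndarray:
        return np.stack([m.genes for m in self.members])


def init_population(
    n_individuals: int,
    n_genes: int = N_GENES,
    seed: int | np.random.Generator = 0,
    **meta,
) -> Population:
    """Create a starting population with stratified-uniform gene values.

    For every locus the ``n_individuals`` values occupy distinct bins of
    width ``1/n_individuals`` spanning [0, 1]; bin-to-individual assignment
    is an independent seeded shuffle per locus.  This prevents the initial
    clustering of genotypes that plain uniform sampling can produce.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_individuals
    genes = np.empty((n, n_genes))
    for j in range(n_genes):
        bins = rng.permutation(n)
        genes[:, j] = (bins + rng.random(n)) / n
    members = [Genome(genes[i]) for i in range(n)]
    return Population(members=members, **meta)


def recombine(
    parent_a: Genome, parent_b: Genome, rng: np.random.Generator
) -> Genome:
    """Uniform per-locus crossover: each child gene is drawn from either
    parent with probability 0.5."""
    if len(parent_a) != len(parent_b):
        raise ValueError("parent gene counts differ")
    take_a = rng.random(len(parent_a)) < 0.5
    child = np.where(take_a, parent_a.genes, parent_b.genes)
    return Genome(child)


def mutate(
    g: Genome,
    rate: float = 0.10,
    sigma: float = 0.05,
    rng: np.random.Generator | None = None,
) -> Genome:
    """Perturb each gene independently with probability ``rate`` by a
    Gaussian step of SD ``sigma``, reflecting at the [0, 1] boundaries."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be a probability")
    if sigma <= 0.0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng() if rng is None else rng
    hit = rng.random(len(g)) < rate
    step = rng.normal(0.0, sigma, len(g))
    x = g.genes + np.where(hit, step, 0.0)
    # reflect into [0, 1]: fold the real line onto the unit interval
    x = np.mod(x, 2.0)
    x = np.where(x > 1.0, 2.0 - x, x)
    return Genome(x)


# ---------------------------------------------------------------------------
# serialization

def population_to_frame(pop: Population) -> pd.DataFrame:
    cols = {f"g{j:02d}": pop.gene_matrix()[:, j] for j in range(len(pop.members[0]))}
    df = pd.DataFrame(cols)
    df.insert(0, "population_id", pop.population_id)
    df.insert(1, "generation", pop.generation)
    return df


def frame_to_population(df: pd.DataFrame, **meta) -> Population:
    gene_cols = sorted(c for c in df.columns if c.startswith("g") and c[1:].isdigit())
    members = [Genome(row[gene_cols].to_numpy(dtype=float)) for _, row in df.iterrows()]
    meta.setdefault("population_id", str(df["population_id"].iloc[0]))
    meta.setdefault("generation", int(df["generation"].iloc[0]))
    return Population(members=members, **meta)


def population_to_json(pop: Population) -> str:
    recs = [
        {
            "population_id": pop.population_id,
            "generation": pop.generation,
            "genes": list(map(float, m.genes)),
        }
        for m in pop.members
    ]
    return json.dumps(recs)


def population_from_json(text: str, **meta) -> Population:
    recs = json.loads(text)
    members = [Genome(np.array(r["genes"], dtype=float)) for r in recs]
    meta.setdefault("population_id", recs[0]["population_id"])
    meta.setdefault("generation", int(recs[0]["generation"]))
    return Population(members=members, **meta)
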