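"""Forward pedigree simulation.

One founder couple at generation 0; every descendant pairs with a fresh
unrelated founder spouse (no inbreeding), and each couple draws a Poisson
number of offspring. Carrier status is left False here; it is derived from
haplotype truth labels after gene dropping and allele planting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Individual", "Pedigree", "PedigreeExtinctionError", "simulate_pedigree"]


class PedigreeExtinctionError(RuntimeError):
    """Raised when a lineage dies out before the requested depth."""

    def __init__(self, generation_reached: int, requested: int):
        self.generation_reached = generation_reached
        self.requested = requested
        super().__init__(
            f"pedigree extinct at generation {generation_reached} "
            f"(requested depth {requested})"
        )


@dataclass
class Individual:
    id: str
    father: str | None
    mother: str | None
    generation: int
    carrier: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    members: dict[str, Individual] = field(default_factory=dict)

    def add(self, ind: Individual) -> None:
        if ind.id in self.members:
            raise ValueError(f"duplicate individual id {ind.id}")
        for parent in (ind.father, ind.mother):
            if parent is not None:
                p = self.members.get(parent)
                if p is None:
                    raise ValueError(f"{ind.id}: unknown parent {parent}")
                if p.generation >= ind.generation:
                    raise ValueError(
                        f"{ind.id}: parent {parent} not from an earlier generation"
                    )
        if (ind.father is None) != (ind.mother is None):
            raise ValueError(f"{ind.id}: must have zero or two parents")
        self.members[ind.id] = ind

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.members

    def __getitem__(self, ind_id: str) -> Individual:
        return self.members[ind_id]

    @property
    def ids(self) -> list[str]:
        return list(self.members)

    @property
    def founders(self) -> list[str]:
        return [i for i, m in self.members.items() if m.is_founder]

    @property
    def n_generations(self) -> int:
        return max(m.generation for m in self.members.values()) + 1

    def children_of(self, ind_id: str) -> list[str]:
        return [
            i
            for i, m in self.members.items()
            if m.father == ind_id or m.mother == ind_id
        ]

    def descendants_of(self, ind_id: str) -> set[str]:
        out: set[str] = set()
        stack = [ind_id]
        while stack:
            for child in self.children_of(stack.pop()):
                if child not in out:
                    out.add(child)
                    stack.append(child)
        return out

    def carriers(self) -> list[str]:
        return [i for i, m in self.members.items() if m.carrier]

    def meioses_between(self, a: str, b: str) -> int | None:
        """Meioses count on the shortest path through a common ancestor.

        Returns None when the pair shares no ancestor (including each other).
        """

        def depths(x: str) -> dict[str, int]:
            out = {x: 0}
            frontier = [x]
            while frontier:
                nxt = []
                for i in frontier:
                    m = self.members[i]
                    for p in (m.father, m.mother):
                        if p is not None and (p not in out or out[p] > out[i] + 1):
                            out[p] = out[i] + 1
                            nxt.append(p)
                frontier = nxt
            return out

        da, db = depths(a), depths(b)
        common = set(da) & set(db)
        if not common:
            return None
        return min(da[x] + db[x] for x in common)


def simulate_pedigree(
    n_generations: int,
    mean_offspring: float,
    seed: int,
    *,
    max_size: int = 100_000,
) -> Pedigree:
    """Grow a pedigree of depth ``n_generations`` (generations 0..n-1).

    Raises :class:`PedigreeExtinctionError` if some generation produces no
    offspring before the requested depth is reached.
    """
    if n_generations < 2:
        raise ValueError("n_generations must be >= 2")
    if mean_offspring <= 0:
        raise ValueError("mean_offspring must be > 0")
    rng = np.random.default_rng(seed)
    ped = Pedigree()
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"P{counter:05d}"

    patriarch, matriarch = new_id(), new_id()
    ped.add(Individual(patriarch, None, None, 0))
    ped.add(Individual(matriarch, None, None, 0))
    couples = [(patriarch, matriarch)]
    for gen in range(1, n_generations):
        children: list[str] = []
        for father, mother in couples:
            for _ in range(rng.poisson(mean_offspring)):
                cid = new_id()
                ped.add(Individual(cid, father, mother, gen))
                children.append(cid)
        if not children:
            raise PedigreeExtinctionError(gen - 1, n_generations)
        if len(ped) > max_size:
            raise ValueError(f"pedigree exceeded max_size={max_size}")
        couples = []
        if gen < n_generations - 1:
            for cid in children:
                spouse = new_id()
                ped.add(Individual(spouse, None, None, gen))
                couples.append((cid, spouse))
    return ped
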