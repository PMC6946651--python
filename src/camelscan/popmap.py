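"""Sample -> population -> group assignments.

Every statistic in the package is configured through a :class:`PopulationMap`:
nucleotide diversity and Watterson's theta are computed per population, Fst per
population pair, and the four-taxon tests over species-level *groups* (e.g.
"east_asian" pooling several domestic populations).  A label passed to any
operation may therefore name either a population or a group; group labels
resolve to the union of their member populations' samples.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np


class PopulationMap:
    """Ordered sample->population (and optional population->group) assignment."""

    def __init__(
        self,
        sample_population: Mapping[str, str],
        population_group: Mapping[str, str] | None = None,
    ) -> None:
        self.sample_population = dict(sample_population)
        self.population_group = dict(population_group or {})
        for pop in self.population_group:
            if pop not in self.sample_population.values():
                raise ValueError(f"group assignment for unknown population {pop!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.sample_population)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.sample_population.values():
            seen.setdefault(pop)
        return list(seen)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for grp in self.population_group.values():
            seen.setdefault(grp)
        return list(seen)

    def is_population(self, label: str) -> bool:
        return label in set(self.sample_population.values())

    def is_group(self, label: str) -> bool:
        return label in set(self.population_group.values())

    def populations_for(self, label) -> list[str]:
        """Populations referred to by ``label``.

        ``label`` may be a population name, a group name, or a list/tuple/set
        of either (the union of their members).
        """
        if isinstance(label, (list, tuple, set, frozenset)):
            pops: dict[str, None] = {}
            for sub in label:
                for p in self.populations_for(sub):
                    pops.setdefault(p)
            return list(pops)
        if self.is_population(label):
            return [label]
        if self.is_group(label):
            return [p for p, g in self.population_group.items() if g == label]
        raise KeyError(f"unknown population or group label {label!r}")

    def samples_for(self, label: str) -> list[str]:
        pops = set(self.populations_for(label))
        return [s for s, p in self.sample_population.items() if p in pops]

    def sample_indices(self, label: str, sample_order: Sequence[str]) -> np.ndarray:
        """Column indices of ``label``'s samples within ``sample_order``."""
        wanted = set(self.samples_for(label))
        idx = [i for i, s in enumerate(sample_order) if s in wanted]
        if not idx:
            raise KeyError(f"no samples of {label!r} present in the matrix")
        return np.asarray(idx, dtype=np.intp)

    # ------------------------------------------------------------------ I/O
    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tpopulation\tgroup\n")
            for s, p in self.sample_population.items():
                g = self.population_group.get(p, p)
                fh.write(f"{s}\t{p}\t{g}\n")

    @classmethod
    def read_tsv(cls, path) -> "PopulationMap":
        sample_population: dict[str, str] = {}
        population_group: dict[str, str] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["sample_id", "population"]:
                raise ValueError(f"{path}: expected columns sample_id, population[, group]")
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 2:
                    continue
                sample_population[fields[0]] = fields[1]
                if len(fields) >= 3:
                    population_group[fields[1]] = fields[2]
        return cls(sample_population, population_group)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PopulationMap)
            and self.sample_population == other.sample_population
            and self.population_group == other.population_group
        )

    def __repr__(self) -> str:
        return (
            f"PopulationMap({len(self.sample_population)} samples, "
            f"{len(self.populations)} populations, {len(self.groups)} groups)"
        )
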