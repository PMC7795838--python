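"""Core container for diploid multilocus SSR genotypes.

Alleles are coded by fragment size (positive integers, typically even sizes
from dinucleotide repeats).  A call is an unordered pair of allele copies per
individual per locus; a missing call is missing as a pair (both copies set to
:data:`MISSING`).  File dialects use their own missing sentinels ("000" in
Genepop, -9 in STRUCTURE); in memory missing is always the explicit
:data:`MISSING` constant, never a data value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: In-memory sentinel for a missing allele copy.
MISSING: int = -1


@dataclass
class GenotypeDataset:
    """Populations of diploid individuals typed at SSR loci.

    Parameters
    ----------
    populations
        Ordered population names.
    pop_index
        For each individual, the index of its population in ``populations``.
        Every individual belongs to exactly one population.
    individuals
        Individual identifiers, unique.
    loci
        Locus (marker) names.
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)`` holding allele
        fragment sizes, with :data:`MISSING` for missing copies.  Both copies
        of a call are missing together.
    """

    populations: list[str]
    pop_index: np.ndarray
    individuals: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.pop_index = np.asarray(self.pop_index, dtype=np.intp)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if self.pop_index.shape != (n,):
            raise ValueError("pop_index must have one entry per individual")
        if n and (self.pop_index.min() < 0 or self.pop_index.max() >= len(self.populations)):
            raise ValueError("pop_index out of range")
        if len(set(self.individuals)) != n:
            raise ValueError("individual identifiers must be unique")
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("population names must be unique")
        missing = self.calls == MISSING
        if np.any(missing[..., 0] != missing[..., 1]):
            raise ValueError("half-missing calls are not allowed")
        valid = self.calls[~missing]
        if valid.size and valid.min() <= 0:
            raise ValueError("allele codes must be positive fragment sizes")

    # -- basic shape -------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    # -- masks and views ---------------------------------------------------
    @property
    def typed(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): call present at that locus."""
        return self.calls[..., 0] != MISSING

    def population_members(self, population: str) -> np.ndarray:
        """Indices of the individuals sampled from ``population``."""
        try:
            p = self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None
        return np.flatnonzero(self.pop_index == p)

    def locus_number(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def subset_population(self, population: str) -> "GenotypeDataset":
        idx = self.population_members(population)
        return GenotypeDataset(
            populations=[population],
            pop_index=np.zeros(len(idx), dtype=np.intp),
            individuals=[self.individuals[i] for i in idx],
            loci=list(self.loci),
            calls=self.calls[idx].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.populations == other.populations
            and self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.pop_index, other.pop_index)
            and np.array_equal(self.calls, other.calls)
        )
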