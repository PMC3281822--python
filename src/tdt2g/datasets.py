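"""Core containers for nuclear-family trio genotype data.

A trio is two parents and one affected child genotyped over an ordered SNP
panel.  Genotypes are unordered allele pairs per marker; alleles are arbitrary
string tokens with ``"0"`` reserved for missing (LINKAGE convention).  When a
dataset originates from a simulator the true phase of each parent is carried
along as a ``(transmitted, nontransmitted)`` haplotype pair; datasets read
from PED files carry no phase and are resolved per window from family
information (:mod:`tdt2g.haplotype_core`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence, Tuple

MISSING = "0"

#: One haplotype: an ordered tuple of allele tokens over a marker window.
Haplotype = Tuple[str, ...]

#: One marker's unordered genotype, stored as a sorted 2-tuple of tokens.
GenotypePair = Tuple[str, str]

#: One individual's genotype over the panel.
Genotype = Tuple[GenotypePair, ...]

#: A parent's phase: (transmitted haplotype, nontransmitted haplotype).
Phase = Tuple[Haplotype, Haplotype]


def genotype_from_haplotypes(h1: Haplotype, h2: Haplotype) -> Genotype:
    """Collapse two haplotypes into an unphased genotype (sorted pairs)."""
    if len(h1) != len(h2):
        raise ValueError("haplotypes differ in length")
    return tuple(tuple(sorted((a, b))) for a, b in zip(h1, h2))  # type: ignore[misc]


@dataclass(frozen=True)
class Trio:
    """One nuclear family: two parental genotypes and one affected child."""

    family_id: str
    father: Genotype
    mother: Genotype
    child: Genotype
    father_phase: Optional[Phase] = None
    mother_phase: Optional[Phase] = None
    subpop: Optional[int] = None

    @property
    def n_markers(self) -> int:
        return len(self.father)

    def drop_phase(self, parent: str) -> "Trio":
        """Return a copy with one parent's stored phase removed."""
        if parent == "father":
            return replace(self, father_phase=None)
        if parent == "mother":
            return replace(self, mother_phase=None)
        raise ValueError(f"unknown parent role {parent!r}")


def trio_from_phases(
    family_id: str,
    father_phase: Phase,
    mother_phase: Phase,
    subpop: Optional[int] = None,
) -> Trio:
    """Build a fully phased trio; the child receives both transmitted haplotypes."""
    father = genotype_from_haplotypes(*father_phase)
    mother = genotype_from_haplotypes(*mother_phase)
    child = genotype_from_haplotypes(father_phase[0], mother_phase[0])
    return Trio(family_id, father, mother, child, father_phase, mother_phase, subpop)


@dataclass
class TrioDataset:
    """A collection of trios over a shared ordered marker panel."""

    trios: list
    n_markers: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.trios:
            if t.n_markers != self.n_markers:
                raise ValueError(
                    f"trio {t.family_id} has {t.n_markers} markers, "
                    f"dataset declares {self.n_markers}"
                )

    def __len__(self) -> int:
        return len(self.trios)

    def __iter__(self) -> Iterator[Trio]:
        return iter(self.trios)

    def __getitem__(self, i: int) -> Trio:
        return self.trios[i]

    def subset(self, indices: Sequence[int]) -> "TrioDataset":
        return TrioDataset([self.trios[i] for i in indices], self.n_markers)
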