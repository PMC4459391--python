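"""Pedigree: binds VCF sample ids to roles (father, mother, affected children)."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path


@dataclass(frozen=True)
class Pedigree:
    father: str
    mother: str
    children: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ValueError("pedigree needs at least one affected child")
        ids = [self.father, self.mother, *self.children]
        if len(set(ids)) != len(ids):
            raise ValueError("pedigree sample ids must be distinct")

    @property
    def samples(self) -> tuple[str, ...]:
        """All sample ids, parents first, children in given order."""
        return (self.father, self.mother, *self.children)

    @property
    def n_children(self) -> int:
        return len(self.children)

    def sibling_pairs(self) -> list[tuple[str, str]]:
        """All unordered pairs of affected children."""
        return list(combinations(self.children, 2))

    @classmethod
    def default(cls, n_children: int = 3) -> "Pedigree":
        return cls(
            father="FATHER",
            mother="MOTHER",
            children=tuple(f"CHILD{i + 1}" for i in range(n_children)),
        )

    @classmethod
    def from_ped_file(cls, path: str | Path) -> "Pedigree":
        """Read a 6-column PED file (family, id, father, mother, sex, phenotype).

        The affected children are the rows whose phenotype is 2 and whose
        parental ids are both non-missing; the named parents must appear as
        rows of the same family.
        """
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"PED line has fewer than 6 columns: {line!r}")
            rows.append(fields[:6])
        affected = [r for r in rows if r[5] == "2" and r[2] != "0" and r[3] != "0"]
        if not affected:
            raise ValueError("PED file contains no affected child with both parents")
        fathers = {r[2] for r in affected}
        mothers = {r[3] for r in affected}
        if len(fathers) != 1 or len(mothers) != 1:
            raise ValueError("affected children must share one father and one mother")
        return cls(
            father=fathers.pop(),
            mother=mothers.pop(),
            children=tuple(r[1] for r in affected),
        )
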