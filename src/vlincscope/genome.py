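"""Genome layout: chromosome names, lengths and explicit autosome flags.

Every interval operation in the package validates coordinates against a
:class:`GenomeLayout`.  Autosome status is part of the layout (a name→flag
table), never inferred by parsing chromosome names.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    is_autosome: bool

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r}: length must be positive, got {self.length}")


class GenomeLayout:
    """Ordered collection of chromosomes with unique names.

    Parameters
    ----------
    chromosomes
        Iterable of ``Chromosome`` or ``(name, length, is_autosome)`` tuples.
    """

    def __init__(self, chromosomes) -> None:
        chroms = []
        for c in chromosomes:
            if not isinstance(c, Chromosome):
                c = Chromosome(str(c[0]), int(c[1]), bool(c[2]))
            chroms.append(c)
        names = [c.name for c in chroms]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome names: {dupes}")
        self._chroms = tuple(chroms)
        self._by_name = {c.name: c for c in chroms}

    @property
    def chromosomes(self) -> tuple[Chromosome, ...]:
        return self._chroms

    @property
    def names(self) -> list[str]:
        return [c.name for c in self._chroms]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self._chroms)

    def __getitem__(self, name: str) -> Chromosome:
        return self._by_name[name]

    def length_of(self, name: str) -> int:
        return self._by_name[name].length

    def is_autosome(self, name: str) -> bool:
        return self._by_name[name].is_autosome

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self._chroms)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and self._chroms == other._chroms

    def __repr__(self) -> str:
        return f"GenomeLayout({len(self)} chromosomes, {self.total_length} bp)"

    @classmethod
    def from_tsv(cls, path) -> "GenomeLayout":
        """Read a layout from a header-less TSV: name, length, autosome (0/1)."""
        chroms = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}: line {i}: expected 3 columns (name, length, autosome 0/1), got {len(fields)}"
                    )
                try:
                    length = int(fields[1])
                    flag = bool(int(fields[2]))
                except ValueError as e:
                    raise ValueError(f"{path}: line {i}: {e}") from None
                chroms.append(Chromosome(fields[0], length, flag))
        return cls(chroms)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for c in self._chroms:
                fh.write(f"{c.name}\t{c.length}\t{int(c.is_autosome)}\n")
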