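"""Curated TE library: canonical family sequences used as the reference
panel for candidate filtering, family assignment and full-length ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .seqs import read_fasta, write_fasta


@dataclass(frozen=True)
class TEFamily:
    """A TE family: canonical sequence plus superfamily tag and a TSD model.

    ``tsd`` is either a fixed length in bp or an inclusive (low, high)
    range; target-site duplication length is characteristic of the
    superfamily (e.g. 4 bp for Gypsy, 5 bp for Pao/Copia LTR elements),
    while non-LTR elements show more variable TSDs.
    """

    name: str
    sequence: str
    superfamily: str = ""
    tsd: int | tuple[int, int] = 0

    def __len__(self) -> int:
        return len(self.sequence)

    def draw_tsd_length(self, rng: np.random.Generator) -> int:
        if isinstance(self.tsd, tuple):
            lo, hi = self.tsd
            return int(rng.integers(lo, hi + 1))
        return int(self.tsd)


class TELibrary:
    """Mapping of family name -> :class:`TEFamily`."""

    def __init__(self, families: Iterable[TEFamily]):
        self.families: dict[str, TEFamily] = {}
        for fam in families:
            if fam.name in self.families:
                raise ValueError(f"duplicate family name {fam.name!r}")
            self.families[fam.name] = fam
        if not self.families:
            raise ValueError("TE library is empty")

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self) -> Iterator[TEFamily]:
        return iter(self.families.values())

    def __contains__(self, name: str) -> bool:
        return name in self.families

    def __getitem__(self, name: str) -> TEFamily:
        return self.families[name]

    @property
    def names(self) -> list[str]:
        return list(self.families)

    def canonical_length(self, name: str) -> int:
        return len(self.families[name].sequence)

    def to_fasta(self, path) -> Path:
        return write_fasta(path, ((f.name, f.sequence) for f in self))

    @classmethod
    def from_fasta(
        cls,
        path,
        superfamilies: dict[str, str] | None = None,
        tsd_model: dict[str, int | tuple[int, int]] | None = None,
    ) -> "TELibrary":
        superfamilies = superfamilies or {}
        tsd_model = tsd_model or {}
        seqs = read_fasta(path)
        return cls(
            TEFamily(
                name,
                seq,
                superfamily=superfamilies.get(name, ""),
                tsd=tsd_model.get(name, 0),
            )
            for name, seq in seqs.items()
        )
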