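"""Genome assemblies as chromosome-name -> length maps (chrom.sizes dialect)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


class GenomeError(ValueError):
    """Raised for invalid genome definitions or out-of-bounds coordinates."""


@dataclass(frozen=True)
class GenomeAssembly:
    """A named set of chromosomes with their lengths in base pairs.

    Coordinates everywhere in this package are 0-based, half-open
    (BED convention), so a chromosome of length L admits positions 0..L-1.
    """

    name: str
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if not isinstance(length, int) or length <= 0:
                raise GenomeError(
                    f"chromosome {chrom!r} has non-positive length {length!r}"
                )

    @property
    def total_length(self) -> int:
        """Total genome size in base pairs."""
        return sum(self.chrom_lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise GenomeError(f"chromosome {chrom!r} not in assembly {self.name!r}") from None


def read_chrom_sizes(path: str | Path, name: str | None = None) -> GenomeAssembly:
    """Read a two-column ``chrom<TAB>length`` file into a GenomeAssembly."""
    path = Path(path)
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise GenomeError(f"{path}:{lineno}: expected 'chrom<TAB>length', got {line!r}")
            chrom, raw = fields[0], fields[1]
            if chrom in lengths:
                raise GenomeError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
            try:
                lengths[chrom] = int(raw)
            except ValueError:
                raise GenomeError(f"{path}:{lineno}: non-integer length {raw!r}") from None
    return GenomeAssembly(name=name or path.stem, chrom_lengths=lengths)


def write_chrom_sizes(genome: GenomeAssembly, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
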