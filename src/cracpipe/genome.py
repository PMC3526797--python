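"""Reference genome container and FASTA IO.

Coordinates throughout the package are 0-based half-open on the forward
strand; sequences are stored uppercase over the alphabet ACGTN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _sanitize(seq: str) -> str:
    """Uppercase and map any character outside ACGTN to N."""
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    return "".join(c if c in _VALID else "N" for c in seq)


@dataclass
class Genome:
    """Named reference sequences with 0-based half-open slicing.

    Attributes
    ----------
    sequences : dict
        Chromosome name -> uppercase nucleotide string (ACGTN).
    """

    sequences: Dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(s) for name, s in self.sequences.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand sequence of ``chrom[start:end)``."""
        return self.sequences[chrom][start:end]

    def add(self, name: str, seq: str) -> None:
        if name in self.sequences:
            raise ValueError(f"duplicate chromosome name: {name!r}")
        self.sequences[name] = _sanitize(seq)

    def items(self) -> Iterator[Tuple[str, str]]:
        return iter(self.sequences.items())


def load_genome(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Lowercase input is uppercased; characters outside ACGTN become N.
    Duplicate record names and empty files are hard errors.
    """
    genome = Genome()
    for rec in SeqIO.parse(str(path), "fasta"):
        genome.add(rec.id, str(rec.seq))
    if not genome.sequences:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_genome(genome: Genome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")
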