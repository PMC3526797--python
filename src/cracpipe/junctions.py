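"""Splice-junction reference library.

For every intron of every spliced feature the library holds three entries:

``EE``   exon|exon junction on the mature (spliced) transcript — the flanking
         sequence is the concatenation of the last ``flank`` nt of the
         upstream exon and the first ``flank`` nt of the downstream exon
         (transcript orientation);
``IE5``  exon|intron junction at the 5' splice site on the unspliced
         precursor;
``IE3``  intron|exon junction at the 3' splice site on the precursor.

EE entries are extra alignment targets (a spliced read cannot align
contiguously to the genome); IE entries lie on the unspliced genomic
sequence and only carry the boundary coordinates used for junction
counting.  Every entry records the genomic coordinate of each of its bases
so junction-entry alignments can be lifted back to genomic M-N-M form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

from .annotation import Feature
from .genome import Genome

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class JunctionEntry:
    feature_id: str
    kind: str  # EE | IE5 | IE3
    intron_index: int  # 0-based, transcript order
    chrom: str
    strand: str
    seq: str  # transcript-oriented flanking sequence
    coords: Tuple[int, ...]  # genomic coordinate of each base of seq
    boundary_index: int  # junction lies between seq[i-1] and seq[i] at i=boundary_index
    truncated: bool = False

    @property
    def name(self) -> str:
        """Structured record name feature|kind|coord used in FASTA export."""
        return f"{self.feature_id}|{self.kind}|{self.genomic_boundary}"

    @property
    def genomic_boundary(self) -> int:
        """Genomic position of the last base 5' of the junction (transcript sense)."""
        return self.coords[self.boundary_index - 1]


@dataclass
class JunctionLibrary:
    entries: List[JunctionEntry] = field(default_factory=list)
    flank: int = 0

    def ee_entries(self) -> List[JunctionEntry]:
        return [e for e in self.entries if e.kind == "EE"]

    def by_name(self) -> Dict[str, JunctionEntry]:
        return {e.name: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


def _entry_bases(genome: Genome, chrom: str, strand: str, coords: Sequence[int]) -> str:
    chrom_seq = genome[chrom]
    if strand == "+":
        return "".join(chrom_seq[c] for c in coords)
    return "".join(chrom_seq[c] for c in coords).translate(_COMP)


def _tx_segment_coords(interval: Tuple[int, int], strand: str) -> List[int]:
    """Genomic coordinates of the interval's bases in transcript order."""
    a, b = interval
    rng = range(a, b)
    return list(rng) if strand == "+" else list(reversed(rng))


def build_junction_library(
    features: Sequence[Feature], genome: Genome, flank: int
) -> JunctionLibrary:
    """One EE, IE5 and IE3 entry per intron of every spliced feature.

    ``flank`` bases are taken on each side of the junction; if an exon or
    intron is shorter than ``flank`` the entry is truncated to the available
    sequence and flagged.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    lib = JunctionLibrary(flank=flank)
    for f in features:
        exons_tx = f.exons_tx()
        introns_tx = f.introns_tx()
        for i, intron in enumerate(introns_tx):
            up_exon = exons_tx[i]
            down_exon = exons_tx[i + 1]
            up = _tx_segment_coords(up_exon, f.strand)
            down = _tx_segment_coords(down_exon, f.strand)
            intr = _tx_segment_coords(intron, f.strand)
            trunc = (
                len(up) < flank or len(down) < flank or len(intr) < flank
            )
            up_tail = up[-flank:]
            down_head = down[:flank]
            intr_head = intr[:flank]
            intr_tail = intr[-flank:]
            for kind, coords, bidx in (
                ("EE", up_tail + down_head, len(up_tail)),
                ("IE5", up_tail + intr_head, len(up_tail)),
                ("IE3", intr_tail + down_head, len(intr_tail)),
            ):
                lib.entries.append(
                    JunctionEntry(
                        feature_id=f.id,
                        kind=kind,
                        intron_index=i,
                        chrom=f.chrom,
                        strand=f.strand,
                        seq=_entry_bases(genome, f.chrom, f.strand, coords),
                        coords=tuple(coords),
                        boundary_index=bidx,
                        truncated=trunc,
                    )
                )
    return lib


def write_junction_fasta(lib: JunctionLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in lib.entries:
            fh.write(f">{e.name}\n{e.seq}\n")
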