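"""Non-templated 3' oligo(A) tail calling and microdeletion extraction.

A read carrying adenosines at its 3' end that are absent from the genome is
the mark the TRAMP complex leaves on RNA-surveillance targets.  The caller
never trusts the aligner's soft-clip directly: the clip is first re-extended
against the downstream reference, any prefix that matches is templated, and
only the remaining suffix can be called a tail (>= ``min_a`` adenosines,
all-A under the default strict purity).  A genomic A immediately downstream
therefore absorbs tail bases — a deliberate, conservative bias.

Microdeletions — 1-2 nt skips introduced by reverse transcriptase at the
crosslinked nucleotide — are read straight off the alignment's D ops, one
event per deleted reference base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .align import AlignedRead
from .genome import Genome

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class TailCall:
    read_id: str
    tail: str
    n_a: int
    a_tailed: bool
    first_a_coord: Optional[int] = None  # genomic coord of first non-templated A
    n_templated: int = 0  # soft-clip prefix re-absorbed as templated


@dataclass
class DeletionSet:
    read_id: str
    positions: List[int]  # 0-based genomic coords of deleted bases, ascending


def call_tail(
    aln: AlignedRead,
    genome: Genome,
    min_a: int = 2,
    tail_purity: float = 1.0,
) -> TailCall:
    """Call a non-templated oligo(A) tail on one alignment.

    The 3' soft-clip is re-extended base by base against the reference
    downstream of the aligned 3' end (in transcript orientation); the
    un-extendable suffix is the candidate tail.  ``a_tailed`` requires at
    least ``min_a`` adenosines and an A fraction >= ``tail_purity``
    (default 1.0: strictly all A).
    """
    clip = aln.soft3
    if not clip:
        return TailCall(aln.read_id, "", 0, False)
    chrom_seq = genome[aln.ref]
    n_templated = 0
    if aln.strand == "+":
        pos = aln.end
        for c in clip:
            if pos < len(chrom_seq) and chrom_seq[pos] == c:
                n_templated += 1
                pos += 1
            else:
                break
    else:
        pos = aln.start - 1
        for c in clip:
            if pos >= 0 and _COMP[chrom_seq[pos]] == c:
                n_templated += 1
                pos -= 1
            else:
                break
    tail = clip[n_templated:]
    n_a = tail.count("A")
    a_tailed = (
        len(tail) >= min_a
        and n_a >= min_a
        and (len(tail) == 0 or n_a / len(tail) >= tail_purity)
    )
    first_a = None
    if a_tailed:
        if aln.strand == "+":
            first_a = aln.end + n_templated
        else:
            first_a = aln.start - 1 - n_templated
    return TailCall(aln.read_id, tail, n_a, a_tailed, first_a, n_templated)


def call_tails(
    alignments: Sequence[AlignedRead],
    genome: Genome,
    min_a: int = 2,
    tail_purity: float = 1.0,
) -> Dict[str, TailCall]:
    return {
        a.read_id: call_tail(a, genome, min_a, tail_purity) for a in alignments
    }


def extract_deletions(aln: AlignedRead) -> DeletionSet:
    """Genomic coordinates of every reference base skipped by a D op."""
    positions: List[int] = []
    pos = aln.start
    for n, op in aln.cigar:
        if op == "D":
            positions.extend(range(pos, pos + n))
            pos += n
        elif op in "MN":
            pos += n
    return DeletionSet(aln.read_id, positions)


def filter_a_tailed(
    alignments: Sequence[AlignedRead], tailcalls: Dict[str, TailCall]
) -> List[AlignedRead]:
    """A-tailed subset of the alignments, original order preserved."""
    out = []
    for a in alignments:
        if a.read_id not in tailcalls:
            raise KeyError(f"no tail call for alignment {a.read_id}")
        if tailcalls[a.read_id].a_tailed:
            out.append(a)
    return out


def write_tailcalls(calls: Dict[str, TailCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttail\tn_a\ta_tailed\tfirst_a_coord\tn_templated\n")
        for c in calls.values():
            fh.write(
                f"{c.read_id}\t{c.tail}\t{c.n_a}\t{int(c.a_tailed)}\t"
                f"{'' if c.first_a_coord is None else c.first_a_coord}\t{c.n_templated}\n"
            )


def write_deletions(dels: Sequence[DeletionSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tpositions\n")
        for d in dels:
            fh.write(f"{d.read_id}\t{','.join(map(str, d.positions))}\n")
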