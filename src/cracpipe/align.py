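"""Read preparation and desk-scale seed-and-extend alignment.

The aligner anchors the 5'-most k-mer of a read by exact match (both
strands, genome plus exon-exon junction entries) and extends 3'-ward with a
small dynamic program that allows mismatches and short reference deletions
— the lesion reverse transcriptase leaves at a crosslinked nucleotide.
Scoring: match +1, mismatch -2, deletion -3 per deleted base, total
deletion budget ``max_del``.  Whatever 3' suffix does not improve the score
is soft-clipped; that suffix is where non-templated oligo(A) tails survive
alignment.  Reads with more than one distinct best locus are flagged multi
and excluded from counting by default.

This is not a general-purpose aligner (no insertions, no paired ends, no
quality-aware scoring); real libraries are expected to arrive as SAM from
an external aligner via :func:`read_sam`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pysam

from .genome import Genome, revcomp
from .junctions import JunctionLibrary

NEG_INF = float("-inf")


@dataclass
class AlignedRead:
    """One mapped read.

    ``cigar`` is in reference-forward order (SAM convention); ``soft3`` is
    the 3' soft-clipped suffix in read orientation (for minus-strand
    alignments it corresponds to the leading S in the CIGAR).  ``seq`` is
    the read sequence in read orientation.
    """

    read_id: str
    ref: str
    strand: str
    start: int
    cigar: List[Tuple[int, str]]
    seq: str
    soft3: str = ""
    count: int = 1
    score: int = 0
    nm: int = 0
    multi: bool = False
    is_junction: bool = False

    @property
    def ref_span(self) -> int:
        return sum(n for n, op in self.cigar if op in "MDN")

    @property
    def end(self) -> int:
        return self.start + self.ref_span

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for n, op in self.cigar)


def collapse_duplicates(reads: Iterable[Tuple[str, str]]) -> List[Tuple[str, str, int]]:
    """Merge sequence-identical reads; first-occurrence order, count kept."""
    seen: Dict[str, int] = {}
    out: List[Tuple[str, str, int]] = []
    for rid, seq in reads:
        if seq in seen:
            i = seen[seq]
            out[i] = (out[i][0], seq, out[i][2] + 1)
        else:
            seen[seq] = len(out)
            out.append((rid, seq, 1))
    return out


def trim_adapter(seq: str, adapter: str, min_overlap: int = 5) -> str:
    """Remove the longest read suffix matching an adapter prefix.

    Mismatches are allowed at a 10% rate of the overlap length (so exact
    match below 10 nt, one mismatch from 10 nt, two from 20 nt); suffixes
    shorter than ``min_overlap`` are trimmed only on an exact match (a read
    that ran just a few cycles into the adapter).  Returns the (possibly
    unchanged) insert.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    L = len(seq)
    for start in range(L):
        tail = seq[start:]
        n = min(len(tail), len(adapter))
        allowed = n // 10 if n >= min_overlap else 0
        mism = sum(1 for a, b in zip(tail[:n], adapter[:n]) if a != b)
        if mism <= allowed:
            return seq[:start]
    return seq


def prepare_reads(
    reads: Iterable[Tuple[str, str]],
    adapter: str,
    min_overlap: int = 5,
    min_length: int = 15,
) -> List[Tuple[str, str, int]]:
    """Collapse duplicates, trim the 3' adapter, drop short inserts."""
    collapsed = collapse_duplicates(reads)
    out = []
    for rid, seq, count in collapsed:
        trimmed = trim_adapter(seq, adapter, min_overlap) if adapter else seq
        if len(trimmed) >= min_length:
            out.append((rid, trimmed, count))
    return out


@dataclass
class AlignParams:
    seed_length: int = 12
    max_del: int = 6
    match: int = 1
    mismatch: int = -2
    gap_per_base: int = -3


class Aligner:
    """Exact 5' k-mer seeding plus banded extension with 3' soft-clipping."""

    def __init__(
        self,
        genome: Genome,
        junctions: Optional[JunctionLibrary] = None,
        params: Optional[AlignParams] = None,
    ):
        self.params = params or AlignParams()
        self.genome = genome
        # reference sequences: chromosomes first, then EE junction entries
        self.refs: List[Tuple[str, str, object]] = []  # (name, forward seq, entry|None)
        for name, seq in genome.items():
            self.refs.append((name, seq, None))
        if junctions is not None:
            for e in junctions.ee_entries():
                self.refs.append((e.name, e.seq, e))
        self._index: Dict[str, List[Tuple[int, str, int]]] = {}
        k = self.params.seed_length
        for ref_i, (_name, seq, _isj) in enumerate(self.refs):
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                for pos in range(len(s) - k + 1):
                    kmer = s[pos : pos + k]
                    if "N" in kmer:
                        continue
                    self._index.setdefault(kmer, []).append((ref_i, strand, pos))

    # -- scoring ----------------------------------------------------------

    def _extend(self, q: str, R: str, p: int):
        """Score/extend read ``q`` placed at oriented-ref position ``p``.

        Returns (score, consumed query bases, deletions layout, nm) where
        the deletions layout is a list of (query_index, gap_length) meaning
        ``gap_length`` reference bases are skipped after ``query_index``
        consumed bases.
        """
        P = self.params
        L = len(q)
        D = P.max_del
        lenR = len(R)

        # fast path: exact full-length match
        if R[p : p + L] == q and p + L <= lenR:
            return L * P.match, L, [], 0

        # fast path: exact prefix then an un-matchable all-A suffix -> clip
        m = 0
        lim = min(L, lenR - p)
        while m < lim and q[m] == R[p + m]:
            m += 1
        suffix = q[m:]
        if (
            m >= P.seed_length
            and suffix
            and set(suffix) == {"A"}
            and "A" not in R[p + m : p + L + D]
        ):
            return m * P.match, m, [], 0

        # full banded DP
        score = [[NEG_INF] * (D + 1) for _ in range(L + 1)]
        parent: List[List[Optional[Tuple[int, int]]]] = [
            [None] * (D + 1) for _ in range(L + 1)
        ]
        score[0][0] = 0.0
        for i in range(1, L + 1):
            qc = q[i - 1]
            row = score[i]
            prev = score[i - 1]
            par = parent[i]
            for d in range(D + 1):
                ri = p + i - 1 + d
                best = NEG_INF
                bpar = None
                if ri < lenR and prev[d] > NEG_INF:
                    s = prev[d] + (P.match if qc == R[ri] else P.mismatch)
                    if s > best:
                        best, bpar = s, (i - 1, d)
                for g in (1, 2, 3):
                    if d - g < 0:
                        break
                    s = row[d - g] + P.gap_per_base * g
                    if s > best:
                        best, bpar = s, (i, d - g)
                row[d] = best
                par[d] = bpar
        best_score, best_i, best_d = NEG_INF, 0, 0
        for i in range(1, L + 1):
            for d in range(D + 1):
                s = score[i][d]
                # prefer higher score, then fewer clipped bases, then fewer dels
                if s > best_score or (
                    s == best_score and (i > best_i or (i == best_i and d < best_d))
                ):
                    best_score, best_i, best_d = s, i, d
        if best_score <= 0:
            return NEG_INF, 0, [], 0
        # traceback for deletion layout and mismatch count
        dels: List[Tuple[int, int]] = []
        nm = 0
        i, d = best_i, best_d
        while (i, d) != (0, 0):
            pi, pd = parent[i][d]
            if pi == i:  # gap
                dels.append((i, d - pd))
            else:
                if q[i - 1] != R[p + i - 1 + d]:
                    nm += 1
            i, d = pi, pd
        dels.reverse()
        # merge adjacent gap steps at the same query index
        merged: List[Tuple[int, int]] = []
        for qi, g in dels:
            if merged and merged[-1][0] == qi:
                merged[-1] = (qi, merged[-1][1] + g)
            else:
                merged.append((qi, g))
        return best_score, best_i, merged, nm

    # -- public API -------------------------------------------------------

    def align(self, read_id: str, seq: str, count: int = 1) -> Optional[AlignedRead]:
        """Best alignment of ``seq``, or None if no seed hit scores > 0."""
        P = self.params
        k = P.seed_length
        if len(seq) < k:
            return None
        hits = self._index.get(seq[:k])
        if not hits:
            return None
        best_score: Optional[int] = None
        best_key = None  # (ref index, fwd start, strand): ties -> lowest locus
        best_data = None
        best_loci: set = set()
        for ref_i, strand, p in hits:
            name, fseq, entry = self.refs[ref_i]
            isj = entry is not None
            R = fseq if strand == "+" else revcomp(fseq)
            sc, consumed, dels, nm = self._extend(seq, R, p)
            if sc == NEG_INF:
                continue
            ref_span = consumed + sum(g for _, g in dels)
            if strand == "+":
                fwd_start = p
            else:
                fwd_start = len(fseq) - (p + ref_span)
            # canonical locus: a junction-entry placement that stays on one
            # side of the junction is the same locus as its genomic image
            if isj:
                seg = entry.coords[fwd_start : fwd_start + ref_span]
                if seg and max(seg) - min(seg) == ref_span - 1:
                    gstrand = (
                        entry.strand
                        if strand == "+"
                        else ("-" if entry.strand == "+" else "+")
                    )
                    locus = (entry.chrom, gstrand, min(seg))
                else:
                    locus = (name, strand, fwd_start)
            else:
                locus = (name, strand, fwd_start)
            key = (ref_i, fwd_start, strand)
            if best_score is None or sc > best_score:
                best_score = sc
                best_key = key
                best_loci = {locus}
                best_data = (name, strand, fwd_start, consumed, dels, nm, isj)
            elif sc == best_score:
                best_loci.add(locus)
                if key < best_key:
                    best_key = key
                    best_data = (name, strand, fwd_start, consumed, dels, nm, isj)
        if best_data is None:
            return None
        name, strand, fwd_start, consumed, dels, nm, isj = best_data
        cigar_fwd5: List[Tuple[int, str]] = []  # read 5'->3' along oriented ref
        qpos = 0
        for qi, g in dels:
            if qi > qpos:
                cigar_fwd5.append((qi - qpos, "M"))
            cigar_fwd5.append((g, "D"))
            qpos = qi
        if consumed > qpos:
            cigar_fwd5.append((consumed - qpos, "M"))
        soft3 = seq[consumed:]
        if soft3:
            cigar_fwd5.append((len(soft3), "S"))
        cigar = cigar_fwd5 if strand == "+" else list(reversed(cigar_fwd5))
        return AlignedRead(
            read_id=read_id,
            ref=name,
            strand=strand,
            start=fwd_start,
            cigar=cigar,
            seq=seq,
            soft3=soft3,
            count=count,
            score=int(best_score),
            nm=nm,
            multi=len(best_loci) > 1,
            is_junction=isj,
        )

    def align_all(
        self, reads: Iterable[Tuple[str, str, int]], drop_multi: bool = True
    ) -> Tuple[List[AlignedRead], int]:
        """Align prepared reads; returns (alignments, n_unmapped).

        Multi-locus reads are dropped when ``drop_multi`` (default),
        matching the reproducibility-first counting policy.
        """
        out: List[AlignedRead] = []
        unmapped = 0
        for rid, seq, count in reads:
            aln = self.align(rid, seq, count)
            if aln is None:
                unmapped += 1
            elif aln.multi and drop_multi:
                unmapped += 1
            else:
                out.append(aln)
        return out, unmapped


# ---------------------------------------------------------------------------
# junction lift-over


def lift_junction_alignment(
    aln: AlignedRead, library: JunctionLibrary
) -> AlignedRead:
    """Lift an EE-entry alignment to genomic coordinates as M-N-M.

    Walks the alignment base by base through the entry's genomic coordinate
    map and re-encodes jumps as N (the intron).
    """
    if not aln.is_junction:
        return aln
    entry = library.by_name()[aln.ref]
    coords = entry.coords  # entry-forward base -> genomic coordinate
    # per-base ops along the entry-forward reference
    ops: List[Tuple[int, str]] = []  # (genomic coord, op) for M/D bases
    clip_left = clip_right = 0
    rpos = aln.start
    for n, op in aln.cigar:
        if op == "S":
            if not ops and rpos == aln.start:
                clip_left = n
            else:
                clip_right = n
        elif op in "MD":
            for _ in range(n):
                ops.append((coords[rpos], op))
                rpos += 1
        else:
            raise ValueError(f"unexpected op {op} in junction alignment")
    ascending = len(ops) < 2 or ops[0][0] < ops[-1][0]
    if not ascending:
        ops.reverse()
        clip_left, clip_right = clip_right, clip_left
    gstrand = entry.strand if aln.strand == "+" else ("-" if entry.strand == "+" else "+")
    cigar: List[Tuple[int, str]] = []
    if clip_left:
        cigar.append((clip_left, "S"))
    prev_g = None
    for g, op in ops:
        if prev_g is not None and g != prev_g + 1:
            cigar.append((g - prev_g - 1, "N"))
        if cigar and cigar[-1][1] == op and cigar[-1][1] != "N":
            cigar[-1] = (cigar[-1][0] + 1, op)
        else:
            cigar.append((1, op))
        prev_g = g
    if clip_right:
        cigar.append((clip_right, "S"))
    return AlignedRead(
        read_id=aln.read_id,
        ref=entry.chrom,
        strand=gstrand,
        start=ops[0][0],
        cigar=cigar,
        seq=aln.seq,
        soft3=aln.soft3,
        count=aln.count,
        score=aln.score,
        nm=aln.nm,
        multi=aln.multi,
        is_junction=True,
    )


def lift_all(alignments: Sequence[AlignedRead], library: Optional[JunctionLibrary]) -> List[AlignedRead]:
    if library is None:
        return list(alignments)
    return [lift_junction_alignment(a, library) for a in alignments]


# ---------------------------------------------------------------------------
# SAM interchange

_SUPPORTED_OPS = set("MIDNS")


def write_sam(path: str | Path, alignments: Sequence[AlignedRead], genome: Genome) -> None:
    """Plain-text SAM with @SQ headers from the genome.

    Junction alignments must be lifted to genomic coordinates first.
    Collapsed multiplicity goes in the ``XC`` tag, the 3' soft-clip
    sequence in ``XT``.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": ln} for name, ln in genome.lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            a = pysam.AlignedSegment(out.header)
            a.query_name = aln.read_id
            a.flag = 16 if aln.strand == "-" else 0
            a.reference_name = aln.ref
            a.reference_start = aln.start
            a.mapping_quality = 0 if aln.multi else 60
            a.cigarstring = aln.cigar_string()
            a.query_sequence = aln.seq if aln.strand == "+" else revcomp(aln.seq)
            a.set_tag("XC", aln.count)
            a.set_tag("NM", aln.nm)
            if aln.soft3:
                a.set_tag("XT", aln.soft3)
            out.write(a)


_OP_CODE = "MIDNSHP=X"


def read_sam(path: str | Path) -> List[AlignedRead]:
    """Import SAM records produced by this package or an external aligner.

    ``=``/``X`` are normalized to M; hard clips and padding are rejected
    with an explanatory error.
    """
    out: List[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            cigar: List[Tuple[int, str]] = []
            for code, n in rec.cigartuples or []:
                op = _OP_CODE[code]
                if op in "=X":
                    op = "M"
                if op not in _SUPPORTED_OPS:
                    raise ValueError(
                        f"record {rec.query_name}: unsupported CIGAR op {op!r} "
                        "(hard-clipped/padded records cannot be represented)"
                    )
                if cigar and cigar[-1][1] == op:
                    cigar[-1] = (cigar[-1][0] + n, op)
                else:
                    cigar.append((n, op))
            strand = "-" if rec.is_reverse else "+"
            seq = rec.query_sequence or ""
            if strand == "-":
                seq = revcomp(seq)
            if strand == "+":
                soft3 = seq[len(seq) - cigar[-1][0]:] if cigar and cigar[-1][1] == "S" else ""
            else:
                soft3 = seq[len(seq) - cigar[0][0]:] if cigar and cigar[0][1] == "S" else ""
            out.append(
                AlignedRead(
                    read_id=rec.query_name,
                    ref=rec.reference_name,
                    strand=strand,
                    start=rec.reference_start,
                    cigar=cigar,
                    seq=seq,
                    soft3=soft3,
                    count=int(rec.get_tag("XC")) if rec.has_tag("XC") else 1,
                    nm=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                    multi=rec.mapping_quality == 0,
                )
            )
    return out
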