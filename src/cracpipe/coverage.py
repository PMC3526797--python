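"""Per-base coverage tracks, single-RNA profiles and anchored metagenes.

Two track kinds exist throughout: ``hits`` (reference bases covered by M
ops) and ``dels`` (reference bases skipped by D ops — positional crosslink
evidence).  Both can be computed from the total library or from the
A-tail-filtered subset, always in hpm with the full library size as the
denominator, so a filtered track never exceeds the total track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import AlignedRead
from .annotation import Feature
from .genome import Genome


@dataclass
class CoverageTrack:
    chrom: str
    start: int
    values: np.ndarray  # per-base density in hpm over [start, start+len)
    kind: str = "hits"  # hits | dels
    filter: str = "total"  # total | a_tailed
    strand: Optional[str] = None  # None = both strands pooled

    @property
    def end(self) -> int:
        return self.start + len(self.values)


def pileup(
    alignments: Sequence[AlignedRead],
    chrom: str,
    start: int,
    end: int,
    kind: str = "hits",
    strand: Optional[str] = None,
    total_mapped: Optional[int] = None,
    genome: Optional[Genome] = None,
    filter_label: str = "total",
) -> CoverageTrack:
    """Per-base hit or deletion density over ``chrom[start:end)`` in hpm.

    ``total_mapped`` is the hpm denominator in read units (defaults to the
    summed multiplicity of the alignments passed in); pass the full library
    size when piling up a filtered subset.  M bases contribute to ``hits``;
    D bases to ``dels``; N gaps to neither.
    """
    if kind not in ("hits", "dels"):
        raise ValueError(f"unknown track kind {kind!r}")
    if genome is not None:
        if chrom not in genome:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(genome[chrom]):
            raise ValueError(f"region {chrom}:{start}-{end} outside genome")
    if end < start:
        raise ValueError("end < start")
    n = total_mapped if total_mapped is not None else sum(a.count for a in alignments)
    scale = 1e6 / n if n else 0.0
    values = np.zeros(end - start, dtype=float)
    for aln in alignments:
        if aln.ref != chrom:
            continue
        if strand is not None and aln.strand != strand:
            continue
        weight = scale * aln.count
        pos = aln.start
        for ln, op in aln.cigar:
            if op in "MD":
                if (op == "M") == (kind == "hits"):
                    lo = max(pos, start)
                    hi = min(pos + ln, end)
                    if hi > lo:
                        values[lo - start : hi - start] += weight
                pos += ln
            elif op == "N":
                pos += ln
    return CoverageTrack(chrom, start, values, kind, filter_label, strand)


@dataclass
class MetageneMatrix:
    """Per-gene coverage rows aligned at a common anchor column.

    ``matrix`` rows are transcript-oriented hpm coverage; ``anchor_col`` is
    the column index of the anchor base in every row; ``row_meta`` carries
    intron boundaries / lengths for display (the red lines of a
    junction-anchored heat map).
    """

    matrix: pd.DataFrame
    anchor_col: int
    anchor_kind: str
    row_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def row_normalized(self) -> pd.DataFrame:
        m = self.matrix.to_numpy(dtype=float)
        denom = np.nansum(np.abs(m), axis=1, keepdims=True)
        denom[denom == 0] = 1.0
        return pd.DataFrame(m / denom, index=self.matrix.index, columns=self.matrix.columns)


def _chrom_tracks(
    alignments: Sequence[AlignedRead],
    genome: Genome,
    kind: str,
    total_mapped: Optional[int],
) -> Dict[Tuple[str, str], np.ndarray]:
    """Strand-specific whole-chromosome pileups, computed once."""
    out: Dict[Tuple[str, str], np.ndarray] = {}
    for chrom, seq in genome.items():
        for strand in "+-":
            sub = [a for a in alignments if a.ref == chrom and a.strand == strand]
            out[(chrom, strand)] = pileup(
                sub, chrom, 0, len(seq), kind=kind,
                total_mapped=total_mapped or sum(a.count for a in alignments),
            ).values
    return out


def metagene_3ss(
    alignments: Sequence[AlignedRead],
    features: Sequence[Feature],
    genome: Genome,
    window: Tuple[int, int] = (300, 100),
    kind: str = "hits",
    total_mapped: Optional[int] = None,
) -> MetageneMatrix:
    """Coverage matrix of spliced genes anchored at their 3' splice sites.

    Rows are ordered by intron length (longest first); genes with several
    introns anchor on the first (5'-most) intron.  Columns run from
    ``-window[0]`` (into the intron / upstream exon) to ``+window[1]``
    (into the downstream exon) in transcript orientation.
    """
    spliced = [f for f in features if f.spliced]
    if not spliced:
        raise ValueError("no spliced genes")
    up, down = window
    tracks = _chrom_tracks(alignments, genome, kind, total_mapped)
    spliced.sort(key=lambda f: (-(f.introns_tx()[0][1] - f.introns_tx()[0][0]), f.id))
    cols = np.arange(-up, down)
    data = np.full((len(spliced), up + down), np.nan)
    meta_rows = []
    for r, f in enumerate(spliced):
        track = tracks[(f.chrom, f.strand)]
        _ss5, ss3 = f.splice_sites_tx()[0]
        ia, ib = f.introns_tx()[0]
        ilen = ib - ia
        step = 1 if f.strand == "+" else -1
        for c, off in enumerate(cols):
            g = ss3 + step * off
            if 0 <= g < len(track):
                data[r, c] = track[g]
        meta_rows.append(
            {"gene": f.id, "intron_length": ilen, "intron_start_col": -ilen + 1, "anchor": ss3}
        )
    mat = pd.DataFrame(data, index=[f.id for f in spliced], columns=cols)
    return MetageneMatrix(mat, anchor_col=up, anchor_kind="3'SS", row_meta=pd.DataFrame(meta_rows))


def trna_profile(
    alignments: Sequence[AlignedRead],
    features: Sequence[Feature],
    genome: Genome,
    flank: int = 30,
    kind: str = "hits",
    total_mapped: Optional[int] = None,
) -> MetageneMatrix:
    """tRNA coverage rows aligned at the mature 5' end, ranked by length.

    Ranking length includes the intron when present; ``flank`` nt of
    flanking coverage are kept on both sides so 5' leaders and 3' trailers
    of precursor reads stay visible.
    """
    trnas = [f for f in features if f.tx_class == "tRNA"]
    if not trnas:
        raise ValueError("no tRNA features")
    tracks = _chrom_tracks(alignments, genome, kind, total_mapped)
    trnas.sort(key=lambda f: (-f.precursor_length, f.id))
    max_len = max(f.precursor_length for f in trnas)
    ncol = flank + max_len + flank
    cols = np.arange(-flank, max_len + flank)
    data = np.full((len(trnas), ncol), np.nan)
    meta_rows = []
    for r, f in enumerate(trnas):
        track = tracks[(f.chrom, f.strand)]
        five = f.five_prime_end()
        step = 1 if f.strand == "+" else -1
        hi = f.precursor_length + flank
        for c, off in enumerate(cols):
            if off >= hi:
                break
            g = five + step * off
            if 0 <= g < len(track):
                data[r, c] = track[g]
        introns = f.introns_tx()
        meta_rows.append(
            {
                "trna": f.id,
                "precursor_length": f.precursor_length,
                "has_intron": bool(introns),
                "intron_cols": [
                    (
                        (ia - f.start) if f.strand == "+" else (f.end - ib),
                        ib - ia,
                    )
                    for ia, ib in introns
                ],
            }
        )
    mat = pd.DataFrame(data, index=[f.id for f in trnas], columns=cols)
    return MetageneMatrix(mat, anchor_col=flank, anchor_kind="mature 5' end", row_meta=pd.DataFrame(meta_rows))


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """0-based half-open bedGraph; zero runs are omitted, equal runs merged."""
    name = f"{track.kind}_{track.filter}" + (f"_{track.strand}" if track.strand else "")
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        v = track.values
        i = 0
        while i < len(v):
            j = i
            while j < len(v) and v[j] == v[i]:
                j += 1
            if v[i] != 0:
                fh.write(f"{track.chrom}\t{track.start + i}\t{track.start + j}\t{v[i]:g}\n")
            i = j


def read_bedgraph(path: str | Path) -> List[Tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("track") or not line.strip():
                continue
            chrom, s, e, val = line.split()
            out.append((chrom, int(s), int(e), float(val)))
    return out


def metagene_to_tsv(mg: MetageneMatrix, path: str | Path) -> None:
    """Matrix as TSV with a `.meta.tsv` row-metadata sidecar."""
    p = Path(path)
    mg.matrix.to_csv(p, sep="\t")
    if not mg.row_meta.empty:
        mg.row_meta.to_csv(p.with_suffix(".meta.tsv"), sep="\t", index=False)
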