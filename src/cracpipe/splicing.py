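"""Pre-mRNA vs mature-mRNA statistics from junction-spanning reads.

Three ratios summarize how much unspliced precursor a protein binds:

* ``IE/EE`` — reads crossing intron-exon boundaries (only possible on the
  precursor) relative to reads crossing exon-exon junctions (only possible
  on spliced mRNA);
* ``introns/total mRNA`` — reads touching intronic sequence relative to
  all mRNA-mapped reads (excised introns are indistinguishable from
  pre-mRNA here);
* ``3'SS/5'SS`` — coverage in windows around 3' splice sites relative to
  5' splice sites.

A read counts toward a junction only if it covers the boundary with at
least ``min_overhang`` aligned nt on each side.  Standard errors come from
replicate spread, or from a seeded bootstrap over genes when only one
replicate exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .align import AlignedRead
from .annotation import Feature
from .coverage import pileup
from .genome import Genome


@dataclass
class GeneJunctionCounts:
    ie5: float = 0.0
    ie3: float = 0.0
    ee: float = 0.0
    intron: float = 0.0
    total_mrna: float = 0.0
    ss5: float = 0.0
    ss3: float = 0.0


@dataclass
class JunctionCounts:
    """Per-experiment junction and splice-site statistics, in hpm."""

    ie5: float = 0.0
    ie3: float = 0.0
    ee: float = 0.0
    intron_hpm: float = 0.0
    total_mrna_hpm: float = 0.0
    ss5: float = 0.0
    ss3: float = 0.0
    per_gene: Dict[str, GeneJunctionCounts] = field(default_factory=dict)

    @property
    def ie(self) -> float:
        return self.ie5 + self.ie3

    def ratio(self, which: str) -> float:
        if which == "IE/EE":
            num, den = self.ie, self.ee
        elif which == "introns/totalmRNA":
            num, den = self.intron_hpm, self.total_mrna_hpm
        elif which == "3SS/5SS":
            num, den = self.ss3, self.ss5
        else:
            raise ValueError(f"unknown ratio {which!r}")
        if den == 0:
            raise ZeroDivisionError(f"zero denominator for {which}")
        return num / den


def _m_covered(aln: AlignedRead) -> List[Tuple[int, int]]:
    """Reference intervals covered by M ops."""
    out = []
    pos = aln.start
    for n, op in aln.cigar:
        if op == "M":
            out.append((pos, pos + n))
            pos += n
        elif op in "DN":
            pos += n
    return out


def _covers(intervals: List[Tuple[int, int]], lo: int, hi: int) -> bool:
    """True iff [lo,hi) is entirely inside one covered interval."""
    return any(a <= lo and hi <= b for a, b in intervals)


def _n_gaps(aln: AlignedRead) -> List[Tuple[int, int]]:
    out = []
    pos = aln.start
    for n, op in aln.cigar:
        if op == "N":
            out.append((pos, pos + n))
            pos += n
        elif op in "MD":
            pos += n
    return out


def count_junctions(
    alignments: Sequence[AlignedRead],
    features: Sequence[Feature],
    min_overhang: int = 1,
    total_mapped: Optional[int] = None,
    ss_window: int = 10,
    genome: Optional[Genome] = None,
) -> JunctionCounts:
    """Count IE/EE junction-spanning reads and intron/mRNA/SS statistics.

    Alignments must be in genomic coordinates (junction alignments lifted
    to M-N-M).  EE is counted when an alignment's N gap matches an
    annotated intron with ``min_overhang`` aligned nt on each side; IE5/IE3
    when a contiguous alignment spans the corresponding boundary.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    o = min_overhang
    n_total = total_mapped if total_mapped is not None else sum(a.count for a in alignments)
    scale = 1e6 / n_total if n_total else 0.0
    mrnas = [f for f in features if f.tx_class == "mRNA"]
    spliced = [f for f in mrnas if f.spliced]
    jc = JunctionCounts(per_gene={f.id: GeneJunctionCounts() for f in mrnas})

    # boundary catalog: (chrom, strand) -> list of (boundary p, kind, gene, intron)
    boundaries: Dict[Tuple[str, str], List[Tuple[int, str, str, Tuple[int, int]]]] = {}
    intron_index: Dict[Tuple[str, str], List[Tuple[Tuple[int, int], str]]] = {}
    for f in spliced:
        key = (f.chrom, f.strand)
        for intron in f.introns:
            ia, ib = intron
            if f.strand == "+":
                b5, b3 = ia - 1, ib - 1  # exon|intron and intron|exon boundaries
            else:
                b5, b3 = ib - 1, ia - 1
            boundaries.setdefault(key, []).append((b5, "IE5", f.id, intron))
            boundaries.setdefault(key, []).append((b3, "IE3", f.id, intron))
            intron_index.setdefault(key, []).append((intron, f.id))

    for aln in alignments:
        key = (aln.ref, aln.strand)
        w = scale * aln.count
        mcov = None
        gaps = _n_gaps(aln)
        if gaps:
            mcov = _m_covered(aln)
            for gap in gaps:
                for intron, gid in intron_index.get(key, []):
                    if gap == intron:
                        ia, ib = intron
                        if _covers(mcov, ia - o, ia) and _covers(mcov, ib, ib + o):
                            jc.ee += w
                            jc.per_gene[gid].ee += w
        else:
            for p, kind, gid, _intron in boundaries.get(key, []):
                if p < aln.start or p + 1 >= aln.end:
                    continue  # boundary not inside the aligned span
                if mcov is None:
                    mcov = _m_covered(aln)
                if _covers(mcov, p - o + 1, p + 1) and _covers(mcov, p + 1, p + o + 1):
                    w_ = w
                    if kind == "IE5":
                        jc.ie5 += w_
                        jc.per_gene[gid].ie5 += w_
                    else:
                        jc.ie3 += w_
                        jc.per_gene[gid].ie3 += w_

    # intron-touching and total mRNA-mapped reads
    for aln in alignments:
        hit_gene = None
        hit_intron = False
        for f in mrnas:
            if f.chrom != aln.ref or f.strand != aln.strand:
                continue
            if aln.start < f.end and aln.end > f.start:
                hit_gene = f.id
                mcov = _m_covered(aln)
                for ia, ib in f.introns:
                    if any(a < ib and b > ia for a, b in mcov):
                        hit_intron = True
                break
        if hit_gene is not None:
            w = scale * aln.count
            jc.total_mrna_hpm += w
            jc.per_gene[hit_gene].total_mrna += w
            if hit_intron:
                jc.intron_hpm += w
                jc.per_gene[hit_gene].intron += w

    # splice-site window coverage (3'SS/5'SS)
    if spliced:
        chroms = {f.chrom for f in spliced}
        tracks: Dict[Tuple[str, str], np.ndarray] = {}
        for chrom in chroms:
            length = (
                len(genome[chrom])
                if genome is not None
                else max(a.end for a in alignments if a.ref == chrom) + 1
                if any(a.ref == chrom for a in alignments)
                else 1
            )
            for strand in "+-":
                sub = [a for a in alignments if a.ref == chrom and a.strand == strand]
                tracks[(chrom, strand)] = pileup(
                    sub, chrom, 0, length, kind="hits", total_mapped=n_total
                ).values
        for f in spliced:
            track = tracks[(f.chrom, f.strand)]
            for ss5, ss3 in f.splice_sites_tx():
                for pos, attr in ((ss5, "ss5"), (ss3, "ss3")):
                    lo, hi = max(0, pos - ss_window), min(len(track), pos + ss_window)
                    s = float(track[lo:hi].sum())
                    setattr(jc, attr, getattr(jc, attr) + s)
                    g = jc.per_gene[f.id]
                    setattr(g, attr, getattr(g, attr) + s)
    return jc


def ratio_with_se(
    counts: Sequence[JunctionCounts],
    which: str,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Mean ratio across replicates and its standard error.

    With one replicate the SE comes from a seeded bootstrap over genes
    (resampling genes with replacement and recomputing the ratio).
    Replicates with a zero denominator are excluded with a warning.
    """
    ratios = []
    for i, c in enumerate(counts):
        try:
            ratios.append(c.ratio(which))
        except ZeroDivisionError:
            import warnings

            warnings.warn(f"replicate {i}: zero denominator for {which}, excluded")
    if not ratios:
        raise ValueError(f"no replicate with nonzero denominator for {which}")
    if len(ratios) > 1:
        return float(np.mean(ratios)), float(np.std(ratios, ddof=1) / np.sqrt(len(ratios)))
    # bootstrap over genes
    c = next(c for c in counts if _has_denominator(c, which))
    genes = list(c.per_gene.values())
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(genes), len(genes))
        num = den = 0.0
        for i in idx:
            g = genes[i]
            if which == "IE/EE":
                num += g.ie5 + g.ie3
                den += g.ee
            elif which == "introns/totalmRNA":
                num += g.intron
                den += g.total_mrna
            else:
                num += g.ss3
                den += g.ss5
        if den > 0:
            boots.append(num / den)
    se = float(np.std(boots, ddof=1)) if len(boots) > 1 else float("nan")
    return ratios[0], se


def _has_denominator(c: JunctionCounts, which: str) -> bool:
    try:
        c.ratio(which)
        return True
    except ZeroDivisionError:
        return False


def ss_preference(
    alignments: Sequence[AlignedRead],
    features: Sequence[Feature],
    genome: Genome,
    window: int = 10,
    total_mapped: Optional[int] = None,
) -> float:
    """Summed coverage in 3'SS windows over 5'SS windows, all spliced genes."""
    if not any(f.spliced and f.tx_class == "mRNA" for f in features):
        raise ValueError("no spliced mRNA genes")
    jc = count_junctions(
        alignments, features, total_mapped=total_mapped, ss_window=window, genome=genome
    )
    if jc.ss5 == 0:
        return float("inf") if jc.ss3 > 0 else float("nan")
    return jc.ss3 / jc.ss5
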