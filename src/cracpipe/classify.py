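"""Transcript-class attribution and hits-per-million count tables.

Every counted alignment is attributed to exactly one feature (or
"intergenic"): among same-strand overlapping features the highest-priority
class wins, ties go to the greatest overlap and then the lexicographically
smallest id; reads within a configurable flank of a feature attribute to it
as 5'/3'-flank (precursor reads extend beyond mature ends).  Counts are
normalized to hits per million mapped sequences (hpm), with intergenic
reads kept in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .align import AlignedRead
from .annotation import Feature
from .tails import TailCall

#: default attribution priority, most specific classes first
DEFAULT_PRIORITY = (
    "rRNA_35S",
    "rRNA_5S",
    "tRNA",
    "snRNA",
    "snoRNA",
    "scR1",
    "other_polIII",
    "CUT",
    "SUT",
    "mRNA",
    "other",
)

INTERGENIC = "intergenic"


@dataclass
class Attribution:
    read_id: str
    feature_id: str  # or "intergenic"
    tx_class: str  # or "intergenic"
    polymerase: Optional[str]
    region: str  # exon | intron | 5'-flank | 3'-flank | junction-EE | intergenic
    weight: float = 1.0  # collapsed read multiplicity


class FeatureIndex:
    """Interval-tree lookup of features by (chromosome, strand), with flanks."""

    def __init__(self, features: Sequence[Feature], flank: int = 50):
        self.flank = flank
        self.features = {f.id: f for f in features}
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        self._flank_trees: Dict[Tuple[str, str], IntervalTree] = {}
        for f in features:
            key = (f.chrom, f.strand)
            self._trees.setdefault(key, IntervalTree())[f.start : f.end] = f
            lo = max(0, f.start - flank)
            hi = f.end + flank
            self._flank_trees.setdefault(key, IntervalTree())[lo:hi] = f

    def overlapping(self, chrom: str, strand: str, start: int, end: int) -> List[Feature]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def flanking(self, chrom: str, strand: str, start: int, end: int) -> List[Feature]:
        tree = self._flank_trees.get((chrom, strand))
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def assign(
    aln: AlignedRead,
    index: FeatureIndex,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> Attribution:
    """Attribute one alignment to a single feature and region."""
    rank = {cls: i for i, cls in enumerate(priority)}
    start, end = aln.start, aln.end
    cands = index.overlapping(aln.ref, aln.strand, start, end)
    flank_hit = False
    if not cands:
        cands = index.flanking(aln.ref, aln.strand, start, end)
        flank_hit = True
    if not cands:
        return Attribution(aln.read_id, INTERGENIC, INTERGENIC, None, INTERGENIC, float(aln.count))
    best = min(
        cands,
        key=lambda f: (
            rank.get(f.tx_class, len(rank)),
            -_overlap(start, end, f.start, f.end),
            f.id,
        ),
    )
    if aln.is_junction:
        region = "junction-EE"
    elif flank_hit:
        # read beyond the feature body: which end, in transcript orientation?
        past_right = start >= best.end
        if best.strand == "+":
            region = "3'-flank" if past_right else "5'-flank"
        else:
            region = "5'-flank" if past_right else "3'-flank"
    else:
        exon_ov = sum(_overlap(start, end, a, b) for a, b in best.exons)
        region = "exon" if exon_ov > 0 else "intron"
    return Attribution(aln.read_id, best.id, best.tx_class, best.polymerase, region, float(aln.count))


def assign_all(
    alignments: Sequence[AlignedRead],
    index: FeatureIndex,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> List[Attribution]:
    return [assign(a, index, priority) for a in alignments]


def class_distribution(attributions: Sequence[Attribution]) -> Dict[str, float]:
    """Percentage of counted sequences per transcript class (sums to 100).

    Weighted by collapsed-read multiplicity, so every sequenced read
    contributes one unit.
    """
    if not attributions:
        raise ValueError("no counted alignments")
    counts: Dict[str, float] = {}
    for at in attributions:
        counts[at.tx_class] = counts.get(at.tx_class, 0.0) + at.weight
    total = sum(counts.values())
    return {cls: 100.0 * n / total for cls, n in sorted(counts.items())}


def polymerase_partition(attributions: Sequence[Attribution]) -> Dict[str, float]:
    """Fraction of feature-mapped reads per producing polymerase (sums to 1)."""
    counts = {"PolI": 0.0, "PolII": 0.0, "PolIII": 0.0}
    total = 0.0
    for at in attributions:
        if at.polymerase is not None:
            counts[at.polymerase] += at.weight
            total += at.weight
    if total == 0:
        raise ValueError("no feature-mapped alignments")
    return {pol: n / total for pol, n in counts.items()}


def atail_frequency_table(
    attributions: Sequence[Attribution],
    tailcalls: Dict[str, TailCall],
) -> Dict[str, float]:
    """Fraction of A-tailed reads: total and per polymerase (NaN if empty)."""
    num: Dict[str, float] = {"total": 0.0, "PolI": 0.0, "PolII": 0.0, "PolIII": 0.0}
    den: Dict[str, float] = dict(num)
    for at in attributions:
        tailed = tailcalls[at.read_id].a_tailed
        for key in ("total", at.polymerase):
            if key is not None:
                den[key] += at.weight
                num[key] += at.weight * tailed
    return {
        k: (num[k] / den[k] if den[k] > 0 else float("nan")) for k in den
    }


def per_rna_counts(
    attributions_by_experiment: Dict[str, Sequence[Attribution]],
    feature_ids: Optional[Sequence[str]] = None,
    log10_transform: bool = False,
) -> pd.DataFrame:
    """Features x experiments matrix in hpm.

    Every column sums to 1e6 over features plus the intergenic row (the
    normalization counts all mapped reads).  ``log10_transform`` returns
    log10(1+hpm) for display export instead.
    """
    if not attributions_by_experiment:
        raise ValueError("need at least one experiment")
    if feature_ids is None:
        ids = sorted(
            {at.feature_id for ats in attributions_by_experiment.values() for at in ats}
            - {INTERGENIC}
        )
    else:
        ids = list(feature_ids)
    rows = ids + [INTERGENIC]
    mat = pd.DataFrame(0.0, index=rows, columns=list(attributions_by_experiment))
    for label, ats in attributions_by_experiment.items():
        total = sum(at.weight for at in ats)
        if total == 0:
            continue
        counts: Dict[str, float] = {}
        for at in ats:
            counts[at.feature_id] = counts.get(at.feature_id, 0.0) + at.weight
        scale = 1e6 / total
        for fid, n in counts.items():
            if fid in mat.index:
                mat.loc[fid, label] = n * scale
    if log10_transform:
        return np.log10(1.0 + mat)
    return mat
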