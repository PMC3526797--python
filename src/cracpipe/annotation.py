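"""Transcript models: stranded multi-exon features with class labels.

Features carry one of a closed vocabulary of transcript classes (mRNA, tRNA,
rRNA units, sn/snoRNA, CUT, SUT, ...) and the RNA polymerase that produces
them.  GFF3 is read and written 1-based inclusive; internally everything is
0-based half-open in genomic (forward-strand) coordinates.  Minus-strand
features keep their exons in genomic order; transcript-oriented access goes
through :meth:`Feature.exons_tx` and friends, so 5'/3' logic always follows
the direction of transcription.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .genome import Genome, revcomp

logger = logging.getLogger(__name__)

TX_CLASSES = (
    "mRNA",
    "tRNA",
    "rRNA_35S",
    "rRNA_5S",
    "snRNA",
    "snoRNA",
    "CUT",
    "SUT",
    "scR1",
    "other_polIII",
    "other",
)

#: transcript class -> producing polymerase.  U6 is the one snRNA made by
#: Pol III; it is handled per-feature (see :func:`polymerase_for`).
CLASS_TO_POLYMERASE = {
    "rRNA_35S": "PolI",
    "tRNA": "PolIII",
    "rRNA_5S": "PolIII",
    "scR1": "PolIII",
    "other_polIII": "PolIII",
    "mRNA": "PolII",
    "snRNA": "PolII",
    "snoRNA": "PolII",
    "CUT": "PolII",
    "SUT": "PolII",
    "other": "PolII",
}

#: feature ids treated as Pol III regardless of class (U6 snRNA).
POLIII_IDS = {"snR6", "U6"}


def polymerase_for(tx_class: str, feature_id: str = "") -> str:
    if feature_id in POLIII_IDS:
        return "PolIII"
    return CLASS_TO_POLYMERASE[tx_class]


@dataclass
class Feature:
    """A stranded transcript model: ordered exons plus class labels.

    ``exons`` are 0-based half-open genomic intervals, non-overlapping and
    sorted in genomic coordinates; introns are the gaps between consecutive
    exons.
    """

    id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    tx_class: str = "other"
    polymerase: Optional[str] = None
    gene_sets: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be + or -, got {self.strand!r}")
        if self.tx_class not in TX_CLASSES:
            raise ValueError(f"{self.id}: unknown tx_class {self.tx_class!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if not a < b:
                raise ValueError(f"{self.id}: empty exon [{a},{b})")
        for (_, b1), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 < b1:
                raise ValueError(f"{self.id}: overlapping exons")
        if self.polymerase is None:
            self.polymerase = polymerase_for(self.tx_class, self.id)
        expected = polymerase_for(self.tx_class, self.id)
        if self.polymerase != expected:
            raise ValueError(
                f"{self.id}: polymerase {self.polymerase} inconsistent with "
                f"class {self.tx_class} (expected {expected})"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> List[Tuple[int, int]]:
        """Genomic intervals of the gaps between consecutive exons."""
        return [
            (b1, a2) for (_, b1), (a2, _) in zip(self.exons, self.exons[1:]) if a2 > b1
        ]

    @property
    def spliced(self) -> bool:
        return len(self.introns) > 0

    def exons_tx(self) -> List[Tuple[int, int]]:
        """Exons in transcript (5'->3') order."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns_tx(self) -> List[Tuple[int, int]]:
        """Introns in transcript (5'->3') order."""
        return self.introns if self.strand == "+" else list(reversed(self.introns))

    @property
    def precursor_length(self) -> int:
        """Unspliced span, introns included."""
        return self.end - self.start

    @property
    def mature_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    def five_prime_end(self) -> int:
        """Genomic coordinate of the transcript 5' end (0-based base)."""
        return self.start if self.strand == "+" else self.end - 1

    def three_prime_end(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def splice_sites_tx(self) -> List[Tuple[int, int]]:
        """Per intron (transcript order): (5'SS base, 3'SS base) genomic coords.

        The 5'SS is the first intronic base after the upstream exon; the 3'SS
        is the last intronic base before the downstream exon, both in
        transcript orientation.
        """
        sites = []
        for a, b in self.introns_tx():
            if self.strand == "+":
                sites.append((a, b - 1))
            else:
                sites.append((b - 1, a))
        return sites

    def precursor_sequence(self, genome: Genome) -> str:
        """Unspliced transcript sequence, 5'->3'."""
        seq = genome.fetch(self.chrom, self.start, self.end)
        return seq if self.strand == "+" else revcomp(seq)

    def mature_sequence(self, genome: Genome) -> str:
        """Spliced transcript sequence, 5'->3'."""
        seq = "".join(genome.fetch(self.chrom, a, b) for a, b in self.exons)
        return seq if self.strand == "+" else revcomp(seq)


def load_annotation(
    path: str | Path,
    genome: Genome,
    class_attr: str = "tx_class",
) -> List[Feature]:
    """Parse a GFF3 file into :class:`Feature` objects.

    Transcript lines carry the class in attribute ``class_attr`` (plus
    optional ``gene_sets``, comma-separated); ``exon`` lines attach to their
    ``Parent``.  A transcript line without exon children is a single-exon
    feature.  Unknown classes sink to "other" with a warning; coordinates
    beyond the chromosome end are a hard error naming the feature.
    """
    transcripts: Dict[str, dict] = {}
    order: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            attrd = _parse_attrs(attrs)
            start0, end0 = int(start) - 1, int(end)  # 1-based incl -> 0-based half-open
            if ftype == "exon":
                parent = attrd.get("Parent")
                if parent is None:
                    raise ValueError(f"exon without Parent: {line!r}")
                transcripts.setdefault(parent, {"exons": []})
                transcripts[parent]["exons"].append((start0, end0))
            else:
                fid = attrd.get("ID", f"{ftype}:{chrom}:{start}")
                if fid not in transcripts:
                    order.append(fid)
                rec = transcripts.setdefault(fid, {"exons": []})
                rec.update(
                    chrom=chrom,
                    strand=strand,
                    span=(start0, end0),
                    tx_class=attrd.get(class_attr, ftype),
                    gene_sets=[
                        s for s in attrd.get("gene_sets", "").split(",") if s
                    ],
                )
    features = []
    for fid in order:
        rec = transcripts[fid]
        if "chrom" not in rec:
            raise ValueError(f"exons reference unknown transcript {fid!r}")
        exons = rec["exons"] or [rec["span"]]
        tx_class = rec["tx_class"]
        if tx_class not in TX_CLASSES:
            logger.warning("feature %s: unknown tx_class %r -> 'other'", fid, tx_class)
            warnings.warn(f"feature {fid}: unknown tx_class {tx_class!r} -> 'other'")
            tx_class = "other"
        feat = Feature(
            id=fid,
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=exons,
            tx_class=tx_class,
            gene_sets=rec["gene_sets"],
        )
        if feat.chrom not in genome:
            raise ValueError(f"feature {fid}: unknown chromosome {feat.chrom!r}")
        if feat.start < 0 or feat.end > len(genome[feat.chrom]):
            raise ValueError(
                f"feature {fid}: exon beyond chromosome end "
                f"({feat.start}-{feat.end} on {feat.chrom}, "
                f"length {len(genome[feat.chrom])})"
            )
        features.append(feat)
    return features


def write_annotation(features: Sequence[Feature], path: str | Path) -> None:
    """Write features as GFF3 (1-based inclusive); inverse of load_annotation."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.id};tx_class={f.tx_class};polymerase={f.polymerase}"
            if f.gene_sets:
                attrs += ";gene_sets=" + ",".join(f.gene_sets)
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        "cracpipe",
                        "transcript",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for i, (a, b) in enumerate(f.exons, 1):
                fh.write(
                    "\t".join(
                        [
                            f.chrom,
                            "cracpipe",
                            "exon",
                            str(a + 1),
                            str(b),
                            ".",
                            f.strand,
                            ".",
                            f"ID={f.id}.exon{i};Parent={f.id}",
                        ]
                    )
                    + "\n"
                )


def _parse_attrs(attrs: str) -> Dict[str, str]:
    out = {}
    for kv in attrs.split(";"):
        kv = kv.strip()
        if kv and "=" in kv:
            k, v = kv.split("=", 1)
            out[k] = v
    return out
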