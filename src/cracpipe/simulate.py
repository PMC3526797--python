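"""Synthetic CRAC read simulator with ground-truth manifest.

Generates a toy genome with embedded transcript features, then draws short
(~20-50 nt) sense-strand reads whose statistical structure mimics a CRAC
cDNA library:

* per-class binding weights (which RNA classes the protein prefers),
* per-feature positional profiles (uniform + a peak at the crosslink site),
* reverse-transcriptase microdeletions of 1-2 nt at crosslink sites with
  probability ``delta``,
* non-templated 3' oligo(A) tails (>= 2 nt, geometric length) at
  class-dependent frequencies ``pi_A``,
* uniform substitution errors, precursor-vs-mature template choice for
  spliced genes, and a 3' sequencing adapter.

Every stochastic event is recorded in a per-read manifest so downstream
callers can be scored against the truth.  All randomness flows from a
single integer seed; a fixed seed reproduces the FASTQ and manifest
byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import Feature
from .genome import Genome, revcomp

#: default per-class binding weights: a nuclear-surveillance-flavoured
#: mixture with strong rRNA and mRNA components and a visible Pol III share.
DEFAULT_CLASS_WEIGHTS: Dict[str, float] = {
    "rRNA_35S": 0.30,
    "mRNA": 0.30,
    "tRNA": 0.14,
    "snoRNA": 0.08,
    "snRNA": 0.05,
    "CUT": 0.05,
    "SUT": 0.04,
    "rRNA_5S": 0.02,
    "scR1": 0.02,
}

#: default per-class oligo(A)-tailing probabilities (surveillance-target
#: classes tail more often).
DEFAULT_PI_A: Dict[str, float] = {
    "rRNA_35S": 0.10,
    "mRNA": 0.05,
    "tRNA": 0.30,
    "snoRNA": 0.10,
    "snRNA": 0.10,
    "CUT": 0.20,
    "SUT": 0.10,
    "rRNA_5S": 0.10,
    "scR1": 0.10,
}

DEFAULT_ADAPTER = "TGGCGTCGTCTGCCGTGGCGT"


@dataclass
class PositionalProfile:
    """Mixture of a uniform component and a peak at the crosslink site.

    ``peak_weight`` is the probability a read start is drawn from the peaked
    component (normal around the site, sd ``width`` nt, shifted so the read
    covers the site); the remainder is uniform over the template.
    """

    peak_weight: float = 0.6
    width: float = 8.0


@dataclass
class SimConfig:
    n_reads: int = 10000
    read_length: Tuple[int, int] = (20, 50)
    class_weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    feature_weights: Dict[str, float] = field(default_factory=dict)
    profile: PositionalProfile = field(default_factory=PositionalProfile)
    crosslink_sites: Dict[str, List[Tuple[int, float]]] = field(default_factory=dict)
    pi_a: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PI_A))
    tail_geom_p: float = 0.5
    seq_error: float = 0.0
    pre_mature_ratio: float = 0.5
    precursor_extension: int = 10
    antisense_rate: float = 0.0
    del_length_probs: Tuple[float, float] = (0.8, 0.2)  # P(1 nt), P(2 nt)
    adapter: str = DEFAULT_ADAPTER
    min_insert: int = 15
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.read_length
        if not (0 < lo <= hi):
            raise ValueError("read_length must satisfy 0 < min <= max")
        if not any(w > 0 for w in self.class_weights.values()):
            raise ValueError("at least one class weight must be positive")
        if any(w < 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be non-negative")
        for name, v in (("seq_error", self.seq_error),
                        ("pre_mature_ratio", self.pre_mature_ratio),
                        ("antisense_rate", self.antisense_rate)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        for cls, p in self.pi_a.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"pi_a[{cls}] must be in [0,1]")
        for fid, sites in self.crosslink_sites.items():
            for _, d in sites:
                if not 0.0 <= d <= 1.0:
                    raise ValueError(f"delta for {fid} must be in [0,1]")


@dataclass
class ManifestRecord:
    read_id: str
    feature_id: str
    tx_class: str
    template: str  # precursor | mature
    strand: str
    genomic_start: int
    genomic_end: int
    deletions: List[int]
    tail: str
    n_errors: int
    antisense: bool

    @property
    def a_tailed(self) -> bool:
        return len(self.tail) >= 2


@dataclass
class TruthManifest:
    config: SimConfig
    records: List[ManifestRecord] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"config": asdict(self.config)}) + "\n")
            for r in self.records:
                fh.write(json.dumps(asdict(r)) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            header = json.loads(fh.readline())
            cfg = header["config"]
            cfg["read_length"] = tuple(cfg["read_length"])
            cfg["del_length_probs"] = tuple(cfg["del_length_probs"])
            cfg["profile"] = PositionalProfile(**cfg["profile"])
            cfg["crosslink_sites"] = {
                k: [tuple(s) for s in v] for k, v in cfg["crosslink_sites"].items()
            }
            config = SimConfig(**cfg)
            records = [ManifestRecord(**json.loads(line)) for line in fh]
        return cls(config=config, records=records)


# ---------------------------------------------------------------------------
# genome forging


@dataclass
class ForgeSpec:
    """How many features of each kind to embed in the toy genome."""

    mrna_spliced: int = 6
    mrna_intronless: int = 6
    trna: int = 4
    trna_spliced: int = 2
    snorna: int = 3
    snrna: int = 1  # plus U6, always included
    rrna_35s: int = 1
    rrna_5s: int = 1
    cut: int = 3
    sut: int = 2
    scr1: int = 1
    spacer: int = 120
    intron_length_bands: Tuple[Tuple[int, int], Tuple[int, int]] = ((80, 120), (350, 450))
    alphabet: str = "ACGT"
    strands: str = "+-"  # "+" places every feature on the forward strand

    def total(self) -> int:
        return (
            self.mrna_spliced + self.mrna_intronless + self.trna + self.trna_spliced
            + self.snorna + self.snrna + self.rrna_35s + self.rrna_5s
            + self.cut + self.sut + self.scr1
        )


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def forge_genome(
    spec: Optional[ForgeSpec] = None, seed: int = 0
) -> Tuple[Genome, List[Feature], Dict[str, int]]:
    """Forge a random genome with embedded annotated features.

    Returns the genome, the feature list (GFF3-writable), and a default
    crosslink site per feature (a genomic coordinate inside the first exon).
    Deterministic given ``seed``.  Features alternate between strands so
    both orientations are exercised.
    """
    spec = spec or ForgeSpec()
    if spec.total() == 0:
        raise ValueError("feature counts are all zero")
    rng = np.random.default_rng(seed)

    plan: List[Tuple[str, str, List[int]]] = []  # (tx_class, id, exon lengths)
    for i in range(spec.mrna_spliced):
        band = spec.intron_length_bands[i % 2]
        intron = int(rng.integers(band[0], band[1] + 1))
        e1 = int(rng.integers(100, 200))
        e2 = int(rng.integers(200, 400))
        plan.append(("mRNA", f"mRNAi{i+1}", [e1, -intron, e2]))
    for i in range(spec.mrna_intronless):
        plan.append(("mRNA", f"mRNA{i+1}", [int(rng.integers(300, 700))]))
    for i in range(spec.trna):
        plan.append(("tRNA", f"tRNA{i+1}", [int(rng.integers(70, 90))]))
    for i in range(spec.trna_spliced):
        e1 = int(rng.integers(30, 40))
        intron = int(rng.integers(14, 30))
        e2 = int(rng.integers(35, 45))
        plan.append(("tRNA", f"tRNAi{i+1}", [e1, -intron, e2]))
    for i in range(spec.snorna):
        plan.append(("snoRNA", f"snoRNA{i+1}", [int(rng.integers(90, 180))]))
    for i in range(spec.snrna):
        plan.append(("snRNA", f"snRNA{i+1}", [int(rng.integers(120, 300))]))
    plan.append(("snRNA", "snR6", [112]))  # U6: Pol III snRNA
    for i in range(spec.rrna_35s):
        # desk-scale 35S unit: 5'-ETS followed by the rRNA body
        plan.append(("rRNA_35S", f"rRNA_35S_{i+1}", [1400]))
    for i in range(spec.rrna_5s):
        plan.append(("rRNA_5S", f"rRNA_5S_{i+1}", [121]))
    for i in range(spec.cut):
        plan.append(("CUT", f"CUT{i+1}", [int(rng.integers(200, 400))]))
    for i in range(spec.sut):
        plan.append(("SUT", f"SUT{i+1}", [int(rng.integers(250, 500))]))
    for i in range(spec.scr1):
        plan.append(("scR1", "scR1" if i == 0 else f"scR1_{i+1}", [522]))

    chrom = "chrS"
    parts: List[str] = []
    pos = 0
    features: List[Feature] = []
    sites: Dict[str, int] = {}
    for idx, (tx_class, fid, segments) in enumerate(plan):
        spacer = _rand_seq(rng, spec.spacer, spec.alphabet)
        parts.append(spacer)
        pos += len(spacer)
        strand = "+" if (spec.strands == "+" or idx % 2 == 0) else "-"
        exons: List[Tuple[int, int]] = []
        cursor = pos
        for seg in segments:
            seglen = abs(seg)
            if seg > 0:
                exons.append((cursor, cursor + seglen))
            cursor += seglen
        body = _rand_seq(rng, cursor - pos, spec.alphabet)
        parts.append(body)
        pos = cursor
        if strand == "-":
            exons = sorted(exons)
        feat = Feature(id=fid, chrom=chrom, strand=strand, exons=exons, tx_class=tx_class)
        features.append(feat)
        # crosslink site: inside the transcript-first exon, away from its
        # edges, and locally non-repetitive so a 1-2 nt deletion there maps
        # back unambiguously (in a homopolymer or period-2 repeat the
        # deleted position is not identifiable from the read)
        first_exon = feat.exons_tx()[0]
        a, b = first_exon
        lo, hi = a + 8, b - 8
        if hi <= lo:
            lo, hi = a, b
        site = int(rng.integers(lo, hi))
        for _ in range(100):
            i = site - (cursor - len(body))  # body-local index
            c0, c1 = body[i], body[i + 1]
            if (
                body[i - 1] != c0
                and c1 != c0
                and (c0, c1) != (body[i + 2], body[i + 3])
            ):
                break
            site = int(rng.integers(lo, hi))
        sites[fid] = site
    parts.append(_rand_seq(rng, spec.spacer, spec.alphabet))
    genome = Genome()
    genome.add(chrom, "".join(parts))
    return genome, features, sites


def sites_with_delta(
    sites: Dict[str, int], delta: float
) -> Dict[str, List[Tuple[int, float]]]:
    """Attach a uniform deletion probability to forged crosslink sites."""
    return {fid: [(pos, delta)] for fid, pos in sites.items()}


# ---------------------------------------------------------------------------
# read simulation


class _Template:
    """A sampling template: sequence plus per-base genomic coordinates."""

    __slots__ = ("seq", "coords", "kind")

    def __init__(self, seq: str, coords: np.ndarray, kind: str):
        self.seq = seq
        self.coords = coords  # genomic coordinate of each template base
        self.kind = kind


def _build_templates(
    feature: Feature, genome: Genome, ext: int
) -> Tuple[_Template, _Template]:
    """Precursor (with flanking extension) and mature templates, 5'->3'."""
    chrom_len = len(genome[feature.chrom])
    lo = max(0, feature.start - ext)
    hi = min(chrom_len, feature.end + ext)
    pre_seq = genome.fetch(feature.chrom, lo, hi)
    pre_coords = np.arange(lo, hi)
    if feature.strand == "-":
        pre_seq = revcomp(pre_seq)
        pre_coords = pre_coords[::-1]
    mat_coords_list: List[np.ndarray] = [np.arange(a, b) for a, b in feature.exons]
    mat_coords = np.concatenate(mat_coords_list)
    mat_seq = "".join(genome.fetch(feature.chrom, a, b) for a, b in feature.exons)
    if feature.strand == "-":
        mat_seq = revcomp(mat_seq)
        mat_coords = mat_coords[::-1]
    return _Template(pre_seq, pre_coords, "precursor"), _Template(
        mat_seq, mat_coords, "mature"
    )


def simulate_reads(
    genome: Genome,
    features: Sequence[Feature],
    config: SimConfig,
) -> Tuple[List[Tuple[str, str]], TruthManifest]:
    """Draw CRAC-like reads; returns ``[(read_id, sequence), ...]`` and truth.

    Each read: feature by class weight -> template (precursor vs mature) ->
    start from the positional profile -> copy with substitution errors ->
    microdeletion at covered crosslink sites with probability delta ->
    oligo(A) tail with probability pi_A -> adapter fill to the raw cycle
    length when the insert is short.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo_len, hi_len = config.read_length

    by_class: Dict[str, List[Feature]] = {}
    for f in features:
        if f.precursor_length < lo_len:
            continue  # too short to yield a read
        by_class.setdefault(f.tx_class, []).append(f)
    classes = [c for c, w in sorted(config.class_weights.items()) if w > 0 and c in by_class]
    if not classes and config.n_reads > 0:
        raise ValueError("no usable features for any weighted class")
    cw = np.array([config.class_weights[c] for c in classes], dtype=float)
    cw /= cw.sum()

    feat_probs: Dict[str, np.ndarray] = {}
    for c in classes:
        w = np.array(
            [config.feature_weights.get(f.id, 1.0) for f in by_class[c]], dtype=float
        )
        feat_probs[c] = w / w.sum()

    templates = {f.id: _build_templates(f, genome, config.precursor_extension)
                 for c in classes for f in by_class[c]}
    alphabet = np.array(list("ACGT"))

    reads: List[Tuple[str, str]] = []
    manifest = TruthManifest(config=config)
    for ridx in range(config.n_reads):
        cls = classes[int(rng.choice(len(classes), p=cw))]
        flist = by_class[cls]
        feat = flist[int(rng.choice(len(flist), p=feat_probs[cls]))]
        pre_t, mat_t = templates[feat.id]
        use_pre = (not feat.spliced) or (rng.random() < config.pre_mature_ratio)
        tmpl = pre_t if use_pre else mat_t
        tlen = len(tmpl.seq)
        L = int(rng.integers(lo_len, min(hi_len, tlen) + 1))

        # template coordinate of the crosslink site (if inside this template)
        sites = config.crosslink_sites.get(feat.id, [])
        site_tpos = -1
        site_delta = 0.0
        if sites:
            gpos, site_delta = sites[0]
            hits = np.nonzero(tmpl.coords == gpos)[0]
            if hits.size:
                site_tpos = int(hits[0])

        prof = config.profile
        start = -1
        if site_tpos >= 0 and rng.random() < prof.peak_weight:
            center = site_tpos - L / 2.0
            start = int(round(rng.normal(center, prof.width)))
        else:
            start = int(rng.integers(0, tlen - L + 1))
        start = max(0, min(start, tlen - L))
        insert = list(tmpl.seq[start : start + L])
        coords = tmpl.coords[start : start + L]

        n_err = 0
        if config.seq_error > 0:
            errs = np.nonzero(rng.random(L) < config.seq_error)[0]
            for e in errs:
                old = insert[e]
                choices = [b for b in "ACGT" if b != old]
                insert[e] = choices[int(rng.integers(0, 3))]
            n_err = len(errs)

        del_positions: List[int] = []
        for gpos, delta in sites:
            hitpos = np.nonzero(coords == gpos)[0]
            if not hitpos.size:
                continue
            i = int(hitpos[0])
            if i < 4 or i > len(insert) - 5:
                continue  # too close to the read end to leave an alignable deletion
            if rng.random() < delta:
                dl = 1 if rng.random() < config.del_length_probs[0] else 2
                dl = min(dl, len(insert) - i - 4)
                del_positions = sorted(int(c) for c in coords[i : i + dl])
                insert = insert[:i] + insert[i + dl :]
                coords = np.concatenate([coords[:i], coords[i + dl :]])
                break

        tail = ""
        if rng.random() < config.pi_a.get(feat.tx_class, 0.0):
            tail_len = 2 + int(rng.geometric(config.tail_geom_p) - 1)
            tail = "A" * tail_len

        antisense = config.antisense_rate > 0 and rng.random() < config.antisense_rate
        if antisense:
            seq = revcomp("".join(insert))
        else:
            seq = "".join(insert) + tail

        if len(seq) < hi_len and config.adapter:
            seq = seq + config.adapter[: hi_len - len(seq)]

        rid = f"read{ridx:07d}"
        reads.append((rid, seq))
        manifest.records.append(
            ManifestRecord(
                read_id=rid,
                feature_id=feat.id,
                tx_class=feat.tx_class,
                template=tmpl.kind,
                strand=feat.strand,
                genomic_start=int(coords.min()) if len(coords) else -1,
                genomic_end=int(coords.max()) + 1 if len(coords) else -1,
                deletions=del_positions,
                tail=tail,
                n_errors=n_err,
                antisense=antisense,
            )
        )
    return reads, manifest


def write_fastq(reads: Sequence[Tuple[str, str]], path: str | Path, qual: str = "I") -> None:
    """Phred+33 FASTQ with constant quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual * len(seq)}\n")


def read_fastq(path: str | Path) -> List[Tuple[str, str]]:
    reads = []
    with open(path) as fh:
        while True:
            h = fh.readline()
            if not h:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append((h.strip()[1:].split()[0], seq))
    return reads
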