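"""End-to-end orchestration: simulate -> prep -> align -> call -> attribute
-> profile -> stats -> cluster, as one reproducible, seeded run.

A single :class:`RunConfig` drives everything; the config is serialized
verbatim into the output directory together with a JSON manifest carrying
SHA-256 checksums of every output, so two runs with identical seeds can be
compared byte for byte.  Any stage failure aborts with a stage-labelled
error and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import classify, cluster, coverage, splicing, tails
from .align import Aligner, AlignParams, lift_all, prepare_reads, write_sam
from .annotation import write_annotation
from .genome import write_genome
from .junctions import build_junction_library, write_junction_fasta
from .simulate import (
    ForgeSpec,
    SimConfig,
    forge_genome,
    sites_with_delta,
    simulate_reads,
    write_fastq,
)

logger = logging.getLogger(__name__)

_KNOWN_TOP_KEYS = {
    "seed",
    "forge",
    "sim",
    "experiments",
    "params",
    "gene_sets",
}


@dataclass
class ExperimentConfig:
    label: str
    condition: str
    feature_weights: Dict[str, float] = field(default_factory=dict)
    overrides: Dict[str, object] = field(default_factory=dict)


@dataclass
class RunConfig:
    seed: int = 0
    forge: ForgeSpec = field(default_factory=ForgeSpec)
    sim: Dict[str, object] = field(default_factory=dict)
    experiments: List[ExperimentConfig] = field(
        default_factory=lambda: [
            ExperimentConfig("wt_1", "wt"),
            ExperimentConfig("wt_2", "wt"),
        ]
    )
    # analysis parameters
    delta: float = 0.3
    min_a: int = 2
    tail_purity: float = 1.0
    attribution_flank: int = 50
    junction_flank: int = 60
    min_overhang: int = 1
    ss_window: int = 10
    metagene_window: tuple = (300, 100)
    trna_flank: int = 30
    cluster_k: int = 2
    gene_sets: Dict[str, List[str]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_TOP_KEYS - {
            f for f in cls.__dataclass_fields__
        }
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "forge" in kwargs:
            fd = dict(kwargs["forge"])
            if "intron_length_bands" in fd:
                fd["intron_length_bands"] = tuple(tuple(b) for b in fd["intron_length_bands"])
            kwargs["forge"] = ForgeSpec(**fd)
        if "experiments" in kwargs:
            kwargs["experiments"] = [ExperimentConfig(**e) for e in kwargs["experiments"]]
        if "metagene_window" in kwargs:
            kwargs["metagene_window"] = tuple(kwargs["metagene_window"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["forge"] = asdict(self.forge)
        d["experiments"] = [asdict(e) for e in self.experiments]
        d["metagene_window"] = list(self.metagene_window)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline into ``outdir``; returns the directory.

    Deterministic given the config seeds: per-experiment simulation seeds
    are derived as ``config.seed * 1000 + index``.
    """
    out = Path(outdir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        config.to_yaml(out / "config.yaml")

        stage = "forge"
        genome, features, xlink = forge_genome(config.forge, seed=config.seed)
        write_genome(genome, out / "genome.fa")
        write_annotation(features, out / "annotation.gff3")
        junctions = build_junction_library(features, genome, flank=config.junction_flank)
        write_junction_fasta(junctions, out / "junctions.fa")

        stage = "align"
        aligner = Aligner(genome, junctions)
        index = classify.FeatureIndex(features, flank=config.attribution_flank)
        sim_defaults = dict(config.sim)
        per_exp: Dict[str, dict] = {}
        accounting: Dict[str, Dict[str, int]] = {}
        for i, exp in enumerate(config.experiments):
            cfg_kwargs = dict(sim_defaults)
            cfg_kwargs.update(exp.overrides)
            cfg_kwargs.setdefault("crosslink_sites", sites_with_delta(xlink, config.delta))
            cfg_kwargs.pop("feature_weights", None)
            cfg_kwargs.pop("seed", None)
            if isinstance(cfg_kwargs.get("profile"), dict):
                from .simulate import PositionalProfile

                cfg_kwargs["profile"] = PositionalProfile(**cfg_kwargs["profile"])
            cfg = SimConfig(
                feature_weights=exp.feature_weights,
                seed=config.seed * 1000 + i,
                **cfg_kwargs,
            )
            reads, manifest = simulate_reads(genome, features, cfg)
            write_fastq(reads, out / f"{exp.label}.fastq")
            manifest.write(out / f"{exp.label}.manifest.jsonl")
            prepared = prepare_reads(reads, cfg.adapter)
            alns, unmapped = aligner.align_all(prepared)
            alns = lift_all(alns, junctions)
            write_sam(out / f"{exp.label}.sam", alns, genome)
            tc = tails.call_tails(alns, genome, config.min_a, config.tail_purity)
            tails.write_tailcalls(tc, out / f"{exp.label}.tails.tsv")
            dels = [tails.extract_deletions(a) for a in alns]
            tails.write_deletions(dels, out / f"{exp.label}.deletions.tsv")
            ats = classify.assign_all(alns, index)
            per_exp[exp.label] = {
                "condition": exp.condition,
                "alignments": alns,
                "tailcalls": tc,
                "attributions": ats,
            }
            accounting[exp.label] = {
                "simulated": len(reads),
                "prepared": len(prepared),
                "mapped": len(alns),
                "unmapped_or_multi": unmapped,
            }
            logger.info("%s: %s", exp.label, accounting[exp.label])

        stage = "tables"
        class_rows, pol_rows, atail_rows = [], [], []
        for label, d in per_exp.items():
            cd = classify.class_distribution(d["attributions"])
            cd["experiment"] = label
            class_rows.append(cd)
            pp = classify.polymerase_partition(d["attributions"])
            pp["experiment"] = label
            pol_rows.append(pp)
            af = classify.atail_frequency_table(d["attributions"], d["tailcalls"])
            af["experiment"] = label
            atail_rows.append(af)
        pd.DataFrame(class_rows).set_index("experiment").to_csv(
            out / "class_distribution.tsv", sep="\t"
        )
        pd.DataFrame(pol_rows).set_index("experiment").to_csv(
            out / "polymerase_partition.tsv", sep="\t"
        )
        pd.DataFrame(atail_rows).set_index("experiment").to_csv(
            out / "atail_frequency.tsv", sep="\t"
        )
        counts = classify.per_rna_counts(
            {label: d["attributions"] for label, d in per_exp.items()},
            feature_ids=[f.id for f in features],
        )
        counts.to_csv(out / "per_rna_hpm.tsv", sep="\t")

        stage = "profiles"
        chrom = next(iter(genome.sequences))
        for label, d in per_exp.items():
            alns = d["alignments"]
            total = sum(a.count for a in alns)
            atailed = tails.filter_a_tailed(alns, d["tailcalls"])
            for kind in ("hits", "dels"):
                for filt, sub in (("total", alns), ("a_tailed", atailed)):
                    for strand in "+-":
                        track = coverage.pileup(
                            sub, chrom, 0, len(genome[chrom]), kind=kind,
                            strand=strand, total_mapped=total, filter_label=filt,
                        )
                        sname = "plus" if strand == "+" else "minus"
                        coverage.write_bedgraph(
                            track, out / f"{label}.{kind}.{filt}.{sname}.bedgraph"
                        )
            if any(f.spliced and f.tx_class == "mRNA" for f in features):
                mg = coverage.metagene_3ss(
                    alns, [f for f in features if f.tx_class == "mRNA"], genome,
                    window=config.metagene_window, total_mapped=total,
                )
                coverage.metagene_to_tsv(mg, out / f"{label}.metagene_3ss.tsv")
            if any(f.tx_class == "tRNA" for f in features):
                tp = coverage.trna_profile(
                    alns, features, genome, flank=config.trna_flank, total_mapped=total
                )
                coverage.metagene_to_tsv(tp, out / f"{label}.trna_profile.tsv")

        stage = "splicing"
        jc_by_label = {
            label: splicing.count_junctions(
                d["alignments"], features, config.min_overhang,
                ss_window=config.ss_window, genome=genome,
            )
            for label, d in per_exp.items()
        }
        conditions: Dict[str, List[str]] = {}
        for exp in config.experiments:
            conditions.setdefault(exp.condition, []).append(exp.label)
        ratio_rows = []
        for cond, labels in conditions.items():
            reps = [jc_by_label[lb] for lb in labels]
            for which in ("IE/EE", "introns/totalmRNA", "3SS/5SS"):
                try:
                    r, se = splicing.ratio_with_se(reps, which, seed=config.seed)
                except (ValueError, ZeroDivisionError):
                    r, se = float("nan"), float("nan")
                ratio_rows.append(
                    {"condition": cond, "ratio": which, "value": r, "se": se}
                )
        pd.DataFrame(ratio_rows).to_csv(out / "splicing_ratios.tsv", sep="\t", index=False)

        stage = "clustering"
        if len(per_exp) >= 2:
            mat = counts.drop(index=[classify.INTERGENIC])
            # experiments axis
            dx = cluster.correlation_distance(mat.T)
            dend_x = cluster.complete_linkage(dx, labels=list(mat.columns))
            (out / "experiments.dendrogram.nwk").write_text(dend_x.to_newick() + "\n")
            # mRNA axis
            mrna_ids = [f.id for f in features if f.tx_class == "mRNA"]
            sub = mat.loc[[i for i in mrna_ids if i in mat.index]]
            if len(sub) >= 2:
                dg = cluster.correlation_distance(sub)
                dend_g = cluster.complete_linkage(dg, labels=list(sub.index))
                (out / "mrnas.dendrogram.nwk").write_text(dend_g.to_newick() + "\n")
                gene_sets = dict(config.gene_sets)
                gene_sets.setdefault(
                    "intron_containing",
                    [f.id for f in features if f.tx_class == "mRNA" and f.spliced],
                )
                for f in features:
                    for gs in f.gene_sets:
                        gene_sets.setdefault(gs, []).append(f.id)
                k = min(config.cluster_k, len(sub))
                if k >= 2:
                    enr = cluster.cut_and_enrich(dend_g, k, gene_sets)
                    cluster.enrichment_to_tsv(enr, out / "enrichment.tsv")

        stage = "manifest"
        outputs = sorted(p for p in out.iterdir() if p.is_file() and p.name != "run_manifest.json")
        manifest = {
            "seed": config.seed,
            "accounting": accounting,
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return out
    except Exception as exc:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
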