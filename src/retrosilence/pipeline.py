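"""Run orchestration: simulate -> align -> quantify -> analyze from one
configuration, with a manifest, config-hash-stamped outputs and a log."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import align as al
from . import cleavage as cl
from . import gene_attribution as ga
from . import methylome as me
from . import seqio
from . import small_rna as sr
from . import synthetic as syn
from . import te_expression as te
from .config import SimConfig
from .synthetic import CHROM

STAGE_ORDER = ["simulate", "align", "methylome", "te_expr", "pirna", "cleavage", "attribute"]

_DEPS = {
    "align": ["simulate"],
    "methylome": ["align"],
    "te_expr": ["align"],
    "pirna": ["align"],
    "cleavage": ["align"],
    "attribute": ["align"],
}


@dataclass
class RunConfig:
    """One end-to-end run: a synthetic world plus one KO-vs-WT comparison."""

    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str = "retrosilence_run"
    stage: str = "proSG_P0"
    ko: str = "Pld6KO"
    wt: str = "WT"
    replicates: int = 2
    fc_threshold: float = 2.0
    fc_up: float = 3.0
    q_alpha: float = 0.05
    window: int = 100_000
    profile_window: int = 100
    min_len: int = 24
    max_len: int = 33
    max_mismatches_pirna: int = 2

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # the output location is not a run parameter
        return hashlib.sha256(
            yaml.safe_dump(d, sort_keys=True).encode()
        ).hexdigest()[:16]


class DependencyError(RuntimeError):
    pass


def _setup_log(outdir: Path) -> logging.Logger:
    logger = logging.getLogger(f"retrosilence.{outdir}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s [%(name)s] %(message)s"))
    logger.addHandler(fh)
    return logger


class Runner:
    """Executes pipeline stages in dependency order against one run directory."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.hash = config.config_hash()
        self.log = _setup_log(self.outdir)
        self.world: syn.World | None = None
        self._alignments: dict[str, al.AlignmentResult] = {}

    # -- helpers -----------------------------------------------------------

    def _tsv(self, name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = self.outdir / name
        with open(path, "w") as fh:
            fh.write(f"# config_hash: {self.hash}\n")
            df.to_csv(fh, sep="\t", index=index)

    def _json(self, name: str, obj: Any) -> None:
        obj = {"config_hash": self.hash, **obj}
        (self.outdir / name).write_text(json.dumps(obj, indent=2, default=str) + "\n")

    def _samples(self) -> list[tuple[str, str, int]]:
        out = []
        for gt in (self.cfg.wt, self.cfg.ko):
            for rep in range(1, self.cfg.replicates + 1):
                out.append((f"{gt}-{rep}", gt, rep))
        return out

    def _require(self, stage: str, done: set[str]) -> None:
        for dep in _DEPS.get(stage, []):
            if dep not in done and not self._stage_outputs_exist(dep):
                raise DependencyError(
                    f"stage {stage!r} requires {dep!r}, which has not been run"
                )

    def _stage_outputs_exist(self, stage: str) -> bool:
        if stage == "simulate":
            return (self.outdir / "world" / "genome.fa").exists()
        if stage == "align":
            return bool(list(self.outdir.glob("*.sam"))) or bool(self._alignments)
        return False

    # -- stages ------------------------------------------------------------

    def run(self, stages: list[str] | None = None) -> dict[str, Any]:
        stages = stages or STAGE_ORDER
        unknown = [s for s in stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        done: set[str] = set()
        results: dict[str, Any] = {}
        for stage in STAGE_ORDER:
            if stage not in stages:
                continue
            self._require(stage, done)
            self.log.info("stage %s start (config_hash=%s)", stage, self.hash)
            results[stage] = getattr(self, f"stage_{stage}")()
            self.log.info("stage %s done", stage)
            done.add(stage)
        manifest = {
            "stages": sorted(done),
            "outputs": sorted(p.name for p in self.outdir.iterdir() if p.is_file()),
        }
        self._json("manifest.json", manifest)
        return results

    def stage_simulate(self) -> dict:
        cfg = self.cfg
        self.world = syn.build_world(cfg.sim, outdir=self.outdir / "world")
        n = {}
        seed0 = cfg.sim.seed
        for sample, gt, rep in self._samples():
            sub = seed0 * 1000 + rep * 10
            reads, _table, _rep = syn.simulate_rnaseq(
                self.world, cfg.stage, gt, seed=sub + 1
            )
            n[f"rna_{sample}"] = seqio.write_fastq(
                self.outdir / f"rna_{sample}.fastq", reads
            )
            wreads = syn.simulate_wgbs(self.world, cfg.stage, gt, seed=sub + 2)
            n[f"wgbs_{sample}"] = seqio.write_fastq(
                self.outdir / f"wgbs_{sample}.fastq", wreads
            )
            sreads = syn.simulate_small_rna(self.world, cfg.stage, gt, seed=sub + 3)
            n[f"srna_{sample}"] = seqio.write_fastq(
                self.outdir / f"srna_{sample}.fastq", sreads
            )
            rreads, _ = syn.simulate_race(self.world, cfg.stage, gt, seed=sub + 4)
            n[f"race_{sample}"] = seqio.write_fastq(
                self.outdir / f"race_{sample}.fastq", rreads
            )
        return n

    def _world(self) -> syn.World:
        if self.world is None:
            raise DependencyError("stage requires 'simulate', which has not been run")
        return self.world

    def stage_align(self) -> dict:
        world = self._world()
        lib = world.library.seqs
        lib_index = al.SeedIndex(lib, seed_len=10)
        counts = {}
        for sample, _gt, _rep in self._samples():
            reads = list(seqio.read_fastq(self.outdir / f"rna_{sample}.fastq"))
            res = al.align_reads(reads, lib_index, max_mismatches=4, seed_len=10)
            self._alignments[f"rna_cons_{sample}"] = res
            al.export_sam(res, world.library.lengths(), self.outdir / f"rna_cons_{sample}.sam")
            counts[f"rna_cons_{sample}"] = len(res.records)
        genome_index = al.SeedIndex({CHROM: world.genome[CHROM]}, seed_len=14)
        for sample, _gt, _rep in self._samples():
            reads = list(seqio.read_fastq(self.outdir / f"rna_{sample}.fastq"))
            res = al.align_reads(reads, genome_index, max_mismatches=2, seed_len=14)
            self._alignments[f"rna_genome_{sample}"] = res
            counts[f"rna_genome_{sample}"] = len(res.records)
        bis_index = al.SeedIndex({CHROM: world.genome[CHROM]}, seed_len=14, bisulfite=True)
        spec = al.ReadPrepSpec(trim5=6, trim3=15, min_quality=30)
        for sample, _gt, _rep in self._samples():
            reads = list(seqio.read_fastq(self.outdir / f"wgbs_{sample}.fastq"))
            prepped, _rep2 = al.preprocess_reads(reads, spec)
            res = al.align_reads(prepped, bis_index, mode="bisulfite", max_mismatches=3, seed_len=14)
            self._alignments[f"wgbs_{sample}"] = res
            counts[f"wgbs_{sample}"] = len(res.records)
        for sample, _gt, _rep in self._samples():
            reads = list(seqio.read_fastq(self.outdir / f"srna_{sample}.fastq"))
            retained, ledger = sr.filter_small_rnas(
                reads, world.blacklist, self.cfg.min_len, self.cfg.max_len
            )
            res = al.align_reads(
                retained, lib_index, max_mismatches=self.cfg.max_mismatches_pirna, seed_len=10
            )
            self._alignments[f"srna_{sample}"] = res
            self._alignments[f"srna_{sample}_ledger"] = ledger  # type: ignore[assignment]
            counts[f"srna_{sample}"] = len(res.records)
            rreads = list(seqio.read_fastq(self.outdir / f"race_{sample}.fastq"))
            res = al.align_reads(rreads, lib_index, max_mismatches=4, seed_len=10)
            self._alignments[f"race_{sample}"] = res
            counts[f"race_{sample}"] = len(res.records)
        return counts

    def stage_methylome(self) -> dict:
        world = self._world()
        cfg = self.cfg
        ref = {CHROM: world.genome[CHROM]}
        copies = world.truth.copies
        regions = copies.assign(target=CHROM, name=copies["copy_id"])[
            ["target", "start", "end", "name"]
        ]
        out = {}
        levels = {}
        for sample, gt, _rep in self._samples():
            res = self._alignments.get(f"wgbs_{sample}")
            if res is None:
                raise DependencyError("methylome requires 'align', which has not been run")
            meth = me.call_methylation(res, ref)
            per_copy = me.aggregate_regions(meth, regions)
            self._tsv(f"meth_copy_{sample}.tsv", per_copy)
            windows = me.aggregate_windows(meth, ref)
            self._tsv(f"meth_windows_{sample}.tsv", windows)
            levels[sample] = windows
            out[sample] = {"conversion_rate": meth.conversion_rate()}
        ko1, wt1 = f"{cfg.ko}-1", f"{cfg.wt}-1"
        r, _tbl = me.methylation_gc_correlation(levels[ko1], levels[wt1])
        out["gc_correlation"] = r
        self._json("methylome_summary.json", out)
        return out

    def stage_te_expr(self) -> dict:
        world = self._world()
        cfg = self.cfg
        lengths = world.library.lengths()
        sample_counts = {}
        totals = {}
        for sample, _gt, _rep in self._samples():
            res = self._alignments.get(f"rna_cons_{sample}")
            if res is None:
                raise DependencyError("te_expr requires 'align', which has not been run")
            sample_counts[sample] = te.count_fractional(res, lengths)
            totals[sample] = float(res.n_reads)  # per million library reads
        matrix = te.expression_matrix(sample_counts, totals=totals)
        rpkm = matrix.rpkm()
        self._tsv("te_rpkm.tsv", rpkm, index=True)
        design = {s: gt for s, gt, _ in self._samples()}
        fc = te.differential(
            rpkm, design, cfg.ko, cfg.wt, fc_threshold=cfg.fc_threshold, alpha=cfg.q_alpha
        )
        self._tsv("te_differential.tsv", fc, index=True)
        # positional profile of the most derepressed piRNA-target element
        element = fc["fold_change"].idxmax()
        prof = te.positional_profile(
            self._alignments[f"rna_cons_{cfg.ko}-1"],
            self._alignments[f"rna_cons_{cfg.wt}-1"],
            element,
            lengths[element],
            window=cfg.profile_window,
        )
        self._tsv("te_positional_profile.tsv", prof)
        return {"n_up": int(fc["up"].sum()), "profiled_element": element}

    def stage_pirna(self) -> dict:
        world = self._world()
        cfg = self.cfg
        lengths = world.library.lengths()
        profiles = {}
        for sample, _gt, _rep in self._samples():
            res = self._alignments.get(f"srna_{sample}")
            if res is None:
                raise DependencyError("pirna requires 'align', which has not been run")
            ledger = self._alignments.get(f"srna_{sample}_ledger") or {}
            profiles[sample] = sr.pirna_rpm(
                res, lengths, n_retained=ledger.get("retained", len(res.records)), ledger=ledger
            )
            self._tsv(f"pirna_rpm_{sample}.tsv", profiles[sample].rpm, index=True)
        fc = seqio.read_tsv(self.outdir / "te_differential.tsv").set_index("element") \
            if (self.outdir / "te_differential.tsv").exists() else None
        out = {}
        if fc is not None:
            grouped, tests = sr.drop_vs_derepression(
                profiles[f"{cfg.wt}-1"], profiles[f"{cfg.ko}-1"], fc
            )
            self._tsv("pirna_drop_groups.tsv", grouped, index=True)
            self._tsv("pirna_drop_tests.tsv", tests)
            out["n_groups"] = int(grouped["bin"].nunique())
        return out

    def stage_cleavage(self) -> dict:
        cfg = self.cfg
        out = {}
        for sample, _gt, _rep in self._samples():
            res = self._alignments.get(f"race_{sample}")
            if res is None:
                raise DependencyError("cleavage requires 'align', which has not been run")
            prof = cl.map_cleavage_ends(res)
            self._tsv(f"cleavage_profile_{sample}.tsv", prof.profile)
            pp = cl.pingpong_fraction(res, self._alignments[f"srna_{sample}"])
            out[sample] = {
                "pingpong_fraction": pp.fraction,
                "family_share": prof.family_share.to_dict(),
            }
        self._json("cleavage_summary.json", out)
        return out

    def stage_attribute(self) -> dict:
        world = self._world()
        cfg = self.cfg
        truth = world.truth
        genes, exons, copies = truth.genes, truth.exons, truth.copies
        lengths = ga.exonic_lengths(genes, exons)
        sample_counts, totals, copy_cnts = {}, {}, {}
        for sample, _gt, _rep in self._samples():
            res = self._alignments.get(f"rna_genome_{sample}")
            if res is None:
                raise DependencyError("attribute requires 'align', which has not been run")
            cnt, total = ga.exonic_counts(res, genes, exons, copies=copies)
            sample_counts[sample] = cnt
            totals[sample] = total
            copy_cnts[sample] = ga.copy_counts(res, copies)
        design = {s: gt for s, gt, _ in self._samples()}
        de = ga.gene_de(
            sample_counts, lengths, totals, design,
            cfg.ko, cfg.wt, fc_threshold=cfg.fc_threshold, q_alpha=cfg.q_alpha,
        )
        self._tsv("gene_de.tsv", de, index=True)
        te_fc = seqio.read_tsv(self.outdir / "te_differential.tsv").set_index("element") \
            if (self.outdir / "te_differential.tsv").exists() else None
        family_up = set(te_fc.index[te_fc["up"]]) if te_fc is not None else set(
            copies["family"].unique()
        )
        act = ga.copy_activation(
            copy_cnts, totals, design, cfg.ko, cfg.wt, family_up, cfg.fc_threshold
        )
        self._tsv("copy_activation.tsv", act)
        up = de[de["fold_change"] > cfg.fc_up]
        records, summary = ga.attribute_genes(up, act, genes, window=cfg.window)
        self._tsv("attribution.tsv", records)
        self._json("attribution_summary.json", summary)
        return summary


def run(config: RunConfig, stages: list[str] | None = None) -> dict[str, Any]:
    """Execute pipeline stages in dependency order; see Runner."""
    return Runner(config).run(stages)
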