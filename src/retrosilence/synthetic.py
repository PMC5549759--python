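"""Synthetic multi-omics world: toy genome, consensus library, ground truth
and simulators for the four read types (RNA-seq, WGBS, small RNA, 5'-RACE).

The generator encodes the causal model the downstream analyses are meant to
recover: perinatal retrotransposon silencing is posttranscriptional (piRNA-
guided cleavage; lost in the Pld6 knockout), spermatocyte silencing is
transcriptional (DNA methylation; lost in the Dnmt3l knockout), GC-poor
genomic blocks lose the most methylation without de novo activity, and a few
activated copies drive readthrough transcription into nearby genes.
"""

from __future__ import annotations

import dataclasses
import warnings
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    GENOTYPES,
    PIRNA_TARGET_FAMILIES,
    STAGES,
    SimConfig,
)
from . import seqio
from .seqio import FastqRead

# ASCII codes for bases; sequences are handled as uint8 arrays throughout
_A, _C, _G, _T, _N = 65, 67, 71, 84, 78
_COMP = np.zeros(256, dtype=np.uint8)
_COMP[_A], _COMP[_C], _COMP[_G], _COMP[_T], _COMP[_N] = _T, _G, _C, _A, _N

CHROM = "chr1"


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


def revcomp(seq: str) -> str:
    return _to_str(revcomp_arr(_to_arr(seq)))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(
        np.array([_A, _C, _G, _T], dtype=np.uint8), size=length, p=p
    )


def _inject_cpgs(rng: np.random.Generator, arr: np.ndarray, lo: int, hi: int, density: float) -> None:
    """Overwrite random dinucleotides in [lo, hi) with CG at the given density."""
    span = hi - lo
    n = int(round(span * density))
    if n <= 0 or span < 2:
        return
    pos = lo + rng.integers(0, span - 1, size=n)
    arr[pos] = _C
    arr[pos + 1] = _G


def _mutate(rng: np.random.Generator, arr: np.ndarray, p: float) -> np.ndarray:
    """Per-base substitution with probability p (no indels)."""
    out = arr.copy()
    if p <= 0:
        return out
    hit = np.nonzero(rng.random(len(arr)) < p)[0]
    if len(hit) == 0:
        return out
    bases = np.array([_A, _C, _G, _T], dtype=np.uint8)
    # shift each hit base by 1..3 within the alphabet: always a different base
    idx = np.searchsorted(bases, out[hit])
    out[hit] = bases[(idx + rng.integers(1, 4, size=len(hit))) % 4]
    return out


def _apply_errors(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    return _mutate(rng, arr, rate) if rate > 0 else arr


# ---------------------------------------------------------------------------
# library / truth containers


@dataclass
class ConsensusLibrary:
    """Named consensus sequences with family labels and sub-region annotations.

    Sub-regions (e.g. the CpG-rich ``5end`` of L1-like families) are interval
    annotations on the full-length consensus, usable as aggregation targets.
    """

    seqs: dict[str, str]
    family: dict[str, str]
    subregions: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.seqs.items()}

    def subregion_frame(self) -> pd.DataFrame:
        rows = []
        for fam, regions in self.subregions.items():
            for label, (s, e) in regions.items():
                rows.append({"target": fam, "start": s, "end": e, "name": f"{fam}_{label}"})
        return pd.DataFrame(rows, columns=["target", "start", "end", "name"])


_TRUTH_FRAMES = (
    "copies",
    "genes",
    "exons",
    "family_meth",
    "background_meth",
    "family_rate",
    "cleavage_sites",
    "cleavage_efficiency",
    "pirna_positions",
    "driven_pairs",
    "snps",
)


@dataclass
class GroundTruth:
    """The generating state of the synthetic world, as tidy tables."""

    copies: pd.DataFrame
    genes: pd.DataFrame
    exons: pd.DataFrame
    family_meth: pd.DataFrame
    background_meth: pd.DataFrame
    family_rate: pd.DataFrame
    cleavage_sites: pd.DataFrame
    cleavage_efficiency: pd.DataFrame
    pirna_positions: pd.DataFrame
    driven_pairs: pd.DataFrame
    snps: pd.DataFrame

    def validate(self) -> None:
        copy_ids = set(self.copies["copy_id"])
        gene_ids = set(self.genes["gene_id"])
        for p in self.driven_pairs.itertuples():
            if p.copy_id not in copy_ids or p.gene_id not in gene_ids:
                raise ValueError(f"driven pair ({p.copy_id}, {p.gene_id}) references unknown ids")
        eff = self.cleavage_efficiency.set_index("genotype")["efficiency"]
        if not eff["Pld6KO"] < eff["WT"]:
            raise ValueError("cleavage efficiency must satisfy Pld6KO < WT")

    # -- lookups -----------------------------------------------------------

    def family_level(self, stage: str, genotype: str) -> pd.Series:
        df = self.family_meth
        sel = df[(df["stage"] == stage) & (df["genotype"] == genotype)]
        return sel.set_index("family")["level"]

    def copy_level(self, stage: str, genotype: str) -> pd.Series:
        fam = self.family_level(stage, genotype)
        return self.copies.set_index("copy_id")["family"].map(fam)

    def background_level(self, stage: str, genotype: str) -> dict[str, float]:
        df = self.background_meth
        sel = df[(df["stage"] == stage) & (df["genotype"] == genotype)]
        return dict(zip(sel["block_class"], sel["level"]))

    def rate_of(self, family: str, stage: str, genotype: str) -> float:
        df = self.family_rate
        sel = df[
            (df["family"] == family) & (df["stage"] == stage) & (df["genotype"] == genotype)
        ]
        return float(sel["rate"].iloc[0])

    def efficiency(self, genotype: str) -> float:
        eff = self.cleavage_efficiency.set_index("genotype")["efficiency"]
        return float(eff[genotype])

    def sites_of(self, family: str) -> pd.DataFrame:
        return self.cleavage_sites[self.cleavage_sites["family"] == family]

    # -- persistence -------------------------------------------------------

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in _TRUTH_FRAMES:
            seqio.write_tsv(outdir / f"{name}.tsv", getattr(self, name))

    @classmethod
    def from_dir(cls, indir: str | Path) -> "GroundTruth":
        indir = Path(indir)
        frames = {}
        for name in _TRUTH_FRAMES:
            df = seqio.read_tsv(indir / f"{name}.tsv")
            for col in df.columns:
                if df[col].dtype == object or df[col].isna().all():
                    df[col] = df[col].fillna("")
            frames[name] = df
        return cls(**frames)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        for name in _TRUTH_FRAMES:
            a = getattr(self, name).reset_index(drop=True)
            b = getattr(other, name).reset_index(drop=True)
            if len(a) != len(b):
                return False
            if len(a) == 0:
                continue
            try:
                pd.testing.assert_frame_equal(a, b, check_dtype=False, check_exact=False)
            except AssertionError:
                return False
        return True


@dataclass
class World:
    """A built synthetic world: sequences, annotations and ground truth."""

    config: SimConfig
    genome: dict[str, str]
    library: ConsensusLibrary
    truth: GroundTruth
    blacklist: dict[str, str]
    _genome_arr: np.ndarray | None = None
    _cpg_pos: np.ndarray | None = None

    @property
    def genome_arr(self) -> np.ndarray:
        if self._genome_arr is None:
            self._genome_arr = _to_arr(self.genome[CHROM])
        return self._genome_arr

    @property
    def cpg_positions(self) -> np.ndarray:
        """Positions of the C of every CpG dinucleotide on the top strand."""
        if self._cpg_pos is None:
            g = self.genome_arr
            self._cpg_pos = np.nonzero((g[:-1] == _C) & (g[1:] == _G))[0]
        return self._cpg_pos

    def cpg_levels(self, stage: str, genotype: str) -> np.ndarray:
        """True methylation level of each CpG site for a stage/genotype."""
        cfg = self.config
        pos = self.cpg_positions
        bg = self.truth.background_level(stage, genotype)
        block = (pos // cfg.block_size) % 2  # 0 = AT_rich, 1 = GC_rich
        levels = np.where(block == 0, bg["AT_rich"], bg["GC_rich"]).astype(float)
        fam_level = self.truth.family_level(stage, genotype)
        for c in self.truth.copies.itertuples():
            lo = np.searchsorted(pos, c.start)
            hi = np.searchsorted(pos, c.end)
            levels[lo:hi] = fam_level[c.family]
        return levels

    def gene_frame(self) -> pd.DataFrame:
        return self.truth.genes

    def cleavage_efficiency(self, stage: str, genotype: str) -> float:
        """Stage-gated cleavage efficiency (zero outside the perinatal window)."""
        if stage not in self.config.expr_model.get("cleavage_stages", list(STAGES)):
            return 0.0
        return self.truth.efficiency(genotype)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all world files; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "consensus": outdir / "consensus.fa",
            "copies": outdir / "te_copies.bed",
            "genes": outdir / "genes.gff3",
            "snps": outdir / "snps.vcf",
            "blacklist": outdir / "blacklist.fa",
            "truth": outdir / "truth",
        }
        seqio.write_fasta(paths["genome"], self.genome)
        seqio.write_fasta(paths["consensus"], self.library.seqs)
        bed = self.truth.copies.assign(
            name=lambda d: d["copy_id"] + "|" + d["family"], score=0
        )[["chrom", "start", "end", "name", "score", "strand"]]
        seqio.write_bed(paths["copies"], bed)
        seqio.write_gff3(paths["genes"], self.truth.genes, self.truth.exons)
        seqio.write_vcf(paths["snps"], self.truth.snps, {CHROM: len(self.genome[CHROM])})
        seqio.write_fasta(paths["blacklist"], self.blacklist)
        self.truth.to_dir(paths["truth"])
        return paths


# ---------------------------------------------------------------------------
# world construction


def _build_library(cfg: SimConfig, rng: np.random.Generator) -> ConsensusLibrary:
    seqs: dict[str, str] = {}
    family: dict[str, str] = {}
    subregions: dict[str, dict[str, tuple[int, int]]] = {}
    lo, hi = cfg.consensus_lengths
    for fam in cfg.families:
        length = int(rng.integers(lo, hi + 1))
        arr = _random_seq(rng, length, gc=0.45)
        if fam.startswith("L1"):
            fe = min(cfg.five_end_length, length // 2)
            _inject_cpgs(rng, arr, 0, fe, cfg.cpg_density["five_end"])
            _inject_cpgs(rng, arr, fe, length, cfg.cpg_density["body"])
            subregions[fam] = {"5end": (0, fe), "body": (fe, length)}
        else:
            _inject_cpgs(rng, arr, 0, length, cfg.cpg_density["body"])
        seqs[fam] = _to_str(arr)
        family[fam] = fam
    return ConsensusLibrary(seqs, family, subregions)


def _make_gene_layout(
    rng: np.random.Generator, n_exons: int = 3, intron_override: int | None = None
) -> tuple[list[tuple[int, int]], int]:
    """Relative exon intervals and total span for one gene."""
    exons = []
    pos = 0
    for i in range(n_exons):
        elen = int(rng.integers(200, 401))
        exons.append((pos, pos + elen))
        pos += elen
        if i < n_exons - 1:
            ilen = intron_override if (intron_override and i == 0) else int(rng.integers(800, 2501))
            pos += ilen
    return exons, pos


class _Placer:
    """Non-overlapping interval placement with a margin, by rejection."""

    def __init__(self, rng: np.random.Generator, genome_length: int, margin: int = 500):
        self.rng = rng
        self.n = genome_length
        self.margin = margin
        self.starts: list[int] = []
        self.ends: list[int] = []

    def place(self, length: int, what: str) -> int:
        if length + 2 * self.margin >= self.n:
            raise ValueError(
                f"genome_length={self.n} too small to place {what} of length {length}"
            )
        for _ in range(2000):
            s = int(self.rng.integers(self.margin, self.n - length - self.margin))
            e = s + length
            i = bisect_left(self.starts, s)
            ok = True
            if i > 0 and self.ends[i - 1] + self.margin > s:
                ok = False
            if ok and i < len(self.starts) and e + self.margin > self.starts[i]:
                ok = False
            if ok:
                insort(self.starts, s)
                self.ends.insert(bisect_left(self.starts, s), e)
                return s
        raise ValueError(
            f"genome_length={self.n} too crowded to place {what} of length {length}; "
            "increase genome_length or reduce copy/gene counts"
        )


def build_world(cfg: SimConfig, outdir: str | Path | None = None) -> World:
    """Build the toy genome, consensus library, annotations and ground truth.

    Coordinates are 0-based half-open throughout. With ``outdir`` given, all
    world files (FASTA/BED/GFF3/VCF and the truth tables) are also written.
    """
    rng = np.random.default_rng(cfg.seed)
    library = _build_library(cfg, rng)
    fam_len = library.lengths()
    families = list(cfg.families)

    # background genome: alternating AT-rich / GC-rich blocks
    n_blocks = cfg.genome_length // cfg.block_size + 1
    chunks = []
    for b in range(n_blocks):
        blen = min(cfg.block_size, cfg.genome_length - b * cfg.block_size)
        if blen <= 0:
            break
        gc = cfg.gc_poor if b % 2 == 0 else cfg.gc_rich
        arr = _random_seq(rng, blen, gc)
        dens = cfg.cpg_density["AT_rich"] if b % 2 == 0 else cfg.cpg_density["GC_rich"]
        _inject_cpgs(rng, arr, 0, blen, dens)
        chunks.append(arr)
    genome = np.concatenate(chunks)

    placer = _Placer(rng, cfg.genome_length)

    rt = cfg.readthrough_model
    drivers = [f for f in rt["driver_families"] if f in families]
    n_pairs = rt["n_driven_pairs"]

    copies_rows: list[dict] = []
    genes_rows: list[dict] = []
    exons_rows: list[dict] = []
    driven_rows: list[dict] = []
    remaining = {f: cfg.n_copies_per_family for f in families}

    def _write_copy(fam: str, start: int, strand: str, driven_gene: str | None) -> str:
        cid = f"copy{len(copies_rows):03d}"
        consensus = _to_arr(library.seqs[fam])
        mutated = _mutate(rng, consensus, cfg.copy_divergence)
        if strand == "-":
            mutated = revcomp_arr(mutated)
        genome[start : start + len(mutated)] = mutated
        copies_rows.append(
            {
                "copy_id": cid,
                "family": fam,
                "chrom": CHROM,
                "start": start,
                "end": start + len(mutated),
                "strand": strand,
                "active_weight": 0.0,
                "driven_gene": driven_gene or "",
            }
        )
        return cid

    def _write_gene(start: int, strand: str, exons_rel: list[tuple[int, int]], span: int) -> str:
        gid = f"gene{len(genes_rows):03d}"
        genes_rows.append(
            {
                "gene_id": gid,
                "chrom": CHROM,
                "start": start,
                "end": start + span,
                "strand": strand,
                "base_rate": float(rng.lognormal(np.log(cfg.expr_model["gene_base_rate"]), 0.4)),
                "direct_response": False,
            }
        )
        for s, e in exons_rel:
            exons_rows.append({"gene_id": gid, "start": start + s, "end": start + e})
        return gid

    # driven pair 0: full-length antisense copy inside the host gene's first intron
    pair_specs: list[tuple[str, str]] = []   # (family, relation)
    if n_pairs > 0 and "L1Md_T" in families and remaining.get("L1Md_T", 0) > 0:
        pair_specs.append(("L1Md_T", "intronic-antisense"))
    while len(pair_specs) < n_pairs and drivers:
        fam = drivers[len(pair_specs) % len(drivers)]
        if remaining[fam] <= len([p for p in pair_specs if p[0] == fam]):
            break
        pair_specs.append((fam, "upstream"))

    for fam, relation in pair_specs:
        strand = "+" if rng.random() < 0.5 else "-"
        if relation == "intronic-antisense":
            intron = fam_len[fam] + 1000
            exons_rel, span = _make_gene_layout(rng, intron_override=intron)
            gstart = placer.place(span, "host gene")
            gid = _write_gene(gstart, strand, exons_rel, span)
            # copy sits inside the (enlarged) first intron, antisense to the gene
            intron_lo = gstart + exons_rel[0][1] + 400
            cstrand = "-" if strand == "+" else "+"
            cid = _write_copy(fam, intron_lo, cstrand, gid)
        else:
            exons_rel, span = _make_gene_layout(rng)
            d = int(rng.integers(rt["min_distance"], rt["max_distance"]))
            clen = fam_len[fam]
            unit = clen + d + span
            ustart = placer.place(unit, "driven pair")
            cstrand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                cid = _write_copy(fam, ustart, cstrand, None)
                gid = _write_gene(ustart + clen + d, strand, exons_rel, span)
            else:
                gid = _write_gene(ustart, strand, exons_rel, span)
                cid = _write_copy(fam, ustart + span + d, cstrand, None)
            copies_rows[-1]["driven_gene"] = gid
        # driven genes are lowly expressed without the readthrough input
        genes_rows[-1]["base_rate"] = rt["driven_gene_base_rate"]
        remaining[fam] -= 1
        driven_rows.append({"copy_id": cid, "gene_id": gid, "relation": relation})

    # remaining ordinary genes
    n_ordinary = cfg.n_genes - len(genes_rows)
    if n_ordinary < 0:
        raise ValueError("n_genes smaller than the number of driven pairs")
    for _ in range(n_ordinary):
        strand = "+" if rng.random() < 0.5 else "-"
        exons_rel, span = _make_gene_layout(rng)
        gstart = placer.place(span, "gene")
        _write_gene(gstart, strand, exons_rel, span)

    # remaining TE copies at random loci
    for fam in families:
        for _ in range(remaining[fam]):
            strand = "+" if rng.random() < 0.5 else "-"
            start = placer.place(fam_len[fam], f"{fam} copy")
            _write_copy(fam, start, strand, None)

    copies = pd.DataFrame(copies_rows)
    genes = pd.DataFrame(genes_rows)
    exons = pd.DataFrame(exons_rows)
    driven_pairs = pd.DataFrame(driven_rows, columns=["copy_id", "gene_id", "relation"])

    # activity: driven copies are always transcribed; plus n_active extra per family
    n_active = cfg.expr_model["n_active_copies"]
    active = set(driven_pairs["copy_id"])
    for fam in families:
        idle = copies[(copies["family"] == fam) & (~copies["copy_id"].isin(active))]
        take = idle["copy_id"].tolist()[:n_active]
        active.update(take)
    copies["active_weight"] = copies["copy_id"].isin(active).astype(float)
    # each active copy carries an equal share of its family's transcription
    share = copies.groupby("family")["active_weight"].transform(
        lambda s: s / max(s.sum(), 1.0)
    )
    copies["active_weight"] = share

    # direct (non-TE-driven) knockout-responsive genes
    n_direct = cfg.expr_model["n_direct_response_genes"]
    eligible = genes[~genes["gene_id"].isin(set(driven_pairs["gene_id"]))]
    direct_ids = eligible["gene_id"].tolist()[:n_direct]
    genes["direct_response"] = genes["gene_id"].isin(direct_ids)

    # truth tables for the generative models
    fam_meth_rows = []
    for fam in families:
        for stage in STAGES:
            for gt in GENOTYPES:
                fam_meth_rows.append(
                    {
                        "family": fam,
                        "stage": stage,
                        "genotype": gt,
                        "level": cfg.meth_model["family_level"][fam][stage][gt],
                    }
                )
    bg_rows = []
    for stage in STAGES:
        for gt in GENOTYPES:
            for blk in ("AT_rich", "GC_rich"):
                bg_rows.append(
                    {
                        "stage": stage,
                        "genotype": gt,
                        "block_class": blk,
                        "level": cfg.meth_model["background_level"][stage][gt][blk],
                    }
                )
    rate_rows = []
    for fam in families:
        for stage in STAGES:
            for gt in GENOTYPES:
                rate_rows.append(
                    {
                        "family": fam,
                        "stage": stage,
                        "genotype": gt,
                        "rate": cfg.expr_model["family_rate"][fam][stage][gt],
                    }
                )

    # cleavage sites on consensus coordinates for piRNA-target families
    site_rows = []
    pp = cfg.pirna_model["ping_pong_fraction"]
    for fam in families:
        if fam not in PIRNA_TARGET_FAMILIES:
            continue
        L = fam_len[fam]
        # even count so a ping-pong fraction of one half is exactly realizable
        n_sites = max(2, 2 * int(round(cfg.expr_model["cleavage_site_rate_per_kb"] * L / 2000)))
        # one site is pinned late in the element so the polyA-retained 3' tail
        # is consistently short when cleavage is active
        lo, hi = 300, max(int(0.75 * L), 400)
        pos = rng.choice(np.arange(lo, hi, 25), size=n_sites - 1, replace=False)
        pos = np.sort(np.concatenate([pos, [int(0.85 * L)]])).astype(int)
        n_guided = int(round(pp * n_sites))
        guided = np.zeros(n_sites, dtype=bool)
        guided[rng.choice(n_sites, size=n_guided, replace=False)] = True
        for p, g in zip(pos, guided):
            site_rows.append({"family": fam, "position": int(p), "guided": bool(g)})
    cleavage_sites = pd.DataFrame(site_rows, columns=["family", "position", "guided"])

    eff_rows = [
        {"genotype": gt, "efficiency": cfg.expr_model["cleavage_efficiency"][gt]}
        for gt in GENOTYPES
    ]

    # piRNA 5'-end position pools (sense coordinates on the consensus)
    pirna_rows = []
    pw = cfg.pirna_model["partner_weight"]
    for fam in cfg.pirna_model["family_weight"]:
        if fam not in families:
            continue
        L = fam_len[fam]
        fam_sites = cleavage_sites[cleavage_sites["family"] == fam]
        partner_pos = set(int(p) + 9 for p in fam_sites[fam_sites["guided"]]["position"])
        forbidden = set(int(p) + 9 for p in fam_sites[~fam_sites["guided"]]["position"])
        for q in sorted(partner_pos):
            pirna_rows.append(
                {"family": fam, "strand": "antisense", "position": q, "weight": pw, "partner": True}
            )
        n_bg = 40
        placed = 0
        while placed < n_bg:
            q = int(rng.integers(35, L - 1))
            if q in partner_pos or q in forbidden:
                continue
            pirna_rows.append(
                {"family": fam, "strand": "antisense", "position": q, "weight": 1.0, "partner": False}
            )
            partner_pos.add(q)  # avoid duplicates
            placed += 1
        for _ in range(n_bg):
            q = int(rng.integers(0, L - 34))
            pirna_rows.append(
                {"family": fam, "strand": "sense", "position": q, "weight": 1.0, "partner": False}
            )
    pirna_positions = pd.DataFrame(
        pirna_rows, columns=["family", "strand", "position", "weight", "partner"]
    )

    # strain SNPs: draw positions, skip CpG dinucleotides so methylation truth
    # is not disturbed, and avoid creating or destroying CpGs
    n_snps = int(rng.poisson(cfg.snp_rate * cfg.genome_length))
    raw = np.unique(rng.integers(1, cfg.genome_length - 1, size=int(n_snps * 1.3)))[:n_snps]
    snp_rows = []
    bases = np.array([_A, _C, _G, _T], dtype=np.uint8)
    for p in raw:
        ref = genome[p]
        if ref not in (_A, _C, _G, _T):
            continue
        if ref == _C and genome[p + 1] == _G:
            continue
        if ref == _G and genome[p - 1] == _C:
            continue
        # alt restricted to A/T: cannot create a CpG
        alt = _T if ref != _T else _A
        snp_rows.append({"chrom": CHROM, "pos": int(p), "ref": chr(ref), "alt": chr(alt)})
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "ref", "alt"])

    truth = GroundTruth(
        copies=copies,
        genes=genes,
        exons=exons,
        family_meth=pd.DataFrame(fam_meth_rows),
        background_meth=pd.DataFrame(bg_rows),
        family_rate=pd.DataFrame(rate_rows),
        cleavage_sites=cleavage_sites,
        cleavage_efficiency=pd.DataFrame(eff_rows),
        pirna_positions=pirna_positions,
        driven_pairs=driven_pairs,
        snps=snps,
    )
    truth.validate()

    # rRNA/miRNA-like decoys for blacklist filtering
    blacklist = {
        name: _to_str(_random_seq(rng, ln, 0.5))
        for name, ln in [("rRNA_1", 300), ("rRNA_2", 200), ("tRNA_1", 80), ("miR_1", 60), ("miR_2", 60)]
    }

    world = World(
        config=cfg,
        genome={CHROM: _to_str(genome)},
        library=library,
        truth=truth,
        blacklist=blacklist,
    )
    if outdir is not None:
        world.write(outdir)
    return world


# ---------------------------------------------------------------------------
# WGBS simulator


def simulate_wgbs(
    world: World,
    stage: str,
    genotype: str,
    seed: int,
    depth: float | None = None,
    conversion_rate: float | None = None,
    error_rate: float | None = None,
    read_len: int | None = None,
) -> list[FastqRead]:
    """Directional bisulfite reads from both genome strands.

    Methylated cytosines are protected; unmethylated cytosines read as T with
    probability ``conversion_rate`` (incomplete conversion leaves residual C).
    Only CpG-context cytosines can be methylated; the truth level of each CpG
    comes from the world's per-copy/per-block model.
    """
    cfg = world.config
    _check_grid(cfg, stage, genotype)
    depth = cfg.library_sizes["wgbs_depth"] if depth is None else depth
    if depth <= 0:
        raise ValueError(f"depth must be > 0, got {depth}")
    conv = cfg.conversion_rate if conversion_rate is None else conversion_rate
    err = cfg.error_rate if error_rate is None else error_rate
    rl = cfg.read_lengths["wgbs"] if read_len is None else read_len

    rng = np.random.default_rng(seed)
    g = world.genome_arr
    G = len(g)
    cpg = world.cpg_positions
    levels = world.cpg_levels(stage, genotype)

    n_reads = int(round(depth * G / rl))
    starts = rng.integers(0, G - rl + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    qual = "I" * rl
    reads: list[FastqRead] = []
    for i in range(n_reads):
        s = int(starts[i])
        if strands[i] == 0:  # original top strand
            seg = g[s : s + rl].copy()
            c_idx = np.nonzero(seg == _C)[0]
            gpos = s + c_idx
            # CpG context = genome C followed by G
            lo = np.searchsorted(cpg, gpos, side="left")
            is_cpg = (lo < len(cpg)) & (cpg[np.minimum(lo, len(cpg) - 1)] == gpos)
            meth = np.zeros(len(c_idx), dtype=bool)
            if is_cpg.any():
                lv = levels[lo[is_cpg]]
                meth[is_cpg] = rng.random(int(is_cpg.sum())) < lv
            convert = (~meth) & (rng.random(len(c_idx)) < conv)
            seg[c_idx[convert]] = _T
        else:  # original bottom strand: Cs of the read are Gs on top
            top = g[s : s + rl]
            g_idx = np.nonzero(top == _G)[0]
            gpos = s + g_idx
            # bottom-strand CpG: top-strand C at gpos-1
            lo = np.searchsorted(cpg, gpos - 1, side="left")
            is_cpg = (lo < len(cpg)) & (cpg[np.minimum(lo, len(cpg) - 1)] == gpos - 1)
            meth = np.zeros(len(g_idx), dtype=bool)
            if is_cpg.any():
                lv = levels[lo[is_cpg]]
                meth[is_cpg] = rng.random(int(is_cpg.sum())) < lv
            convert = (~meth) & (rng.random(len(g_idx)) < conv)
            seg = top.copy()
            seg[g_idx[convert]] = _A  # G->A on top == C->T on bottom
            seg = revcomp_arr(seg)
        seg = _apply_errors(rng, seg, err)
        reads.append(FastqRead(f"wgbs:{stage}:{genotype}:{i}", _to_str(seg), qual))
    return reads


def _check_grid(cfg: SimConfig, stage: str, genotype: str) -> None:
    if (stage, genotype) not in [tuple(x) for x in cfg.grid]:
        raise ValueError(f"({stage}, {genotype}) not in the configured stage/genotype grid")


# ---------------------------------------------------------------------------
# RNA-seq simulator


@dataclass
class _Transcript:
    tid: str
    kind: str            # te | gene | readthrough
    source: str          # copy_id or gene_id
    family: str | None
    strand: str          # transcription strand on the genome
    gpos: np.ndarray     # genomic position of each transcript base (5'->3')
    comp: bool           # bases are complemented relative to the top strand
    rate: float
    cleavage: np.ndarray  # cleavage 5' positions in transcript coordinates
    allele_policy: str   # 'mix' or 'A'


def _transcript_seq(g: np.ndarray, t: _Transcript) -> np.ndarray:
    seq = g[t.gpos]
    return _COMP[seq] if t.comp else seq


def _build_transcripts(world: World, stage: str, genotype: str) -> tuple[list[_Transcript], int]:
    cfg = world.config
    truth = world.truth
    fam_len = world.library.lengths()
    eff = world.cleavage_efficiency(stage, genotype)
    tx: list[_Transcript] = []
    skipped = 0

    # TE copy transcripts (sense of the copy)
    for c in truth.copies.itertuples():
        if c.active_weight <= 0:
            continue
        rate = truth.rate_of(c.family, stage, genotype) * c.active_weight
        if rate <= 0:
            continue
        L = c.end - c.start
        if c.strand == "+":
            gpos = np.arange(c.start, c.end)
            comp = False
        else:
            gpos = np.arange(c.end - 1, c.start - 1, -1)
            comp = True
        sites = truth.sites_of(c.family)["position"].to_numpy()
        sites = np.sort(sites[sites < L])
        cleaved = eff > 0 and c.family in PIRNA_TARGET_FAMILIES
        tx.append(
            _Transcript(
                tid=f"te:{c.copy_id}",
                kind="te",
                source=c.copy_id,
                family=c.family,
                strand=c.strand,
                gpos=gpos,
                comp=comp,
                rate=rate,
                cleavage=sites if cleaved else np.array([], dtype=int),
                allele_policy="mix",
            )
        )

    # spliced gene transcripts
    exons = truth.exons
    for gene in truth.genes.itertuples():
        rate = gene.base_rate
        if gene.direct_response and genotype != "WT":
            rate *= cfg.expr_model["direct_response_multiplier"]
        ex = exons[exons["gene_id"] == gene.gene_id].sort_values("start")
        blocks = [np.arange(s, e) for s, e in zip(ex["start"], ex["end"])]
        gpos = np.concatenate(blocks)
        comp = gene.strand == "-"
        if comp:
            gpos = gpos[::-1]
        tx.append(
            _Transcript(
                tid=f"gene:{gene.gene_id}",
                kind="gene",
                source=gene.gene_id,
                family=None,
                strand=gene.strand,
                gpos=gpos,
                comp=comp,
                rate=rate,
                cleavage=np.array([], dtype=int),
                allele_policy="mix",
            )
        )

    # readthrough transcripts from driving copies into/through their genes
    rt = cfg.readthrough_model
    genes_ix = truth.genes.set_index("gene_id")
    copies_ix = truth.copies.set_index("copy_id")
    ext = int(rt.get("extension", 1000))
    for pair in truth.driven_pairs.itertuples():
        gene = genes_ix.loc[pair.gene_id]
        cp = copies_ix.loc[pair.copy_id]
        rate = rt["readthrough_strength"] * truth.rate_of(cp["family"], stage, genotype)
        # chimeric readthrough RNA: the copy plus a short run-on toward the
        # gene (flank evidence), spliced onto the gene's exons
        ex = exons[exons["gene_id"] == pair.gene_id].sort_values("start")
        glen = len(world.genome[CHROM])
        if gene["strand"] == "+":
            blocks = [(int(cp["start"]), min(int(cp["end"]) + ext, glen))]
            blocks += [(int(s), int(e)) for s, e in zip(ex["start"], ex["end"])]
            gpos = np.concatenate([np.arange(s, e) for s, e in blocks])
            comp = False
        else:
            blocks = [(max(int(cp["start"]) - ext, 0), int(cp["end"]))]
            blocks += [(int(s), int(e)) for s, e in zip(ex["start"][::-1], ex["end"][::-1])]
            gpos = np.concatenate([np.arange(e - 1, s - 1, -1) for s, e in blocks])
            comp = True
        # a readthrough RNA carrying the copy in sense orientation is itself
        # a piRNA cleavage target (the copy occupies transcript coords 0..len)
        clen = int(cp["end"]) - int(cp["start"])
        if (
            cp["strand"] == gene["strand"]
            and cp["family"] in PIRNA_TARGET_FAMILIES
            and eff > 0
        ):
            rt_sites = truth.sites_of(cp["family"])["position"].to_numpy()
            rt_sites = np.sort(rt_sites[rt_sites < clen])
        else:
            rt_sites = np.array([], dtype=int)
        tx.append(
            _Transcript(
                tid=f"rt:{pair.copy_id}:{pair.gene_id}",
                kind="readthrough",
                source=pair.gene_id,
                family=cp["family"],
                strand=gene["strand"],
                gpos=gpos,
                comp=comp,
                rate=rate,
                cleavage=rt_sites,
                allele_policy="A",
            )
        )
    return tx, skipped


def simulate_rnaseq(
    world: World,
    stage: str,
    genotype: str,
    seed: int,
    n_reads: int | None = None,
    read_len: int | None = None,
    error_rate: float | None = None,
) -> tuple[list[FastqRead], pd.DataFrame, dict]:
    """Stranded polyA(+) RNA-seq reads.

    Each TE transcript is independently cleaved at its truth sites with the
    genotype's efficiency; only the 3'-terminal fragment of a cleaved molecule
    retains the polyA tail and is sampled, so cleavage depletes 5' coverage.
    Returns (reads, per-transcript truth table, report).
    """
    cfg = world.config
    _check_grid(cfg, stage, genotype)
    n_reads = cfg.library_sizes["rnaseq"] if n_reads is None else n_reads
    rl = cfg.read_lengths["rnaseq"] if read_len is None else read_len
    err = cfg.error_rate if error_rate is None else error_rate

    rng = np.random.default_rng(seed)
    g = world.genome_arr
    tx, _ = _build_transcripts(world, stage, genotype)
    eff = world.cleavage_efficiency(stage, genotype)

    # per-transcript sampling weight: rate x eligible (3'-retained) positions
    outcomes: list[tuple[np.ndarray, np.ndarray]] = []  # (start offsets s*, probs)
    weights = np.zeros(len(tx))
    skipped_short = 0
    for i, t in enumerate(tx):
        L = len(t.gpos)
        if L < rl:
            skipped_short += 1
            continue
        sites = t.cleavage
        m = len(sites)
        if m == 0:
            starts = np.array([0])
            probs = np.array([1.0])
        else:
            e = eff
            starts = np.concatenate([[0], sites])
            p_un = (1 - e) ** m
            p_sites = np.array([e * (1 - e) ** (m - 1 - j) for j in range(m)])
            probs = np.concatenate([[p_un], p_sites])
        npos = np.maximum(L - rl + 1 - starts, 0)
        mass = probs * npos
        total = mass.sum()
        if total <= 0:
            skipped_short += 1
            continue
        outcomes.append((starts, mass / total))
        weights[i] = t.rate * total
    keep = np.nonzero(weights > 0)[0]
    weights = weights[keep]
    kept_tx = [tx[i] for i in keep]
    counts = rng.multinomial(n_reads, weights / weights.sum())

    snp_pos = world.truth.snps["pos"].to_numpy()
    snp_alt = np.frombuffer(
        "".join(world.truth.snps["alt"]).encode("ascii"), dtype=np.uint8
    ) if len(world.truth.snps) else np.array([], dtype=np.uint8)

    reads: list[FastqRead] = []
    qual = "I" * rl
    table_rows = []
    ridx = 0
    for (t, n), (starts, probs) in zip(zip(kept_tx, counts), outcomes):
        table_rows.append(
            {"tid": t.tid, "kind": t.kind, "source": t.source, "family": t.family or "",
             "rate": t.rate, "length": len(t.gpos), "n_reads": int(n)}
        )
        if n == 0:
            continue
        tseq = _transcript_seq(g, t)
        L = len(tseq)
        js = rng.choice(len(starts), size=n, p=probs)
        for j in js:
            smin = int(starts[j])
            start = smin + int(rng.integers(0, L - rl + 1 - smin))
            seg = tseq[start : start + rl].copy()
            allele = "A" if t.allele_policy == "A" else ("A" if rng.random() < 0.5 else "B")
            if allele == "B" and len(snp_pos):
                gslice = t.gpos[start : start + rl]
                idx = np.searchsorted(snp_pos, gslice)
                idx[idx == len(snp_pos)] = 0
                hit = np.nonzero(snp_pos[idx] == gslice)[0]
                if len(hit):
                    alt = snp_alt[idx[hit]]
                    seg[hit] = _COMP[alt] if t.comp else alt
            seg = _apply_errors(rng, seg, err)
            reads.append(
                FastqRead(f"rna:{stage}:{genotype}:{t.tid}:{ridx}", _to_str(seg), qual)
            )
            ridx += 1
    report = {"skipped_short_transcripts": skipped_short, "n_reads": len(reads)}
    return reads, pd.DataFrame(table_rows), report


# ---------------------------------------------------------------------------
# small RNA simulator


_PIRNA_LEN = np.arange(24, 34)
_PIRNA_LEN_W = np.array([1, 2, 3, 5, 6, 6, 4, 3, 2, 1], dtype=float)
_PIRNA_LEN_W /= _PIRNA_LEN_W.sum()


def simulate_small_rna(
    world: World,
    stage: str,
    genotype: str,
    seed: int,
    n_reads: int | None = None,
) -> list[FastqRead]:
    """A small-RNA pool: TE piRNAs (24-33 nt, ping-pong-structured antisense
    positions), genic background, off-range contaminants and blacklist decoys.

    In the piRNA-pathway knockout the TE-derived fraction of the pool shrinks
    by the configured multiplier; the freed share becomes genic background so
    the library size is preserved.
    """
    cfg = world.config
    _check_grid(cfg, stage, genotype)
    n_reads = cfg.library_sizes["small_rna"] if n_reads is None else n_reads
    pm = cfg.pirna_model
    rng = np.random.default_rng(seed)

    n_black = int(round(pm["blacklist_fraction"] * n_reads))
    n_contam = int(round(pm["contaminant_fraction"] * n_reads))
    n_te = int(round(pm["te_fraction"] * n_reads))
    if genotype in ("Pld6KO", "DKO"):
        n_te = int(round(n_te * pm["pld6_te_multiplier"]))
    n_genic = n_reads - n_black - n_contam - n_te

    g = world.genome_arr
    G = len(g)
    reads: list[FastqRead] = []
    err = cfg.error_rate

    def _emit(seq_arr: np.ndarray, tag: str) -> None:
        seq_arr = _apply_errors(rng, seq_arr, err)
        reads.append(
            FastqRead(
                f"sRNA:{stage}:{genotype}:{tag}:{len(reads)}",
                _to_str(seq_arr),
                "I" * len(seq_arr),
            )
        )

    # TE piRNAs
    fams = [f for f in pm["family_weight"] if f in cfg.families]
    fw = np.array([pm["family_weight"][f] for f in fams])
    fw = fw / fw.sum()
    pool = world.truth.pirna_positions
    lib = {f: _to_arr(world.library.seqs[f]) for f in fams}
    pools: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for fam in fams:
        for strand in ("sense", "antisense"):
            sub = pool[(pool["family"] == fam) & (pool["strand"] == strand)]
            w = sub["weight"].to_numpy(dtype=float)
            pools[(fam, strand)] = (sub["position"].to_numpy(), w / w.sum())
    fam_draw = rng.choice(len(fams), size=n_te, p=fw)
    anti = rng.random(n_te) < pm["antisense_fraction"]
    lens = rng.choice(_PIRNA_LEN, size=n_te, p=_PIRNA_LEN_W)
    for i in range(n_te):
        fam = fams[fam_draw[i]]
        strand = "antisense" if anti[i] else "sense"
        positions, w = pools[(fam, strand)]
        q = int(positions[rng.choice(len(positions), p=w)])
        L = int(lens[i])
        cons = lib[fam]
        if strand == "sense":
            if q + L > len(cons):
                L = len(cons) - q
            seq = cons[q : q + L]
        else:
            lo = max(q - L + 1, 0)
            seq = revcomp_arr(cons[lo : q + 1])
        _emit(seq.copy(), f"te_{strand}")

    # genic background: random genomic fragments, random strand
    lens = rng.choice(_PIRNA_LEN, size=n_genic, p=_PIRNA_LEN_W)
    for i in range(n_genic):
        L = int(lens[i])
        s = int(rng.integers(0, G - L))
        seq = g[s : s + L].copy()
        if rng.random() < 0.5:
            seq = revcomp_arr(seq)
        _emit(seq, "genic")

    # off-range contaminants
    off = np.concatenate([np.arange(18, 24), np.arange(34, 41)])
    lens = rng.choice(off, size=n_contam)
    for i in range(n_contam):
        L = int(lens[i])
        s = int(rng.integers(0, G - L))
        _emit(g[s : s + L].copy(), "contam")

    # blacklist decoys (exact substrings of the decoy sequences)
    bl_names = list(world.blacklist)
    for i in range(n_black):
        name = bl_names[int(rng.integers(0, len(bl_names)))]
        src = _to_arr(world.blacklist[name])
        L = int(rng.choice([22, 28, 30]))
        s = int(rng.integers(0, len(src) - L))
        _emit(src[s : s + L].copy(), "decoy")

    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


# ---------------------------------------------------------------------------
# 5'-RACE simulator


def simulate_race(
    world: World,
    stage: str,
    genotype: str,
    seed: int,
    n_reads: int | None = None,
    read_len: int | None = None,
) -> tuple[list[FastqRead], dict]:
    """5'-monophosphate (cleaved) RNA 5'-end reads.

    Reads from piRNA-target families start exactly at truth cleavage sites
    with mass proportional to transcription rate x cleavage efficiency; a
    genotype-independent background of other degradome fragments fills the
    rest of the library, so the family share of the cleaved pool drops when
    cleavage is lost.
    """
    cfg = world.config
    _check_grid(cfg, stage, genotype)
    n_reads = cfg.library_sizes["race"] if n_reads is None else n_reads
    rl = cfg.read_lengths["race"] if read_len is None else read_len
    rng = np.random.default_rng(seed)
    truth = world.truth
    eff = world.cleavage_efficiency(stage, genotype)

    entries: list[tuple[str, int]] = []  # (family, site) or ("", genomic pos placeholder)
    masses: list[float] = []
    for fam in cfg.families:
        if fam not in PIRNA_TARGET_FAMILIES:
            continue
        sites = truth.sites_of(fam)["position"].to_numpy()
        if len(sites) == 0:
            continue
        rate = truth.rate_of(fam, stage, genotype)
        for s in sites:
            entries.append((fam, int(s)))
            masses.append(rate * eff / len(sites))
    te_mass = float(np.sum(masses))
    bg_mass = cfg.expr_model["race_background_rate"]

    if te_mass <= 0 and bg_mass <= 0:
        warnings.warn("no cleavage events to sample; emitting an empty read set")
        return [], {"n_te": 0, "n_background": 0}
    if te_mass <= 0:
        warnings.warn("zero cleavage signal for this genotype; background-only library")

    probs = np.array(masses + [bg_mass])
    probs = probs / probs.sum()
    counts = rng.multinomial(n_reads, probs)
    g = world.genome_arr
    G = len(g)
    err = cfg.error_rate
    reads: list[FastqRead] = []
    for (fam, site), n in zip(entries, counts[:-1]):
        cons = _to_arr(world.library.seqs[fam])
        seq0 = cons[site : site + rl]
        for _ in range(int(n)):
            seq = _apply_errors(rng, seq0.copy(), err)
            reads.append(
                FastqRead(
                    f"race:{stage}:{genotype}:{fam}:{site}:{len(reads)}",
                    _to_str(seq),
                    "I" * len(seq),
                )
            )
    for _ in range(int(counts[-1])):
        s = int(rng.integers(0, G - rl))
        seq = g[s : s + rl].copy()
        if rng.random() < 0.5:
            seq = revcomp_arr(seq)
        seq = _apply_errors(rng, seq, err)
        reads.append(
            FastqRead(f"race:{stage}:{genotype}:bg:{len(reads)}", _to_str(seq), "I" * rl)
        )
    order = rng.permutation(len(reads))
    report = {"n_te": int(counts[:-1].sum()), "n_background": int(counts[-1])}
    return [reads[i] for i in order], report
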