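"""Tests of the synthetic world generator and read simulators."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from retrosilence import seqio
from retrosilence import synthetic as syn
from retrosilence.config import SimConfig
from retrosilence.synthetic import CHROM, revcomp

from conftest import tiny_config


def _world_hash(world: syn.World, tmpdir: Path) -> dict[str, str]:
    paths = world.write(tmpdir)
    out = {}
    for key, p in paths.items():
        if p.is_dir():
            for f in sorted(p.iterdir()):
                out[f"{key}/{f.name}"] = seqio.sha256_file(f)
        else:
            out[key] = seqio.sha256_file(p)
    return out


class TestBuildWorld:
    def test_copy_count_conservation(self, tiny_world):
        cfg = tiny_world.config
        assert len(tiny_world.truth.copies) == cfg.n_families * cfg.n_copies_per_family

    def test_copies_match_bed_and_library(self, tiny_world, tmp_path):
        paths = tiny_world.write(tmp_path)
        bed = seqio.read_bed(paths["copies"])
        lib = seqio.read_fasta(paths["consensus"])
        assert len(bed) == len(tiny_world.truth.copies)
        for name in bed["name"]:
            _copy_id, family = name.split("|")
            assert family in lib

    def test_zero_divergence_copies_verbatim(self):
        world = syn.build_world(tiny_config(seed=3, copy_divergence=0.0))
        genome = world.genome[CHROM]
        for c in world.truth.copies.itertuples():
            sub = genome[c.start : c.end]
            cons = world.library.seqs[c.family]
            assert sub == (cons if c.strand == "+" else revcomp(cons))

    def test_same_seed_identical_outputs(self, tmp_path):
        h1 = _world_hash(syn.build_world(tiny_config(seed=7)), tmp_path / "a")
        h2 = _world_hash(syn.build_world(tiny_config(seed=7)), tmp_path / "b")
        assert h1 == h2

    def test_intronic_antisense_pair_exists(self, tiny_world):
        pairs = tiny_world.truth.driven_pairs
        intronic = pairs[pairs["relation"] == "intronic-antisense"]
        assert len(intronic) >= 1
        copies = tiny_world.truth.copies.set_index("copy_id")
        genes = tiny_world.truth.genes.set_index("gene_id")
        for p in intronic.itertuples():
            c, g = copies.loc[p.copy_id], genes.loc[p.gene_id]
            assert g["start"] <= c["start"] and c["end"] <= g["end"]
            assert c["strand"] != g["strand"]
            # full-length: the copy footprint spans the whole consensus
            assert c["end"] - c["start"] == len(tiny_world.library.seqs[c["family"]])

    def test_genome_too_small_raises(self):
        with pytest.raises(ValueError, match="genome_length"):
            syn.build_world(tiny_config(seed=0, genome_length=20_000))

    def test_truth_round_trip(self, tiny_world, tmp_path):
        tiny_world.truth.to_dir(tmp_path / "truth")
        back = syn.GroundTruth.from_dir(tmp_path / "truth")
        assert back == tiny_world.truth

    def test_cleavage_efficiency_invariant(self, tiny_world):
        eff = tiny_world.truth.cleavage_efficiency.set_index("genotype")["efficiency"]
        assert eff["Pld6KO"] < eff["WT"]

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(copy_divergence=1.5)
        with pytest.raises(ValueError):
            SimConfig(n_genes=0)


def _uniform_meth_config(seed: int, level: float):
    cfg = tiny_config(seed=seed)
    for fam in cfg.meth_model["family_level"].values():
        for stage in fam.values():
            for gt in stage:
                stage[gt] = level
    for stage in cfg.meth_model["background_level"].values():
        for gt in stage.values():
            gt["GC_rich"] = gt["AT_rich"] = level
    return cfg


def _call(world, reads, unique_only=False):
    from retrosilence import align as al
    from retrosilence import methylome as me

    ref = {CHROM: world.genome[CHROM]}
    index = al.SeedIndex(ref, seed_len=14, bisulfite=True)
    res = al.align_reads(reads, index, mode="bisulfite", max_mismatches=2, seed_len=14)
    if unique_only:
        res.records = [r for r in res.records if r.k == 1]
    return me.call_methylation(res, ref)


class TestWgbs:
    def test_fully_methylated_protected(self):
        world = syn.build_world(_uniform_meth_config(2, level=1.0))
        reads = syn.simulate_wgbs(
            world, "proSG_P0", "WT", seed=1, depth=0.5, conversion_rate=1.0, error_rate=0.0
        )
        # unique placements only: a multimapping tie onto a diverged sister
        # copy can mimic an unmethylated call without any conversion
        meth = _call(world, reads, unique_only=True)
        # no CpG cytosine converts: every CpG call is methylated
        assert meth.cpg["n_unmeth"].sum() == 0
        assert meth.cpg["n_meth"].sum() > 100
        # non-CpG cytosines convert fully
        assert meth.non_cpg["n_meth"].sum() == 0

    def test_unmethylated_residual_matches_conversion(self):
        world = syn.build_world(_uniform_meth_config(4, level=0.0))
        conv = 0.99
        reads = syn.simulate_wgbs(
            world, "proSG_P0", "WT", seed=9, depth=1.5, conversion_rate=conv, error_rate=0.0
        )
        meth = _call(world, reads)
        cpg_level = meth.cpg["n_meth"].sum() / (
            meth.cpg["n_meth"].sum() + meth.cpg["n_unmeth"].sum()
        )
        assert cpg_level == pytest.approx(1 - conv, abs=0.005)
        assert meth.conversion_rate() == pytest.approx(conv, abs=0.005)

    def test_depth_must_be_positive(self, tiny_world):
        with pytest.raises(ValueError, match="depth"):
            syn.simulate_wgbs(tiny_world, "proSG_P0", "WT", seed=1, depth=0)

    def test_unknown_grid_cell(self, tiny_world):
        with pytest.raises(ValueError, match="grid"):
            syn.simulate_wgbs(tiny_world, "proSG_P0", "nosuch", seed=1, depth=1)

    def test_fixed_seed_identical_fastq(self, tiny_world, tmp_path):
        for name in ("a", "b"):
            reads = syn.simulate_wgbs(tiny_world, "proSG_P0", "WT", seed=5, depth=0.2)
            seqio.write_fastq(tmp_path / f"{name}.fastq", reads)
        assert seqio.sha256_file(tmp_path / "a.fastq") == seqio.sha256_file(tmp_path / "b.fastq")


class TestRnaseq:
    def test_no_cleavage_read_shares_track_transcription_rates(self, tiny_world_seed1):
        # at the spermatocyte stage cleavage is inactive for every genotype,
        # so family read shares follow transcription rates alone
        world = tiny_world_seed1
        tabs = {}
        for gt, sd in [("WT", 21), ("Dnmt3lKO", 22)]:
            _reads, table, _ = syn.simulate_rnaseq(world, "LZ_P21", gt, seed=sd, n_reads=20000)
            te = table[table["kind"] == "te"]
            tabs[gt] = te.groupby("family")["n_reads"].sum()

        def rate(fam, gt):
            return world.truth.rate_of(fam, "LZ_P21", gt)

        # L1Md_A rises ~6x relative to IAPEz-free baseline families; compare
        # the KO/WT share ratio of L1Md_A against IAPEz to the truth rates
        obs = (tabs["Dnmt3lKO"]["L1Md_A"] / tabs["WT"]["L1Md_A"]) / (
            tabs["Dnmt3lKO"]["IAPEz"] / tabs["WT"]["IAPEz"]
        )
        expected = (rate("L1Md_A", "Dnmt3lKO") / rate("L1Md_A", "WT")) / (
            rate("IAPEz", "Dnmt3lKO") / rate("IAPEz", "WT")
        )
        assert obs == pytest.approx(expected, rel=0.3)

    def test_full_cleavage_depletes_five_prime(self):
        cfg = tiny_config(seed=6)
        cfg.expr_model["cleavage_efficiency"]["WT"] = 1.0
        world = syn.build_world(cfg)
        reads, _table, _ = syn.simulate_rnaseq(
            world, "proSG_P0", "WT", seed=3, n_reads=8000, error_rate=0.0
        )
        # with certain cleavage, no read from a cleaved TE transcript can start
        # 5' of its transcript's first cleavage site; in particular no error-free
        # te read equals its copy's 5'-terminal 50-mer
        genome = world.genome[CHROM]
        heads = {}
        for c in world.truth.copies.itertuples():
            if c.family not in set(world.truth.cleavage_sites["family"]):
                continue
            seq = genome[c.start : c.end]
            if c.strand == "-":
                seq = revcomp(seq)
            heads[c.copy_id] = seq[:50]
        n_te = 0
        for r in reads:
            parts = r.name.split(":")
            if parts[3] == "te" and parts[4] in heads:
                n_te += 1
                assert r.seq != heads[parts[4]]
        assert n_te > 0

    def test_driven_pair_reads_span_copy_and_exons(self, tiny_world):
        reads, table, _ = syn.simulate_rnaseq(tiny_world, "LZ_P21", "Pld6KO", seed=4, n_reads=6000)
        rt = table[table["kind"] == "readthrough"]
        assert len(rt) == len(tiny_world.truth.driven_pairs)
        assert rt["n_reads"].sum() > 0

    def test_read_count_conservation(self, tiny_world):
        n = 3123
        reads, _table, report = syn.simulate_rnaseq(tiny_world, "proSG_P0", "WT", seed=8, n_reads=n)
        assert len(reads) == n == report["n_reads"]


class TestSmallRnaAndRace:
    def test_pingpong_one_gives_partner_for_every_guided_site(self):
        cfg = tiny_config(seed=7)
        cfg.pirna_model["ping_pong_fraction"] = 1.0
        world = syn.build_world(cfg)
        sites = world.truth.cleavage_sites
        assert sites["guided"].all()
        pool = world.truth.pirna_positions
        partners = pool[pool["partner"]]
        for s in sites.itertuples():
            match = partners[
                (partners["family"] == s.family) & (partners["position"] == s.position + 9)
            ]
            assert len(match) == 1

    def test_pingpong_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="ping_pong"):
            cfg = tiny_config(seed=0)
            cfg.pirna_model["ping_pong_fraction"] = 1.5
            cfg.validate()

    def test_pld6_te_pirna_collapse(self, tiny_world_seed1):
        world = tiny_world_seed1
        mult = world.config.pirna_model["pld6_te_multiplier"]
        wt = syn.simulate_small_rna(world, "proSG_P0", "WT", seed=11, n_reads=12000)
        ko = syn.simulate_small_rna(world, "proSG_P0", "Pld6KO", seed=12, n_reads=12000)

        def n_te(reads):
            return sum(1 for r in reads if ":te_" in r.name)

        ratio = n_te(ko) / n_te(wt)
        assert ratio == pytest.approx(mult, rel=0.25)

    def test_race_zero_cleavage_warns_and_is_background_only(self):
        cfg = tiny_config(seed=8)
        cfg.expr_model["cleavage_stages"] = []
        world = syn.build_world(cfg)
        with pytest.warns(UserWarning, match="cleavage"):
            reads, report = syn.simulate_race(world, "proSG_P0", "WT", seed=1, n_reads=100)
        assert report["n_te"] == 0

    def test_race_reads_start_at_truth_sites(self, tiny_world):
        reads, report = syn.simulate_race(tiny_world, "proSG_P0", "WT", seed=2, n_reads=3000)
        lib = tiny_world.library.seqs
        sites = tiny_world.truth.cleavage_sites
        ok = 0
        for r in reads:
            parts = r.name.split(":")
            if parts[3] == "bg":
                continue
            fam, site = parts[3], int(parts[4])
            assert ((sites["family"] == fam) & (sites["position"] == site)).any()
            assert r.seq[:20] == lib[fam][site : site + 20] or "N" not in r.seq
            ok += 1
        assert ok == report["n_te"] > 0
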