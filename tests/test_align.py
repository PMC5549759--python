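"""Aligner tests: preprocessing contracts, tie multiplicity, the brute-force
placement oracle, and SAM round trips."""

import numpy as np
import pytest

from retrosilence import align as al
from retrosilence.seqio import FastqRead
from retrosilence.synthetic import revcomp

Q40 = "I"


def _read(seq: str, name: str = "r", qual: str | None = None) -> FastqRead:
    return FastqRead(name, seq, qual or Q40 * len(seq))


# ---------------------------------------------------------------------------
# brute-force oracle: exhaustive contained-placement scan


def _convert(seq: str, rule: str) -> str:
    if rule == "CT":
        return seq.replace("C", "T")
    if rule == "GA":
        return seq.replace("G", "A")
    return seq


def brute_force(read: str, targets: dict[str, str], mode: str, cap: int | None):
    """All co-best ungapped contained placements by exhaustive scan."""
    hits = []
    if mode == "plain":
        variants = [(read, "+", "plain", "plain"), (revcomp(read), "-", "plain", "plain")]
    else:
        variants = [(read, "+", "CT", "CT"), (revcomp(read), "-", "GA", "GA")]
    for q, strand, qrule, trule in variants:
        qc = _convert(q, qrule)
        for name, tgt in targets.items():
            tc = _convert(tgt, trule)
            for s in range(0, len(tgt) - len(q) + 1):
                nm = sum(a != b for a, b in zip(qc, tc[s : s + len(q)]))
                if cap is None or nm <= cap:
                    hits.append((name, s, strand, nm))
    if not hits:
        return []
    best = min(h[3] for h in hits)
    return sorted(h for h in hits if h[3] == best)


def _impl_placements(res: al.AlignmentResult):
    return sorted((r.target, r.start, r.strand, r.nm) for r in res.records)


class TestPreprocess:
    def test_fixed_end_trims(self):
        reads, report = al.preprocess_reads(
            [_read("A" * 100)], al.ReadPrepSpec(trim5=6, trim3=15)
        )
        assert len(reads[0].seq) == 79
        assert report == {"n_in": 1, "n_out": 1, "n_dropped": 0, "n_adaptor_stripped": 0}

    def test_truncation_keeps_first_50(self):
        seq = "ACGT" * 25
        reads, _ = al.preprocess_reads([_read(seq)], al.ReadPrepSpec(truncate_to=50))
        assert reads[0].seq == seq[:50]

    def test_low_quality_read_dropped_and_counted(self):
        reads, report = al.preprocess_reads(
            [_read("ACGTACGTAC", qual="#" * 10)],  # '#' = Q2
            al.ReadPrepSpec(min_quality=30),
        )
        assert reads == [] and report["n_dropped"] == 1

    def test_low_quality_stretch_truncates(self):
        # quality drops for a 3-base run starting at position 6
        qual = Q40 * 6 + "###" + Q40 * 3
        reads, _ = al.preprocess_reads(
            [_read("ACGTACGTACGT"[:12], qual=qual + Q40 * 2)],
            al.ReadPrepSpec(min_quality=30),
        )
        assert len(reads[0].seq) == 6

    def test_adaptor_stripped(self):
        reads, report = al.preprocess_reads(
            [_read("ADAPT" + "ACGTACGTACGT", qual=Q40 * 17)],
            al.ReadPrepSpec(adaptor="ADAPT"),
        )
        assert reads[0].seq == "ACGTACGTACGT"
        assert report["n_adaptor_stripped"] == 1


class TestAlign:
    def test_unique_exact_hit(self):
        rng = np.random.default_rng(0)
        tgt = "".join(rng.choice(list("ACGT"), 500))
        read = tgt[100:130]
        res = al.align_reads([_read(read)], {"t1": tgt}, seed_len=10)
        assert len(res.records) == 1
        rec = res.records[0]
        assert (rec.target, rec.start, rec.strand, rec.nm, rec.k) == ("t1", 100, "+", 0, 1)
        assert rec.score == 30

    def test_shared_substring_ties_k3(self):
        rng = np.random.default_rng(1)
        core = "".join(rng.choice(list("ACGT"), 40))
        targets = {
            f"t{i}": "".join(rng.choice(list("ACGT"), 100)) + core + "".join(rng.choice(list("ACGT"), 100))
            for i in range(3)
        }
        res = al.align_reads([_read(core)], targets, seed_len=10)
        assert len(res.records) == 3
        assert all(r.k == 3 for r in res.records)
        assert {r.target for r in res.records} == set(targets)

    def test_unmapped_read_reported(self):
        res = al.align_reads(
            [_read("A" * 30)], {"t": "CG" * 200}, max_mismatches=2, seed_len=10
        )
        assert res.records == [] and res.unmapped == ["r"]

    def test_negative_mismatch_cap_rejected(self):
        with pytest.raises(ValueError):
            al.align_reads([_read("ACGT" * 10)], {"t": "ACGT" * 30}, max_mismatches=-1)

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            al.SeedIndex({})

    def test_k_equals_number_of_cobest_records(self):
        rng = np.random.default_rng(2)
        targets = {f"t{i}": "".join(rng.choice(list("ACGT"), 300)) for i in range(4)}
        reads = []
        for i in range(30):
            t = rng.choice(list(targets))
            s = int(rng.integers(0, 260))
            seq = targets[t][s : s + 40]
            reads.append(_read(seq if i % 2 else revcomp(seq), name=f"r{i}"))
        res = al.align_reads(reads, targets, max_mismatches=2, seed_len=10)
        by_read: dict[str, list] = {}
        for rec in res.records:
            by_read.setdefault(rec.read_id, []).append(rec)
        for recs in by_read.values():
            assert all(r.k == len(recs) for r in recs)

    @pytest.mark.parametrize("mode", ["plain", "bisulfite"])
    def test_oracle_equivalence_random_instances(self, mode):
        """Implementation equals the exhaustive scan on random small instances."""
        rng = np.random.default_rng(42 if mode == "plain" else 43)
        for trial in range(40):
            targets = {
                f"t{i}": "".join(rng.choice(list("ACGT"), int(rng.integers(80, 400))))
                for i in range(int(rng.integers(1, 4)))
            }
            name = rng.choice(list(targets))
            L = int(rng.integers(36, 51))
            tgt = targets[name]
            s = int(rng.integers(0, len(tgt) - L + 1))
            read = list(tgt[s : s + L])
            for _ in range(int(rng.integers(0, 3))):  # plant up to 2 mutations
                j = int(rng.integers(0, L))
                read[j] = rng.choice([b for b in "ACGT" if b != read[j]])
            read = "".join(read)
            if mode == "bisulfite" and rng.random() < 0.5:
                read = read.replace("C", "T")  # converted read
            if rng.random() < 0.5:
                read = revcomp(read)
            res = al.align_reads([_read(read)], targets, mode=mode, max_mismatches=2, seed_len=12)
            expected = brute_force(read, targets, mode, cap=2)
            assert _impl_placements(res) == expected, f"trial {trial}"


class TestSamRoundTrip:
    def _random_result(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        targets = {f"t{i}": "".join(rng.choice(list("ACGT"), 400)) for i in range(3)}
        reads = [
            _read(targets[f"t{int(rng.integers(0, 3))}"][s : s + 40], name=f"r{i}")
            for i, s in enumerate(rng.integers(0, 360, size=n))
        ]
        return al.align_reads(reads, targets, seed_len=10), targets

    def test_round_trip_preserves_records(self, tmp_path):
        res, targets = self._random_result()
        path = tmp_path / "x.sam"
        al.export_sam(res, {k: len(v) for k, v in targets.items()}, path)
        back = al.import_sam(path)
        orig = sorted((r.read_id, r.target, r.start, r.end, r.strand, r.k) for r in res.records)
        got = sorted((r.read_id, r.target, r.start, r.end, r.strand, r.k) for r in back.records)
        assert orig == got

    def test_k_inferred_from_external_sam(self, tmp_path):
        sam = tmp_path / "ext.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:c1\tLN:100\n"
            "r1\t0\tc1\t1\t255\t10M\t*\t0\t0\tACGTACGTAC\t*\tNM:i:0\n"
            "r1\t0\tc1\t51\t255\t10M\t*\t0\t0\tACGTACGTAC\t*\tNM:i:0\n"
        )
        back = al.import_sam(sam)
        assert [r.k for r in back.records] == [2, 2]

    def test_missing_sq_lines_error(self, tmp_path):
        sam = tmp_path / "bad.sam"
        sam.write_text("@HD\tVN:1.6\nr1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n")
        with pytest.raises(ValueError, match="@SQ"):
            al.import_sam(sam)

    def test_unknown_reference_error(self, tmp_path):
        sam = tmp_path / "bad2.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:c1\tLN:100\n"
            "r1\t0\tcX\t1\t255\t4M\t*\t0\t0\tACGT\t*\n"
        )
        with pytest.raises(ValueError, match="cX"):
            al.import_sam(sam)


def test_bisulfite_mode_agrees_with_plain_on_unmethylated_data(tiny_world):
    """Fully converted reads from an unmethylated genome map at the same loci
    in bisulfite mode as their untreated versions do in plain mode."""
    from retrosilence.synthetic import CHROM

    rng = np.random.default_rng(5)
    genome = tiny_world.genome[CHROM]
    n, L = 300, 80
    starts = rng.integers(0, len(genome) - L, size=n)
    plain_reads, bis_reads = [], []
    for i, s in enumerate(starts):
        seq = genome[s : s + L]
        plain_reads.append(_read(seq, name=f"r{i}"))
        bis_reads.append(_read(seq.replace("C", "T"), name=f"r{i}"))
    ref = {CHROM: genome}
    plain = al.align_reads(plain_reads, ref, mode="plain", max_mismatches=2, seed_len=14)
    bis = al.align_reads(
        bis_reads, al.SeedIndex(ref, seed_len=14, bisulfite=True), mode="bisulfite",
        max_mismatches=2, seed_len=14,
    )
    pos_plain = {r.read_id: r.start for r in plain.records if r.k == 1}
    pos_bis = {r.read_id: r.start for r in bis.records if r.k == 1}
    shared = set(pos_plain) & set(pos_bis)
    agree = sum(pos_plain[r] == pos_bis[r] for r in shared)
    assert len(shared) > 0.9 * n
    assert agree / len(shared) >= 0.99
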