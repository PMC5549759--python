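"""Read preprocessing and a minimal ungapped seed-and-extend aligner.

The aligner stands in for the external short-read mappers at desk scale:
exact k-mer seeding over a sorted-array index, full-length ungapped
extension (match +1 / mismatch -1, no indels), and reporting of *all*
co-best placements with their tie multiplicity k, which drives fractional
multimapper counting downstream.  A bisulfite mode aligns in three-letter
space (C/T collapsed on the converted strand) while retaining the original
read bases for methylation calling.

With a mismatch cap m and at least m+1 non-overlapping seeds on the read,
seeding is exhaustive by pigeonhole: every placement with <= m mismatches
shares at least one exact seed, so the reported optimum equals a brute-force
scan.  Without a cap the default 4 seeds make the search heuristic (akin to
the external tools it replaces).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam

from .seqio import FastqRead

_ENC = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
    _ENC[ord(chr(b).lower())] = i

_COMP_STR = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP_STR)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _bis_ct(enc: np.ndarray) -> np.ndarray:
    out = enc.copy()
    out[out == 1] = 3  # C -> T
    return out


def _bis_ga(enc: np.ndarray) -> np.ndarray:
    out = enc.copy()
    out[out == 2] = 0  # G -> A
    return out


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class ReadPrepSpec:
    """Fixed-end trimming, quality truncation and adaptor handling.

    ``min_quality`` triggers truncation at the first base of the leftmost run
    of >= ``min_quality_run`` consecutive bases below the threshold (the
    conventional reading of removing 3'-ward low-quality stretches).
    """

    trim5: int = 0
    trim3: int = 0
    min_quality: int | None = None
    min_quality_run: int = 3
    truncate_to: int | None = None
    adaptor: str | None = None

    def __post_init__(self) -> None:
        if self.trim5 < 0 or self.trim3 < 0:
            raise ValueError("trims must be non-negative")
        if self.truncate_to is not None and self.truncate_to < 1:
            raise ValueError("truncate_to must be >= 1")


def preprocess_reads(
    reads: Iterable[FastqRead], spec: ReadPrepSpec
) -> tuple[list[FastqRead], dict]:
    """Apply adaptor stripping, fixed trims, quality truncation, truncation.

    Reads trimmed to zero length are dropped and counted in the report.
    """
    out: list[FastqRead] = []
    report = {"n_in": 0, "n_out": 0, "n_dropped": 0, "n_adaptor_stripped": 0}
    for r in reads:
        report["n_in"] += 1
        seq, qual = r.seq, r.qual
        if spec.adaptor and seq.startswith(spec.adaptor):
            seq = seq[len(spec.adaptor):]
            qual = qual[len(spec.adaptor):]
            report["n_adaptor_stripped"] += 1
        end = len(seq) - spec.trim3
        seq, qual = seq[spec.trim5:end], qual[spec.trim5:end]
        if spec.min_quality is not None and seq:
            q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(int) - 33
            low = q < spec.min_quality
            run = spec.min_quality_run
            if len(low) >= run:
                window = np.convolve(low.astype(int), np.ones(run, dtype=int), "valid")
                hits = np.nonzero(window == run)[0]
                if len(hits):
                    cut = int(hits[0])
                    seq, qual = seq[:cut], qual[:cut]
        if spec.truncate_to is not None:
            seq, qual = seq[: spec.truncate_to], qual[: spec.truncate_to]
        if len(seq) == 0:
            report["n_dropped"] += 1
            continue
        out.append(FastqRead(r.name, seq, qual))
        report["n_out"] += 1
    return out, report


# ---------------------------------------------------------------------------
# alignment records


@dataclass(slots=True)
class AlignmentRecord:
    """One placement of a read; k is the number of co-best placements."""

    read_id: str
    target: str
    start: int
    end: int
    strand: str
    score: int
    nm: int
    k: int
    seq: str  # original bases, oriented to the target's forward strand

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("tie multiplicity k must be >= 1")


@dataclass
class AlignmentResult:
    records: list[AlignmentRecord]
    unmapped: list[str]
    n_reads: int
    mode: str
    max_mismatches: int | None

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# index


class SeedIndex:
    """Sorted k-mer array index over a set of target sequences."""

    def __init__(self, targets: dict[str, str], seed_len: int = 12, bisulfite: bool = False):
        if not targets:
            raise ValueError("empty target set")
        self.seed_len = seed_len
        self.bisulfite = bisulfite
        self.names = list(targets)
        lengths = [len(targets[n]) for n in self.names]
        self.lengths = dict(zip(self.names, lengths))
        gap = seed_len
        starts = []
        pos = 0
        parts = []
        for n in self.names:
            starts.append(pos)
            parts.append(_encode(targets[n]))
            pos += self.lengths[n]
            parts.append(np.full(gap, 4, dtype=np.uint8))
            pos += gap
        self.t_starts = np.array(starts, dtype=np.int64)
        self.t_ends = self.t_starts + np.array(lengths, dtype=np.int64)
        self.enc = np.concatenate(parts)
        if bisulfite:
            self.enc_ct = _bis_ct(self.enc)
            self.enc_ga = _bis_ga(self.enc)
            self._tables = {"CT": self._build(self.enc_ct), "GA": self._build(self.enc_ga)}
        else:
            self._tables = {"plain": self._build(self.enc)}

    def _build(self, enc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        k = self.seed_len
        n = len(enc)
        if n < k:
            return np.array([], dtype=np.int32), np.array([], dtype=np.int32)
        m = n - k + 1
        dtype = np.int32 if k <= 15 else np.int64
        codes = np.zeros(m, dtype=dtype)
        for j in range(k):
            codes <<= 2
            np.add(codes, enc[j : m + j], out=codes, casting="unsafe")
        # non-ACGT positions are rare (target separators); mask their windows
        mask = np.ones(m, dtype=bool)
        for b in np.nonzero(enc >= 4)[0]:
            mask[max(0, b - k + 1) : b + 1] = False
        valid = np.nonzero(mask)[0].astype(np.int32)
        codes = codes[valid]
        order = np.argsort(codes)
        return codes[order], valid[order]

    def lookup(self, table: str, code: int) -> np.ndarray:
        codes, positions = self._tables[table]
        # match the stored dtype: a plain int would trigger an O(n) cast
        v = codes.dtype.type(code)
        lo = np.searchsorted(codes, v, side="left")
        hi = np.searchsorted(codes, v, side="right")
        return positions[lo:hi]

    def locate(self, gpos: int) -> int:
        """Index of the target containing a global position."""
        return int(np.searchsorted(self.t_starts, gpos, side="right") - 1)


# ---------------------------------------------------------------------------
# alignment


def _candidates(index: SeedIndex, table: str, q: np.ndarray, n_seeds: int) -> np.ndarray:
    k = index.seed_len
    L = len(q)
    cands = []
    for i in range(n_seeds):
        o = i * k
        if o + k > L:
            break
        seed = q[o : o + k]
        if (seed >= 4).any():
            continue
        code = 0
        for b in seed:
            code = code * 4 + int(b)
        hits = index.lookup(table, code)
        if len(hits):
            cands.append(hits.astype(np.int64) - o)
    if not cands:
        return np.array([], dtype=np.int64)
    return np.unique(np.concatenate(cands))


def _extend(
    enc: np.ndarray,
    index: SeedIndex,
    starts: np.ndarray,
    q: np.ndarray,
    cap: int | None,
) -> list[tuple[int, int]]:
    """(global start, mismatches) for contained placements within one target."""
    L = len(q)
    out = []
    for s in starts:
        s = int(s)
        if s < 0:
            continue
        t = index.locate(s)
        if t < 0 or s < index.t_starts[t] or s + L > index.t_ends[t]:
            continue
        nm = int(np.count_nonzero(enc[s : s + L] != q))
        if cap is None or nm <= cap:
            out.append((s, nm))
    return out


def align_reads(
    reads: Iterable[FastqRead],
    targets: dict[str, str] | SeedIndex,
    mode: str = "plain",
    max_mismatches: int | None = None,
    seed_len: int = 12,
    default_seeds: int = 4,
) -> AlignmentResult:
    """Align reads against the targets, reporting all co-best placements.

    plain mode searches both strands; bisulfite mode searches the two
    bisulfite strand conversions (read C->T against the C->T-converted
    target, and reverse-complemented read G->A against the G->A-converted
    target) and keeps the original bases in each record.
    """
    if mode not in ("plain", "bisulfite"):
        raise ValueError(f"unknown mode {mode!r}")
    if max_mismatches is not None and max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    if isinstance(targets, SeedIndex):
        index = targets
        if index.bisulfite != (mode == "bisulfite"):
            raise ValueError("index was built for a different mode")
    else:
        index = SeedIndex(targets, seed_len=seed_len, bisulfite=(mode == "bisulfite"))

    records: list[AlignmentRecord] = []
    unmapped: list[str] = []
    n_reads = 0
    for r in reads:
        n_reads += 1
        L = len(r.seq)
        if L < index.seed_len:
            unmapped.append(r.name)
            continue
        want = max_mismatches + 1 if max_mismatches is not None else default_seeds
        n_seeds = max(1, min(want, L // index.seed_len))
        hits: list[tuple[int, int, str, str]] = []  # (gstart, nm, strand, oriented seq)
        if mode == "plain":
            variants = [
                (r.seq, "+", _encode(r.seq), index.enc, "plain"),
                (_revcomp(r.seq), "-", _encode(_revcomp(r.seq)), index.enc, "plain"),
            ]
        else:
            rc = _revcomp(r.seq)
            variants = [
                (r.seq, "+", _bis_ct(_encode(r.seq)), index.enc_ct, "CT"),
                (rc, "-", _bis_ga(_encode(rc)), index.enc_ga, "GA"),
            ]
        for oriented, strand, q, enc, table in variants:
            cands = _candidates(index, table, q, n_seeds)
            for s, nm in _extend(enc, index, cands, q, max_mismatches):
                hits.append((s, nm, strand, oriented))
        if not hits:
            unmapped.append(r.name)
            continue
        best_nm = min(h[1] for h in hits)
        best = [h for h in hits if h[1] == best_nm]
        k = len(best)
        for s, nm, strand, oriented in best:
            t = index.locate(s)
            local = s - int(index.t_starts[t])
            records.append(
                AlignmentRecord(
                    read_id=r.name,
                    target=index.names[t],
                    start=local,
                    end=local + L,
                    strand=strand,
                    score=L - 2 * nm,
                    nm=nm,
                    k=k,
                    seq=oriented,
                )
            )
    return AlignmentResult(records, unmapped, n_reads, mode, max_mismatches)


# ---------------------------------------------------------------------------
# SAM interchange


def export_sam(
    result: AlignmentResult | Sequence[AlignmentRecord],
    target_lengths: dict[str, int],
    path: str | os.PathLike,
) -> None:
    """Write records as SAM 1.x; the tie multiplicity travels as NH:i."""
    records = list(result.records if isinstance(result, AlignmentResult) else result)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": int(l)} for n, l in target_lengths.items()],
    }
    tid = {n: i for i, n in enumerate(target_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rec.read_id
            a.query_sequence = rec.seq
            a.flag = 16 if rec.strand == "-" else 0
            a.reference_id = tid[rec.target]
            a.reference_start = rec.start
            a.mapping_quality = 255
            a.cigar = [(0, rec.end - rec.start)]
            a.set_tag("NH", rec.k)
            a.set_tag("NM", rec.nm)
            a.set_tag("AS", rec.score)
            fh.write(a)
        if isinstance(result, AlignmentResult):
            for name in result.unmapped:
                a = pysam.AlignedSegment(fh.header)
                a.query_name = name
                a.flag = 4
                fh.write(a)


def import_sam(path: str | os.PathLike) -> AlignmentResult:
    """Read a SAM file back into alignment records.

    External SAM without the NH tag gets k inferred as the per-read count of
    co-best records (by alignment score, falling back to mismatch count).
    """
    with open(path) as fh:
        text = fh.readlines()
    refs = {
        line.split("\t")[1][3:]
        for line in text
        if line.startswith("@SQ") and "\tSN:" in line
    }
    if not refs:
        raise ValueError(f"{path}: SAM file has no @SQ reference lines")
    for line in text:
        if line.startswith("@"):
            continue
        fields = line.split("\t")
        if len(fields) > 2 and fields[2] not in ("*",) and fields[2] not in refs:
            raise ValueError(f"{path}: unknown reference name {fields[2]!r}")

    raw: list[dict] = []
    unmapped: list[str] = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            if a.is_unmapped:
                unmapped.append(a.query_name)
                continue
            raw.append(
                {
                    "read_id": a.query_name,
                    "target": a.reference_name,
                    "start": a.reference_start,
                    "end": a.reference_end,
                    "strand": "-" if a.is_reverse else "+",
                    "nm": a.get_tag("NM") if a.has_tag("NM") else 0,
                    "score": a.get_tag("AS") if a.has_tag("AS") else None,
                    "k": a.get_tag("NH") if a.has_tag("NH") else None,
                    "seq": a.query_sequence or "",
                }
            )
    # infer k where absent: count of co-best records per read
    by_read: dict[str, list[dict]] = {}
    for rec in raw:
        by_read.setdefault(rec["read_id"], []).append(rec)
    records = []
    for rid, recs in by_read.items():
        if any(r["k"] is None for r in recs):
            scores = [
                r["score"] if r["score"] is not None else -r["nm"] for r in recs
            ]
            best = max(scores)
            co_best = [r for r, s in zip(recs, scores) if s == best]
            for r in co_best:
                r["k"] = len(co_best)
            recs = co_best
        for r in recs:
            if r["score"] is None:
                r["score"] = (r["end"] - r["start"]) - 2 * r["nm"]
            records.append(
                AlignmentRecord(
                    read_id=r["read_id"],
                    target=r["target"],
                    start=r["start"],
                    end=r["end"],
                    strand=r["strand"],
                    score=int(r["score"]),
                    nm=int(r["nm"]),
                    k=int(r["k"]),
                    seq=r["seq"],
                )
            )
    n_reads = len(by_read) + len(unmapped)
    return AlignmentResult(records, unmapped, n_reads, "imported", None)
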