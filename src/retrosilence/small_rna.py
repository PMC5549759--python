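"""piRNA processing: blacklist filtering, 24-33 nt selection, fractional
strand-split RPM on the consensus library, length profiles, and the
piRNA-drop vs RNA-derepression grouped comparison.

The 24-33 nt window selects PIWI-bound small RNAs; known structural RNAs
(rRNA/tRNA/miRNA decoys here) are removed before the length filter so the
filter ledger attributes each removed read to exactly one cause.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentResult, AlignmentRecord
from .seqio import FastqRead


def _matches_blacklist(seq: str, entries: list[str], max_mismatch: int) -> bool:
    for entry in entries:
        if seq in entry:
            return True
        if max_mismatch > 0 and len(seq) <= len(entry):
            q = np.frombuffer(seq.encode(), dtype=np.uint8)
            e = np.frombuffer(entry.encode(), dtype=np.uint8)
            for off in range(len(e) - len(q) + 1):
                if int((e[off : off + len(q)] != q).sum()) <= max_mismatch:
                    return True
    return False


def filter_small_rnas(
    reads: list[FastqRead],
    blacklist: dict[str, str],
    min_len: int = 24,
    max_len: int = 33,
    blacklist_mismatch: int = 0,
) -> tuple[list[FastqRead], dict]:
    """Remove blacklist-matching reads, then keep the 24-33 nt window.

    Blacklist matching (exact substring; optionally one mismatch full-length)
    takes precedence over the length filter in the ledger.  The ledger counts
    plus retained reads sum to the input reads.
    """
    import warnings

    if not blacklist:
        warnings.warn("empty blacklist: only the length filter will apply")
    entries = list(blacklist.values())
    retained: list[FastqRead] = []
    ledger = {"n_in": len(reads), "blacklist": 0, "out_of_range": 0, "retained": 0}
    for r in reads:
        if entries and _matches_blacklist(r.seq, entries, blacklist_mismatch):
            ledger["blacklist"] += 1
        elif not (min_len <= len(r.seq) <= max_len):
            ledger["out_of_range"] += 1
        else:
            retained.append(r)
            ledger["retained"] += 1
    return retained, ledger


def length_histogram(reads: list[FastqRead], lo: int = 18, hi: int = 40) -> pd.Series:
    """Read-length histogram over [lo, hi]; lengths outside are clipped out."""
    lengths = np.array([len(r.seq) for r in reads])
    counts = {L: int((lengths == L).sum()) for L in range(lo, hi + 1)}
    return pd.Series(counts, name="count")


@dataclass
class SmallRNAProfile:
    """Element x strand piRNA abundance (RPM) plus bookkeeping."""

    rpm: pd.DataFrame             # element x {sense, antisense} RPM
    counts: pd.DataFrame          # same shape, fractional read counts
    n_retained: int
    n_mapped: float
    ledger: dict = field(default_factory=dict)
    length_hist: pd.Series | None = None


def pirna_rpm(
    alignments: AlignmentResult | list[AlignmentRecord],
    lengths: dict[str, int],
    n_retained: int,
    denominator: str = "retained",
    ledger: dict | None = None,
    length_hist: pd.Series | None = None,
) -> SmallRNAProfile:
    """Fractional (1/k) piRNA counts per element and strand, as RPM.

    ``denominator`` selects the RPM normalizer: "retained" (per million
    retained reads) or "mapped" (per million library-mapped reads).
    """
    if isinstance(alignments, AlignmentResult):
        if alignments.max_mismatches not in (None, 2):
            import warnings

            warnings.warn(
                f"alignments were produced with max_mismatches="
                f"{alignments.max_mismatches}, not the conventional 2"
            )
        recs = alignments.records
    else:
        recs = alignments
    idx = {name: i for i, name in enumerate(lengths)}
    sense = np.zeros(len(idx))
    anti = np.zeros(len(idx))
    mapped = 0.0
    for rec in recs:
        w = 1.0 / rec.k
        mapped += w
        if rec.strand == "+":
            sense[idx[rec.target]] += w
        else:
            anti[idx[rec.target]] += w
    counts = pd.DataFrame(
        {"sense": sense, "antisense": anti}, index=pd.Index(list(idx), name="element")
    )
    denom = n_retained if denominator == "retained" else mapped
    if denom <= 0:
        raise ValueError("RPM denominator is zero")
    rpm = counts / denom * 1e6
    return SmallRNAProfile(
        rpm=rpm,
        counts=counts,
        n_retained=n_retained,
        n_mapped=mapped,
        ledger=ledger or {},
        length_hist=length_hist,
    )


def mannwhitney_exact(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sample Mann-Whitney U; exact distribution for small samples,
    normal approximation with tie correction for larger ones."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    method = "exact" if (len(x) <= 20 and len(y) <= 20 and _no_ties(x, y)) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def _no_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) == len(pooled)


def drop_vs_derepression(
    profile_wt: SmallRNAProfile,
    profile_ko: SmallRNAProfile,
    rna_fc: pd.DataFrame,
    bin_edges: tuple[float, ...] = (10.0, 100.0, 1000.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group elements by antisense piRNA RPM decrease (WT - KO) and compare
    RNA fold-change distributions between adjacent groups.

    The decrease is an RPM difference, not a ratio, so the default top bin is
    the ">1000 RPM drop" group.  Returns (per-element grouped table with
    per-bin medians/quartiles in attrs, U-test table); comparisons involving
    a bin with < 2 elements report a missing P.
    """
    shared = profile_wt.rpm.index.intersection(profile_ko.rpm.index).intersection(
        rna_fc.index
    )
    if len(shared) == 0:
        raise ValueError("no shared elements between piRNA profiles and RNA table")
    drop = (
        profile_wt.rpm.loc[shared, "antisense"] - profile_ko.rpm.loc[shared, "antisense"]
    )
    edges = [-np.inf, *bin_edges, np.inf]
    labels = [
        f"<={bin_edges[0]:g}",
        *[f"{a:g}-{b:g}" for a, b in zip(bin_edges[:-1], bin_edges[1:])],
        f">{bin_edges[-1]:g}",
    ]
    grouped = pd.DataFrame(
        {
            "antisense_drop": drop,
            "rna_fc": rna_fc.loc[shared, "fold_change"],
            "bin": pd.cut(drop, bins=edges, labels=labels),
        }
    )
    summary = (
        grouped.groupby("bin", observed=False)["rna_fc"]
        .agg(n="count", median="median", q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75))
        .reset_index()
    )
    tests = []
    present = [b for b in labels if (grouped["bin"] == b).any()]
    for a, b in zip(present[:-1], present[1:]):
        xa = grouped.loc[grouped["bin"] == a, "rna_fc"].to_numpy()
        xb = grouped.loc[grouped["bin"] == b, "rna_fc"].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            tests.append({"bin_low": a, "bin_high": b, "U": np.nan, "p_value": np.nan})
            continue
        u, p = mannwhitney_exact(xa, xb)
        tests.append({"bin_low": a, "bin_high": b, "U": u, "p_value": p})
    grouped.attrs["summary"] = summary
    return grouped, pd.DataFrame(tests, columns=["bin_low", "bin_high", "U", "p_value"])
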