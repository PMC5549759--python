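"""Gene differential expression and retrotransposon-to-gene activation
attribution.

An upregulated gene is attributed to a retrotransposon copy when an
*activated* copy (family derepressed on the consensus AND locally
upregulated) lies within a fixed window (default 100 kb, span-to-span,
inclusive) of the gene or inside one of its introns; the intronic-antisense
relation captures the L1 antisense-promoter case where a full-length copy
in an intron drives transcription into downstream exons.  Reads overlapping
annotated repeat copies are excluded from gene exonic counts because their
origin is ambiguous.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .align import AlignmentResult, AlignmentRecord
from .small_rna import mannwhitney_exact
from .te_expression import stabilized_fold_change


def _records(alignments) -> list[AlignmentRecord]:
    return alignments.records if isinstance(alignments, AlignmentResult) else alignments


class _IntervalIndex:
    """Overlap queries against a set of (possibly strand-labelled) intervals."""

    def __init__(self, starts, ends, payload=None, max_len: int | None = None):
        order = np.argsort(starts)
        self.starts = np.asarray(starts)[order]
        self.ends = np.asarray(ends)[order]
        self.payload = (
            [payload[i] for i in order] if payload is not None else list(order)
        )
        self.max_len = (
            int((self.ends - self.starts).max()) if len(self.starts) and max_len is None
            else (max_len or 0)
        )

    def overlapping(self, s: int, e: int) -> list:
        if not len(self.starts):
            return []
        lo = int(np.searchsorted(self.starts, s - self.max_len))
        hi = int(np.searchsorted(self.starts, e))
        out = []
        for i in range(lo, hi):
            if self.ends[i] > s and self.starts[i] < e:
                out.append(self.payload[i])
        return out


def _exon_index(genes: pd.DataFrame, exons: pd.DataFrame) -> _IntervalIndex:
    g = genes.set_index("gene_id")
    payload = [
        (e.gene_id, g.loc[e.gene_id, "strand"]) for e in exons.itertuples()
    ]
    return _IntervalIndex(exons["start"].to_numpy(), exons["end"].to_numpy(), payload)


def _copy_index(copies: pd.DataFrame) -> _IntervalIndex:
    return _IntervalIndex(
        copies["start"].to_numpy(), copies["end"].to_numpy(), list(copies["copy_id"])
    )


def exonic_counts(
    alignments: AlignmentResult | list[AlignmentRecord],
    genes: pd.DataFrame,
    exons: pd.DataFrame,
    copies: pd.DataFrame | None = None,
    strand_matched: bool = True,
) -> tuple[pd.Series, float]:
    """Fractional strand-matched exonic read counts per gene.

    Reads overlapping an annotated repeat copy are excluded when ``copies``
    is given.  Returns (per-gene counts, total mapped reads seen).
    """
    zero_len = genes[
        ~genes["gene_id"].isin(exons["gene_id"])
    ]
    if len(zero_len):
        raise ValueError(
            f"genes without exons (zero exonic length): {zero_len['gene_id'].tolist()}"
        )
    eidx = _exon_index(genes, exons)
    cidx = _copy_index(copies) if copies is not None else None
    counts = {g: 0.0 for g in genes["gene_id"]}
    total = 0.0
    seen: set[str] = set()
    for rec in _records(alignments):
        if rec.read_id not in seen:
            total += 1.0
            seen.add(rec.read_id)
        if cidx is not None and cidx.overlapping(rec.start, rec.end):
            continue
        hits = {
            gid
            for gid, strand in eidx.overlapping(rec.start, rec.end)
            if (not strand_matched) or strand == rec.strand
        }
        for gid in hits:
            counts[gid] += 1.0 / rec.k
    return pd.Series(counts, name="count"), total


def exonic_lengths(genes: pd.DataFrame, exons: pd.DataFrame) -> pd.Series:
    lens = exons.assign(length=lambda d: d["end"] - d["start"]).groupby("gene_id")[
        "length"
    ].sum()
    return lens.reindex(genes["gene_id"]).fillna(0).astype(int)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style) over all-positive rows."""
    pos = counts[(counts > 0).all(axis=1)]
    if len(pos) < 3:
        return pd.Series(1.0, index=counts.columns)
    log_geo = np.log(pos).mean(axis=1)
    sf = np.exp(np.log(pos).sub(log_geo, axis=0).median(axis=0))
    return sf / np.exp(np.log(sf).mean())


def gene_de(
    sample_counts: dict[str, pd.Series],
    lengths: pd.Series,
    totals: dict[str, float],
    design: dict[str, str],
    ko: str,
    wt: str,
    fc_threshold: float = 2.0,
    q_alpha: float = 0.05,
    pseudocount: float = 0.1,
    normalization: str = "median_ratio",
) -> pd.DataFrame:
    """Gene differential expression with BH correction.

    Expression is RPKM over exonic length; the test is a two-sided t test on
    log2(RPKM + pseudocount) across replicates; classes are assigned from the
    stabilized fold change of replicate means (> threshold up, < 1/threshold
    down) gated on the BH q value.

    With ``normalization="median_ratio"`` (default) the library totals are
    rescaled by DESeq-style size factors so that the typical unchanged gene
    anchors the fold changes; global shifts in repeat-derived read mass
    between genotypes then do not masquerade as gene-level change.
    ``normalization="totals"`` uses the raw per-million totals.
    """
    ko_samples = [s for s, c in design.items() if c == ko]
    wt_samples = [s for s, c in design.items() if c == wt]
    if len(ko_samples) < 2 or len(wt_samples) < 2:
        raise ValueError("gene_de requires >= 2 replicates per condition")
    samples = ko_samples + wt_samples
    counts = pd.DataFrame({s: sample_counts[s] for s in samples})
    eff_totals = pd.Series({s: float(totals[s]) for s in samples})
    if normalization == "median_ratio":
        sf = size_factors(counts)
        mean_total = eff_totals.mean()
        eff_totals = sf * mean_total
    elif normalization != "totals":
        raise ValueError(f"unknown normalization {normalization!r}")
    rpkm = pd.DataFrame(
        {
            s: counts[s] / (lengths / 1000.0) / (eff_totals[s] / 1e6)
            for s in samples
        }
    )
    mean_ko = rpkm[ko_samples].mean(axis=1)
    mean_wt = rpkm[wt_samples].mean(axis=1)
    fc = stabilized_fold_change(mean_ko.to_numpy(), mean_wt.to_numpy())
    a = np.log2(rpkm[ko_samples].to_numpy() + pseudocount)
    b = np.log2(rpkm[wt_samples].to_numpy() + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        _t, p = stats.ttest_ind(a, b, axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    _rej, q, _a1, _a2 = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "rpkm_wt": mean_wt,
            "rpkm_ko": mean_ko,
            "fold_change": fc,
            "p_value": p,
            "q_value": q,
        },
        index=rpkm.index.rename("gene_id"),
    )
    out["class"] = "unchanged"
    out.loc[(out["fold_change"] > fc_threshold) & (out["q_value"] < q_alpha), "class"] = "up"
    out.loc[(out["fold_change"] < 1 / fc_threshold) & (out["q_value"] < q_alpha), "class"] = "down"
    return out


# ---------------------------------------------------------------------------
# copy activation and attribution


def copy_counts(
    alignments: AlignmentResult | list[AlignmentRecord],
    copies: pd.DataFrame,
    flank: int = 1000,
    unique_only: bool = True,
) -> pd.DataFrame:
    """Reads overlapping each copy footprint and its flanks.

    By default only uniquely mapped reads (k = 1) are counted: fractional
    shares of multimapping reads would smear a derepressed family's signal
    across all of its copies and make every copy look locally activated.
    """
    cidx = _IntervalIndex(
        copies["start"].to_numpy(), copies["end"].to_numpy(), list(copies.index)
    )
    body = {i: 0.0 for i in copies.index}
    fl = {i: 0.0 for i in copies.index}
    spans = copies[["start", "end"]].to_dict("index")
    total = 0.0
    seen: set[str] = set()
    fidx = _IntervalIndex(
        np.concatenate(
            [copies["start"].to_numpy() - flank, copies["end"].to_numpy()]
        ),
        np.concatenate(
            [copies["start"].to_numpy(), copies["end"].to_numpy() + flank]
        ),
        list(copies.index) + list(copies.index),
    )
    for rec in _records(alignments):
        if rec.read_id not in seen:
            total += 1.0
            seen.add(rec.read_id)
        if unique_only and rec.k > 1:
            continue
        for i in cidx.overlapping(rec.start, rec.end):
            body[i] += 1.0 / rec.k
        for i in fidx.overlapping(rec.start, rec.end):
            fl[i] += 1.0 / rec.k
    out = copies.copy()
    out["count"] = pd.Series(body)
    out["flank_count"] = pd.Series(fl)
    out.attrs["total"] = total
    return out


def copy_activation(
    counts_by_sample: dict[str, pd.DataFrame],
    totals: dict[str, float],
    design: dict[str, str],
    ko: str,
    wt: str,
    family_up: set[str],
    fc_threshold: float = 2.0,
    min_count: float = 5.0,
) -> pd.DataFrame:
    """Flag copies as activated: family consensus-level up AND local FC >= threshold.

    Local coverage fold change is the stabilized FC of mean RPKM-like values
    over the copy footprint; the flanking-coverage FC is recorded as an
    intervening-readthrough evidence flag.  ``min_count`` additionally
    requires a mean of that many (unique) reads over the footprint in the KO,
    so one or two stray reads over an untranscribed copy cannot flag it.
    """
    ko_samples = [s for s, c in design.items() if c == ko]
    wt_samples = [s for s, c in design.items() if c == wt]
    any_df = next(iter(counts_by_sample.values()))
    length_kb = (any_df["end"] - any_df["start"]) / 1000.0

    def _mean_norm(col: str, samples: list[str]) -> pd.Series:
        vals = [
            counts_by_sample[s][col] / length_kb / (totals[s] / 1e6) for s in samples
        ]
        return pd.concat(vals, axis=1).mean(axis=1)

    out = any_df[["copy_id", "family", "start", "end", "strand"]].copy()
    out["fc"] = stabilized_fold_change(
        _mean_norm("count", ko_samples).to_numpy(),
        _mean_norm("count", wt_samples).to_numpy(),
    )
    out["flank_fc"] = stabilized_fold_change(
        _mean_norm("flank_count", ko_samples).to_numpy(),
        _mean_norm("flank_count", wt_samples).to_numpy(),
    )
    out["family_up"] = out["family"].isin(family_up)
    mean_ko_count = pd.concat(
        [counts_by_sample[s]["count"] for s in ko_samples], axis=1
    ).mean(axis=1)
    out["activated"] = (
        out["family_up"] & (out["fc"] >= fc_threshold) & (mean_ko_count >= min_count)
    )
    out["readthrough_evidence"] = out["flank_fc"] >= fc_threshold
    return out


def attribute_genes(
    up_genes: pd.DataFrame,
    activated: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 100_000,
) -> tuple[pd.DataFrame, dict]:
    """Link strongly upregulated genes to nearby activated copies.

    ``up_genes`` is a GeneDE subset (indexed by gene_id, with fold_change);
    ``activated`` is the copy_activation table.  A copy qualifies if it is
    activated and intronic to the gene or within ``window`` bp of the gene
    span (inclusive at exactly ``window``); the nearest qualifying copy is
    recorded.  Returns (attribution records, summary with per-family counts
    and the attributed percentage).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    act = activated[activated["activated"]] if "activated" in activated else activated
    gspan = genes.set_index("gene_id")
    rows = []
    for gid in up_genes.index:
        g = gspan.loc[gid]
        best = None
        for c in act.itertuples():
            if c.start < g["end"] and c.end > g["start"]:
                dist = 0
                relation = (
                    "intronic-sense" if c.strand == g["strand"] else "intronic-antisense"
                )
            else:
                if c.end <= g["start"]:
                    dist = int(g["start"] - c.end)
                    left = True
                else:
                    dist = int(c.start - g["end"])
                    left = False
                if dist > window:
                    continue
                upstream = left if g["strand"] == "+" else not left
                relation = "upstream" if upstream else "downstream"
            if best is None or dist < best["distance"]:
                best = {
                    "gene_id": gid,
                    "copy_id": c.copy_id,
                    "family": c.family,
                    "relation": relation,
                    "distance": dist,
                    "copy_fc": c.fc,
                    "readthrough_evidence": bool(getattr(c, "readthrough_evidence", False)),
                }
        if best is not None:
            best["gene_fc"] = float(up_genes.loc[gid, "fold_change"]) if "fold_change" in up_genes else np.nan
            rows.append(best)
    records = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "copy_id", "family", "relation", "distance",
            "copy_fc", "readthrough_evidence", "gene_fc",
        ],
    )
    per_family = records["family"].value_counts().to_dict() if len(records) else {}
    summary = attribution_summary(per_family, total=len(up_genes))
    return records, summary


def attribution_summary(per_family: dict[str, int], total: int) -> dict:
    """Summarize attribution counts: total up genes, attributed, percentage.

    The percentage is rounded to the nearest integer (the convention used
    when quoting e.g. "13 of 19 (68%)").
    """
    attributed = int(sum(per_family.values()))
    if attributed > total:
        raise ValueError("attributed count exceeds the number of up genes")
    pct = round(100.0 * attributed / total) if total > 0 else float("nan")
    return {
        "total_up": int(total),
        "attributed": attributed,
        "percentage": pct,
        "per_family": dict(sorted(per_family.items(), key=lambda kv: -kv[1])),
    }


def attribution_enrichment(
    attributed: int, up_total: int, background_with_copy: int, background_total: int
) -> float:
    """One-sided (enrichment) Fisher exact P for copy proximity among up genes.

    The 2x2 table is [up genes near an activated copy, up genes without] vs
    [other genes near a copy, other genes without].
    """
    if attributed > up_total:
        raise ValueError("attributed > up_total")
    if background_with_copy > background_total:
        raise ValueError("background_with_copy > background_total")
    other_total = background_total - up_total
    other_with = background_with_copy - attributed
    if other_total < 0 or other_with < 0 or other_with > other_total:
        raise ValueError("inconsistent 2x2 margins")
    table = [[attributed, up_total - attributed], [other_with, other_total - other_with]]
    _odds, p = stats.fisher_exact(table, alternative="greater")
    return float(p)


def neighbor_control(
    attribution: pd.DataFrame,
    de: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 100_000,
) -> dict:
    """Compare fold changes of driven genes vs their <= window neighbors.

    Neighbors are non-driven genes whose span lies within ``window`` bp of a
    driven gene's span.  Reports medians/quartiles and a two-sided U test
    (skipped with a reason when either group has < 2 members)."""
    driven_ids = list(attribution["gene_id"]) if len(attribution) else []
    if not driven_ids:
        return {"n_driven": 0, "n_neighbors": 0, "p_value": None, "note": "no driven genes"}
    gspan = genes.set_index("gene_id")
    neighbors: set[str] = set()
    for gid in driven_ids:
        g = gspan.loc[gid]
        near = genes[
            (genes["start"] <= g["end"] + window)
            & (genes["end"] >= g["start"] - window)
            & (~genes["gene_id"].isin(driven_ids))
        ]
        neighbors.update(near["gene_id"])
    driven_fc = de.loc[[g for g in driven_ids if g in de.index], "fold_change"]
    neigh_fc = de.loc[[g for g in neighbors if g in de.index], "fold_change"]

    def _q(s: pd.Series) -> dict:
        return (
            {"median": float(s.median()), "q1": float(s.quantile(0.25)), "q3": float(s.quantile(0.75))}
            if len(s)
            else {"median": None, "q1": None, "q3": None}
        )

    out = {
        "n_driven": len(driven_fc),
        "n_neighbors": len(neigh_fc),
        "driven": _q(driven_fc),
        "neighbors": _q(neigh_fc),
        "p_value": None,
    }
    if len(driven_fc) >= 2 and len(neigh_fc) >= 2:
        _u, p = mannwhitney_exact(driven_fc.to_numpy(), neigh_fc.to_numpy())
        out["p_value"] = p
    else:
        out["note"] = "too few genes for a U test"
    return out


def gene_antisense_pirna_rpm(
    alignments: AlignmentResult | list[AlignmentRecord],
    genes: pd.DataFrame,
    n_retained: int,
) -> pd.Series:
    """Per-gene RPM of small RNAs mapped antisense to the gene span."""
    gidx = _IntervalIndex(
        genes["start"].to_numpy(),
        genes["end"].to_numpy(),
        list(zip(genes["gene_id"], genes["strand"])),
    )
    counts = {g: 0.0 for g in genes["gene_id"]}
    for rec in _records(alignments):
        for gid, strand in gidx.overlapping(rec.start, rec.end):
            if strand != rec.strand:  # antisense to the gene
                counts[gid] += 1.0 / rec.k
    return pd.Series(counts, name="antisense_rpm") / max(n_retained, 1) * 1e6


def antisense_pirna_grouping(
    de: pd.DataFrame,
    antisense_rpm: pd.Series,
    bin_edges: tuple[float, ...] = (1.0, 10.0, 100.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group genes by antisense piRNA abundance; compare FC between bins.

    The lowest bin includes zero-RPM genes.  Returns (grouped table with a
    per-bin summary in attrs, adjacent-bin U tests).
    """
    shared = de.index.intersection(antisense_rpm.index)
    edges = [-np.inf, *bin_edges, np.inf]
    labels = [
        f"<={bin_edges[0]:g}",
        *[f"{a:g}-{b:g}" for a, b in zip(bin_edges[:-1], bin_edges[1:])],
        f">{bin_edges[-1]:g}",
    ]
    grouped = pd.DataFrame(
        {
            "antisense_rpm": antisense_rpm[shared],
            "fold_change": de.loc[shared, "fold_change"],
            "bin": pd.cut(antisense_rpm[shared], bins=edges, labels=labels),
        }
    )
    summary = (
        grouped.groupby("bin", observed=False)["fold_change"]
        .agg(n="count", median="median")
        .reset_index()
    )
    tests = []
    present = [b for b in labels if (grouped["bin"] == b).any()]
    for a, b in zip(present[:-1], present[1:]):
        xa = grouped.loc[grouped["bin"] == a, "fold_change"].to_numpy()
        xb = grouped.loc[grouped["bin"] == b, "fold_change"].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            tests.append({"bin_low": a, "bin_high": b, "U": np.nan, "p_value": np.nan})
            continue
        u, p = mannwhitney_exact(xa, xb)
        tests.append({"bin_low": a, "bin_high": b, "U": u, "p_value": p})
    grouped.attrs["summary"] = summary
    return grouped, pd.DataFrame(tests, columns=["bin_low", "bin_high", "U", "p_value"])


# ---------------------------------------------------------------------------
# allelic ratios


def allelic_ratio(
    alignments: AlignmentResult | list[AlignmentRecord],
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    exons: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene allele-A/allele-B read counts from strain SNPs.

    Each exonic, strand-matched read overlapping >= 1 SNP is assigned to the
    allele its base(s) match; reads mismatching both alleles or giving
    conflicting assignments across SNPs are discarded and counted.
    """
    eidx = _exon_index(genes, exons)
    pos = snps["pos"].to_numpy()
    order = np.argsort(pos)
    pos = pos[order]
    ref = snps["ref"].to_numpy()[order]
    alt = snps["alt"].to_numpy()[order]
    counts: dict[str, list[float]] = {g: [0.0, 0.0] for g in genes["gene_id"]}
    discarded = {"mismatch": 0, "conflict": 0}
    for rec in _records(alignments):
        lo = np.searchsorted(pos, rec.start)
        hi = np.searchsorted(pos, rec.end)
        if hi == lo:
            continue
        hits = {
            gid
            for gid, strand in eidx.overlapping(rec.start, rec.end)
            if strand == rec.strand
        }
        if not hits:
            continue
        alleles = set()
        bad = False
        for i in range(lo, hi):
            base = rec.seq[pos[i] - rec.start]
            if base == ref[i]:
                alleles.add("A")
            elif base == alt[i]:
                alleles.add("B")
            else:
                bad = True
        if bad:
            discarded["mismatch"] += 1
            continue
        if len(alleles) != 1:
            discarded["conflict"] += 1
            continue
        j = 0 if alleles == {"A"} else 1
        for gid in hits:
            counts[gid][j] += 1.0 / rec.k
    rows = []
    for gid, (a, b) in counts.items():
        total = a + b
        rows.append(
            {
                "gene_id": gid,
                "allele_a": a,
                "allele_b": b,
                "ratio": (a / total) if total > 0 else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["discarded"] = discarded
    return out
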