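"""CpG methylation calling and aggregation from bisulfite alignments.

A methylation level is defined as methylated cytosine calls divided by total
calls at the site(s); the two strands of one CpG are pooled onto the C
position of the dinucleotide.  Non-CpG cytosine calls are tallied separately
per target and give the bisulfite conversion-rate estimate (non-CpG
cytosines are assumed unmethylated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentResult, AlignmentRecord, _encode

_ENC_A, _ENC_C, _ENC_G, _ENC_T = 0, 1, 2, 3


@dataclass
class MethTable:
    """Per-CpG call counts plus per-target non-CpG (conversion) totals."""

    cpg: pd.DataFrame       # target, pos, n_meth, n_unmeth
    non_cpg: pd.DataFrame   # target, n_meth, n_unmeth

    def levels(self) -> pd.DataFrame:
        df = self.cpg.copy()
        total = df["n_meth"] + df["n_unmeth"]
        df["level"] = np.where(total > 0, df["n_meth"] / total.clip(lower=1e-300), np.nan)
        return df

    def conversion_rate(self) -> float:
        """Estimated conversion rate from non-CpG context (1 - apparent level)."""
        m = self.non_cpg["n_meth"].sum()
        u = self.non_cpg["n_unmeth"].sum()
        if m + u == 0:
            raise ValueError("no non-CpG calls available for conversion estimation")
        return float(u / (m + u))


def call_methylation(
    alignments: AlignmentResult | list[AlignmentRecord],
    reference: dict[str, str],
    weight_by_k: bool = True,
) -> MethTable:
    """Tally methylated/unmethylated CpG calls from bisulfite alignments.

    On the original-top strand a read C at a reference CpG-C is a methylated
    call and a read T an unmethylated call; on the original-bottom strand the
    same logic applies at the G of the CpG (read G methylated, read A not),
    pooled onto the C position.  Other read bases are ignored.  Multi-mapped
    records contribute 1/k when ``weight_by_k``.
    """
    if isinstance(alignments, AlignmentResult):
        if alignments.mode not in ("bisulfite", "imported"):
            raise ValueError(
                "call_methylation requires bisulfite-mode alignments "
                f"(got mode={alignments.mode!r})"
            )
        records = alignments.records
    else:
        records = alignments

    ctx: dict[str, dict[str, np.ndarray]] = {}
    acc: dict[str, dict[str, np.ndarray | float]] = {}
    for name, seq in reference.items():
        enc = _encode(seq)
        is_c = enc == _ENC_C
        is_g = enc == _ENC_G
        cpg_c = np.nonzero(is_c[:-1] & is_g[1:])[0]
        cpg_g = cpg_c + 1
        nc_c = np.nonzero(is_c & ~np.isin(np.arange(len(enc)), cpg_c))[0]
        nc_g = np.nonzero(is_g & ~np.isin(np.arange(len(enc)), cpg_g))[0]
        ctx[name] = {"cpg_c": cpg_c, "cpg_g": cpg_g, "nc_c": nc_c, "nc_g": nc_g}
        acc[name] = {
            "meth": np.zeros(len(cpg_c)),
            "unmeth": np.zeros(len(cpg_c)),
            "nc_meth": 0.0,
            "nc_unmeth": 0.0,
        }

    for rec in records:
        if rec.target not in ctx:
            raise KeyError(f"alignment target {rec.target!r} absent from reference")
        c = ctx[rec.target]
        a = acc[rec.target]
        w = 1.0 / rec.k if weight_by_k else 1.0
        q = _encode(rec.seq)
        if rec.strand == "+":
            site_pos, meth_base, unmeth_base = c["cpg_c"], _ENC_C, _ENC_T
            nc_pos = c["nc_c"]
        else:
            site_pos, meth_base, unmeth_base = c["cpg_g"], _ENC_G, _ENC_A
            nc_pos = c["nc_g"]
        lo = np.searchsorted(site_pos, rec.start)
        hi = np.searchsorted(site_pos, rec.end)
        if hi > lo:
            idx = np.arange(lo, hi)
            bases = q[site_pos[idx] - rec.start]
            np.add.at(a["meth"], idx[bases == meth_base], w)
            np.add.at(a["unmeth"], idx[bases == unmeth_base], w)
        lo = np.searchsorted(nc_pos, rec.start)
        hi = np.searchsorted(nc_pos, rec.end)
        if hi > lo:
            bases = q[nc_pos[lo:hi] - rec.start]
            a["nc_meth"] += w * int(np.count_nonzero(bases == meth_base))
            a["nc_unmeth"] += w * int(np.count_nonzero(bases == unmeth_base))

    cpg_rows = []
    nc_rows = []
    for name in reference:
        c, a = ctx[name], acc[name]
        covered = (a["meth"] + a["unmeth"]) > 0
        for i in np.nonzero(covered)[0]:
            cpg_rows.append(
                {
                    "target": name,
                    "pos": int(c["cpg_c"][i]),
                    "n_meth": float(a["meth"][i]),
                    "n_unmeth": float(a["unmeth"][i]),
                }
            )
        nc_rows.append(
            {"target": name, "n_meth": a["nc_meth"], "n_unmeth": a["nc_unmeth"]}
        )
    cpg = pd.DataFrame(cpg_rows, columns=["target", "pos", "n_meth", "n_unmeth"])
    return MethTable(cpg=cpg, non_cpg=pd.DataFrame(nc_rows))


# ---------------------------------------------------------------------------
# aggregation


def aggregate_regions(meth: MethTable, regions: pd.DataFrame) -> pd.DataFrame:
    """Pooled methylation level per region (columns target, start, end, name).

    The region level is pooled mC / (mC + uC) over the region's covered CpG
    sites; regions without calls are flagged missing (level NaN), not zero.
    """
    out = []
    cpg = meth.cpg
    for target, sub in [(t, cpg[cpg["target"] == t]) for t in regions["target"].unique()]:
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos)
        pos = pos[order]
        m = sub["n_meth"].to_numpy()[order]
        u = sub["n_unmeth"].to_numpy()[order]
        cm = np.concatenate([[0.0], np.cumsum(m)])
        cu = np.concatenate([[0.0], np.cumsum(u)])
        for r in regions[regions["target"] == target].itertuples():
            lo = np.searchsorted(pos, r.start)
            hi = np.searchsorted(pos, r.end)
            rm, ru = cm[hi] - cm[lo], cu[hi] - cu[lo]
            total = rm + ru
            out.append(
                {
                    "name": r.name,
                    "target": target,
                    "start": r.start,
                    "end": r.end,
                    "level": (rm / total) if total > 0 else np.nan,
                    "n_meth": rm,
                    "n_unmeth": ru,
                    "n_sites": int(hi - lo),
                    "missing": total == 0,
                }
            )
    return pd.DataFrame(out)


def aggregate_windows(
    meth: MethTable, reference: dict[str, str], window: int = 100_000
) -> pd.DataFrame:
    """Mean CpG methylation and GC fraction in half-open tiling windows."""
    rows = []
    for target, seq in reference.items():
        sub = meth.cpg[meth.cpg["target"] == target]
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos)
        pos, m, u = (
            pos[order],
            sub["n_meth"].to_numpy()[order],
            sub["n_unmeth"].to_numpy()[order],
        )
        enc = _encode(seq)
        is_gc = np.isin(enc, (_ENC_C, _ENC_G))
        cg = np.concatenate([[0], np.cumsum(is_gc)])
        for start in range(0, len(seq), window):
            end = min(start + window, len(seq))
            lo = np.searchsorted(pos, start)
            hi = np.searchsorted(pos, end)
            wm, wu = m[lo:hi].sum(), u[lo:hi].sum()
            total = wm + wu
            rows.append(
                {
                    "target": target,
                    "start": start,
                    "end": end,
                    "level": (wm / total) if total > 0 else np.nan,
                    "gc": (cg[end] - cg[start]) / (end - start),
                    "n_calls": total,
                }
            )
    return pd.DataFrame(rows)


def methylation_gc_correlation(
    windows: pd.DataFrame, baseline: pd.DataFrame | None = None
) -> tuple[float, pd.DataFrame]:
    """Pearson R between per-window methylation and GC fraction.

    With ``baseline`` (e.g. wild type) given, the correlated quantity is the
    per-window methylation DECREASE baseline - windows, so a stronger loss in
    GC-poor windows yields a negative R.  Windows missing a level in either
    input are excluded and counted in the returned table's attrs.
    """
    if baseline is not None:
        merged = windows.merge(
            baseline[["target", "start", "level"]],
            on=["target", "start"],
            suffixes=("", "_baseline"),
        )
        merged["value"] = merged["level_baseline"] - merged["level"]
    else:
        merged = windows.copy()
        merged["value"] = merged["level"]
    n_all = len(merged)
    merged = merged.dropna(subset=["value", "gc"])
    if len(merged) < 3:
        raise ValueError(f"need >= 3 windows with calls, got {len(merged)}")
    r, _p = stats.pearsonr(merged["value"], merged["gc"])
    merged.attrs["n_excluded"] = n_all - len(merged)
    return float(r), merged


def window_correlation(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Pearson R between two window-level methylation vectors."""
    merged = a.merge(b[["target", "start", "level"]], on=["target", "start"], suffixes=("_a", "_b"))
    merged = merged.dropna(subset=["level_a", "level_b"])
    if len(merged) < 3:
        raise ValueError("need >= 3 shared windows with calls")
    r, _ = stats.pearsonr(merged["level_a"], merged["level_b"])
    return float(r)


# ---------------------------------------------------------------------------
# de novo methylation extent and severity (late minus early stage)


def de_novo_extent(late: pd.Series, early: pd.Series) -> tuple[pd.Series, dict]:
    """Per-element late - early methylation delta; negative deltas permitted.

    Elements missing a stage are excluded and reported.
    """
    shared = late.index.intersection(early.index)
    missing = sorted(set(late.index).symmetric_difference(early.index))
    delta = (late[shared] - early[shared]).rename("delta")
    return delta, {"n_excluded": len(missing), "excluded": missing}


def classify_severe(
    delta_wt: pd.Series, delta_ko: pd.Series, threshold: float = 0.3
) -> pd.DataFrame:
    """Label elements whose de novo extent drops by >= threshold in the KO."""
    shared = delta_wt.index.intersection(delta_ko.index)
    df = pd.DataFrame(
        {
            "delta_wt": delta_wt[shared],
            "delta_ko": delta_ko[shared],
        }
    )
    df["difference"] = df["delta_wt"] - df["delta_ko"]
    df["severe"] = df["difference"] >= threshold
    return df


def promoter_regions(
    genes: pd.DataFrame, upstream: int = 1000, downstream: int = 500
) -> pd.DataFrame:
    """Strand-aware promoter windows around each gene's TSS."""
    rows = []
    for g in genes.itertuples():
        if g.strand == "+":
            start, end = g.start - upstream, g.start + downstream
        else:
            start, end = g.end - downstream, g.end + upstream
        rows.append(
            {
                "target": g.chrom,
                "start": max(start, 0),
                "end": end,
                "name": f"{g.gene_id}_promoter",
            }
        )
    return pd.DataFrame(rows)
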