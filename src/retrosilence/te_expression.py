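"""Retrotransposon expression from consensus-mapped stranded RNA-seq.

Multimapping reads are allocated fractionally: a read tied across k co-best
elements contributes 1/k to each.  Expression is RPKM; fold changes use the
stabilized rule — when the wild-type RPKM is below 1, the same quantity
(1 - RPKM_WT) is added to numerator and denominator so the denominator
becomes 1, damping fold changes computed from very low expression values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentResult, AlignmentRecord


def _records(alignments: AlignmentResult | list[AlignmentRecord]) -> list[AlignmentRecord]:
    return alignments.records if isinstance(alignments, AlignmentResult) else alignments


def count_fractional(
    alignments: AlignmentResult | list[AlignmentRecord],
    lengths: dict[str, int],
) -> pd.DataFrame:
    """Fractional (1/k) read counts per element, split by alignment strand.

    Returns a frame indexed by element with columns count_sense,
    count_antisense and length; the total over both strands conserves the
    number of distinct mapped reads.
    """
    recs = _records(alignments)
    idx = {name: i for i, name in enumerate(lengths)}
    sense = np.zeros(len(idx))
    anti = np.zeros(len(idx))
    for rec in recs:
        if rec.k < 1:
            raise ValueError("alignment record lacks tie multiplicity k")
        w = 1.0 / rec.k
        i = idx[rec.target]
        if rec.strand == "+":
            sense[i] += w
        else:
            anti[i] += w
    return pd.DataFrame(
        {
            "count_sense": sense,
            "count_antisense": anti,
            "length": [lengths[n] for n in idx],
        },
        index=pd.Index(list(idx), name="element"),
    )


@dataclass
class ExpressionMatrix:
    """Element x sample fractional counts with lengths and library totals."""

    counts: pd.DataFrame        # elements x samples (sense-strand counts)
    lengths: pd.Series          # element -> bp
    totals: pd.Series           # sample -> total mapped reads used for normalization

    def rpkm(self) -> pd.DataFrame:
        kb = self.lengths.reindex(self.counts.index) / 1000.0
        millions = self.totals.reindex(self.counts.columns) / 1e6
        if (millions <= 0).any():
            bad = millions.index[millions <= 0].tolist()
            raise ValueError(f"zero total mapped reads for samples {bad}")
        return self.counts.div(kb, axis=0).div(millions, axis=1)


def expression_matrix(
    sample_counts: dict[str, pd.DataFrame],
    totals: dict[str, float] | None = None,
    strand: str = "sense",
) -> ExpressionMatrix:
    """Assemble per-sample ``count_fractional`` frames into a matrix.

    By default only sense-strand counts enter expression (stranded
    libraries); totals default to each sample's mapped-read sum over both
    strands.
    """
    col = f"count_{strand}"
    counts = pd.DataFrame({s: df[col] for s, df in sample_counts.items()})
    lengths = next(iter(sample_counts.values()))["length"]
    if totals is None:
        totals = {
            s: float(df["count_sense"].sum() + df["count_antisense"].sum())
            for s, df in sample_counts.items()
        }
    return ExpressionMatrix(counts=counts, lengths=lengths, totals=pd.Series(totals))


def stabilized_fold_change(rpkm_ko, rpkm_wt):
    """KO/WT fold change, stabilized when the denominator is below 1 RPKM.

    For RPKM_WT < 1 the identical quantity (1 - RPKM_WT) is added to both
    numerator and denominator, i.e. FC = RPKM_KO + 1 - RPKM_WT; the rule is
    continuous at RPKM_WT = 1 and keeps FC monotone in RPKM_KO.
    """
    ko = np.asarray(rpkm_ko, dtype=float)
    wt = np.asarray(rpkm_wt, dtype=float)
    if (ko < 0).any() or (wt < 0).any():
        raise ValueError("RPKM values must be non-negative")
    out = np.where(wt >= 1.0, np.divide(ko, np.where(wt >= 1.0, wt, 1.0)), ko + 1.0 - wt)
    if np.isscalar(rpkm_ko) or np.ndim(rpkm_ko) == 0:
        return float(out)
    return out


def differential(
    rpkm: pd.DataFrame,
    design: dict[str, str],
    ko: str,
    wt: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 0.1,
    welch: bool = False,
) -> pd.DataFrame:
    """Replicate-level differential TE expression.

    Fold change is the stabilized FC of replicate-mean RPKMs; the test is a
    two-sided two-sample t test on log2(RPKM + pseudocount) across
    replicates (equal-variance by default).  With fewer than 2 replicates on
    either side P is reported missing.
    """
    ko_samples = [s for s, c in design.items() if c == ko]
    wt_samples = [s for s, c in design.items() if c == wt]
    missing = [s for s in ko_samples + wt_samples if s not in rpkm.columns]
    if missing:
        raise ValueError(f"design names samples absent from the matrix: {missing}")
    mean_ko = rpkm[ko_samples].mean(axis=1)
    mean_wt = rpkm[wt_samples].mean(axis=1)
    fc = stabilized_fold_change(mean_ko.to_numpy(), mean_wt.to_numpy())
    if len(ko_samples) >= 2 and len(wt_samples) >= 2:
        a = np.log2(rpkm[ko_samples].to_numpy() + pseudocount)
        b = np.log2(rpkm[wt_samples].to_numpy() + pseudocount)
        with np.errstate(divide="ignore", invalid="ignore"):
            _t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
        p = np.where(np.isnan(p), 1.0, p)
    else:
        p = np.full(len(rpkm), np.nan)
    out = pd.DataFrame(
        {
            "rpkm_wt": mean_wt,
            "rpkm_ko": mean_ko,
            "fold_change": fc,
            "p_value": p,
        },
        index=rpkm.index,
    )
    out["up"] = out["fold_change"] > fc_threshold
    out["down"] = out["fold_change"] < 1.0 / fc_threshold
    out["significant"] = out["p_value"] < alpha
    return out


def positional_profile(
    ko_alignments: AlignmentResult | list[AlignmentRecord],
    wt_alignments: AlignmentResult | list[AlignmentRecord],
    element: str,
    length: int,
    window: int = 100,
    ko_total: float | None = None,
    wt_total: float | None = None,
) -> pd.DataFrame:
    """Per-window (default 100 bp, non-overlapping) stabilized fold change.

    Sense-strand reads are assigned to windows by alignment start; each
    window count is depth-normalized (per million mapped) before the
    stabilized FC.  A trailing partial window is kept and flagged.
    """
    if length < window:
        raise ValueError("element length must be >= window")

    def _starts(alignments) -> tuple[np.ndarray, float]:
        recs = _records(alignments)
        starts, weights = [], []
        n_total = 0.0
        seen = set()
        for rec in recs:
            n_total += 1.0 / rec.k if rec.read_id not in seen else 0.0
            seen.add(rec.read_id)
            if rec.target == element and rec.strand == "+":
                starts.append(rec.start)
                weights.append(1.0 / rec.k)
        edges = np.arange(0, length + window, window)
        hist = np.zeros(len(edges) - 1)
        if starts:
            idx = np.minimum(np.searchsorted(edges, starts, side="right") - 1, len(hist) - 1)
            np.add.at(hist, idx, weights)
        return hist, n_total

    hist_ko, n_ko = _starts(ko_alignments)
    hist_wt, n_wt = _starts(wt_alignments)
    n_ko = ko_total if ko_total is not None else max(n_ko, 1.0)
    n_wt = wt_total if wt_total is not None else max(n_wt, 1.0)
    norm_ko = hist_ko / n_ko * 1e6
    norm_wt = hist_wt / n_wt * 1e6
    fc = stabilized_fold_change(norm_ko, norm_wt)
    edges = np.arange(0, length + window, window)
    n_windows = len(edges) - 1
    # an element absent from the library would have produced no records at all
    return pd.DataFrame(
        {
            "window_start": edges[:-1],
            "window_end": np.minimum(edges[1:], length),
            "ko": norm_ko,
            "wt": norm_wt,
            "fold_change": fc,
            "partial": [False] * (n_windows - 1) + [edges[-1] > length],
        }
    )


def positional_trend(profile: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation of window fold change with position along the
    element; a strong negative rho indicates 5'-restored (posttranscriptional)
    derepression, while transcriptional derepression gives a flat profile."""
    sub = profile.dropna(subset=["fold_change"])
    rho, p = stats.spearmanr(sub["window_start"], sub["fold_change"])
    return float(rho), float(p)
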