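"""5'-RACE degradome analysis: cleavage-site profiles and the ping-pong
10-nt complementarity signature.

A 5'-RACE read reports the 5'-monophosphate end of a cleaved RNA; its
alignment start on the consensus is one cleavage observation.  A cleaved
sense RNA with 5' end at position p carries the piRNA-guided signature when
an antisense piRNA's 5' end sits at sense coordinate p+9, i.e. the piRNA's
first 10 nt are reverse-complementary to sense positions p..p+9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import AlignmentResult, AlignmentRecord
from .synthetic import revcomp


def _records(alignments) -> list[AlignmentRecord]:
    return alignments.records if isinstance(alignments, AlignmentResult) else alignments


@dataclass
class CleavageProfile:
    """Per-element 5'-end weight by position, with family pool shares."""

    profile: pd.DataFrame        # element, pos, count, rpm  (sense reads)
    antisense: pd.DataFrame      # same columns, tallied separately
    family_share: pd.Series      # family -> fraction of the mapped cleaved pool
    total_mapped: float
    per_family: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def map_cleavage_ends(
    alignments: AlignmentResult | list[AlignmentRecord],
    family_map: dict[str, str] | None = None,
    total_mapped: float | None = None,
) -> CleavageProfile:
    """Tally fractional (1/k) alignment 5' ends as cleavage observations.

    Antisense alignments are tallied separately and never merged into the
    sense profiles.  ``family_map`` maps target names to family labels for
    the pool-share computation (identity by default).  ``total_mapped``
    overrides the share denominator, e.g. with the whole-genome mapped total
    when profiles are built on the consensus only.
    """
    sense: dict[tuple[str, int], float] = {}
    anti: dict[tuple[str, int], float] = {}
    mapped = 0.0
    per_family: dict[str, float] = {}
    for rec in _records(alignments):
        w = 1.0 / rec.k
        mapped += w
        if rec.strand == "+":
            key = (rec.target, rec.start)
            sense[key] = sense.get(key, 0.0) + w
            fam = family_map.get(rec.target, rec.target) if family_map else rec.target
            per_family[fam] = per_family.get(fam, 0.0) + w
        else:
            # a '-' alignment's 5' end is its highest coordinate
            key = (rec.target, rec.end - 1)
            anti[key] = anti.get(key, 0.0) + w
    denom = total_mapped if total_mapped is not None else mapped
    denom = max(denom, 1e-300)

    def _frame(d: dict[tuple[str, int], float]) -> pd.DataFrame:
        rows = [
            {"element": t, "pos": p, "count": c, "rpm": c / denom * 1e6}
            for (t, p), c in sorted(d.items())
        ]
        return pd.DataFrame(rows, columns=["element", "pos", "count", "rpm"])

    fam_counts = pd.Series(per_family, dtype=float).sort_index()
    return CleavageProfile(
        profile=_frame(sense),
        antisense=_frame(anti),
        family_share=fam_counts / denom,
        total_mapped=denom,
        per_family=fam_counts,
    )


@dataclass
class PingPongResult:
    n_evaluated: int
    n_qualifying: int

    @property
    def fraction(self) -> float:
        if self.n_evaluated == 0:
            return float("nan")
        return self.n_qualifying / self.n_evaluated


def pingpong_fraction(
    cleaved: AlignmentResult | list[AlignmentRecord],
    pirna: AlignmentResult | list[AlignmentRecord],
    overlap: int = 10,
    per_site: bool = False,
    strict_sequences: dict[str, str] | None = None,
) -> PingPongResult:
    """Fraction of cleaved sense reads with a 10-nt antisense piRNA partner.

    A sense cleavage read with 5' end at p qualifies iff >= 1 antisense piRNA
    read aligns with its 5' end at sense coordinate p + overlap - 1 on the
    same element.  With ``per_site`` the unit is distinct cleavage sites
    rather than reads.  ``strict_sequences`` (element -> consensus sequence)
    additionally verifies the 10-mer reverse-complement identity.
    """
    if overlap < 1:
        raise ValueError("overlap must be >= 1")
    pirna_5p: dict[str, set[int]] = {}
    pirna_word: dict[tuple[str, int], str] = {}
    for rec in _records(pirna):
        if rec.strand == "-":
            p5 = rec.end - 1
            pirna_5p.setdefault(rec.target, set()).add(p5)
            if strict_sequences is not None and (rec.target, p5) not in pirna_word:
                # the piRNA's own 5'->3' first `overlap` nt
                pirna_word[(rec.target, p5)] = revcomp(rec.seq)[:overlap]
    n_eval = 0
    n_qual = 0
    seen_sites: set[tuple[str, int]] = set()
    for rec in _records(cleaved):
        if rec.strand != "+":
            continue
        if rec.end - rec.start < overlap:
            continue  # too short to evaluate the overlap
        key = (rec.target, rec.start)
        if per_site:
            if key in seen_sites:
                continue
            seen_sites.add(key)
        n_eval += 1
        partner = rec.start + overlap - 1
        ok = partner in pirna_5p.get(rec.target, ())
        if ok and strict_sequences is not None:
            cons = strict_sequences[rec.target]
            sense_word = cons[rec.start : rec.start + overlap]
            ok = pirna_word.get((rec.target, partner)) == revcomp(sense_word)
        if ok:
            n_qual += 1
    return PingPongResult(n_evaluated=n_eval, n_qualifying=n_qual)
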