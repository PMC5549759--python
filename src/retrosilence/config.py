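"""Simulation and run configuration.

The synthetic world emulates four successive male germ-cell stages
(E13.5 primordial germ cells, P0 prospermatogonia, P7 spermatogonia,
P21 leptotene/zygotene spermatocytes) in four genotypes: wild type, a
piRNA-pathway knockout (Pld6), a de novo DNA-methylation knockout (Dnmt3l)
and the double knockout.  The defaults encode the causal structure the
analysis is meant to recover: the piRNA knockout removes posttranscriptional
cleavage (and piRNA-directed methylation of its target families) while the
methylation knockout lifts transcriptional silencing in spermatocytes, with
GC-poor genomic regions losing the most methylation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

STAGES = ("PGC_E13.5", "proSG_P0", "SG_P7", "LZ_P21")
GENOTYPES = ("WT", "Pld6KO", "Dnmt3lKO", "DKO")

#: family names follow the RepeatMasker/RepBase naming style for the mouse
#: retrotransposon families the analysis revolves around
FAMILY_NAMES = ("L1Md_A", "L1Md_T", "IAPEz", "RLTR10", "MMERGLN", "B1")

#: families under piRNA-guided posttranscriptional control
PIRNA_TARGET_FAMILIES = ("L1Md_A", "L1Md_T", "RLTR10")

#: families whose spermatocyte derepression is methylation-dependent
METH_SENSITIVE_FAMILIES = ("L1Md_A", "L1Md_T", "IAPEz", "RLTR10", "MMERGLN")


def _default_meth_model() -> dict[str, Any]:
    """Per-family beta means per stage/genotype plus the genomic background."""
    fam: dict[str, dict[str, dict[str, float]]] = {}
    for f in FAMILY_NAMES:
        fam[f] = {}
        for stage in STAGES:
            if stage == "PGC_E13.5":
                # pre-de novo: everything hypomethylated
                fam[f][stage] = {g: 0.03 for g in GENOTYPES}
                continue
            wt = 0.88 if f.startswith("L1") else 0.85
            d3l = 0.30 if f.startswith("L1") else (0.55 if f != "B1" else 0.62)
            pld6 = 0.45 if f in PIRNA_TARGET_FAMILIES else wt
            fam[f][stage] = {
                "WT": wt,
                "Pld6KO": pld6,
                "Dnmt3lKO": d3l,
                "DKO": min(pld6, d3l),
            }
    background = {}
    for stage in STAGES:
        if stage == "PGC_E13.5":
            background[stage] = {g: {"GC_rich": 0.05, "AT_rich": 0.05} for g in GENOTYPES}
        else:
            background[stage] = {
                "WT": {"GC_rich": 0.74, "AT_rich": 0.76},
                "Pld6KO": {"GC_rich": 0.74, "AT_rich": 0.76},
                # GC-poor (AT-rich) blocks lag hardest without de novo activity
                "Dnmt3lKO": {"GC_rich": 0.55, "AT_rich": 0.30},
                "DKO": {"GC_rich": 0.55, "AT_rich": 0.30},
            }
    return {"family_level": fam, "background_level": background}


def _default_expr_model() -> dict[str, Any]:
    """Transcription rates (arbitrary units) and cleavage parameters."""
    rate: dict[str, dict[str, dict[str, float]]] = {}
    for f in FAMILY_NAMES:
        rate[f] = {}
        for stage in STAGES:
            if stage in ("PGC_E13.5", "proSG_P0", "SG_P7"):
                # perinatal: transcription is genotype-flat (silencing there is
                # posttranscriptional); L1Md_A is the abundantly transcribed family
                base = {
                    "L1Md_A": 30.0,
                    "L1Md_T": 12.0,
                    "IAPEz": 10.0,
                    "RLTR10": 8.0,
                    "MMERGLN": 5.0,
                    "B1": 18.0,
                }[f]
                rate[f][stage] = {g: base for g in GENOTYPES}
            else:  # LZ_P21 spermatocytes: methylation now rules transcription
                wt = {
                    "L1Md_A": 5.0,
                    "L1Md_T": 5.0,
                    "IAPEz": 4.0,
                    "RLTR10": 4.0,
                    "MMERGLN": 3.0,
                    "B1": 10.0,
                }[f]
                up = 6.0 if f in METH_SENSITIVE_FAMILIES else 1.0
                pld6_up = 6.0 if f in PIRNA_TARGET_FAMILIES else 1.0
                rate[f][stage] = {
                    "WT": wt,
                    "Pld6KO": wt * pld6_up,
                    "Dnmt3lKO": wt * up,
                    "DKO": wt * max(up, pld6_up),
                }
    return {
        "family_rate": rate,
        "cleavage_site_rate_per_kb": 2.0,
        "cleavage_efficiency": {"WT": 0.8, "Pld6KO": 0.05, "Dnmt3lKO": 0.85, "DKO": 0.05},
        # piRNA-guided slicing operates in perinatal germ cells; spermatocyte
        # silencing is transcriptional (methylation-dependent)
        "cleavage_stages": ["proSG_P0", "SG_P7"],
        "n_active_copies": 1,
        "gene_base_rate": 8.0,
        "n_direct_response_genes": 10,
        "direct_response_multiplier": 5.0,
        "race_background_rate": 30.0,
    }


def _default_pirna_model() -> dict[str, Any]:
    return {
        "antisense_fraction": 0.7,
        "ping_pong_fraction": 0.5,
        "te_fraction": 0.6,           # fraction of the retained pool that is TE-derived
        "contaminant_fraction": 0.08,  # off-range lengths (18-23 / 34-40 nt)
        "blacklist_fraction": 0.08,    # rRNA/miRNA decoy reads
        "pld6_te_multiplier": 0.05,    # TE-piRNA collapse in the piRNA-pathway KO
        "family_weight": {"L1Md_A": 0.6, "L1Md_T": 0.2, "RLTR10": 0.2},
        "partner_weight": 4.0,         # ping-pong-amplified piRNA species are abundant
    }


def _default_readthrough_model() -> dict[str, Any]:
    return {
        "n_driven_pairs": 5,
        "readthrough_strength": 0.5,   # rate multiplier relative to the family rate
        "min_distance": 5_000,
        "max_distance": 60_000,
        "extension": 1_000,            # run-on past the copy, for flank evidence
        "driven_gene_base_rate": 2.0,  # driven genes are lowly expressed in WT
        "driver_families": ["L1Md_A", "RLTR10"],
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-omics world.

    Identical configurations (including ``seed``) produce byte-identical
    output files.
    """

    seed: int = 0
    n_families: int = 6
    consensus_lengths: tuple[int, int] = (2_000, 3_500)
    n_copies_per_family: int = 8
    copy_divergence: float = 0.03
    genome_length: int = 40_000_000
    n_genes: int = 150
    replicates: int = 2
    grid: list[tuple[str, str]] = field(
        default_factory=lambda: [(s, g) for s in STAGES for g in GENOTYPES]
    )
    meth_model: dict[str, Any] = field(default_factory=_default_meth_model)
    expr_model: dict[str, Any] = field(default_factory=_default_expr_model)
    pirna_model: dict[str, Any] = field(default_factory=_default_pirna_model)
    readthrough_model: dict[str, Any] = field(default_factory=_default_readthrough_model)
    library_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "rnaseq": 60_000,
            "wgbs_depth": 5,       # mean genome coverage, not a read count
            "small_rna": 30_000,
            "race": 12_000,
        }
    )
    read_lengths: dict[str, int] = field(
        default_factory=lambda: {"rnaseq": 50, "wgbs": 100, "race": 50}
    )
    conversion_rate: float = 0.992
    error_rate: float = 0.001
    snp_rate: float = 0.001       # strain SNPs per bp
    block_size: int = 100_000     # AT-rich / GC-rich alternation period
    gc_rich: float = 0.52
    gc_poor: float = 0.34
    cpg_density: dict[str, float] = field(
        default_factory=lambda: {
            "five_end": 1 / 12,   # CpG-island-like L1 5' region
            "body": 1 / 60,
            "GC_rich": 1 / 40,
            "AT_rich": 1 / 120,
        }
    )
    five_end_length: int = 600    # length of the CpG-rich 5' sub-region

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, p in [
            ("copy_divergence", self.copy_divergence),
            ("conversion_rate", self.conversion_rate),
            ("error_rate", self.error_rate),
            ("snp_rate", self.snp_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        pp = self.pirna_model.get("ping_pong_fraction", 0.5)
        if not 0.0 <= pp <= 1.0:
            raise ValueError(f"ping_pong_fraction must be in [0, 1], got {pp}")
        for name, c in [
            ("n_families", self.n_families),
            ("n_copies_per_family", self.n_copies_per_family),
            ("genome_length", self.genome_length),
            ("n_genes", self.n_genes),
            ("replicates", self.replicates),
        ]:
            if c < 1:
                raise ValueError(f"{name} must be >= 1, got {c}")
        if self.n_families > len(FAMILY_NAMES):
            raise ValueError(
                f"n_families <= {len(FAMILY_NAMES)} supported, got {self.n_families}"
            )
        for stage, genotype in self.grid:
            if stage not in STAGES or genotype not in GENOTYPES:
                raise ValueError(f"unknown stage/genotype ({stage}, {genotype})")

    @property
    def families(self) -> tuple[str, ...]:
        return FAMILY_NAMES[: self.n_families]

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["consensus_lengths"] = list(self.consensus_lengths)
        d["grid"] = [list(x) for x in self.grid]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        if "consensus_lengths" in d:
            d["consensus_lengths"] = tuple(d["consensus_lengths"])
        if "grid" in d:
            d["grid"] = [tuple(x) for x in d["grid"]]
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def small_test_config(seed: int = 0, **overrides: Any) -> SimConfig:
    """A desk-scale configuration for fast tests (2 Mb genome, fewer genes)."""
    kw: dict[str, Any] = dict(
        seed=seed,
        genome_length=2_000_000,
        n_genes=20,
        n_copies_per_family=5,
        library_sizes={"rnaseq": 20_000, "wgbs_depth": 5, "small_rna": 15_000, "race": 8_000},
    )
    kw.update(overrides)
    return SimConfig(**kw)
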