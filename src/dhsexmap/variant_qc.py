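"""SNP quality filters for the low-coverage DH panel.

Each rule uses the strict inequality exactly as stated: a site is removed
when its average read depth across the population is < 1, it is an indel,
it shows > 2 alleles, it has < 5 non-reference reads across the panel, its
site genotype-quality score is < 900, more than 4 individuals are called
heterozygous, or its combined read depth falls below 120 or above 500.
Boundary values (depth 120/500, quality 900, 4 het calls) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InputError

# genotype codes shared across the package
GT_MISSING = -1
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2


@dataclass
class SnpRecord:
    """One biallelic site with per-individual genotype and depth calls.

    ``genotypes`` uses codes -1 missing / 0 hom-ref / 1 het / 2 hom-alt;
    ``qual`` is the site-level genotype-quality score.  Depth summaries are
    derived properties so the invariant combined == sum(per-individual)
    holds by construction.
    """

    contig: str
    pos: int                 # 1-based, VCF convention
    ref: str
    alt: str
    n_alleles: int
    genotypes: np.ndarray
    depths: np.ndarray
    qual: float
    is_indel: bool = False

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        if self.genotypes.shape != self.depths.shape:
            raise InputError(
                f"{self.contig}:{self.pos}: genotype and depth vectors differ in length")

    @property
    def panel_size(self) -> int:
        return int(self.genotypes.size)

    @property
    def combined_depth(self) -> int:
        return int(self.depths.sum())

    @property
    def avg_depth(self) -> float:
        return self.combined_depth / self.panel_size

    @property
    def n_het(self) -> int:
        """Heterozygous calls: any call with two distinct alleles."""
        return int((self.genotypes == GT_HET).sum())

    @property
    def nonref_reads(self) -> float:
        """Non-reference reads across the panel, apportioning het-call
        depth half to each allele."""
        frac = np.zeros(self.panel_size)
        frac[self.genotypes == GT_HET] = 0.5
        frac[self.genotypes == GT_HOM_ALT] = 1.0
        return float((self.depths * frac).sum())


@dataclass(frozen=True)
class FilterThresholds:
    min_avg_depth: float = 1.0
    max_alleles: int = 2
    exclude_indels: bool = True
    min_nonref_reads: float = 5.0
    min_gq: float = 900.0
    max_het_calls: int = 4
    min_combined_depth: int = 120
    max_combined_depth: int = 500

    def validate(self) -> None:
        for name in ("min_avg_depth", "max_alleles", "min_nonref_reads",
                     "min_gq", "max_het_calls", "min_combined_depth",
                     "max_combined_depth"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.min_combined_depth > self.max_combined_depth:
            raise ConfigError("min_combined_depth must not exceed max_combined_depth")


# rule names in reporting order
FILTER_RULES = (
    "low_avg_depth", "indel", "multiallelic", "few_nonref_reads",
    "low_site_quality", "excess_het", "low_combined_depth", "high_combined_depth",
)


def violated_rules(rec: SnpRecord, th: FilterThresholds) -> list[str]:
    """All filter rules a record violates (empty list = retained)."""
    rules = []
    if rec.avg_depth < th.min_avg_depth:
        rules.append("low_avg_depth")
    if th.exclude_indels and rec.is_indel:
        rules.append("indel")
    if rec.n_alleles > th.max_alleles:
        rules.append("multiallelic")
    if rec.nonref_reads < th.min_nonref_reads:
        rules.append("few_nonref_reads")
    if rec.qual < th.min_gq:
        rules.append("low_site_quality")
    if rec.n_het > th.max_het_calls:
        rules.append("excess_het")
    if rec.combined_depth < th.min_combined_depth:
        rules.append("low_combined_depth")
    if rec.combined_depth > th.max_combined_depth:
        rules.append("high_combined_depth")
    return rules


@dataclass
class FilterResult:
    retained: list[SnpRecord]
    removed: list[SnpRecord]
    tally: dict[str, int] = field(default_factory=dict)
    unique_removed: int = 0

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.removed)


def filter_snps(records: list[SnpRecord],
                thresholds: FilterThresholds | None = None) -> FilterResult:
    """Partition records into retained and removed sets.

    A record is removed iff it violates at least one rule; the tally
    attributes each removed record to every rule it violates, and
    ``unique_removed`` counts removed records once each.
    """
    th = thresholds or FilterThresholds()
    th.validate()
    panel_sizes = {r.panel_size for r in records}
    if len(panel_sizes) > 1:
        raise InputError(f"inconsistent panel sizes across records: {sorted(panel_sizes)}")
    tally = {rule: 0 for rule in FILTER_RULES}
    retained, removed = [], []
    for rec in records:
        rules = violated_rules(rec, th)
        if rules:
            removed.append(rec)
            for rule in rules:
                tally[rule] += 1
        else:
            retained.append(rec)
    return FilterResult(retained=retained, removed=removed, tally=tally,
                        unique_removed=len(removed))
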