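"""Synthetic doubled-haploid panel generator.

Emulates the mapping design the pipeline assumes: a population of fully
homozygous doubled-haploid (DH) progeny, each derived from a single gamete
of one XY male parent, genotyped by low-coverage resequencing alongside the
parent and its two DH grandparents.  One chromosome carries a hemizygous,
non-recombining Y region: DH progeny that inherit it are YY supermales,
progeny that do not are XX females, and its contigs show presence/absence
read-depth segregation instead of SNPs.

Crossovers follow a no-interference (Poisson) model with mean count equal
to map length / 100 cM and uniform placement; breakpoints falling inside
the Y region are redrawn, enforcing suppressed recombination.  Read depth
is Poisson per site around a per-individual mean; genotype calls are
perturbed by a symmetric miscall model and by random missingness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, InputError
from .variant_qc import SnpRecord

# genotype codes (ref-based, as read from a VCF GT field)
GT_MISSING = -1
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2

# phase codes (grandparent origin)
PH_MISSING = -1
PH_A = 0
PH_B = 1
PH_HET = 2

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class YRegion:
    """The planted hemizygous, non-recombining region.

    ``start_cM``/``end_cM`` delimit the interval on chromosome ``chrom``
    (0-based index) inside which crossovers are suppressed.  ``gene_ids``
    and ``hemizygous`` describe the gene content: hemizygous genes exist
    only on the Y haplotype (zero copies in XX individuals), the remaining
    genes are shared with the X.
    """

    chrom: int = 0
    start_cM: float = 45.0
    end_cM: float = 55.0
    gene_ids: tuple[str, ...] = (
        "SOFF", "Y02", "Y03", "Y04", "Y05", "Y06", "aspTDF1",
        "Y08", "Y09", "Y10", "Y11", "Y12", "Y13",
    )
    hemizygous: tuple[bool, ...] = (True,) * 12 + (False,)


@dataclass(frozen=True)
class PanelConfig:
    """Study-design parameters for the synthetic DH panel.

    Defaults mirror the mapping population: 74 DH progeny (35 XX females,
    39 YY supermales) from one XY male, ten 100-cM chromosomes, ~x3.5
    sequencing depth for the panel and x10 for mutants.
    """

    n_progeny: int = 74
    n_female: int = 35
    n_male: int = 39
    n_chromosomes: int = 10
    chrom_length_cM: float = 100.0
    chrom_length_bp: int = 132_400_000
    contigs_per_chrom: int = 30
    snps_per_contig: int = 20
    mean_depth_progeny: float = 3.5
    mean_depth_mutant: float = 10.0
    genotype_error_rate: float = 0.01
    missing_rate: float = 0.05
    contamination_rate: float = 0.0
    depth_spread: float = 0.15          # lognormal sigma of per-individual mean depth
    gene_sites: int = 30                # sites averaged for per-gene depth
    cds_length: int = 300
    y_region: YRegion = field(default_factory=YRegion)
    seed: int = 0

    def validate(self) -> None:
        if self.n_progeny <= 0:
            raise ConfigError("n_progeny must be positive")
        if self.n_female + self.n_male != self.n_progeny:
            raise ConfigError("n_female + n_male must equal n_progeny")
        if self.n_chromosomes <= 0:
            raise ConfigError("n_chromosomes must be positive")
        if self.chrom_length_cM <= 0:
            raise ConfigError("chrom_length_cM must be positive")
        if self.contigs_per_chrom <= 0:
            raise ConfigError("contigs_per_chrom must be positive")
        if self.snps_per_contig <= 0:
            raise ConfigError("snps_per_contig must be positive")
        for name in ("genotype_error_rate", "missing_rate", "contamination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        yr = self.y_region
        if not 0 <= yr.chrom < self.n_chromosomes:
            raise ConfigError("y_region.chrom must index an existing chromosome")
        if not 0.0 <= yr.start_cM < yr.end_cM <= self.chrom_length_cM:
            raise ConfigError("y_region interval must lie within its chromosome")
        if len(yr.gene_ids) != len(yr.hemizygous):
            raise ConfigError("y_region gene_ids and hemizygous flags differ in length")
        if len(set(yr.gene_ids)) != len(yr.gene_ids):
            raise ConfigError("y_region gene_ids must be unique")
        if self.cds_length % 3 != 0 or self.cds_length < 6:
            raise ConfigError("cds_length must be a positive multiple of 3")


@dataclass
class ContigInfo:
    contig: str
    chrom: int
    cM: float
    start_bp: int
    end_bp: int
    hemizygous: bool
    anchored: bool = True


@dataclass
class GameteTruth:
    """One gamete along one chromosome: starting grandparent origin plus
    crossover breakpoints in cM.  Origin at position x flips at each
    breakpoint below x."""

    start_origin: int
    breakpoints: list[float]

    def origin_at(self, pos_cM: float) -> int:
        flips = sum(1 for b in self.breakpoints if b <= pos_cM)
        return (self.start_origin + flips) % 2


@dataclass
class TruthSet:
    """Simulation ground truth used by recovery tests."""

    sample_names: list[str]
    progeny_names: list[str]
    sex: dict[str, str]                       # progeny -> "XX" | "YY"
    y_present: dict[str, bool]
    gametes: dict[str, list[GameteTruth]]     # progeny -> per-chromosome
    contigs: list[ContigInfo]
    genes: "pd.DataFrame"                     # gene_id, chrom, start_bp, end_bp, hemizygous
    cds: dict[str, str]                       # gene_id -> CDS sequence
    config: PanelConfig

    def phase_at(self, progeny: str, chrom: int, pos_cM: float) -> int:
        return self.gametes[progeny][chrom].origin_at(pos_cM)

    def region_contigs(self) -> list[str]:
        yr = self.config.y_region
        return [c.contig for c in self.contigs
                if c.chrom == yr.chrom and yr.start_cM <= c.cM <= yr.end_cM]


# deferred import: pandas used for the depth tables
import pandas as pd  # noqa: E402

from .hemizygosity import DepthProfile  # noqa: E402


def simulate_crossovers(chrom_length_cM: float, y_region: tuple[float, float] | None,
                        rng: np.random.Generator) -> list[float]:
    """Draw crossover breakpoints for one gamete on one chromosome.

    Count ~ Poisson(length/100), placement uniform; any breakpoint inside
    ``y_region`` (a (start, end) cM interval, or None) is redrawn, which
    leaves placement uniform over the complement of the interval.
    """
    if chrom_length_cM <= 0:
        raise ConfigError("chrom_length_cM must be positive")
    n = rng.poisson(chrom_length_cM / 100.0)
    points: list[float] = []
    for _ in range(n):
        while True:
            x = rng.uniform(0.0, chrom_length_cM)
            if y_region is None or not (y_region[0] <= x <= y_region[1]):
                points.append(x)
                break
            # region spanning the whole chromosome: no valid placement exists
            if y_region[0] <= 0.0 and y_region[1] >= chrom_length_cM:
                break
    return sorted(points)


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + random non-stop codons + TAA."""
    codons = ["ATG"]
    bases = "ACGT"
    for _ in range(length // 3 - 2):
        while True:
            c = "".join(bases[i] for i in rng.integers(0, 4, size=3))
            if c not in STOP_CODONS:
                break
        codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _layout(config: PanelConfig) -> tuple[list[ContigInfo], pd.DataFrame]:
    """Place contigs evenly along each chromosome; mark Y-region contigs
    hemizygous; lay the 13 region genes across the Y-region bp span."""
    contigs: list[ContigInfo] = []
    yr = config.y_region
    bp_per_cM = config.chrom_length_bp / config.chrom_length_cM
    for c in range(config.n_chromosomes):
        for j in range(config.contigs_per_chrom):
            cm = (j + 0.5) * config.chrom_length_cM / config.contigs_per_chrom
            width_bp = int(config.chrom_length_bp / config.contigs_per_chrom)
            start = j * width_bp
            hemi = c == yr.chrom and yr.start_cM <= cm <= yr.end_cM
            contigs.append(ContigInfo(
                contig=f"ctg{c + 1:02d}_{j + 1:03d}", chrom=c, cM=cm,
                start_bp=start, end_bp=start + width_bp, hemizygous=hemi))
    region_start = int(yr.start_cM * bp_per_cM)
    region_end = int(yr.end_cM * bp_per_cM)
    n_genes = len(yr.gene_ids)
    span = region_end - region_start
    rows = []
    for k, (gid, hemi) in enumerate(zip(yr.gene_ids, yr.hemizygous)):
        gstart = region_start + int((k + 0.25) * span / n_genes)
        gend = region_start + int((k + 0.75) * span / n_genes)
        rows.append({"gene_id": gid, "chrom": yr.chrom, "start_bp": gstart,
                     "end_bp": gend, "hemizygous": hemi})
    return contigs, pd.DataFrame(rows)


def _observe_genotypes(true_gt: np.ndarray, depth: np.ndarray,
                       error: float, missing: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Apply the observation model to a (sites x samples) true-genotype
    matrix: zero-depth or randomly dropped calls become missing; miscalls
    go half to a heterozygous call, half to the opposite homozygote (for a
    true het, to either homozygote)."""
    obs = true_gt.astype(np.int8).copy()
    u = rng.random(obs.shape)
    miscall = u < error
    flavour = rng.random(obs.shape) < 0.5
    hom = (obs == GT_HOM_REF) | (obs == GT_HOM_ALT)
    obs[miscall & hom & flavour] = GT_HET
    wrong = miscall & hom & ~flavour
    obs[wrong] = 2 - true_gt[wrong]
    het = true_gt == GT_HET
    obs[miscall & het] = np.where(flavour[miscall & het], GT_HOM_REF, GT_HOM_ALT)
    obs[depth == 0] = GT_MISSING
    obs[rng.random(obs.shape) < missing] = GT_MISSING
    return obs


def _contig_depth(copy: np.ndarray, means: np.ndarray, n_sites: int,
                  contamination: float, rng: np.random.Generator) -> np.ndarray:
    """Average per-base depth over a contig/gene: mean of ``n_sites``
    per-site Poisson draws with rate mean * copy/2 (+ contamination)."""
    lam = means * (copy / 2.0) + contamination * means
    total = rng.poisson(np.maximum(lam, 0.0) * n_sites)
    return total / n_sites


def simulate_panel(config: PanelConfig) -> tuple[TruthSet, list[SnpRecord], DepthProfile]:
    """Simulate the full resequenced panel.

    Returns the ground truth, the SNP call set over all 77 sequenced
    samples (progeny, XY parent, two DH grandparents), and the contig- and
    gene-level depth profile.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_progeny
    progeny = [f"DH{i + 1:03d}" for i in range(n)]
    parent, gp_a, gp_b = "XY_parent", "GP_female", "GP_male"
    samples = progeny + [parent, gp_a, gp_b]

    # --- sexes: fixed counts, random assignment -------------------------
    sex_vec = np.array(["XX"] * config.n_female + ["YY"] * config.n_male)
    rng.shuffle(sex_vec)
    sex = {p: s for p, s in zip(progeny, sex_vec)}

    # --- meiosis: one gamete per progeny per chromosome ------------------
    yr = config.y_region
    mid = 0.5 * (yr.start_cM + yr.end_cM)
    gametes: dict[str, list[GameteTruth]] = {}
    for p in progeny:
        per_chrom: list[GameteTruth] = []
        for c in range(config.n_chromosomes):
            region = (yr.start_cM, yr.end_cM) if c == yr.chrom else None
            bps = simulate_crossovers(config.chrom_length_cM, region, rng)
            if c == yr.chrom:
                # Y rides on grandparental haplotype B; anchor the origin at
                # the region so the assigned sex is realised exactly
                want = PH_B if sex[p] == "YY" else PH_A
                flips = sum(1 for b in bps if b <= mid)
                start = (want + flips) % 2
            else:
                start = int(rng.integers(0, 2))
            per_chrom.append(GameteTruth(start_origin=start, breakpoints=bps))
        gametes[p] = per_chrom

    contigs, genes = _layout(config)

    # --- per-sample mean depths ------------------------------------------
    means = config.mean_depth_progeny * rng.lognormal(0.0, config.depth_spread, size=len(samples))

    # --- SNP records ------------------------------------------------------
    records: list[SnpRecord] = []
    bases = "ACGT"
    n_samples = len(samples)
    for ci in contigs:
        if ci.hemizygous:
            continue  # Y-specific sequence carries no segregating SNPs
        origin = np.array([gametes[p][ci.chrom].origin_at(ci.cM) for p in progeny],
                          dtype=np.int8)
        m = config.snps_per_contig
        # allele carried by haplotype A is ref or alt per site
        a_is_ref = rng.random(m) < 0.5
        # progeny genotype: A-origin gamete is hom for the A allele
        base = np.where(origin == PH_A, GT_HOM_REF, GT_HOM_ALT).astype(np.int8)
        true_gt = np.empty((m, n_samples), dtype=np.int8)
        true_gt[:, :n] = np.where(a_is_ref[:, None], base[None, :], 2 - base[None, :])
        true_gt[:, n] = GT_HET
        true_gt[:, n + 1] = np.where(a_is_ref, GT_HOM_REF, GT_HOM_ALT)
        true_gt[:, n + 2] = np.where(a_is_ref, GT_HOM_ALT, GT_HOM_REF)
        depth = rng.poisson(means, size=(m, n_samples)).astype(np.int32)
        obs = _observe_genotypes(true_gt, depth,
                                 config.genotype_error_rate, config.missing_rate, rng)
        qual = np.round(rng.normal(1500.0, 200.0, size=m)).clip(min=0.0)
        low = rng.random(m) < 0.005
        qual[low] = np.round(rng.uniform(0.0, 900.0, size=low.sum()))
        while True:  # duplicate draws are vanishingly rare at contig scale
            positions = np.sort(rng.integers(ci.start_bp + 1, ci.end_bp, size=m))
            if np.unique(positions).size == m:
                break
        ref_i = rng.integers(0, 4, size=m)
        alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
        for k in range(m):
            records.append(SnpRecord(
                contig=ci.contig, pos=int(positions[k]),
                ref=bases[ref_i[k]], alt=bases[alt_i[k]], n_alleles=2,
                genotypes=obs[k].copy(), depths=depth[k].copy(),
                qual=float(qual[k]), is_indel=False))

    # --- depth profile ----------------------------------------------------
    y_copy_sample = np.empty(n_samples)
    for i, p in enumerate(progeny):
        y_copy_sample[i] = 2.0 if sex[p] == "YY" else 0.0
    y_copy_sample[n] = 1.0      # XY parent
    y_copy_sample[n + 1] = 0.0  # XX grandmother
    y_copy_sample[n + 2] = 2.0  # YY grandfather

    depth_rows = {}
    for ci in contigs:
        copy = y_copy_sample if ci.hemizygous else np.full(n_samples, 2.0)
        depth_rows[ci.contig] = _contig_depth(
            copy, means, config.snps_per_contig, config.contamination_rate, rng)
    depth_df = pd.DataFrame.from_dict(depth_rows, orient="index", columns=samples)

    gene_rows = {}
    for _, g in genes.iterrows():
        copy = y_copy_sample if g["hemizygous"] else np.full(n_samples, 2.0)
        gene_rows[g["gene_id"]] = _contig_depth(
            copy, means, config.gene_sites, config.contamination_rate, rng)
    gene_df = pd.DataFrame.from_dict(gene_rows, orient="index", columns=samples)

    cds = {g: _random_cds(rng, config.cds_length) for g in yr.gene_ids}

    truth = TruthSet(sample_names=samples, progeny_names=progeny, sex=sex,
                     y_present={p: sex[p] == "YY" for p in progeny},
                     gametes=gametes, contigs=contigs, genes=genes, cds=cds,
                     config=config)
    profile = DepthProfile(depth=depth_df, gene_depth=gene_df)
    return truth, records, profile


def simulate_mutant(truth: TruthSet, deletion: str | Sequence[str] | None,
                    config: PanelConfig | None = None, seed: int = 0,
                    sample_id: str = "mutant",
                    cds_deletion: tuple[str, int] | None = None,
                    ) -> tuple[DepthProfile, dict[str, str] | None]:
    """Resequence one gamma-irradiation-style XY mutant at mutant depth.

    ``deletion`` is ``"full_region"``, a list of region gene ids, or None
    (unmutated control).  The XY background carries one copy of every
    hemizygous region gene; deleted genes drop to zero copies.  With
    ``cds_deletion=(gene_id, pos)`` the returned CDS set carries a 1-bp
    deletion at that 1-based coordinate of the gene's coding sequence.
    """
    config = config or truth.config
    rng = np.random.default_rng(seed)
    gene_ids = list(truth.genes["gene_id"])
    if deletion == "full_region":
        deleted = set(gene_ids)
    elif deletion is None:
        deleted = set()
    else:
        deleted = set(deletion)
        unknown = deleted - set(gene_ids)
        if unknown:
            raise InputError(f"unknown gene id(s) in deletion: {sorted(unknown)}")

    mean = config.mean_depth_mutant * rng.lognormal(0.0, config.depth_spread)
    means = np.array([mean])

    rows = {}
    for _, g in truth.genes.iterrows():
        gid = g["gene_id"]
        if gid in deleted:
            copy = np.array([0.0])
        elif g["hemizygous"]:
            copy = np.array([1.0])  # single Y copy in an XY plant
        else:
            copy = np.array([2.0])
        rows[gid] = _contig_depth(copy, means, config.gene_sites,
                                  config.contamination_rate, rng)
    gene_df = pd.DataFrame.from_dict(rows, orient="index", columns=[sample_id])

    contig_rows = {}
    for ci in truth.contigs:
        if ci.hemizygous:
            copy = np.array([0.0 if deleted >= set(gene_ids) else 1.0])
        else:
            copy = np.array([2.0])
        contig_rows[ci.contig] = _contig_depth(copy, means, config.snps_per_contig,
                                               config.contamination_rate, rng)
    depth_df = pd.DataFrame.from_dict(contig_rows, orient="index", columns=[sample_id])

    mutated = None
    if cds_deletion is not None:
        gid, pos = cds_deletion
        if gid not in truth.cds:
            raise InputError(f"unknown gene id in cds_deletion: {gid}")
        seq = truth.cds[gid]
        if not 1 <= pos <= len(seq):
            raise InputError(f"cds_deletion position {pos} outside CDS of {gid}")
        mutated = dict(truth.cds)
        mutated[gid] = seq[: pos - 1] + seq[pos:]

    return DepthProfile(depth=depth_df, gene_depth=gene_df), mutated
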