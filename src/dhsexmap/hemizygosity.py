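"""Depth-of-coverage as a segregating trait: hemizygosity mapping.

Y-specific (hemizygous) sequence has no X counterpart, so it carries no
heterozygous SNPs in the XY parent and cannot be placed on a SNP map.  It
does, however, segregate for presence/absence of read coverage in the DH
panel: progeny that inherited the Y carry it, the rest show ~zero depth.
This module normalizes per-individual coverage, converts it to tri-state
presence calls, matches presence patterns against the SNP linkage map, and
delimits the sex-linked non-recombining region as the span of contigs whose
pattern cosegregates perfectly with sex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InputError
from .linkage import (PH_A, PH_B, PH_MISSING, LinkageMap, RecombinationBin,
                      _compatible_overlap)

DEFAULT_ABSENT_MAX = 0.2
DEFAULT_PRESENT_MIN = 0.6

PRESENT = 1
ABSENT = 0
AMBIGUOUS = 2


@dataclass
class DepthProfile:
    """Contig x individual read depth, raw or normalized.

    ``gene_depth`` optionally carries the same measure per gene model.
    ``excluded`` lists individuals dropped at normalization (zero depth).
    """

    depth: pd.DataFrame
    gene_depth: pd.DataFrame | None = None
    normalized: bool = False
    excluded: list[str] = field(default_factory=list)


def normalize_depth(profile: DepthProfile) -> DepthProfile:
    """Scale each individual by its median contig depth.

    The median over all contigs stands in for the autosomal baseline (the
    hemizygous fraction of the genome is small, so the median is robust to
    it).  Multiplying an individual's raw depths by a constant leaves its
    normalized profile unchanged.  Individuals with zero total depth are
    excluded and reported.
    """
    totals = profile.depth.sum(axis=0)
    excluded = [s for s in profile.depth.columns if totals[s] <= 0]
    kept = [s for s in profile.depth.columns if s not in excluded]
    med = profile.depth[kept].median(axis=0)
    if (med <= 0).any():
        bad = list(med.index[med <= 0])
        raise InputError(f"nonpositive median depth for individual(s): {bad}")
    norm = profile.depth[kept] / med
    gene = None
    if profile.gene_depth is not None:
        gene = profile.gene_depth[kept] / med
    return DepthProfile(depth=norm, gene_depth=gene, normalized=True,
                        excluded=excluded)


def call_presence(normalized: pd.DataFrame,
                  absent_max: float = DEFAULT_ABSENT_MAX,
                  present_min: float = DEFAULT_PRESENT_MIN) -> pd.DataFrame:
    """Tri-state presence calls from normalized depth.

    Strictly below ``absent_max`` -> absent, strictly above ``present_min``
    -> present, anything between (inclusive) -> ambiguous.
    """
    if absent_max >= present_min:
        raise InputError("absent_max must be below present_min")
    calls = pd.DataFrame(AMBIGUOUS, index=normalized.index,
                         columns=normalized.columns, dtype=np.int8)
    calls[normalized < absent_max] = ABSENT
    calls[normalized > present_min] = PRESENT
    return calls


def _presence_to_phases(row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Both polarity encodings of a presence row as phase patterns."""
    fwd = np.full(row.shape, PH_MISSING, dtype=np.int8)
    fwd[row == PRESENT] = PH_A
    fwd[row == ABSENT] = PH_B
    rev = np.full(row.shape, PH_MISSING, dtype=np.int8)
    rev[row == PRESENT] = PH_B
    rev[row == ABSENT] = PH_A
    return fwd, rev


@dataclass
class DepthPlacement:
    contig: str
    status: str                 # "placed" | "uninformative" | "unplaced"
    group: int | None = None
    bin_id: int | None = None
    cM: float | None = None
    overlap: int = 0
    mismatches: int = 0
    polarity: str | None = None  # "present=A" | "present=B"


def map_depth_segregating(contig: str, presence_row: np.ndarray,
                          linkage_map: LinkageMap,
                          min_overlap: int = 20) -> DepthPlacement:
    """Place one contig on the map by its presence/absence pattern.

    The pattern (present -> one phase, absent -> the other; both polarities
    tried) must be compatible — zero mismatches at mutually informative
    positions — with a mapped bin, exactly as in pattern clustering; the
    compatible bin with the largest informative overlap wins.  A pattern
    that is constant across informative progeny carries no segregation
    signal and is reported uninformative.
    """
    row = np.asarray(presence_row)
    informative = row != AMBIGUOUS
    if int(informative.sum()) < min_overlap:
        return DepthPlacement(contig=contig, status="uninformative",
                              overlap=int(informative.sum()))
    vals = set(row[informative].tolist())
    if len(vals) < 2:
        return DepthPlacement(contig=contig, status="uninformative",
                              overlap=int(informative.sum()))
    best: tuple[int, int, RecombinationBin, str, int] | None = None
    for pattern, pol in zip(_presence_to_phases(row), ("present=A", "present=B")):
        for g in linkage_map.groups:
            for b in g.bins:
                ov = _compatible_overlap(pattern, b.pattern)
                if ov is not None and ov >= min_overlap:
                    key = (ov, b.bin_id, b, pol, g.group_id)
                    if best is None or ov > best[0] or (ov == best[0] and b.bin_id < best[1]):
                        best = key
    if best is None:
        return DepthPlacement(contig=contig, status="unplaced",
                              overlap=int(informative.sum()))
    ov, bin_id, b, pol, gid = best
    return DepthPlacement(contig=contig, status="placed", group=gid,
                          bin_id=bin_id, cM=b.cM, overlap=ov, mismatches=0,
                          polarity=pol)


def find_sex_linked(patterns: dict[str, np.ndarray], sex_labels: list[str],
                    max_mismatch: int = 0) -> dict[str, str]:
    """Elements whose pattern cosegregates with sex.

    ``patterns`` maps an id to a presence row (tri-state codes) or phase
    pattern over progeny; ``sex_labels`` holds "XX"/"YY" per progeny.  An
    element is returned when, among its informative calls, the number of
    individuals contradicting either sex polarity is <= ``max_mismatch``.
    Returns id -> polarity ("present=YY" or "present=XX").
    """
    sex = np.array([1 if s == "YY" else 0 for s in sex_labels], dtype=np.int8)
    out: dict[str, str] = {}
    for name in sorted(patterns):
        row = np.asarray(patterns[name])
        if set(np.unique(row)) <= {PH_MISSING, PH_A, PH_B}:
            informative = row != PH_MISSING
            one = row == PH_B
        else:  # presence codes
            informative = row != AMBIGUOUS
            one = row == PRESENT
        if not informative.any():
            continue
        if len(set(one[informative].tolist())) < 2:
            continue  # constant pattern: cannot cosegregate with a mixed-sex panel
        mm_fwd = int(np.sum(one[informative] != (sex[informative] == 1)))
        mm_rev = int(np.sum(one[informative] != (sex[informative] == 0)))
        if mm_fwd <= max_mismatch:
            out[name] = "present=YY"
        elif mm_rev <= max_mismatch:
            out[name] = "present=XX"
    return out


def classify_gene_presence(gene_id: str, female_normalized: pd.Series | np.ndarray,
                           absent_max: float = DEFAULT_ABSENT_MAX) -> str:
    """Hemizygous (Y-specific) vs shared: a gene whose median normalized
    depth across XX females is strictly below ``absent_max`` has no X copy."""
    vals = np.asarray(female_normalized, dtype=float)
    if vals.size == 0:
        raise InputError(f"no female depth values for gene {gene_id}")
    return "hemizygous" if float(np.median(vals)) < absent_max else "shared"


@dataclass
class SexRegion:
    """The delimited non-recombining sex-determination region."""

    chrom: str
    start: int                    # 0-based, half-open
    end: int
    chrom_length: int
    genes: list[dict] = field(default_factory=list)  # id, hemizygous, anchored
    unanchored_contigs: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def fraction_percent(self) -> float:
        return summarize_region(self.length, self.chrom_length).percent


@dataclass(frozen=True)
class RegionFraction:
    percent: float
    percent_truncated: float


def summarize_region(region_length_bp: float, chromosome_length_bp: float) -> RegionFraction:
    """Region size as a percentage of its chromosome, full precision plus
    the value truncated to two decimals (as printed in reports)."""
    if chromosome_length_bp <= 0:
        raise InputError("chromosome length must be positive")
    if not 0 <= region_length_bp <= chromosome_length_bp:
        raise InputError("region length must lie within [0, chromosome length]")
    pct = 100.0 * region_length_bp / chromosome_length_bp
    return RegionFraction(percent=pct,
                          percent_truncated=math.floor(pct * 100.0) / 100.0)


def delimit_region(sex_linked_contigs: list[str], contig_table: pd.DataFrame,
                   chrom_length: int, gene_classes: list[dict] | None = None,
                   ) -> SexRegion:
    """Union bp span of anchored sex-linked contigs on their chromosome.

    ``contig_table`` needs columns contig, chrom, start_bp, end_bp,
    anchored.  Unanchored sex-linked contigs are listed but excluded from
    the span.  All sex-linked contigs must sit on one chromosome.
    """
    sub = contig_table[contig_table["contig"].isin(sex_linked_contigs)]
    if sub.empty:
        raise InputError("no sex-linked contigs to delimit")
    chroms = sub["chrom"].unique()
    if len(chroms) != 1:
        raise InputError(f"sex-linked contigs span multiple chromosomes: {list(chroms)}")
    anchored = sub[sub["anchored"]]
    unanchored = list(sub.loc[~sub["anchored"], "contig"])
    if anchored.empty:
        raise InputError("no anchored sex-linked contigs; region span undefined")
    return SexRegion(chrom=str(chroms[0]),
                     start=int(anchored["start_bp"].min()),
                     end=int(anchored["end_bp"].max()),
                     chrom_length=int(chrom_length),
                     genes=gene_classes or [],
                     unanchored_contigs=unanchored)


def load_gene_table(path: str | None = None) -> pd.DataFrame:
    """Load the packaged 13-gene annotation table for the non-recombining
    region (or a user table in the same TSV layout).

    Columns: gene_id, annotation, anchored (bool; unanchored genes sit on
    contigs that could not be anchored onto the optical map),
    hemizygous_table (bool), hemizygous_per_text (string; the prose count
    of genes missing from XX females does not identify which gene is the
    exception, so the per-text status is unresolved for every row).
    """
    if path is None:
        ref = resources.files("dhsexmap").joinpath("data/table1_genes.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "annotation", "anchored", "hemizygous_table",
                "hemizygous_per_text"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"gene table missing column(s): {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise InputError("gene table has duplicate gene ids")
    df["anchored"] = df["anchored"].astype(bool)
    df["hemizygous_table"] = df["hemizygous_table"].astype(bool)
    return df
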