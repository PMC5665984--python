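"""Sex-conversion mutant classification and frameshift detection.

Gamma-irradiated XY plants that flower female or hermaphrodite are
resequenced and compared against an unmutated XY control.  Per-gene
coverage ratios (mutant normalized depth / control normalized depth) over
the 13 non-recombining-region genes reveal what was deleted: the whole
region (male -> female conversion, the Y's female suppressor and male
promoter both lost) or a single gene.  Loss of only the female suppressor
SOFF, with the male-promoting aspTDF1 retained, converts males to
hermaphrodites.  A separate CDS comparison detects frameshift point
mutants: a spontaneous 1-bp deletion in SOFF shifts the reading frame and
introduces a premature stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .errors import InputError

DEFAULT_DELETED_MAX = 0.1
SOFF_GENE = "SOFF"
TDF1_GENE = "aspTDF1"

VALID_BASES = set("ACGTN")


@dataclass
class MutantCall:
    sample_id: str
    ratios: dict[str, float]
    deletion_class: str                  # full_region_deletion | single_gene_deletion | none
    deleted_genes: list[str] = field(default_factory=list)
    phenotype: str = "male"              # female | hermaphrodite | male | undetermined

    def to_dict(self) -> dict:
        return {"sample_id": self.sample_id,
                "deletion_class": self.deletion_class,
                "deleted_genes": self.deleted_genes,
                "phenotype": self.phenotype,
                "ratios": {g: round(v, 4) for g, v in self.ratios.items()}}


def coverage_ratios(mutant_gene_depth, control_gene_depth,
                    hemizygous_only: Iterable[str] | None = None) -> dict[str, float]:
    """Per-gene mutant/control normalized-depth ratios.

    Both inputs are normalized per-gene depth Series (gene id -> value).
    A control gene with ~zero depth makes the ratio undefined and raises.
    """
    out = {}
    genes = hemizygous_only if hemizygous_only is not None else list(mutant_gene_depth.index)
    for g in genes:
        if g not in mutant_gene_depth.index or g not in control_gene_depth.index:
            raise InputError(f"missing depth for gene {g}")
        c = float(control_gene_depth[g])
        if c <= 0:
            raise InputError(f"control depth for gene {g} is zero; ratio undefined")
        out[g] = float(mutant_gene_depth[g]) / c
    return out


def classify_mutant(sample_id: str, ratios: dict[str, float],
                    region_genes: Sequence[str],
                    soff_genes: Sequence[str] = (SOFF_GENE,),
                    tdf1_gene: str = TDF1_GENE,
                    deleted_max: float = DEFAULT_DELETED_MAX) -> MutantCall:
    """Call the deletion class and predicted floral phenotype.

    A region gene counts as deleted when its coverage ratio is <=
    ``deleted_max``.  All region genes deleted -> full_region_deletion,
    predicted female (both the female suppressor and the male promoter are
    lost).  Exactly the female-suppressor gene(s) deleted ->
    single_gene_deletion, predicted hermaphrodite.  Nothing deleted ->
    none, male.  Any other deleted subset is reported as
    single_gene_deletion over that subset, hermaphrodite iff the female
    suppressor is lost while ``tdf1_gene`` is retained, else undetermined
    (the two-gene logic only predicts those combinations).
    """
    missing = [g for g in region_genes if g not in ratios]
    if missing:
        raise InputError(f"missing coverage ratio for gene(s): {missing}")
    bad = {g: ratios[g] for g in region_genes if ratios[g] < 0}
    if bad:
        raise InputError(f"negative coverage ratio(s): {bad}")
    deleted = [g for g in region_genes if ratios[g] <= deleted_max]
    region_ratios = {g: ratios[g] for g in region_genes}
    if len(deleted) == len(list(region_genes)):
        return MutantCall(sample_id, region_ratios, "full_region_deletion",
                          deleted, "female")
    if not deleted:
        return MutantCall(sample_id, region_ratios, "none", [], "male")
    if set(deleted) == set(soff_genes):
        return MutantCall(sample_id, region_ratios, "single_gene_deletion",
                          deleted, "hermaphrodite")
    soff_lost = set(soff_genes) <= set(deleted)
    tdf1_kept = tdf1_gene not in deleted
    phen = "hermaphrodite" if (soff_lost and tdf1_kept) else "undetermined"
    return MutantCall(sample_id, region_ratios, "single_gene_deletion", deleted, phen)


@dataclass
class FrameshiftReport:
    """Outcome of comparing an observed CDS against its reference."""

    has_variant: bool = False
    variant_position: int | None = None   # 1-based in reference CDS, first indel
    indel_length: int = 0                 # net; deletions negative
    frame_offset: int = 0                 # net indel length mod 3
    n_substitutions: int = 0
    premature_stop_codon: int | None = None  # 1-based codon index in the observed frame
    truncated_protein_length: int | None = None
    reference_protein_length: int = 0

    @property
    def is_frameshift(self) -> bool:
        return self.frame_offset != 0


def _validate_seq(name: str, seq: str) -> str:
    s = seq.upper()
    if not s:
        raise InputError(f"{name} sequence is empty")
    if set(s) - VALID_BASES:
        raise InputError(f"{name} sequence contains non-ACGTN characters")
    return s


def _alignment_indels(ref: str, obs: str) -> tuple[list[tuple[int, int]], int]:
    """Indels from a global alignment at unit edit costs.

    Returns ([(ref_pos_0based, signed_length), ...], n_substitutions).
    Deletions (bases missing from the observed CDS) have negative length.
    The first alignment from the deterministic aligner is used and each
    indel is then left-shifted maximally, giving leftmost placement.
    """
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(ref, obs)[0]
    ref_blocks, obs_blocks = aln.aligned
    indels: list[tuple[int, int]] = []
    subs = 0
    prev_r_end = prev_o_end = 0
    for (rs, re), (os_, oe) in zip(ref_blocks, obs_blocks):
        dr = rs - prev_r_end
        do = os_ - prev_o_end
        if dr and not do:
            indels.append((prev_r_end, -dr))
        elif do and not dr:
            indels.append((prev_r_end, do))
        elif dr and do:  # aligner emitted adjacent gaps; record both
            indels.append((prev_r_end, -dr))
            indels.append((prev_r_end, do))
        subs += int(sum(a != b for a, b in zip(ref[rs:re], obs[os_:oe])))
        prev_r_end, prev_o_end = re, oe
    dr = len(ref) - prev_r_end
    do = len(obs) - prev_o_end
    if dr:
        indels.append((prev_r_end, -dr))
    if do:
        indels.append((prev_r_end, do))
    # leftmost placement: shift each indel left over equal bases
    shifted = []
    for pos, length in indels:
        pos, length = int(pos), int(length)
        n = abs(length)
        if length < 0:
            while pos > 0 and ref[pos - 1] == ref[pos + n - 1]:
                pos -= 1
        shifted.append((pos, length))
    return sorted(shifted), subs


def detect_frameshift(reference_cds: str, observed_cds: str) -> FrameshiftReport:
    """Compare an observed CDS against its reference and report any
    frameshift and resulting premature stop codon.

    The reference must be codon-complete (length divisible by 3).  Indels
    are located by global alignment at unit costs with leftmost placement;
    the net frame offset is the total indel length mod 3.  The observed
    sequence is translated from its start with the standard genetic code
    and the first in-frame stop is compared with the reference stop: a
    stop strictly before the reference's terminal codon is premature.
    """
    ref = _validate_seq("reference", reference_cds)
    obs = _validate_seq("observed", observed_cds)
    if len(ref) % 3 != 0:
        raise InputError("reference CDS length is not divisible by 3")
    ref_protein_len = len(ref) // 3 - 1  # excluding the stop codon
    report = FrameshiftReport(reference_protein_length=ref_protein_len)
    if ref == obs:
        return report

    indels, subs = _alignment_indels(ref, obs)
    report.has_variant = True
    report.n_substitutions = subs
    if indels:
        report.variant_position = indels[0][0] + 1
        report.indel_length = sum(length for _, length in indels)
        report.frame_offset = report.indel_length % 3

    # translate the observed CDS from its start and find the first stop
    n_codons = len(obs) // 3
    trans = str(Seq(obs[: n_codons * 3]).translate())
    stop_idx = trans.find("*")
    if stop_idx != -1:
        stop_codon = stop_idx + 1
        if stop_codon < len(ref) // 3:
            report.premature_stop_codon = stop_codon
            report.truncated_protein_length = stop_idx
    return report


def format_report(report: FrameshiftReport) -> str:
    """Human-readable frameshift report."""
    if not report.has_variant:
        return "No variant: observed CDS is identical to the reference.\n"
    lines = []
    if report.indel_length != 0:
        kind = "deletion" if report.indel_length < 0 else "insertion"
        lines.append(f"{abs(report.indel_length)}-bp net {kind} at CDS position "
                     f"{report.variant_position}")
        lines.append(f"frame offset: {report.frame_offset}"
                     + (" (frameshift)" if report.is_frameshift else " (in-frame)"))
    if report.n_substitutions:
        lines.append(f"substitutions: {report.n_substitutions}")
    if report.premature_stop_codon is not None:
        lines.append(f"premature stop at codon {report.premature_stop_codon} "
                     f"(truncated protein: {report.truncated_protein_length} aa of "
                     f"{report.reference_protein_length})")
    else:
        lines.append("no premature stop codon")
    return "\n".join(lines) + "\n"
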