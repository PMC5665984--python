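"""Linkage-map construction from contig consensus genotypes.

The map is built the way low-coverage DH panels are mapped in practice:

1. SNP calls are phased to grandparent origin using the two resequenced
   grandparents (sites where they are not opposite homozygotes carry no
   phase information and are dropped).
2. SNPs from a contig are collapsed to one consensus call per individual:
   a call is assigned when strictly more than 90% of the non-missing SNP
   genotypes for that individual agree.
3. Contigs sharing a segregation pattern collapse into recombination bins;
   a contig with missing cells joins a bin when it is compatible at every
   informative position and overlaps it at enough individuals.
4. Bins join linkage groups by single-linkage clustering on pairwise
   recombination fraction, then each group is ordered by a greedy
   nearest-neighbour chain refined with 2-opt; map distances come from the
   Haldane function.

Chimeric contigs — runs of consecutive SNPs mapping to well-separated
loci, the signature of a mis-assembly join — are detected against a
preliminary map built from SNP-rich contigs and split before the final
map is assembled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InputError
from .variant_qc import GT_HET, GT_HOM_ALT, GT_HOM_REF, SnpRecord

logger = logging.getLogger(__name__)

# phase codes (grandparent origin)
PH_MISSING = -1
PH_A = 0
PH_B = 1
PH_HET = 2

DEFAULT_CONSENSUS_THRESHOLD = 0.90
DEFAULT_MIN_OVERLAP = 20
DEFAULT_RF_THRESHOLD = 0.25
RF_CAP = 0.49  # recombination fractions are capped below 0.5 before Haldane


# ---------------------------------------------------------------------------
# phasing

def phase_records(records: list[SnpRecord], progeny_idx: list[int],
                  gp_a_idx: int, gp_b_idx: int) -> dict[str, dict]:
    """Phase SNP genotypes to grandparent origin.

    Keeps only sites where the grandparents are opposite homozygotes (the
    informative sites; all segregating alleles are identifiable there).
    Returns contig -> {"phase": (n_snps x n_progeny) int8 matrix,
    "pos": positions} with codes A/B/het/missing.
    """
    out: dict[str, dict] = {}
    for rec in records:
        ga = rec.genotypes[gp_a_idx]
        gb = rec.genotypes[gp_b_idx]
        if {int(ga), int(gb)} != {GT_HOM_REF, GT_HOM_ALT}:
            continue
        prog = rec.genotypes[progeny_idx]
        phase = np.full(prog.shape, PH_MISSING, dtype=np.int8)
        phase[prog == ga] = PH_A
        phase[prog == gb] = PH_B
        phase[prog == GT_HET] = PH_HET
        entry = out.setdefault(rec.contig, {"phase": [], "pos": []})
        entry["phase"].append(phase)
        entry["pos"].append(rec.pos)
    for contig, entry in out.items():
        entry["phase"] = np.vstack(entry["phase"])
        entry["pos"] = np.asarray(entry["pos"])
    return out


# ---------------------------------------------------------------------------
# consensus

@dataclass
class ConsensusMatrix:
    """Contig x individual consensus calls (A/B/missing) with per-cell
    supporting-SNP counts."""

    contigs: list[str]
    individuals: list[str]
    calls: np.ndarray          # int8, PH_A / PH_B / PH_MISSING
    support: np.ndarray        # int32, SNPs backing each call

    def row(self, contig: str) -> np.ndarray:
        return self.calls[self.contigs.index(contig)]


def consensus_call(phases: np.ndarray, threshold: float = DEFAULT_CONSENSUS_THRESHOLD,
                   ) -> tuple[int, int]:
    """Consensus over one contig/individual SNP phase vector.

    The majority genotype class (A, B or het) must hold a share strictly
    above ``threshold`` of the non-missing calls; a het consensus cannot
    be phased and reports missing.  Returns (call, supporting count).
    """
    informative = phases[phases != PH_MISSING]
    if informative.size == 0:
        return PH_MISSING, 0
    counts = [(informative == c).sum() for c in (PH_A, PH_B, PH_HET)]
    best = int(np.argmax(counts))
    if counts[best] / informative.size > threshold:
        if best < 2:  # A or B
            return best, int(counts[best])
        return PH_MISSING, int(counts[best])
    return PH_MISSING, 0


def call_consensus(phased: dict[str, dict], individuals: list[str],
                   threshold: float = DEFAULT_CONSENSUS_THRESHOLD) -> ConsensusMatrix:
    """Collapse per-SNP phases to one consensus call per contig/individual."""
    contigs = sorted(phased)
    n = len(individuals)
    calls = np.full((len(contigs), n), PH_MISSING, dtype=np.int8)
    support = np.zeros((len(contigs), n), dtype=np.int32)
    for r, contig in enumerate(contigs):
        mat = phased[contig]["phase"]
        if mat.shape[0] == 0:
            logger.warning("contig %s has no informative SNPs; omitted", contig)
            continue
        counts = np.stack([(mat == c).sum(axis=0) for c in (PH_A, PH_B, PH_HET)])
        n_inf = counts.sum(axis=0)
        best = counts.argmax(axis=0)
        best_count = counts.max(axis=0)
        ok = (n_inf > 0) & (best_count > threshold * n_inf) & (best < 2)
        calls[r, ok] = best[ok].astype(np.int8)
        support[r, ok] = best_count[ok]
    return ConsensusMatrix(contigs=contigs, individuals=individuals,
                           calls=calls, support=support)


# ---------------------------------------------------------------------------
# pattern binning

@dataclass
class RecombinationBin:
    """A distinct segregation pattern and the contigs carrying it."""

    bin_id: int
    pattern: np.ndarray                 # int8 over progeny, PH_A/PH_B/PH_MISSING
    members: list[str] = field(default_factory=list)
    group: int | None = None
    order_index: int | None = None
    cM: float | None = None
    votes: np.ndarray | None = None     # (n_progeny x 2) A/B member votes

    def informative(self) -> np.ndarray:
        return self.pattern != PH_MISSING


def _compatible_overlap(pattern: np.ndarray, other: np.ndarray) -> int | None:
    """Informative overlap if the two patterns agree at every position
    where both are non-missing, else None."""
    both = (pattern != PH_MISSING) & (other != PH_MISSING)
    n = int(both.sum())
    if n == 0:
        return 0
    if np.any(pattern[both] != other[both]):
        return None
    return n


def _bin_pattern_from_votes(votes: np.ndarray) -> np.ndarray:
    """Per-position majority of member calls; ties report missing."""
    pattern = np.full(votes.shape[0], PH_MISSING, dtype=np.int8)
    pattern[votes[:, 0] > votes[:, 1]] = PH_A
    pattern[votes[:, 1] > votes[:, 0]] = PH_B
    return pattern


def cluster_patterns(matrix: ConsensusMatrix,
                     min_overlap: int = DEFAULT_MIN_OVERLAP) -> list[RecombinationBin]:
    """Merge contigs with compatible segregation patterns into bins.

    Contigs are visited in sorted-id order.  A contig joins the existing
    bin with the largest informative overlap among bins it is compatible
    with (zero mismatches at mutually informative positions, overlap >=
    ``min_overlap``); ties go to the lowest bin id; otherwise it founds a
    new bin.  Bin patterns are per-position majorities over members.
    """
    if not matrix.contigs:
        raise InputError("consensus matrix is empty")
    bins: list[RecombinationBin] = []
    pat_stack = np.empty((0, matrix.calls.shape[1]), dtype=np.int8)
    for r, contig in enumerate(matrix.contigs):
        row = matrix.calls[r]
        best: RecombinationBin | None = None
        if bins:
            both = (row[None, :] != PH_MISSING) & (pat_stack != PH_MISSING)
            mism = (both & (row[None, :] != pat_stack)).sum(axis=1)
            ov = both.sum(axis=1)
            ok = (mism == 0) & (ov >= min_overlap)
            if ok.any():
                # largest overlap wins; argmax ties go to the lowest bin id
                best = bins[int(np.argmax(np.where(ok, ov, -1)))]
        if best is None:
            votes = np.zeros((row.size, 2), dtype=np.int32)
            votes[row == PH_A, 0] = 1
            votes[row == PH_B, 1] = 1
            bins.append(RecombinationBin(bin_id=len(bins), pattern=row.copy(),
                                         members=[contig], votes=votes))
            pat_stack = np.vstack([pat_stack, row[None, :]])
        else:
            best.members.append(contig)
            best.votes[row == PH_A, 0] += 1
            best.votes[row == PH_B, 1] += 1
            best.pattern = _bin_pattern_from_votes(best.votes)
            pat_stack[best.bin_id] = best.pattern
    return bins


# ---------------------------------------------------------------------------
# recombination fractions, grouping, ordering

def recombination_fraction(p: np.ndarray, q: np.ndarray,
                           min_overlap: int = DEFAULT_MIN_OVERLAP,
                           ) -> tuple[float | None, int]:
    """Two-point recombination fraction over mutually informative progeny.

    Phases are absolute (grandparent origin), so rf is simply the mismatch
    fraction.  Returns (rf, overlap); rf is None when the overlap is below
    ``min_overlap``.
    """
    both = (p != PH_MISSING) & (q != PH_MISSING)
    n = int(both.sum())
    if n < min_overlap:
        return None, n
    rf = float(np.mean(p[both] != q[both]))
    return rf, n


def haldane_cm(rf: float) -> float:
    """Haldane map distance in cM; rf is capped just below 0.5."""
    r = min(max(rf, 0.0), RF_CAP)
    return -50.0 * math.log(1.0 - 2.0 * r)


def _signed(patterns: np.ndarray) -> np.ndarray:
    """Encode phase patterns as +1 (A) / -1 (B) / 0 (missing): mismatch
    counts then reduce to matrix products."""
    s = np.zeros(patterns.shape, dtype=np.float64)
    s[patterns == PH_A] = 1.0
    s[patterns == PH_B] = -1.0
    return s


def _rf_matrix(bins: list[RecombinationBin], min_overlap: int) -> np.ndarray:
    """Dense rf matrix; undefined pairs (overlap < min_overlap) hold NaN."""
    k = len(bins)
    s = _signed(np.stack([b.pattern for b in bins]))
    a = np.abs(s)
    overlap = a @ a.T
    agree = s @ s.T
    with np.errstate(invalid="ignore", divide="ignore"):
        rf = (overlap - agree) / (2.0 * overlap)
    rf[overlap < min_overlap] = np.nan
    np.fill_diagonal(rf, 0.0)
    return rf


def group_linkage(bins: list[RecombinationBin],
                  rf_threshold: float = DEFAULT_RF_THRESHOLD,
                  min_overlap: int = DEFAULT_MIN_OVERLAP,
                  ) -> tuple[list[list[RecombinationBin]], list[RecombinationBin]]:
    """Single-linkage clustering of bins into linkage groups.

    Bins join one group iff some pairwise rf < ``rf_threshold``.  Bins
    with no defined rf against any other bin (informative overlap below
    ``min_overlap`` everywhere) are left unplaced and reported separately.
    Groups are returned largest-first (ties by lowest member bin id).
    """
    if not bins:
        raise InputError("no bins to group")
    k = len(bins)
    rf = _rf_matrix(bins, min_overlap)
    parent = list(range(k))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            if not np.isnan(rf[i, j]) and rf[i, j] < rf_threshold:
                parent[find(i)] = find(j)

    def is_placeable(i: int) -> bool:
        if k == 1:
            return True
        if np.any(~np.isnan(np.delete(rf[i], i))):
            return True
        # no measurable rf against any other bin: place it as a singleton
        # group only if the bin itself is informative enough to be real
        return int(bins[i].informative().sum()) >= min_overlap

    placeable = [i for i in range(k) if is_placeable(i)]
    unplaced = [bins[i] for i in range(k) if i not in placeable]
    clusters: dict[int, list[int]] = {}
    for i in placeable:
        clusters.setdefault(find(i), []).append(i)
    ordered = sorted(clusters.values(), key=lambda ix: (-len(ix), min(ix)))
    groups = []
    for gid, idxs in enumerate(ordered, start=1):
        members = [bins[i] for i in sorted(idxs)]
        for b in members:
            b.group = gid
        groups.append(members)
    return groups, unplaced


def _chain_objective(order: list[int], rf: np.ndarray) -> float:
    """Sum of adjacent recombination fractions (undefined pairs cost 0.5)."""
    total = 0.0
    for a, b in zip(order, order[1:]):
        r = rf[a, b]
        total += 0.5 if np.isnan(r) else r
    return total


def order_bins(group: list[RecombinationBin],
               min_overlap: int = DEFAULT_MIN_OVERLAP) -> list[RecombinationBin]:
    """Order one linkage group and assign cM positions.

    Greedy nearest-neighbour chain seeded at the minimum-rf pair, extended
    at either end, then locally improved by 2-opt segment reversal until
    the total adjacent rf stops decreasing.  cM positions are cumulative
    Haldane distances between adjacent bins.  The orientation with the
    lowest-id bin first is reported (orderings are defined up to reversal).
    """
    if not group:
        raise InputError("empty linkage group")
    k = len(group)
    if k == 1:
        group[0].order_index, group[0].cM = 0, 0.0
        return list(group)
    rf = _rf_matrix(group, min_overlap)
    cost = np.where(np.isnan(rf), 0.5, rf)
    np.fill_diagonal(cost, np.inf)

    # seed with the globally closest pair (ties: lowest indices)
    i0, j0 = divmod(int(np.argmin(cost)), k)
    order = [min(i0, j0), max(i0, j0)]
    used = set(order)
    while len(order) < k:
        left, right = order[0], order[-1]
        candidates = [(cost[left, m], 0, m) for m in range(k) if m not in used]
        candidates += [(cost[right, m], 1, m) for m in range(k) if m not in used]
        c, side, m = min(candidates, key=lambda t: (t[0], t[2], t[1]))
        if side == 0:
            order.insert(0, m)
        else:
            order.append(m)
        used.add(m)

    # 2-opt: first-improvement sweeps until stable
    improved = True
    while improved:
        improved = False
        base = _chain_objective(order, np.where(np.isinf(cost), 0.0, cost))
        for i in range(k - 1):
            for j in range(i + 1, k):
                cand = order[:i] + order[i:j + 1][::-1] + order[j + 1:]
                if _chain_objective(cand, np.where(np.isinf(cost), 0.0, cost)) < base - 1e-12:
                    order = cand
                    improved = True
                    break
            if improved:
                break

    if order[0] > order[-1]:
        order = order[::-1]
    pos = 0.0
    out = []
    for idx, b_idx in enumerate(order):
        b = group[b_idx]
        if idx > 0:
            prev = group[order[idx - 1]]
            r, _ = recombination_fraction(prev.pattern, b.pattern, min_overlap)
            pos += haldane_cm(0.5 if r is None else r)
        b.order_index, b.cM = idx, pos
        out.append(b)
    return out


# ---------------------------------------------------------------------------
# chimera detection

@dataclass(frozen=True)
class ChimeraPolicy:
    """A contig is cut where two adjacent runs of at least
    ``min_consecutive_snps`` SNPs each map to loci strictly more than
    ``min_distance_cM`` apart (or to different linkage groups)."""

    min_consecutive_snps: int = 5
    min_distance_cM: float = 5.0

    def validate(self) -> None:
        if self.min_consecutive_snps < 2:
            raise ConfigError("min_consecutive_snps must be >= 2")
        if self.min_distance_cM < 0:
            raise ConfigError("min_distance_cM must be nonnegative")


def detect_chimeras(assignments: list[tuple[int, float] | None],
                    policy: ChimeraPolicy | None = None) -> list[int]:
    """Find cut points in one contig's ordered per-SNP locus assignments.

    ``assignments[k]`` is the (linkage group, cM) locus of SNP k, or None
    when unassigned (unassigned SNPs are skipped and never break a run).
    Returns indices k such that the contig is cut between SNP k-1 and k.
    """
    policy = policy or ChimeraPolicy()
    policy.validate()
    # maximal runs of equal locus among assigned SNPs
    runs: list[tuple[tuple[int, float], int, int]] = []  # (locus, first_idx, count)
    for k, a in enumerate(assignments):
        if a is None:
            continue
        if runs and runs[-1][0] == a:
            locus, first, count = runs[-1]
            runs[-1] = (locus, first, count + 1)
        else:
            runs.append((a, k, 1))
    cuts = []
    for (la, _, na), (lb, start_b, nb) in zip(runs, runs[1:]):
        if na < policy.min_consecutive_snps or nb < policy.min_consecutive_snps:
            continue
        different = la[0] != lb[0] or abs(la[1] - lb[1]) > policy.min_distance_cM
        if different:
            cuts.append(start_b)
    return cuts


def assign_snps_to_loci(phase_matrix: np.ndarray, bins: list[RecombinationBin],
                        min_overlap: int = DEFAULT_MIN_OVERLAP,
                        max_mismatch_frac: float = 0.2,
                        ) -> list[tuple[int, float] | None]:
    """Assign each SNP (row of ``phase_matrix``) to the mapped bin whose
    pattern it mismatches least, as a (group, cM) locus; None when no bin
    overlaps enough or the best mismatch fraction exceeds the cap."""
    mapped = [b for b in bins if b.group is not None and b.cM is not None]
    if not mapped:
        return [None] * phase_matrix.shape[0]
    snps = np.where(phase_matrix == PH_HET, PH_MISSING, phase_matrix)
    s = _signed(snps)
    p = _signed(np.stack([b.pattern for b in mapped]))
    overlap = np.abs(s) @ np.abs(p).T            # (n_snps x n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (overlap - s @ p.T) / (2.0 * overlap)
    frac[overlap < min_overlap] = np.inf
    out: list[tuple[int, float] | None] = []
    best_idx = np.argmin(frac, axis=1)           # ties: lowest bin index
    best_frac = frac[np.arange(frac.shape[0]), best_idx]
    for k in range(phase_matrix.shape[0]):
        if not np.isfinite(best_frac[k]) or best_frac[k] > max_mismatch_frac:
            out.append(None)
        else:
            b = mapped[int(best_idx[k])]
            out.append((b.group, b.cM))
    return out


# ---------------------------------------------------------------------------
# the full map

@dataclass
class LinkageGroup:
    group_id: int
    bins: list[RecombinationBin]  # ordered, with cM set


@dataclass
class LinkageMap:
    groups: list[LinkageGroup]
    unplaced: list[RecombinationBin]
    splits: dict[str, list[int]] = field(default_factory=dict)  # contig -> cut indices

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_bins(self) -> int:
        return sum(len(g.bins) for g in self.groups) + len(self.unplaced)

    def all_bins(self) -> list[RecombinationBin]:
        out = [b for g in self.groups for b in g.bins]
        return out + list(self.unplaced)

    def contig_assignment(self) -> dict[str, tuple[int | None, int, int | None, float | None]]:
        """contig -> (group, bin_id, order_index, cM); group None = unplaced."""
        out = {}
        for g in self.groups:
            for b in g.bins:
                for c in b.members:
                    out[c] = (g.group_id, b.bin_id, b.order_index, b.cM)
        for b in self.unplaced:
            for c in b.members:
                out[c] = (None, b.bin_id, None, None)
        return out

    def to_dataframe(self):
        import pandas as pd
        rows = []
        sym = {PH_A: "A", PH_B: "B", PH_MISSING: "-"}
        for g in self.groups + [None]:
            bins = g.bins if g is not None else self.unplaced
            gid = g.group_id if g is not None else ""
            for b in bins:
                pat = "".join(sym[int(v)] for v in b.pattern)
                for c in b.members:
                    rows.append({"contig": c, "linkage_group": gid, "bin_id": b.bin_id,
                                 "order_index": "" if b.order_index is None else b.order_index,
                                 "cM": "" if b.cM is None else round(b.cM, 4),
                                 "pattern": pat})
        return pd.DataFrame(rows, columns=["contig", "linkage_group", "bin_id",
                                           "order_index", "cM", "pattern"])


def build_linkage_map(matrix: ConsensusMatrix,
                      min_overlap: int = DEFAULT_MIN_OVERLAP,
                      rf_threshold: float = DEFAULT_RF_THRESHOLD) -> LinkageMap:
    """Bin, group and order a consensus matrix into a linkage map."""
    bins = cluster_patterns(matrix, min_overlap)
    groups, unplaced = group_linkage(bins, rf_threshold, min_overlap)
    lg = [LinkageGroup(group_id=i + 1, bins=order_bins(g, min_overlap))
          for i, g in enumerate(groups)]
    return LinkageMap(groups=lg, unplaced=unplaced)


def split_contig(phased_entry: dict, cuts: list[int]) -> dict[str, dict]:
    """Split one contig's phased SNPs at the given cut indices."""
    bounds = [0] + sorted(cuts) + [phased_entry["phase"].shape[0]]
    parts = {}
    for part, (a, b) in enumerate(zip(bounds, bounds[1:]), start=1):
        parts[f":{part}"] = {"phase": phased_entry["phase"][a:b],
                             "pos": phased_entry["pos"][a:b]}
    return parts


def build_map_iterative(phased: dict[str, dict], individuals: list[str],
                        consensus_threshold: float = DEFAULT_CONSENSUS_THRESHOLD,
                        min_overlap: int = DEFAULT_MIN_OVERLAP,
                        rf_threshold: float = DEFAULT_RF_THRESHOLD,
                        chimera_policy: ChimeraPolicy | None = None,
                        big_contig_snps: int = 100) -> LinkageMap:
    """Build the map in passes: SNP-rich contigs first, then everything.

    Pass 1 uses contigs with strictly more than ``big_contig_snps``
    informative SNPs (falling back to all contigs, with a warning, when
    none qualify) to build a preliminary map.  Every contig is then
    scanned for chimeric joins against that map and split where the
    chimera rule fires.  The final map re-clusters all (split) contigs.
    """
    policy = chimera_policy or ChimeraPolicy()
    big = {c: e for c, e in phased.items() if e["phase"].shape[0] > big_contig_snps}
    if not big:
        logger.warning("no contig exceeds %d SNPs; building the preliminary map "
                       "from all contigs", big_contig_snps)
        big = phased
    prelim = build_linkage_map(call_consensus(big, individuals, consensus_threshold),
                               min_overlap, rf_threshold)

    splits: dict[str, list[int]] = {}
    final_phased: dict[str, dict] = {}
    prelim_bins = prelim.all_bins()
    for contig in sorted(phased):
        entry = phased[contig]
        assignments = assign_snps_to_loci(entry["phase"], prelim_bins, min_overlap)
        cuts = detect_chimeras(assignments, policy)
        if cuts:
            splits[contig] = cuts
            for suffix, part in split_contig(entry, cuts).items():
                final_phased[contig + suffix] = part
        else:
            final_phased[contig] = entry

    final = build_linkage_map(call_consensus(final_phased, individuals,
                                             consensus_threshold),
                              min_overlap, rf_threshold)
    final.splits = splits
    return final
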