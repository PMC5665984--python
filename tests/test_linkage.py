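"""Consensus, binning, grouping, ordering and chimera detection."""

import numpy as np
import pytest

import dhsexmap as d
from dhsexmap.linkage import (PH_A, PH_B, PH_HET, PH_MISSING, _chain_objective,
                              _rf_matrix, build_linkage_map, call_consensus,
                              consensus_call)

from conftest import small_config

N_PROG = 74


def phased_entry(phase_matrix):
    phase_matrix = np.asarray(phase_matrix, dtype=np.int8)
    return {"phase": phase_matrix, "pos": np.arange(1, phase_matrix.shape[0] + 1)}


class TestConsensus:
    def test_unanimous_snps_give_the_call(self):
        assert consensus_call(np.full(10, PH_A, np.int8)) == (PH_A, 10)

    def test_ninety_percent_is_not_enough(self):
        # 9 of 10: share exactly 0.90, rule requires strictly more
        phases = np.array([PH_A] * 9 + [PH_B], np.int8)
        assert consensus_call(phases)[0] == PH_MISSING

    def test_missing_data_excluded_from_denominator(self):
        # 19 A + 1 missing: 19/19 non-missing agree
        phases = np.array([PH_A] * 19 + [PH_MISSING], np.int8)
        assert consensus_call(phases) == (PH_A, 19)

    def test_het_consensus_cannot_be_phased(self):
        assert consensus_call(np.full(12, PH_HET, np.int8))[0] == PH_MISSING

    def test_matrix_agrees_with_cellwise_rule(self):
        rng = np.random.default_rng(5)
        mat = rng.choice([PH_MISSING, PH_A, PH_B, PH_HET], size=(15, 8),
                         p=[0.1, 0.45, 0.4, 0.05]).astype(np.int8)
        cm = call_consensus({"c1": phased_entry(mat)}, [f"i{k}" for k in range(8)])
        for i in range(8):
            assert cm.calls[0, i] == consensus_call(mat[:, i])[0]

    def test_error_free_panel_recovers_true_phase(self):
        cfg = small_config(seed=3, genotype_error_rate=0.0, missing_rate=0.0,
                           mean_depth_progeny=5.0)
        truth, records, _ = d.simulate_panel(cfg)
        res = d.filter_snps(records)
        phased = d.phase_records(res.retained, list(range(cfg.n_progeny)),
                                 cfg.n_progeny + 1, cfg.n_progeny + 2)
        cm = call_consensus(phased, truth.progeny_names)
        by_contig = {c.contig: c for c in truth.contigs}
        for r, contig in enumerate(cm.contigs):
            ci = by_contig[contig]
            expected = [truth.phase_at(p, ci.chrom, ci.cM) for p in truth.progeny_names]
            defined = cm.calls[r] != PH_MISSING
            assert defined.all()
            assert np.array_equal(cm.calls[r], np.array(expected, np.int8))


def base_patterns(k, n=N_PROG, seed=0):
    """k mutually distant random patterns."""
    rng = np.random.default_rng(seed)
    while True:
        pats = rng.integers(0, 2, size=(k, n)).astype(np.int8)
        dist = (pats[:, None, :] != pats[None, :, :]).sum(axis=2)
        np.fill_diagonal(dist, n)
        if dist.min() > n // 3:
            return pats


def closure_oracle(rows, min_overlap):
    """Brute-force all-pairs compatibility closure (union-find)."""
    k = len(rows)
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            both = (rows[i] != PH_MISSING) & (rows[j] != PH_MISSING)
            if both.sum() >= min_overlap and not (rows[i][both] != rows[j][both]).any():
                parent[find(i)] = find(j)
    groups = {}
    for i in range(k):
        groups.setdefault(find(i), set()).add(i)
    return set(frozenset(g) for g in groups.values())


class TestClusterPatterns:
    def make_matrix(self, rows):
        rows = np.asarray(rows, dtype=np.int8)
        contigs = [f"c{i:03d}" for i in range(rows.shape[0])]
        return d.ConsensusMatrix(contigs=contigs,
                                 individuals=[f"i{j}" for j in range(rows.shape[1])],
                                 calls=rows, support=np.ones_like(rows, np.int32))

    def test_identical_patterns_merge(self):
        pat = base_patterns(1)[0]
        bins = d.cluster_patterns(self.make_matrix([pat, pat]))
        assert len(bins) == 1 and bins[0].members == ["c000", "c001"]

    def test_one_individual_difference_separates(self):
        pat = base_patterns(1)[0]
        other = pat.copy()
        other[0] = 1 - other[0]
        bins = d.cluster_patterns(self.make_matrix([pat, other]))
        assert len(bins) == 2

    def test_missing_cells_join_compatible_bin(self):
        pat = base_patterns(1)[0]
        gappy = pat.copy()
        gappy[:10] = PH_MISSING
        bins = d.cluster_patterns(self.make_matrix([pat, gappy]))
        assert len(bins) == 1

    def test_matches_brute_force_closure(self):
        # <= 50 contigs derived from 5 bases with random missing cells
        rng = np.random.default_rng(11)
        bases = base_patterns(5, seed=2)
        rows = []
        for _ in range(48):
            row = bases[rng.integers(0, 5)].copy()
            mask = rng.random(N_PROG) < 0.25
            row[mask] = PH_MISSING
            rows.append(row)
        mat = self.make_matrix(rows)
        bins = d.cluster_patterns(mat, min_overlap=20)
        got = set(frozenset(int(m[1:]) for m in b.members) for b in bins)
        assert got == closure_oracle(rows, min_overlap=20)

    def test_empty_matrix_rejected(self):
        with pytest.raises(d.InputError):
            d.cluster_patterns(self.make_matrix(np.zeros((0, 5))))


def bin_from(pattern, bin_id=0):
    return d.RecombinationBin(bin_id=bin_id, pattern=np.asarray(pattern, np.int8),
                              members=[f"m{bin_id}"])


class TestGrouping:
    def test_close_bins_share_a_group(self):
        a = base_patterns(1)[0]
        b = a.copy()
        b[:2] = 1 - b[:2]  # rf ~ 0.027
        groups, unplaced = d.group_linkage([bin_from(a, 0), bin_from(b, 1)])
        assert len(groups) == 1 and not unplaced

    def test_unlinked_bins_split(self):
        a, b = base_patterns(2, seed=4)
        groups, _ = d.group_linkage([bin_from(a, 0), bin_from(b, 1)])
        assert len(groups) == 2

    def test_single_bin_is_one_group(self):
        groups, unplaced = d.group_linkage([bin_from(base_patterns(1)[0])])
        assert len(groups) == 1 and not unplaced

    def test_low_overlap_bin_reported_unplaced(self):
        a = base_patterns(1)[0]
        sparse = np.full(N_PROG, PH_MISSING, np.int8)
        sparse[:5] = a[:5]
        groups, unplaced = d.group_linkage([bin_from(a, 0), bin_from(sparse, 1)])
        assert len(groups) == 1
        assert [b.bin_id for b in unplaced] == [1]

    def test_groups_sorted_largest_first(self, default_panel):
        cfg, truth, records, _ = default_panel
        res = d.filter_snps(records)
        phased = d.phase_records(res.retained, list(range(74)), 75, 76)
        lmap = d.build_map_iterative(phased, truth.progeny_names)
        sizes = [sum(len(b.members) for b in g.bins) for g in lmap.groups]
        assert sizes == sorted(sizes, reverse=True)


class TestOrdering:
    def test_three_bin_order_matches_exhaustive_minimum(self):
        # rf(1,2)=rf(2,3)~4/74, rf(1,3)~8/74: unique optimum is 1-2-3
        a = np.zeros(N_PROG, np.int8)
        b = a.copy(); b[:4] = PH_B
        c = a.copy(); c[:8] = PH_B
        bins = [bin_from(a, 0), bin_from(b, 1), bin_from(c, 2)]
        ordered = d.order_bins(bins)
        assert [x.bin_id for x in ordered] == [0, 1, 2]
        assert ordered[0].cM == 0.0
        assert ordered[1].cM < ordered[2].cM

    def test_collinear_simulation_recovered_up_to_reversal(self):
        cfg = small_config(seed=6, genotype_error_rate=0.0, missing_rate=0.0,
                           mean_depth_progeny=5.0)
        truth, records, _ = d.simulate_panel(cfg)
        res = d.filter_snps(records)
        phased = d.phase_records(res.retained, list(range(cfg.n_progeny)),
                                 cfg.n_progeny + 1, cfg.n_progeny + 2)
        lmap = d.build_map_iterative(phased, truth.progeny_names)
        cm_of = {c.contig: c.cM for c in truth.contigs}
        for g in lmap.groups:
            true_pos = [np.mean([cm_of[m] for m in b.members]) for b in g.bins]
            diffs = np.diff(true_pos)
            assert (diffs >= 0).all() or (diffs <= 0).all()

    def test_objective_not_worse_than_input_order(self):
        rng = np.random.default_rng(8)
        pats = base_patterns(1, seed=9)[0]
        bins = []
        cur = pats.copy()
        for i in range(8):
            cur = cur.copy()
            flip = rng.integers(0, N_PROG, size=3)
            cur[flip] = 1 - cur[flip]
            bins.append(bin_from(cur, i))
        rng.shuffle(bins)
        for i, b in enumerate(bins):
            b.bin_id = i
        rf = np.where(np.isnan(_rf_matrix(bins, 20)), 0.5, _rf_matrix(bins, 20))
        before = _chain_objective(list(range(len(bins))), rf)
        ordered = d.order_bins(bins)
        idx = {b.bin_id: k for k, b in enumerate(bins)}
        after = _chain_objective([idx[b.bin_id] for b in ordered], rf)
        assert after <= before + 1e-12

    def test_single_bin_trivially_ordered(self):
        out = d.order_bins([bin_from(base_patterns(1)[0])])
        assert out[0].order_index == 0 and out[0].cM == 0.0

    def test_haldane_nonnegative_and_monotone(self):
        rfs = np.linspace(0.0, 0.49, 50)
        cms = [d.haldane_cm(r) for r in rfs]
        assert cms[0] == 0.0
        assert all(x >= 0 for x in cms)
        assert all(b > a for a, b in zip(cms, cms[1:]))


class TestChimeraRule:
    def locus(self, cm, group=1):
        return (group, cm)

    def test_five_plus_five_beyond_5cm_is_cut(self):
        calls = [self.locus(10.0)] * 5 + [self.locus(16.0)] * 5
        assert d.detect_chimeras(calls) == [5]

    def test_four_plus_five_is_not_cut(self):
        calls = [self.locus(10.0)] * 4 + [self.locus(16.0)] * 5
        assert d.detect_chimeras(calls) == []

    def test_exactly_5cm_apart_is_not_cut(self):
        calls = [self.locus(10.0)] * 5 + [self.locus(15.0)] * 5
        assert d.detect_chimeras(calls) == []

    def test_different_groups_always_distant(self):
        calls = [(1, 10.0)] * 5 + [(2, 10.0)] * 5
        assert d.detect_chimeras(calls) == [5]

    def test_unassigned_snps_do_not_break_runs(self):
        calls = ([self.locus(10.0)] * 3 + [None] + [self.locus(10.0)] * 2
                 + [self.locus(20.0)] * 5)
        assert d.detect_chimeras(calls) == [6]

    def test_policy_validation(self):
        with pytest.raises(d.ConfigError, match="min_consecutive_snps"):
            d.detect_chimeras([], d.ChimeraPolicy(min_consecutive_snps=1))


class TestIterativeMap:
    def test_all_big_contigs_single_pass_equals_direct(self):
        cfg = small_config(seed=12, n_chromosomes=2, contigs_per_chrom=6,
                           snps_per_contig=120)
        truth, records, _ = d.simulate_panel(cfg)
        res = d.filter_snps(records)
        phased = d.phase_records(res.retained, list(range(cfg.n_progeny)),
                                 cfg.n_progeny + 1, cfg.n_progeny + 2)
        iterative = d.build_map_iterative(phased, truth.progeny_names)
        direct = build_linkage_map(call_consensus(phased, truth.progeny_names))
        assert iterative.splits == {}
        got = {frozenset(b.members) for g in iterative.groups for b in g.bins}
        want = {frozenset(b.members) for g in direct.groups for b in g.bins}
        assert got == want

    def test_planted_chimera_is_split_and_both_halves_placed(self):
        cfg = small_config(seed=13, genotype_error_rate=0.0, missing_rate=0.0,
                           mean_depth_progeny=5.0)
        truth, records, _ = d.simulate_panel(cfg)
        res = d.filter_snps(records)
        phased = d.phase_records(res.retained, list(range(cfg.n_progeny)),
                                 cfg.n_progeny + 1, cfg.n_progeny + 2)
        # graft: SNPs of a chromosome-1 contig followed by a chromosome-2 contig
        a, b = "ctg01_002", "ctg02_009"
        chimera = {"phase": np.vstack([phased[a]["phase"], phased[b]["phase"]]),
                   "pos": np.concatenate([phased[a]["pos"], phased[b]["pos"]])}
        del phased[a], phased[b]
        phased["chimera"] = chimera
        lmap = d.build_map_iterative(phased, truth.progeny_names)
        assert "chimera" in lmap.splits
        assign = lmap.contig_assignment()
        g1, g2 = assign["chimera:1"][0], assign["chimera:2"][0]
        assert g1 is not None and g2 is not None and g1 != g2
        chrom_of_group = {}
        by_contig = {c.contig: c.chrom for c in truth.contigs}
        for contig, (grp, *_rest) in assign.items():
            root = contig.split(":")[0]
            if root in by_contig and grp is not None:
                chrom_of_group.setdefault(grp, set()).add(by_contig[root])
        assert chrom_of_group[g1] == {0} and chrom_of_group[g2] == {1}

    def test_error_free_panel_places_every_contig(self):
        cfg = small_config(seed=14, genotype_error_rate=0.0, missing_rate=0.0,
                           mean_depth_progeny=5.0)
        truth, records, _ = d.simulate_panel(cfg)
        res = d.filter_snps(records)
        phased = d.phase_records(res.retained, list(range(cfg.n_progeny)),
                                 cfg.n_progeny + 1, cfg.n_progeny + 2)
        lmap = d.build_map_iterative(phased, truth.progeny_names)
        assert lmap.unplaced == []
        placed = {m for g in lmap.groups for b in g.bins for m in b.members}
        assert placed == set(phased)


def test_group_recovery_rate_over_seeds():
    """Default-condition panels recover the simulated chromosome number in
    >= 95% of replicates."""
    hits = 0
    for seed in range(20):
        cfg = d.PanelConfig(seed=seed)
        truth, records, _ = d.simulate_panel(cfg)
        res = d.filter_snps(records)
        phased = d.phase_records(res.retained, list(range(74)), 75, 76)
        lmap = d.build_map_iterative(phased, truth.progeny_names)
        hits += lmap.n_groups == cfg.n_chromosomes
    assert hits >= 19
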