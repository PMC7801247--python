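import numpy as np
import pytest

from wgdscan import (
    assign_events,
    blocks_cross,
    date_event,
    depth_profile,
    find_peaks,
    ortholog_peak,
    rank_hits,
    reconstruct_ancestral,
    score_pairs,
    simulate_species_pair,
)
from wgdscan.colinearity import ColinearBlock, GenePair

from conftest import make_annotation


def block(scaffold_a, scaffold_b, points, median_ks=None, p_value=0.001, label=None):
    return ColinearBlock(
        scaffold_a=scaffold_a, scaffold_b=scaffold_b,
        pairs=tuple(GenePair(a, b, x, y) for (a, b, x, y) in points),
        orientation="parallel", p_value=p_value, median_ks=median_ks,
        event_label=label,
    )


class TestFindPeaks:
    def test_recovers_bimodal_lognormal(self):
        rng = np.random.default_rng(12)
        values = np.concatenate([
            np.exp(rng.normal(np.log(0.12), 0.3, 1200)),
            np.exp(rng.normal(np.log(1.2), 0.3, 800)),
        ])
        peaks = find_peaks(values, seed=0)
        assert len(peaks) == 2
        assert peaks[0].mode_ks == pytest.approx(0.12, abs=0.05)
        assert peaks[1].mode_ks == pytest.approx(1.2, abs=0.2)
        assert peaks[0].interval[1] <= peaks[1].interval[0] + 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_single_lognormal_yields_one_peak(self, seed):
        rng = np.random.default_rng(100 + seed)
        values = np.exp(rng.normal(np.log(0.5), 0.3, 1500))
        peaks = find_peaks(values, seed=seed)
        assert len(peaks) == 1

    def test_out_of_range_values_ignored(self):
        rng = np.random.default_rng(1)
        inside = np.exp(rng.normal(np.log(0.3), 0.2, 500))
        outside = np.full(300, 5.0)  # beyond the saturation guard
        peaks = find_peaks(np.concatenate([inside, outside]), seed=0)
        assert sum(p.n_pairs for p in peaks) <= 500

    def test_too_few_values_is_error(self):
        with pytest.raises(ValueError, match="histogram"):
            find_peaks([0.1] * 10)


class TestAssignEvents:
    def test_young_block_labeled_xi(self):
        [b] = assign_events([block("s1", "s2", [], median_ks=0.12)])
        assert b.event_label == "xi"

    def test_old_block_labeled_eta(self):
        [b] = assign_events([block("s1", "s2", [], median_ks=1.2)])
        assert b.event_label == "eta"

    def test_intermediate_block_unlabeled(self):
        [b] = assign_events([block("s1", "s2", [], median_ks=0.7)])
        assert b.event_label is None

    def test_heterozygosity_guard_blocks_label(self):
        [b] = assign_events([block("s1", "s2", [], median_ks=0.05)])
        assert b.event_label is None
        [b] = assign_events([block("s1", "s2", [], median_ks=0.05)],
                            heterozygosity_guard=None)
        assert b.event_label == "xi"


class TestDateEvent:
    def test_arithmetic(self):
        lo, hi = date_event(0.13, 6.5e-9, 6.5e-9)
        assert lo == pytest.approx(10.0)
        assert hi == pytest.approx(10.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            date_event(0.0)
        with pytest.raises(ValueError):
            date_event(0.5, -1e-9, 1e-9)

    @pytest.mark.parametrize("ks", [0.05, 0.12, 0.5, 1.2, 2.0])
    def test_linearity(self, ks):
        lo1, hi1 = date_event(ks)
        lo2, hi2 = date_event(2 * ks)
        assert lo2 == pytest.approx(2 * lo1)
        assert hi2 == pytest.approx(2 * hi1)


class TestDepthProfile:
    def test_no_blocks_all_depth_zero(self):
        annot = make_annotation({"s1": 10})
        profile = depth_profile([], annot)
        assert profile.fraction_at_depth == {0: 1.0}

    def test_fractions_partition(self):
        annot = make_annotation({"s1": 20, "s2": 10})
        blocks = [
            block("s1", "s2", [("a", "b", 1, 1), ("c", "d", 10, 5)]),
            block("s1", "s1", [("e", "f", 5, 15), ("g", "h", 8, 18)]),
        ]
        profile = depth_profile(blocks, annot, axis="both", min_len=2)
        assert sum(profile.fraction_at_depth.values()) == pytest.approx(1.0, abs=1e-9)

    def test_two_round_lossfree_interior_depth(self):
        """After two loss-free WGDs every region has 3 homoeologous partners."""
        from wgdscan import SimConfig, WGDSpec, simulate_genome

        config = SimConfig(n_ancestral_genes=80, n_scaffolds=1,
                           events=(WGDSpec(0.6, 1.0), WGDSpec(0.2, 1.0)), seed=2)
        annot, store, truth = simulate_genome(config)
        from wgdscan import blocks_self

        hits = rank_hits(score_pairs(store, store, max_hits_per_query=6))
        blocks_found = blocks_self(annot, hits, min_len=5, n_perm=200, seed=0)
        profile = depth_profile(blocks_found, annot, axis="both", min_len=5)
        interior = [g.id for sc in annot.scaffolds
                    for g in annot.genes[sc][10:-10]]
        assert interior
        frac_deep = np.mean([profile.depth[g] >= 3 for g in interior])
        assert frac_deep >= 0.95


class TestReconstructAncestral:
    def test_lossfree_collapse_is_exact(self, tetraploid_lossfree):
        from wgdscan import blocks_self

        from wgdscan import block_divergence

        annot, store, truth = tetraploid_lossfree
        hits = rank_hits(score_pairs(store, store))
        found = blocks_self(annot, hits, min_len=5, n_perm=200, seed=3)
        labeled = assign_events([block_divergence(b, store) for b in found])
        ancestral = reconstruct_ancestral(
            [b for b in labeled if b.event_label == "xi"], annot)
        assert ancestral.n_genes == len(truth.ancestor_map)
        for copies in ancestral.copy_map().values():
            assert len(copies) == 2

    def test_no_extant_gene_claimed_twice(self, tetraploid_lossfree):
        from wgdscan import blocks_self

        annot, store, _ = tetraploid_lossfree
        hits = rank_hits(score_pairs(store, store))
        found = blocks_self(annot, hits, min_len=5, n_perm=200, seed=3)
        ancestral = reconstruct_ancestral(found, annot)
        seen = []
        for copies in ancestral.copy_map().values():
            seen.extend(copies)
        assert len(seen) == len(set(seen))
        assert ancestral.n_genes <= annot.n_genes

    def test_empty_blocks_empty_genome(self):
        annot = make_annotation({"s1": 5})
        ancestral = reconstruct_ancestral([], annot)
        assert ancestral.n_genes == 0


class TestOrthologPeak:
    def test_split_recovered_from_cross_blocks(self):
        annot_a, annot_b, store, orthologs = simulate_species_pair(
            n_genes=150, n_scaffolds=2, split_ks=0.8, seed=6)
        hits = score_pairs(store, store)
        # restrict to cross-species hits
        a_ids = {g.id for g in annot_a.all_genes()}
        from wgdscan import HitTable

        cross = HitTable(hits=[h for h in hits
                               if h.query in a_ids and h.subject not in a_ids])
        found = blocks_cross(annot_a, annot_b, cross, min_len=4, n_perm=200, seed=0)
        peak = ortholog_peak(found, store, seed=0)
        assert peak.mode_ks == pytest.approx(0.8, abs=0.1)

    def test_identical_genomes_peak_near_zero(self):
        annot_a, annot_b, store, _ = simulate_species_pair(
            n_genes=120, n_scaffolds=2, split_ks=0.05, seed=9)
        a_ids = {g.id for g in annot_a.all_genes()}
        from wgdscan import HitTable

        hits = score_pairs(store, store)
        cross = HitTable(hits=[h for h in hits
                               if h.query in a_ids and h.subject not in a_ids])
        found = blocks_cross(annot_a, annot_b, cross, min_len=4, n_perm=200, seed=0)
        peak = ortholog_peak(found, store, seed=0, ks_range=(0.001, 3.0))
        assert peak.mode_ks < 0.1
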