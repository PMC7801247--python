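import numpy as np
import pytest
from scipy.stats import spearmanr

from wgdscan import align_codons, block_divergence, four_dtv, ng86
from wgdscan.colinearity import ColinearBlock, GenePair
from wgdscan.genome import SequenceStore

from conftest import random_cds
from oracles import ng86_oracle

NG_FIELDS = ("S", "N", "Sd", "Nd", "ks", "ka")


def mutated_pair(rng, n_codons=80, n_subs=10):
    """A CDS and a copy with up to 2 random substitutions per codon."""
    from wgdscan._codon import SENSE_CODONS

    a = random_cds(n_codons, rng)
    b = list(a)
    for _ in range(n_subs):
        i = int(rng.integers(0, len(a)))
        b[i] = "ACGT"[rng.integers(4)]
        codon = "".join(b[3 * (i // 3) : 3 * (i // 3) + 3])
        if codon not in SENSE_CODONS:  # keep the frame stop-free
            b[i] = a[i]
    return a, "".join(b)


class TestNG86:
    def test_identical_sequences_are_zero(self, rng):
        cds = random_cds(60, rng)
        est = ng86(align_codons(cds, cds))
        assert est.Sd == est.Nd == 0
        assert est.ks == 0 and est.ka == 0
        assert not est.saturated

    def test_site_counts_partition_codons(self, rng):
        a, b = mutated_pair(rng)
        est = ng86(align_codons(a, b))
        assert est.S + est.N == pytest.approx(3 * est.n_codons, abs=1e-9)
        assert est.Sd <= est.S and est.Nd <= est.N

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_bruteforce_oracle(self, rng, trial):
        """Path-averaged counting must agree with explicit path enumeration."""
        a, b = mutated_pair(rng, n_codons=40 + trial, n_subs=6 + trial % 7)
        aln = align_codons(a, b)
        est = ng86(aln)
        ref = ng86_oracle(list(aln.codons_a), list(aln.codons_b))
        for f in NG_FIELDS:
            got, want = getattr(est, f), ref[f]
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-9), f

    def test_symmetry(self, rng):
        a, b = mutated_pair(rng)
        e1 = ng86(align_codons(a, b))
        e2 = ng86(align_codons(b, a))
        for f in NG_FIELDS + ("fourdtv", "n_4d_sites", "saturated"):
            assert getattr(e1, f) == getattr(e2, f)


class TestFourDtv:
    def pad(self, codon):
        # a shared constant context so the alignment is long enough to matter
        return "ATGGCT" * 3 + codon

    def test_transversion_at_fourfold_site(self):
        aln = align_codons(self.pad("GCT"), self.pad("GCA"))
        rate, n = four_dtv(aln)
        # GCT context codons are 4D sites too; the T->A column is the only change
        assert n >= 1
        assert rate == pytest.approx(1.0 / n)

    def test_transition_counts_zero(self):
        aln = align_codons(self.pad("GCT"), self.pad("GCC"))
        rate, n = four_dtv(aln)
        assert rate == 0.0 and n >= 1

    def test_no_shared_fourfold_sites_is_undefined(self):
        # AAA/AAG (Lys) are twofold; no 4D columns at all
        aln = align_codons("AAA" * 40, "AAG" * 40)
        rate, n = four_dtv(aln)
        assert rate is None and n == 0

    def test_tracks_ks_on_divergence_grid(self, rng):
        """4Dtv and Ks must rise together: both proxy the same divergence."""
        from wgdscan.simulate import _mutate
        from wgdscan._codon import SENSE_CODONS

        ks_grid = [0.05, 0.2, 0.5, 0.9, 1.5]
        ks_est, tv_est = [], []
        for ks in ks_grid:
            for _ in range(20):
                a = rng.integers(0, len(SENSE_CODONS), 200)
                b = a.copy()
                _mutate(b, ks, 0.1, rng)
                cds_a = "".join(SENSE_CODONS[i] for i in a)
                cds_b = "".join(SENSE_CODONS[i] for i in b)
                est = ng86(align_codons(cds_a, cds_b))
                if est.ks is not None and est.fourdtv is not None and not est.saturated:
                    ks_est.append(est.ks)
                    tv_est.append(est.fourdtv)
        rho = spearmanr(ks_est, tv_est).statistic
        assert rho > 0.8


class TestAlignCodons:
    def test_identical_no_masking(self, rng):
        cds = random_cds(100, rng)
        aln = align_codons(cds, cds)
        assert aln.n_codons == 100 and aln.n_masked == 0

    def test_internal_insertion_masks_one_column(self, rng):
        cds = random_cds(60, rng)
        insert = cds[:90] + "GCT" + cds[90:]
        aln = align_codons(cds, insert)
        assert aln.n_codons == 60
        assert aln.n_masked == 1

    def test_short_random_pair_flagged_unalignable(self, rng):
        a = random_cds(40, np.random.default_rng(1))
        b = random_cds(40, np.random.default_rng(2))
        aln = align_codons(a, b)
        assert aln.n_codons <= 40
        if aln.n_codons < 30:
            assert aln.unalignable


class TestBlockDivergence:
    def make_block(self, pairs):
        return ColinearBlock(
            scaffold_a="x", scaffold_b="y",
            pairs=tuple(GenePair(a, b, i + 1, i + 1) for i, (a, b) in enumerate(pairs)),
            orientation="parallel",
        )

    def test_median_over_usable_pairs(self, rng):
        store = SequenceStore()
        pairs = []
        for i, ks in enumerate([0.1, 0.12, 0.9]):
            from wgdscan.simulate import _mutate
            from wgdscan._codon import SENSE_CODONS

            a = rng.integers(0, len(SENSE_CODONS), 150)
            b = a.copy()
            _mutate(b, ks, 0.1, rng)
            store.add(f"a{i}", "".join(SENSE_CODONS[j] for j in a))
            store.add(f"b{i}", "".join(SENSE_CODONS[j] for j in b))
            pairs.append((f"a{i}", f"b{i}"))
        block = block_divergence(self.make_block(pairs), store)
        assert block.median_ks == pytest.approx(0.12, rel=0.5)

    def test_all_pairs_missing_gives_undefined_median(self):
        block = block_divergence(self.make_block([("nope1", "nope2")]), SequenceStore())
        assert block.median_ks is None and block.median_4dtv is None

    def test_single_pair_median_is_that_ks(self, tiny_store):
        block = block_divergence(self.make_block([("a", "b")]), tiny_store)
        est = ng86(align_codons(tiny_store.cds("a"), tiny_store.cds("b")))
        assert block.median_ks == pytest.approx(est.ks)
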