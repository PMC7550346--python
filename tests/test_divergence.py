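"""Alignment statistics: nucleotide diversity against a brute-force
oracle, sliding windows, distance models (TN93 frozen against values
computed independently with ape::dist.dna), and Nei-Gojobori counting
against an exhaustive pathway-enumeration oracle."""

import itertools
import math

import numpy as np
import pytest

from mitocomp.codons import CODON_TO_AA, STOP_CODONS
from mitocomp.divergence import (Alignment, distance_matrix, jukes_cantor,
                                 ng86_pair, nucleotide_diversity, p_distance,
                                 pairwise_distance, sliding_window_diversity,
                                 tn93_distance, ungapped_codon_alignment)

# ------------------------------------------------------------- oracles ----


def pi_oracle(rows):
    """All-pairs brute force: mean of per-pair diff fractions with
    pairwise deletion.  Independent of the library implementation."""
    vals = []
    for r1, r2 in itertools.combinations(rows, 2):
        diffs = sites = 0
        for a, b in zip(r1, r2):
            if a in "ACGT" and b in "ACGT":
                sites += 1
                diffs += a != b
        if sites:
            vals.append(diffs / sites)
    return sum(vals) / len(vals) if vals else math.nan


def ng86_oracle(cds1, cds2):
    """Independent Nei-Gojobori implementation.

    Sites: per codon position, the fraction of the three single-base
    changes that are synonymous (stop-producing changes count as
    nonsynonymous), averaged over the two codons.  Differences: average
    over all orderings of the differing positions, excluding orderings
    that pass through a stop (all orderings if every one is blocked).
    """
    def syn_sites(codon):
        syn = 0.0
        for pos in range(3):
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1:]
                if mut not in STOP_CODONS and \
                        CODON_TO_AA[mut] == CODON_TO_AA[codon]:
                    syn += 1 / 3
        return syn

    def path_diffs(c1, c2):
        positions = [i for i in range(3) if c1[i] != c2[i]]
        if not positions:
            return 0.0, 0.0
        ok, blocked = [], []
        for order in itertools.permutations(positions):
            cur, syn, non, hit_stop = c1, 0, 0, False
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if nxt in STOP_CODONS:
                    hit_stop = True
                    non += 1  # amino acid necessarily changes
                elif CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                    syn += 1
                else:
                    non += 1
                cur = nxt
            (blocked if hit_stop else ok).append((syn, non))
        paths = ok or blocked
        return (sum(p[0] for p in paths) / len(paths),
                sum(p[1] for p in paths) / len(paths))

    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds1), 3):
        a, b = cds1[i:i + 3], cds2[i:i + 3]
        if (set(a) | set(b)) - set("ACGT") or \
                a in STOP_CODONS or b in STOP_CODONS:
            continue
        S += (syn_sites(a) + syn_sites(b)) / 2
        N += 3 - (syn_sites(a) + syn_sites(b)) / 2
        sd, nd = path_diffs(a, b)
        Sd += sd
        Nd += nd
    return N, S, Nd, Sd


def random_codon_pair(rng, n_codons):
    def codon():
        while True:
            c = "".join(rng.choice(list("ACGT"), size=3))
            if c not in STOP_CODONS:
                return c
    c1 = [codon() for _ in range(n_codons)]
    c2 = []
    for c in c1:
        if rng.random() < 0.4:  # diverge some codons, up to 3 changes
            c2.append(codon())
        else:
            c2.append(c)
    return "".join(c1), "".join(c2)


# ---------------------------------------------------------------- pi ------

class TestNucleotideDiversity:
    def test_identical_rows(self):
        aln = Alignment(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        assert nucleotide_diversity(aln) == 0.0

    def test_direct_count(self):
        aln = Alignment(["a", "b"], ["AAAAAAAAAA", "AAAAAAAACC"])
        assert nucleotide_diversity(aln) == pytest.approx(0.2)

    def test_matches_bruteforce_on_random_alignments(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(2, 7))
            L = int(rng.integers(10, 120))
            rows = ["".join(rng.choice(list("ACGT-N"), size=L,
                                       p=[.23, .23, .23, .23, .05, .03]))
                    for _ in range(n)]
            aln = Alignment([f"r{i}" for i in range(n)], rows)
            expected = pi_oracle(rows)
            got = nucleotide_diversity(aln)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_row_order_and_gap_column_invariance(self):
        rows = ["ACGTAC", "ACGTTC", "AGGTAC"]
        aln = Alignment(["a", "b", "c"], rows)
        pi1 = nucleotide_diversity(aln)
        shuffled = Alignment(["c", "a", "b"],
                             [rows[2], rows[0], rows[1]])
        padded = Alignment(["a", "b", "c"], [r + "-" for r in rows])
        assert nucleotide_diversity(shuffled) == pytest.approx(pi1, abs=1e-15)
        assert nucleotide_diversity(padded) == pytest.approx(pi1, abs=1e-15)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(Alignment(["a"], ["ACGT"]))


class TestSlidingWindow:
    def test_constant_alignment_all_zero(self):
        aln = Alignment(["a", "b"], ["A" * 500, "A" * 500])
        values = sliding_window_diversity(aln)
        assert values and all(w.pi == 0.0 for w in values)
        assert values[0].start == 1 and values[0].end == 200
        assert values[1].start == 26 and values[1].end == 225

    def test_single_window_consistency(self):
        rows = ["ACGTACGTAC", "ACGTACGTCC"]
        aln = Alignment(["a", "b"], rows)
        values = sliding_window_diversity(aln, window=10, step=10)
        assert len(values) == 1
        assert values[0].pi == pytest.approx(nucleotide_diversity(aln))

    def test_windows_match_per_window_oracle(self):
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), size=730))
        rows = [base,
                base[:400] + "".join(rng.choice(list("ACGT"), size=330)),
                base[:200] + "".join(rng.choice(list("ACGT"), size=530))]
        aln = Alignment(["a", "b", "c"], rows)
        values = sliding_window_diversity(aln, window=200, step=25)
        for w in values:
            expected = pi_oracle([r[w.start - 1:w.end] for r in rows])
            assert w.pi == pytest.approx(expected, abs=1e-12)
        # trailing partial window is present and flagged
        assert values[-1].end == 730
        assert values[-1].partial

    def test_short_alignment_single_whole_window(self):
        aln = Alignment(["a", "b"], ["ACGT", "ACGA"])
        values = sliding_window_diversity(aln, window=200, step=25)
        assert len(values) == 1 and values[0].sites_used == 4


# ------------------------------------------------------------ distances ---

# Frozen oracle: ape::dist.dna(model="TN93"/"JC69", pairwise.deletion=TRUE)
# on each pair of the three rows below (so base frequencies are
# pair-specific, matching this implementation's convention).
_ROW_A = "ATGCGTACGTTAGCCGATAAATTTGGGCCCAAATTTGCGTGCACGTATGCATGCAAGGTTACGTACGATCG"
_ROW_B = "ATGCGAACGTTAGCCGATAAATTCGGGCCCTAATTTGCGTGCACGAATGCATGCAAGGTTACGAACGATCG"
_ROW_C = "ATACGTACGTTAGCCGTTAAATTTGGGCCCAAATTTGCGTGCACGTATGCTTGCAAGGTTACGTACGTTCG"
_APE_TN93 = {("A", "B"): 0.074395817591, ("A", "C"): 0.058822512146,
             ("B", "C"): 0.139107870762}
_APE_JC = {("A", "B"): 0.0739514826034, ("A", "C"): 0.0585663277286,
           ("B", "C"): 0.1388568248517}


class TestDistances:
    def test_identical_rows_zero_under_every_model(self):
        for model in ("p", "jc", "tn93"):
            assert pairwise_distance("ACGTAC", "ACGTAC", model) == 0.0

    def test_p_distance(self):
        assert p_distance("AAAA", "AAAT") == pytest.approx(0.25)

    def test_jc_closed_form(self):
        assert jukes_cantor(0.25) == pytest.approx(-0.75 * math.log(2 / 3))
        assert math.isnan(jukes_cantor(0.8))

    @pytest.mark.parametrize("pair,rows", [
        (("A", "B"), (_ROW_A, _ROW_B)),
        (("A", "C"), (_ROW_A, _ROW_C)),
        (("B", "C"), (_ROW_B, _ROW_C)),
    ])
    def test_tn93_and_jc_match_ape(self, pair, rows):
        assert tn93_distance(*rows) == pytest.approx(_APE_TN93[pair],
                                                     abs=1e-10)
        jc = jukes_cantor(p_distance(*rows))
        assert jc == pytest.approx(_APE_JC[pair], abs=1e-10)

    def test_matrix_symmetric_zero_diagonal(self):
        aln = Alignment(["A", "B", "C"], [_ROW_A, _ROW_B, _ROW_C])
        dm = distance_matrix(aln, "tn93")
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.allclose(np.diag(dm.matrix), 0.0)
        assert dm.value("A", "B") == pytest.approx(_APE_TN93[("A", "B")])

    def test_pairwise_deletion(self):
        # gapped/N sites are excluded from both numerator and denominator
        assert p_distance("ACGT-N", "ACTTAA") == pytest.approx(0.25)


# ---------------------------------------------------------------- NG86 ----

class TestNeiGojobori:
    def test_identical_pair(self):
        rates = ng86_pair("ATGAAACCC", "ATGAAACCC")
        assert rates.Nd == rates.Sd == 0.0
        assert rates.dN == rates.dS == 0.0

    def test_fourfold_synonymous_change(self):
        rates = ng86_pair("GGA", "GGG")
        assert rates.Sd == pytest.approx(1.0)
        assert rates.Nd == pytest.approx(0.0)
        assert rates.dN == 0.0

    def test_sites_total_three_per_codon(self):
        rates = ng86_pair("ATGAAACCC", "ATGAAACCC")
        assert rates.N_sites + rates.S_sites == pytest.approx(9.0)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        c1, c2 = random_codon_pair(rng, 60)
        a = ng86_pair(c1, c2)
        b = ng86_pair(c2, c1)
        assert (a.N_sites, a.S_sites, a.Nd, a.Sd) == \
            pytest.approx((b.N_sites, b.S_sites, b.Nd, b.Sd))

    def test_matches_pathway_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            c1, c2 = random_codon_pair(rng, 100)
            rates = ng86_pair(c1, c2)
            N, S, Nd, Sd = ng86_oracle(c1, c2)
            assert rates.N_sites == pytest.approx(N, abs=1e-10)
            assert rates.S_sites == pytest.approx(S, abs=1e-10)
            assert rates.Nd == pytest.approx(Nd, abs=1e-10)
            assert rates.Sd == pytest.approx(Sd, abs=1e-10)

    def test_synonymous_only_divergence_gives_zero_dn(self):
        # low divergence keeps every codon single-hit, where the pathway
        # count between synonymous-only descendants is purely synonymous
        from mitocomp.synthetic import EvolutionSpec, evolve_cds
        aln, _ = evolve_cds(EvolutionSpec(n_codons=300, divergence=0.06,
                                          omega=0.0, seed=9))
        row1, row2 = aln.rows
        assert all(sum(a != b for a, b in zip(row1[i:i + 3],
                                              row2[i:i + 3])) <= 1
                   for i in range(0, len(row1), 3))
        rates = ng86_pair(row1, row2)
        assert rates.Nd == 0.0
        assert rates.dN == 0.0
        assert rates.Sd > 0

    def test_gapped_and_stop_codons_excluded(self):
        rates = ng86_pair("ATG-AATAACCC", "ATGAAATAGCCC")
        # codon 2 has a gap, codon 3 is a stop in one row: both excluded
        assert rates.codons_compared == 2
        assert rates.excluded_codons == 2

    def test_undefined_ratio_flagged(self):
        rates = ng86_pair("ATGAAA", "ATGAAA")
        assert math.isnan(rates.ratio)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            ng86_pair("ATGAAA", "ATGAAACCC")


class TestCodonAlignment:
    def test_identity_alignment(self):
        aln = ungapped_codon_alignment(["a", "b"], ["ATGAAA", "ATGCCC"])
        assert aln.n_rows == 2 and aln.n_cols == 6

    def test_unequal_lengths_need_external_aligner(self):
        with pytest.raises(ValueError, match="align"):
            ungapped_codon_alignment(["a", "b"],
                                     ["A" * 1530, "A" * 1533])

    def test_single_row_allowed(self):
        aln = ungapped_codon_alignment(["a"], ["ATGAAA"])
        assert aln.n_rows == 1
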