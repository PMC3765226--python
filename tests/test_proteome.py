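"""ORF discovery, working-set selection, alignment search and RBH."""

import numpy as np
import pandas as pd
import pytest

from conftest import revcomp, sw_best_hits
from xerotome.proteome import (
    BestHit,
    OrfRecord,
    family_size_comparison,
    find_orfs,
    protein_similarity_search,
    rbh,
    reciprocal_best_hits,
    select_working_set,
)
from xerotome.synthetic import mutate_peptides, random_peptides


def _orf_oracle(seq, min_aa):
    """Independent 6-frame stop-to-stop scanner using an explicit codon
    walk (no shared translation path)."""
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    found = set()
    n = len(seq)
    for strand in "+-":
        work = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            aa, start_codon = [], frame
            j = frame
            while j + 3 <= n:
                codon = work[j:j + 3]
                if codon in table.stop_codons:
                    if len(aa) >= min_aa:
                        found.add((strand, frame, "".join(aa),
                                   start_codon, j + 3))
                    aa, start_codon = [], j + 3
                else:
                    aa.append(table.forward_table.get(codon, "X"))
                j += 3
            if len(aa) >= min_aa:
                found.add((strand, frame, "".join(aa), start_codon, j))
    return found


class TestFindOrfs:
    def test_constructed_single_orf(self):
        # TAA | 31 non-stop codons | TAG, frame 0, + strand
        body = "GCT" * 31
        seq = "TAA" + body + "TAG"
        orfs = [o for o in find_orfs("c", seq, min_aa=30) if o.strand == "+"
                and o.frame == 0]
        assert len(orfs) == 1
        assert orfs[0].aa_sequence == "A" * 31
        # CDS includes the closing stop codon
        assert (orfs[0].cds_start, orfs[0].cds_end) == (3, 3 + 93 + 3)

    def test_29_codons_rejected_at_min_30(self):
        seq = "TAA" + "ATG" + "GCT" * 28 + "TAG"  # 29 aa between stops
        hits = [o for o in find_orfs("c", seq, min_aa=30)
                if o.strand == "+" and o.frame == 0]
        assert hits == []

    def test_reverse_complement_mirrors_orf_set(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        fwd = find_orfs("c", seq, min_aa=15)
        rev = find_orfs("c", revcomp(seq), min_aa=15)
        flip = {"+": "-", "-": "+"}
        mirrored = {(flip[o.strand], o.aa_sequence,
                     len(seq) - o.cds_end, len(seq) - o.cds_start)
                    for o in rev}
        ours = {(o.strand, o.aa_sequence, o.cds_start, o.cds_end)
                for o in fwd}
        assert ours == mirrored

    def test_matches_sixframe_oracle_on_random_sequence(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        ours = {(o.strand, o.frame, o.aa_sequence) for o in
                find_orfs("c", seq, min_aa=20)}
        oracle = {(s, f, aa) for s, f, aa, _a, _b in _orf_oracle(seq, 20)}
        assert ours == oracle

    def test_deterministic_ordering_and_ids(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        orfs = find_orfs("c", seq, min_aa=10)
        keys = [(o.strand == "-", o.frame, o.cds_start) for o in orfs]
        assert keys == sorted(keys)
        assert [o.protein_id for o in orfs] == \
            [f"c_orf{i}" for i in range(1, len(orfs) + 1)]


class TestWorkingSet:
    def _orf(self, contig, aa_len, strand="+", start=0):
        return OrfRecord(f"{contig}_{strand}{start}", contig, strand, 0,
                         start, start + 3 * aa_len, "A" * aa_len)

    def test_cds_fraction_and_length_rules(self):
        versions = {"c": 1}
        lengths = {"c": 600}
        keep = self._orf("c", 120)  # 360 nt >= 300
        assert select_working_set([keep], versions, lengths) == [keep]
        short_cds = self._orf("c", 76)  # 228 nt < 300: fails CDS fraction
        assert select_working_set([short_cds], versions, lengths) == []
        short_aa = self._orf("c", 75)  # fails the 76-aa floor
        assert select_working_set([short_aa], versions, lengths) == []

    def test_minus_strand_and_non_v1_rejected(self):
        lengths = {"c": 600, "d": 600}
        minus = self._orf("c", 150, strand="-")
        assert select_working_set([minus], {"c": 1}, lengths) == []
        on_v2 = self._orf("d", 150)
        assert select_working_set([on_v2], {"d": 2}, lengths) == []

    def test_longest_per_contig_wins(self):
        versions, lengths = {"c": 1}, {"c": 600}
        a, b = self._orf("c", 110), self._orf("c", 150, start=30)
        assert select_working_set([a, b], versions, lengths) == [b]

    def test_idempotent_and_order_invariant(self):
        versions, lengths = {"c": 1, "d": 1}, {"c": 600, "d": 900}
        orfs = [self._orf("c", 120), self._orf("d", 200),
                self._orf("d", 180, start=60)]
        once = select_working_set(orfs, versions, lengths)
        twice = select_working_set(once, versions, lengths)
        reversed_in = select_working_set(orfs[::-1], versions, lengths)
        assert once == twice == reversed_in


class TestSimilaritySearch:
    def test_identical_sequence_is_best_hit(self):
        peps = random_peptides(5, (60, 100), seed=3)
        subjects = {f"s{i}": p for i, p in enumerate(peps)}
        hits = protein_similarity_search({"q": peps[2]}, subjects)
        assert hits["q"].subject_id == "s2"

    def test_no_hit_below_score_threshold(self):
        hits = protein_similarity_search({"q": "AAAA"}, {"s": "WWWW"},
                                         min_score=40.0)
        assert hits == {}

    def test_tie_goes_to_smallest_subject_id(self):
        pep = random_peptides(1, (80, 80), seed=4)[0]
        hits = protein_similarity_search({"q": pep},
                                         {"zz": pep, "aa": pep})
        assert hits["q"].subject_id == "aa"

    def test_exhaustive_matches_sw_oracle(self):
        a = {f"a{i:02d}": p for i, p in
             enumerate(random_peptides(15, (60, 150), seed=5))}
        b = {f"b{i:02d}": p for i, p in
             enumerate(random_peptides(15, (60, 150), seed=6))}
        ours = protein_similarity_search(a, b, mode="exhaustive")
        oracle = sw_best_hits(a, b)
        assert {q: (h.subject_id, h.score) for q, h in ours.items()} == oracle

    def test_seeded_recovers_planted_orthologs(self):
        peps = random_peptides(40, (80, 200), seed=7)
        a = {f"a{i:02d}": p for i, p in enumerate(peps)}
        b = {f"b{i:02d}": p for i, p in
             enumerate(mutate_peptides(peps, 0.05, seed=8))}
        hits = protein_similarity_search(a, b, mode="seeded")
        correct = sum(1 for q, h in hits.items()
                      if h.subject_id[1:] == q[1:])
        assert correct == len(a)


class TestRbh:
    def test_identical_proteomes_pair_perfectly(self):
        peps = random_peptides(12, (60, 120), seed=9)
        a = {f"a{i:02d}": p for i, p in enumerate(peps)}
        b = {f"b{i:02d}": p for i, p in enumerate(peps)}
        pairs = rbh(a, b)
        assert len(pairs) == 12
        assert all(p.protein_a[1:] == p.protein_b[1:] for p in pairs)
        assert all(p.identity == pytest.approx(1.0) for p in pairs)

    def test_non_mutual_best_is_dropped(self):
        ab = {"a1": BestHit("b1", 100.0)}
        ba = {"b1": BestHit("a2", 90.0)}
        assert reciprocal_best_hits(ab, ba) == []

    def test_mutual_best_is_paired(self):
        ab = {"a1": BestHit("b1", 100.0)}
        ba = {"b1": BestHit("a1", 95.0)}
        [pair] = reciprocal_best_hits(ab, ba)
        assert (pair.protein_a, pair.protein_b) == ("a1", "b1")

    def test_partial_matching_invariant(self):
        peps = random_peptides(20, (60, 150), seed=10)
        a = {f"a{i:02d}": p for i, p in enumerate(peps)}
        b = {f"b{i:02d}": p for i, p in
             enumerate(mutate_peptides(peps, 0.1, seed=11))}
        pairs = rbh(a, b)
        assert len({p.protein_a for p in pairs}) == len(pairs)
        assert len({p.protein_b for p in pairs}) == len(pairs)

    def test_symmetric_under_proteome_swap(self):
        peps = random_peptides(10, (60, 120), seed=12)
        a = {f"a{i:02d}": p for i, p in enumerate(peps)}
        b = {f"b{i:02d}": p for i, p in
             enumerate(mutate_peptides(peps, 0.05, seed=13))}
        fwd = {(p.protein_a, p.protein_b) for p in rbh(a, b)}
        rev = {(p.protein_b, p.protein_a) for p in rbh(b, a)}
        assert fwd == rev


class TestFamilySizes:
    def test_equal_counts_never_significant(self):
        table = pd.DataFrame(np.full((10, 8), 3.0),
                             columns=[f"sp{i}" for i in range(8)])
        result = family_size_comparison(table, ["sp0", "sp1"])
        assert (result.p_adjusted > 0.05).all()

    def test_expanded_family_has_minimal_adjusted_p(self):
        rng = np.random.default_rng(14)
        counts = rng.integers(2, 5, size=(12, 10)).astype(float)
        counts[3, :2] = 40.0  # focal species hugely expanded in family 3
        table = pd.DataFrame(counts, columns=[f"sp{i}" for i in range(10)])
        result = family_size_comparison(table, ["sp0", "sp1"])
        assert result.p_adjusted.idxmin() == 3

    def test_adjustment_is_bh_of_raw(self):
        from xerotome.stats import bh_adjust

        rng = np.random.default_rng(15)
        table = pd.DataFrame(rng.integers(1, 10, size=(6, 6)).astype(float),
                             columns=[f"sp{i}" for i in range(6)])
        result = family_size_comparison(table, ["sp0"])
        np.testing.assert_allclose(result.p_adjusted,
                                   bh_adjust(result.p_raw))
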