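"""Six-frame translation, local alignment, E-values and genome search."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cemag.homology import (
    SearchParams, bitscore, evalue, local_align, scoring_matrix,
    search_genome, six_frame_translate,
)
from cemag.records import GenomeRecord
from cemag.simulate import mutate_protein, reverse_translate, revcomp

from oracles import brute_force_smith_waterman

AAS = list("ARNDCQEGHILKMFPSTWYV")
NTS = list("ACGT")


class TestSixFrameTranslate:
    def test_standard_code(self):
        assert six_frame_translate("ATGAAA")[1] == "MK"

    def test_stop_codons_retained(self):
        assert six_frame_translate("ATGTAA")[1] == "M*"

    def test_n_translates_to_x(self):
        assert six_frame_translate("ATGANA")[1] == "MX"

    def test_frame_lengths(self):
        L = 100
        seq = "".join(np.random.default_rng(0).choice(NTS, L))
        frames = six_frame_translate(seq)
        assert len(frames[1]) == L // 3
        assert len(frames[2]) == (L - 1) // 3
        assert len(frames[3]) == (L - 2) // 3

    @given(st.text(alphabet="ACGT", min_size=3, max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_reverse_complement_consistency(self, seq):
        # frame -1 of S equals frame +1 of revcomp(S)
        assert six_frame_translate(seq)[-1] == six_frame_translate(revcomp(seq))[1]

    def test_empty_sequence(self):
        assert all(f == "" for f in six_frame_translate("").values())


class TestLocalAlign:
    def test_self_alignment_is_perfect(self):
        q = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        aln = local_align(q, q)
        assert aln.identities == len(q)
        assert aln.qstart == aln.sstart == 1
        assert aln.qend == aln.send == len(q)
        assert 100.0 * aln.identities / aln.aln_length == 100.0

    def test_no_positive_region_gives_none(self):
        # tryptophan vs glycine scores negative everywhere in BLOSUM62
        assert local_align("WWWW", "GGGG") is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "MKT")

    def test_matches_brute_force_on_random_pairs(self):
        """Seeded-aligner optimum equals textbook Gotoh DP on random pairs,
        including pairs with an embedded mutated fragment."""
        rng = np.random.default_rng(7)
        sub = scoring_matrix()
        for trial in range(40):
            nq = int(rng.integers(5, 80))
            ns = int(rng.integers(5, 120))
            q = "".join(rng.choice(AAS, nq))
            s = "".join(rng.choice(AAS, ns))
            if trial % 3 == 0 and nq > 20:
                frag = mutate_protein(q[: nq // 2], 0.7, rng)
                pos = int(rng.integers(0, ns - len(frag))) if ns > len(frag) else 0
                s = s[:pos] + frag + s[pos + len(frag):]
            aln = local_align(q, s)
            got = 0 if aln is None else aln.score
            assert got == brute_force_smith_waterman(q, s, sub)

    def test_gap_cost_accounting(self):
        # one internal deletion: score = matches - (open + extend)
        q = "MKTAYIAKQRDEFGHIKLMN"
        s = q[:10] + q[12:]  # remove 2 residues
        aln = local_align(q, s)
        assert aln.aln_length == len(q)
        assert aln.identities == len(q) - 2


class TestEvalue:
    def test_unit_expectation(self):
        # bitscore such that m*n*2^-bits = 1
        m, n = 300, 1_000_000
        bits = math.log2(m * n)
        assert evalue(bits, m, n) == pytest.approx(1.0)

    def test_doubling_database_doubles_e(self):
        e1 = evalue(50.0, 300, 10**6)
        e2 = evalue(50.0, 300, 2 * 10**6)
        assert e2 == pytest.approx(2 * e1)

    def test_closed_form(self):
        # E = m*n*2^-((lambda*S - ln K)/ln 2), hand-evaluated independently
        params = SearchParams()
        raw, m, n = 100, 300, 10**6
        bits = (0.267 * raw - math.log(0.041)) / math.log(2)
        expected = m * n * 2.0 ** (-bits)
        assert evalue(bitscore(raw, params), m, n) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_in_bitscore(self):
        assert evalue(60, 300, 10**6) < evalue(50, 300, 10**6)


def _genome_with_gene(catalog_seq, identity, seed, contig_length=6000):
    """Plant one mutated, reverse-translated gene mid-contig, random strand."""
    rng = np.random.default_rng(seed)
    mutated = mutate_protein(catalog_seq, identity, rng)
    gene = reverse_translate(mutated, rng)
    if rng.random() < 0.5:
        gene = revcomp(gene)
    bg = "".join(rng.choice(NTS, contig_length))
    pos = int(rng.integers(0, contig_length - len(gene)))
    contig = bg[:pos] + gene + bg[pos + len(gene):]
    return GenomeRecord("G", {"c1": contig})


class TestSearchGenome:
    def test_embedded_gene_found_and_low_identity_absent(self):
        rng = np.random.default_rng(3)
        query = "".join(rng.choice(AAS, 300))
        high = _genome_with_gene(query, 0.9, seed=11)
        low = _genome_with_gene(query, 0.15, seed=12)
        params = SearchParams()
        hits_high = search_genome({"q1": query}, high, params)
        hits_low = search_genome({"q1": query}, low, params)
        assert [h.query_id for h in hits_high] == ["q1"]
        assert hits_high[0].pident > 80
        assert hits_high[0].qcovhsp > 95
        assert hits_low == []

    def test_filters_are_strict_thresholds(self, catalog, ice_genome):
        genome, truth = ice_genome
        hits = search_genome(catalog, genome, SearchParams())
        for h in hits:
            assert h.evalue < 1e-10
            assert h.pident > 25
            assert h.qcovhsp > 70

    def test_tightening_thresholds_never_adds_hits(self, catalog, ice_genome):
        genome, _ = ice_genome
        loose = {h.query_id for h in search_genome(catalog, genome, SearchParams())}
        tight = {h.query_id for h in search_genome(
            catalog, genome, SearchParams(pident_min=60, qcovhsp_min=90, evalue_max=1e-50))}
        assert tight <= loose

    def test_strand_symmetry(self, catalog, ice_genome):
        """Reverse-complementing every contig flips frames/coordinates but
        preserves which queries are found and their scores."""
        genome, _ = ice_genome
        flipped = GenomeRecord(
            genome.genome_id, {cid: revcomp(s) for cid, s in genome.contigs.items()},
        )
        h1 = {h.query_id: h for h in search_genome(catalog, genome, SearchParams())}
        h2 = {h.query_id: h for h in search_genome(catalog, flipped, SearchParams())}
        assert h1.keys() == h2.keys()
        for qid in h1:
            a, b = h1[qid], h2[qid]
            assert a.raw_score == b.raw_score
            L = len(genome.contigs[a.contig_id])
            assert (b.sstart, b.send) == (L - a.send + 1, L - a.sstart + 1)

    def test_zero_contig_genome(self, catalog):
        assert search_genome(catalog, GenomeRecord("empty", {})) == []

    def test_one_hit_per_query(self, catalog, ice_genome):
        genome, _ = ice_genome
        hits = search_genome(catalog, genome, SearchParams())
        ids = [h.query_id for h in hits]
        assert len(ids) == len(set(ids))
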