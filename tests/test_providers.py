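import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hostscope import providers as pv


# ---------------------------------------------------------------------------
# blast parsing / aggregation
# ---------------------------------------------------------------------------

def _blast_row(virus="v1", subject="G1", ident=95.0, length=800, evalue=1e-10):
    return (f"{virus}\t{subject}\t{ident}\t{length}\t3\t0\t1\t{length}\t"
            f"1\t{length}\t{evalue}\t1200")


class TestBlastParsing:
    def test_filter_cascade(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("\n".join([
            _blast_row(ident=79.0),            # identity below 80 -> dropped
            _blast_row(length=400),            # alignment below 500 nt -> dropped
            _blast_row(evalue=0.1),            # e-value above 1e-3 -> dropped
            _blast_row(ident=95.0, length=800, evalue=1e-10),
        ]) + "\n")
        out = pv.parse_blast_tab(p)
        assert len(out) == 1
        assert out.iloc[0]["identity"] == 95.0
        assert out.iloc[0]["length"] == 800

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(_blast_row() + "\nnot\tenough\tcolumns\n")
        with pytest.raises(ValueError, match="line 2"):
            pv.parse_blast_tab(p)

    def test_contig_map_resolution(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(_blast_row(subject="ctg7") + "\n")
        out = pv.parse_blast_tab(p, contig_map={"ctg7": "G9"})
        assert list(out["genome_id"]) == ["G9"]
        with pytest.raises(KeyError, match="ctg7"):
            pv.parse_blast_tab(p, contig_map={})
        with pytest.warns(UserWarning):
            out = pv.parse_blast_tab(p, contig_map={}, on_unknown="skip")
        assert out.empty


class TestAggregateBlast:
    def test_summary_arithmetic(self):
        hsps = pd.DataFrame({
            "virus_id": ["v", "v"], "genome_id": ["G", "G"],
            "identity": [90.0, 100.0], "length": [600, 1400],
        })
        out = pv.aggregate_blast(hsps)
        assert len(out) == 1
        r = out.iloc[0]
        assert r["n_matches"] == 2
        assert r["mean_identity"] == pytest.approx(95.0)
        assert r["total_aln_len"] == 2000

    def test_singleton_and_grouping(self):
        hsps = pd.DataFrame({
            "virus_id": ["v", "v"], "genome_id": ["G1", "G2"],
            "identity": [88.0, 91.0], "length": [700, 900],
        })
        out = pv.aggregate_blast(hsps)
        assert len(out) == 2  # no cross-genome pooling
        assert set(out["genome_id"]) == {"G1", "G2"}

    def test_conserves_counts_and_length(self):
        rng = np.random.default_rng(0)
        hsps = pd.DataFrame({
            "virus_id": rng.choice(["v1", "v2"], 50),
            "genome_id": rng.choice(["G1", "G2", "G3"], 50),
            "identity": rng.uniform(80, 100, 50),
            "length": rng.integers(500, 5000, 50),
        })
        out = pv.aggregate_blast(hsps)
        assert out["n_matches"].sum() == len(hsps)
        assert out["total_aln_len"].sum() == hsps["length"].sum()


# ---------------------------------------------------------------------------
# spacer complexity
# ---------------------------------------------------------------------------

class TestSpacerComplexity:
    def test_skew_branch(self):
        assert pv.spacer_complexity("A" * 30) == pytest.approx(1.1)

    def test_entropy_branch(self):
        assert pv.spacer_complexity("AT" * 15) == pytest.approx(-2.0)
        assert pv.spacer_complexity("G" * 30) == pytest.approx(-4.0)

    def test_inverted_variant(self):
        cfg = pv.ComplexityConfig(cwf_variant="inverted")
        # homopolymer G: entropy 0 -> (2-0)*2 = 4 (flagged as low complexity)
        assert pv.spacer_complexity("G" * 30, cfg) == pytest.approx(4.0)

    def test_at_content_variant(self):
        cfg = pv.ComplexityConfig(skew_variant="at_content")
        # AT-only sequence: AT fraction 1 > 0.65 -> 1 + 0.1
        assert pv.spacer_complexity("ATAT" * 5, cfg) == pytest.approx(1.1)

    def test_reversal_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            assert pv.spacer_complexity(seq) == pytest.approx(
                pv.spacer_complexity(seq[::-1]))

    def test_empty_or_all_n_rejected(self):
        with pytest.raises(ValueError):
            pv.spacer_complexity("NNN")


# ---------------------------------------------------------------------------
# spacer matching
# ---------------------------------------------------------------------------

def brute_force_placements(virus: str, spacer: str, max_mm: int):
    """Independent oracle: enumerate every placement, both strands, keeping
    each placement once with its minimum-mismatch strand (+ on ties)."""
    def hamming(window, seq):
        return sum(1 for a, b in zip(window, seq)
                   if a != b or a == "N" or b == "N")

    rc = pv.reverse_complement(spacer)
    out = []
    for pos in range(len(virus) - len(spacer) + 1):
        window = virus[pos:pos + len(spacer)]
        fwd, rev = hamming(window, spacer), hamming(window, rc)
        mm, strand = (fwd, "+") if fwd <= rev else (rev, "-")
        if mm <= max_mm:
            out.append((len(spacer), mm, strand, pos))
    return sorted(out)


class TestMatchSpacers:
    def test_exact_substring(self):
        hits = pv.match_spacers("TTACGTTT", [("s1", "ACGT")], max_mm=0)
        assert len(hits) == 1
        r = hits.iloc[0]
        assert (r["mismatches"], r["strand"], r["virus_pos"]) == (0, "+", 2)

    def test_reverse_strand(self):
        hits = pv.match_spacers("GGGTTTGG", [("s1", "AAAC")], max_mm=0)
        assert len(hits) == 1
        assert hits.iloc[0]["strand"] == "-"

    def test_single_mismatch(self):
        hits = pv.match_spacers("TTACCTTT", [("s1", "ACGT")], max_mm=1)
        plus = hits[hits["strand"] == "+"]
        assert len(plus) == 1
        assert plus.iloc[0]["mismatches"] == 1

    def test_spacer_longer_than_virus_is_no_hit(self):
        assert pv.match_spacers("ACG", [("s1", "ACGTACGT")], max_mm=7).empty

    def test_n_counts_as_mismatch(self):
        hits = pv.match_spacers("AANT", [("s1", "AANT")], max_mm=7)
        exact = hits[(hits["strand"] == "+") & (hits["virus_pos"] == 0)]
        assert exact.iloc[0]["mismatches"] == 1

    def test_equals_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            virus = "".join(rng.choice(list("ACGTN"), size=int(rng.integers(20, 120)),
                                       p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            spacer = "".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 30))))
            max_mm = int(rng.integers(0, 8))
            got = pv.match_spacers(virus, [("s", spacer)], max_mm=max_mm)
            got_set = sorted(zip(got["spacer_len"], got["mismatches"],
                                 got["strand"], got["virus_pos"]))
            assert got_set == brute_force_placements(virus, spacer, max_mm)

    def test_best_hit_tie_break(self):
        hits = pd.DataFrame({
            "spacer_id": ["s", "s"], "spacer_len": [4, 4],
            "mismatches": [1, 1], "strand": ["-", "+"], "virus_pos": [3, 9],
        })
        best = pv.best_spacer_hits(hits)
        assert len(best) == 1
        assert best.iloc[0]["strand"] == "+"   # + strand preferred on ties


class TestFilterSpacerHits:
    SEQS = {"short": "ACGTACGTACGTACGTACGTACGT",        # 24 nt
            "good": "ACGTTGCAATCGGATCCATGCAATCGAT",     # 28 nt, complex
            "poly": "A" * 30}                           # complexity 1.1

    def _hits(self):
        return pd.DataFrame({
            "virus_id": "v", "genome_id": "G",
            "spacer_id": ["short", "good", "good", "poly"],
            "spacer_len": [24, 28, 28, 30],
            "mismatches": [0, 8, 2, 0],
            "strand": "+", "virus_pos": 0,
        })

    def test_cascade(self):
        out = pv.filter_spacer_hits(self._hits(), self.SEQS)
        # 24 nt spacer dropped; 8-mismatch hit dropped; homopolymer dropped
        assert len(out) == 1
        assert out.iloc[0]["spacer_id"] == "good"
        assert out.iloc[0]["mismatches"] == 2

    def test_subset_and_idempotent(self):
        hits = self._hits()
        once = pv.filter_spacer_hits(hits, self.SEQS)
        twice = pv.filter_spacer_hits(once, self.SEQS)
        assert len(once) <= len(hits)
        pd.testing.assert_frame_equal(once, twice)


# ---------------------------------------------------------------------------
# Markov model scorer
# ---------------------------------------------------------------------------

class TestMarkov:
    def test_order0_base_frequencies(self):
        m = pv.train_markov("AAAT", order=0, pseudocount=1.0)
        probs = m.prob_table()[0]
        assert probs[0] == pytest.approx((3 + 1) / (4 + 4))  # A
        assert probs[3] == pytest.approx((1 + 1) / (4 + 4))  # T

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        m = pv.train_markov(seq, order=2)
        assert np.allclose(m.prob_table().sum(axis=1), 1.0)

    def test_unseen_context_finite(self):
        m = pv.train_markov("AAAAAAAAAA", order=2, pseudocount=0.5)
        s = pv.markov_score("GCGCGC", m)
        assert np.isfinite(s)

    def test_pvalue_at_null_mean_is_half(self):
        m = pv.train_markov("ACGT" * 100, order=1, seed=4)
        assert pv.markov_pvalue(m.null_mean, m) == pytest.approx(0.5)
        assert pv.markov_pvalue(m.null_mean + 50 * m.null_sd, m) < 1e-6

    def test_composition_bias_recovered(self):
        rng = np.random.default_rng(9)
        at_host = "".join(rng.choice(list("ACGT"), size=2000, p=[0.4, 0.1, 0.1, 0.4]))
        gc_host = "".join(rng.choice(list("ACGT"), size=2000, p=[0.1, 0.4, 0.4, 0.1]))
        m_at = pv.train_markov(at_host, order=2, genome_id="AT", seed=1)
        m_gc = pv.train_markov(gc_host, order=2, genome_id="GC", seed=1)
        wins = 0
        for _ in range(20):
            virus = "".join(rng.choice(list("ACGT"), size=600,
                                       p=[0.4, 0.1, 0.1, 0.4]))
            if pv.markov_score(virus, m_at) > pv.markov_score(virus, m_gc):
                wins += 1
        assert wins > 10  # majority of replicates

    def test_order_validation(self):
        with pytest.raises(ValueError):
            pv.train_markov("ACGT", order=-1)
        m = pv.train_markov("ACGTACGT", order=0)
        with pytest.raises(ValueError):
            pv.markov_score("", m)


# ---------------------------------------------------------------------------
# generic tables
# ---------------------------------------------------------------------------

class TestScoreTables:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("virus_id\tgenome_id\tscore\nv1\tG1\t0.5\nv1\tG2\t0.9\nv2\tG1\t0.1\n")
        out = pv.parse_score_table(p, "s2star_like")
        assert len(out) == 3

    def test_dedupe_keeps_best_orientation(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("virus_id\tgenome_id\tscore\nv1\tG1\t0.5\nv1\tG1\t0.9\n")
        with pytest.warns(UserWarning):
            out = pv.parse_score_table(p, "s2star_like")
        assert out.iloc[0]["score"] == 0.9
        # lower-better tool keeps the smaller value
        p2 = tmp_path / "t2.tsv"
        p2.write_text("virus_id\tgenome_id\tscore\nv1\tG1\t0.5\nv1\tG1\t0.01\n")
        with pytest.warns(UserWarning):
            out2 = pv.parse_score_table(p2, "kmer_model")
        assert out2.iloc[0]["pvalue"] == 0.01

    def test_non_numeric_score_reports_line(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("virus_id\tgenome_id\tscore\nv1\tG1\tNA\n")
        with pytest.raises(ValueError, match="line 2"):
            pv.parse_score_table(p, "php_like")

    def test_unknown_tool_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("virus_id\tgenome_id\tscore\nv1\tG1\t1\n")
        with pytest.raises(ValueError, match="tool"):
            pv.parse_score_table(p, "mystery")

    def test_phage_based(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("virus_id\tpredicted_label\tscore\nv1\tLx\t0.8\nv2\tLy\t0.3\n")
        out = pv.parse_phage_based(p)
        assert list(out["predicted_label"]) == ["Lx", "Ly"]
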