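"""Flank extraction, IUPAC motif scanning, Fisher enrichment and BH FDR."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import reverse_complement
from hypothesis import given, settings
from hypothesis import strategies as st

from splicetime.rbp_enrichment import (
    IUPAC,
    ExonInterval,
    MotifDefinition,
    RegionSet,
    bh_fdr,
    bundled_motifs,
    crossref_interactome,
    extract_flanks,
    fisher_enrichment,
    scan_motifs,
)


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive two-sided Fisher p: sum of hypergeometric probabilities of
    all tables with the same margins that are no more probable than the
    observed one."""
    n1, n2, k = a + b, c + d, a + c
    lo, hi = max(0, k - n2), min(n1, k)
    weights = [comb(n1, x) * comb(n2, k - x) for x in range(lo, hi + 1)]
    total = sum(weights)
    observed = weights[a - lo]
    return sum(w for w in weights if w <= observed * (1 + 1e-9)) / total


class TestExtractFlanks:
    def test_plus_strand_window_lengths(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=2000))}
        ex = ExonInterval("e1", "chr1", 1000, 1100, "+")
        (region,) = extract_flanks([ex], genome)
        assert len(region.upstream) == 200
        assert len(region.exon) == 100
        assert len(region.downstream) == 200
        assert region.exon == genome["chr1"][1000:1100]
        assert region.upstream == genome["chr1"][800:1000]

    def test_minus_strand_is_reverse_complement(self, rng):
        plus = "".join(rng.choice(list("ACGT"), size=1000))
        genome_plus = {"chr1": plus}
        genome_minus = {"chr1": reverse_complement(plus)}
        ex_plus = ExonInterval("e1", "chr1", 400, 460, "+")
        # same locus coordinates on the flipped genome
        ex_minus = ExonInterval("e1", "chr1", 1000 - 460, 1000 - 400, "-")
        (r_plus,) = extract_flanks([ex_plus], genome_plus)
        (r_minus,) = extract_flanks([ex_minus], genome_minus)
        assert r_plus.exon == r_minus.exon
        assert r_plus.upstream == r_minus.upstream
        assert r_plus.downstream == r_minus.downstream

    def test_short_intron_clips_flank(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=1500))}
        ex = ExonInterval("e1", "chr1", 500, 600, "+", left_bound=450)
        (region,) = extract_flanks([ex], genome)
        assert len(region.upstream) == 50

    def test_chromosome_end_clips_flank(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=700))}
        (region,) = extract_flanks([ExonInterval("e1", "chr1", 500, 600, "+")], genome)
        assert len(region.downstream) == 100

    def test_interval_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            extract_flanks([ExonInterval("e1", "chr1", 500, 900, "+")], {"chr1": "A" * 600})

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError):
            ExonInterval("e1", "chr1", 0, 10, "?")


class TestScanMotifs:
    def region(self, exon, up="", down=""):
        return RegionSet("e1", exon=exon, upstream=up, downstream=down)

    def test_exact_match_found_once(self):
        motif = MotifDefinition("RBFOX2", ("TGCATG",))
        presence, counts = scan_motifs([self.region("AAATGCATGAAA")], [motif])
        assert bool(presence.loc["e1", "RBFOX2"])
        assert counts.loc["e1", "RBFOX2"] == 1

    def test_iupac_mismatch(self):
        motif = MotifDefinition("NOVA-type", ("YCAY",))
        presence, _ = scan_motifs([self.region("ACAG")], [motif])
        assert not bool(presence.loc["e1", "NOVA-type"])

    def test_iupac_degenerate_matches_counted(self):
        motif = MotifDefinition("NOVA-type", ("YCAY",))
        _, counts = scan_motifs([self.region("TCATTCAC")], [motif])
        assert counts.loc["e1", "NOVA-type"] == 2

    def test_overlapping_matches_counted(self):
        motif = MotifDefinition("HNRNPC", ("TTTT",))
        _, counts = scan_motifs([self.region("TTTTTT")], [motif])
        assert counts.loc["e1", "HNRNPC"] == 3

    def test_n_in_sequence_never_matches(self):
        motif = MotifDefinition("X", ("NNNN",))
        presence, _ = scan_motifs([self.region("ANNA")], [motif])
        assert not bool(presence.loc["e1", "X"])

    def test_presence_pools_windows(self):
        motif = MotifDefinition("RBFOX2", ("TGCATG",))
        presence, _ = scan_motifs(
            [self.region("AAAA", up="TGCATG", down="CCCC")], [motif]
        )
        assert bool(presence.loc["e1", "RBFOX2"])

    def test_empty_motif_list_rejected(self):
        with pytest.raises(ValueError):
            scan_motifs([self.region("ACGT")], [])

    def test_bundled_motif_set_has_46_rbps(self):
        motifs = bundled_motifs()
        assert len(motifs) == 46
        assert all(
            all(b in IUPAC for b in c) for m in motifs for c in m.consensus
        )

    def brute_force_count(self, seq, consensus):
        hits = 0
        k = len(consensus)
        for i in range(len(seq) - k + 1):
            if all(seq[i + j] in IUPAC[consensus[j]] for j in range(k)):
                hits += 1
        return hits

    @given(
        seq=st.text(alphabet="ACGTN", min_size=1, max_size=60),
        consensus=st.text(alphabet=list(IUPAC), min_size=1, max_size=6),
    )
    @settings(max_examples=300, deadline=None)
    def test_property_matches_sliding_window_oracle(self, seq, consensus):
        motif = MotifDefinition("X", (consensus,))
        _, counts = scan_motifs([self.region(seq)], [motif])
        assert counts.loc["e1", "X"] == self.brute_force_count(seq, consensus)


def presence_frame(a, b, c, d, rbp="X"):
    """Presence matrix realising the 2x2 table a/b (affected) c/d (background)."""
    ids = [f"aff{i}" for i in range(a + b)] + [f"bg{i}" for i in range(c + d)]
    values = [True] * a + [False] * b + [True] * c + [False] * d
    frame = pd.DataFrame({rbp: values}, index=pd.Index(ids, name="exon_id"))
    affected = ids[: a + b]
    background = ids[a + b :]
    return frame, affected, background


class TestFisherEnrichment:
    def test_balanced_table_is_null(self):
        frame, aff, bg = presence_frame(5, 5, 5, 5)
        res = fisher_enrichment(frame, aff, bg)
        assert res.loc[0, "odds_ratio"] == pytest.approx(1.0)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_hand_checked_table(self):
        frame, aff, bg = presence_frame(3, 1, 1, 3)
        res = fisher_enrichment(frame, aff, bg)
        assert res.loc[0, "odds_ratio"] == pytest.approx(9.0)
        assert res.loc[0, "p_value"] == pytest.approx(fisher_two_sided_oracle(3, 1, 1, 3))

    def test_zero_cell_odds_ratio_is_corrected(self):
        frame, aff, bg = presence_frame(4, 0, 1, 3)
        res = fisher_enrichment(frame, aff, bg)
        assert res.loc[0, "odds_ratio"] == pytest.approx((4.5 * 3.5) / (0.5 * 1.5))

    def test_overlapping_sets_rejected(self):
        frame, aff, bg = presence_frame(2, 2, 2, 2)
        with pytest.raises(ValueError):
            fisher_enrichment(frame, aff, aff)

    def test_empty_set_rejected(self):
        frame, aff, bg = presence_frame(2, 2, 2, 2)
        with pytest.raises(ValueError):
            fisher_enrichment(frame, [], bg)

    def test_unknown_exons_ignored(self):
        frame, aff, bg = presence_frame(3, 1, 1, 3)
        res = fisher_enrichment(frame, aff + ["ghost"], bg)
        assert res.loc[0, "a_affected_with"] == 3

    @given(
        a=st.integers(0, 12),
        b=st.integers(0, 12),
        c=st.integers(0, 12),
        d=st.integers(0, 12),
    )
    @settings(max_examples=200, deadline=None)
    def test_property_matches_hypergeometric_oracle(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        frame, aff, bg = presence_frame(a, b, c, d)
        res = fisher_enrichment(frame, aff, bg)
        assert res.loc[0, "p_value"] == pytest.approx(
            fisher_two_sided_oracle(a, b, c, d), abs=1e-12
        )


class TestBhFdr:
    @pytest.mark.parametrize(
        "p,q",
        [
            ([0.01], [0.01]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            ([0.005, 0.04, 0.5], [0.015, 0.06, 0.5]),  # hand BH: m*p/rank cummin
        ],
    )
    def test_hand_computed_qvalues(self, p, q):
        assert bh_fdr(p) == pytest.approx(q)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_properties(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)
        # invariant to input order
        perm = np.random.default_rng(0).permutation(len(p))
        q_perm = bh_fdr(np.asarray(p)[perm])
        assert q_perm == pytest.approx(np.asarray(q)[perm])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_discoveries_monotone_in_alpha(self, p):
        q = bh_fdr(p)
        for alpha in (0.01, 0.05, 0.1, 0.2):
            assert (q <= alpha).sum() <= (q <= alpha + 0.05).sum()


class TestCrossref:
    def enrichment(self, names, qs):
        return pd.DataFrame({"rbp_name": names, "q_value": qs})

    def test_only_listed_names_flagged(self):
        res = crossref_interactome(
            self.enrichment(["NOVA1", "RBFOX2", "U2AF2"], [0.01, 0.01, 0.01]),
            ["u2af2"],
        )
        assert res.set_index("rbp_name")["in_interactome"].tolist() == [
            False,
            False,
            True,
        ]

    def test_empty_interactome_yields_no_candidates(self):
        res = crossref_interactome(self.enrichment(["NOVA1"], [0.001]), [])
        assert not res["refined_candidate"].any()

    def test_aliases_resolve(self):
        res = crossref_interactome(
            self.enrichment(["RBFOX2"], [0.01]), ["Fox-2"], aliases={"FOX-2": "RBFOX2"}
        )
        assert res.loc[0, "refined_candidate"]

    def test_significance_gate(self):
        res = crossref_interactome(
            self.enrichment(["RBFOX2", "NOVA1"], [0.2, 0.01]), ["RBFOX2", "NOVA1"]
        )
        assert res.set_index("rbp_name")["refined_candidate"].to_dict() == {
            "RBFOX2": False,
            "NOVA1": True,
        }
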