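from __future__ import annotations

import numpy as np
import pytest

from bloomloci.datamodel_io import OrfRecord
from bloomloci import pul_detection as pul
from bloomloci import synthetic_data as syn

from tests._oracles import locus_window_oracle


def gene(oid, start, end, strand="+", contig="c1", cazy=(), pfam=(),
         tigrfam=(), tax=None):
    return OrfRecord(oid, contig, start, end, strand,
                     taxonomy=tax or {}, cazy_families=set(cazy),
                     pfam_ids=set(pfam), tigrfam_ids=set(tigrfam))


class TestTagSusGenes:
    def test_pf07715_is_susc(self, sets):
        roles = pul.tag_sus_genes([gene("a", 1, 900, pfam={"PF07715"})], sets)
        assert roles == {"a": "susC"}

    def test_tigr04056_is_susc(self, sets):
        roles = pul.tag_sus_genes([gene("a", 1, 900, tigrfam={"TIGR04056"})], sets)
        assert roles == {"a": "susC"}

    def test_pf12741_is_susd(self, sets):
        roles = pul.tag_sus_genes([gene("a", 1, 900, pfam={"PF12741"})], sets)
        assert roles == {"a": "susD"}

    def test_unflagged_gene(self, sets):
        assert pul.tag_sus_genes([gene("a", 1, 900, pfam={"PF00001"})], sets) == {}

    def test_double_match_prefers_susc_and_logs(self, sets, caplog):
        orfs = [gene("a", 1, 900, pfam={"PF00593", "PF07980"})]
        with caplog.at_level("ERROR"):
            roles = pul.tag_sus_genes(orfs, sets)
        assert roles == {"a": "susC"}
        assert "both" in caplog.text


class TestFindTandems:
    def _pair(self, gap=50, strand_d="+", insert_between=False):
        genes = [gene("c", 1, 1500, pfam={"PF00593"})]
        pos = 1500
        if insert_between:
            genes.append(gene("x", pos + 51, pos + 950))
            pos += 950
        genes.append(gene("d", pos + gap + 1, pos + gap + 1250,
                          strand=strand_d, pfam={"PF07980"}))
        return genes

    def test_forward_pair_gap_50(self, sets):
        tandems = pul.find_tandems(self._pair(), sets)
        assert len(tandems) == 1
        assert (tandems[0].susc_orf, tandems[0].susd_orf) == ("c", "d")

    def test_gap_at_threshold_excluded(self, sets):
        assert pul.find_tandems(self._pair(gap=102), sets) == []
        assert len(pul.find_tandems(self._pair(gap=101), sets)) == 1

    def test_opposite_strands_excluded(self, sets):
        assert pul.find_tandems(self._pair(strand_d="-"), sets) == []

    def test_intervening_gene_breaks_adjacency(self, sets):
        assert pul.find_tandems(self._pair(insert_between=True), sets) == []

    def test_susd_first_order_accepted(self, sets):
        genes = [gene("d", 1, 1250, pfam={"PF07980"}),
                 gene("c", 1301, 2800, pfam={"PF00593"})]
        tandems = pul.find_tandems(genes, sets)
        assert len(tandems) == 1
        assert tandems[0].susc_orf == "c"

    def test_shared_susc_yields_two_tandems(self, sets):
        genes = [
            gene("d1", 1, 1000, pfam={"PF07980"}),
            gene("c", 1051, 2500, pfam={"PF00593"}),
            gene("d2", 2551, 3500, pfam={"PF07980"}),
        ]
        assert len(pul.find_tandems(genes, sets)) == 2


class TestExtendLocus:
    def _detect(self, contig_id, sets):
        orfs, _ = syn.plant_pul_contigs(
            [l for l in syn.decoy_library() if l.contig_id == contig_id],
            sets=sets,
        )
        tandems = pul.find_tandems(orfs, sets)
        assert len(tandems) == 1
        return pul.extend_locus(orfs, tandems[0], sets), orfs

    def test_tandem_plus_three_cazymes(self, sets):
        cand, _ = self._detect("pul|true_basic", sets)
        assert len(cand.locus_genes) == 5
        assert cand.cazyme_count == 3

    def test_noncazyme_gap_over_limit_stops(self, sets):
        cand, _ = self._detect("pul|decoy_severed", sets)
        assert len(cand.locus_genes) == 2  # pair only

    def test_cazyme_exempt_from_gap_rule(self, sets):
        cand, _ = self._detect("pul|gap_exempt_cazyme", sets)
        assert cand.cazyme_count == 3

    def test_cazyme_then_blocked_noncazyme(self, sets):
        genes = [
            gene("c", 1, 1500, pfam={"PF00593"}),
            gene("d", 1551, 2800, pfam={"PF07980"}),
            gene("z", 3301, 4300, cazy={"GH16"}),   # gap 500, cazyme: in
            gene("x", 4451, 5400),                   # gap 150, non-cazyme: out
        ]
        tandem = pul.find_tandems(genes, sets)[0]
        cand = pul.extend_locus(genes, tandem, sets)
        assert [i for i, _ in cand.locus_genes] == ["c", "d", "z"]

    def test_extends_upstream_too(self, sets):
        genes = [
            gene("z", 1, 1000, cazy={"GH16"}),
            gene("c", 1051, 2500, pfam={"PF00593"}),
            gene("d", 2551, 3800, pfam={"PF07980"}),
        ]
        tandem = pul.find_tandems(genes, sets)[0]
        cand = pul.extend_locus(genes, tandem, sets)
        assert [i for i, _ in cand.locus_genes] == ["z", "c", "d"]

    def test_input_order_invariance(self, sets):
        orfs, _ = syn.plant_pul_contigs(syn.decoy_library(), sets=sets)
        rng = np.random.default_rng(0)
        shuffled = list(orfs)
        rng.shuffle(shuffled)
        a, _ = pul.detect_puls(orfs, sets)
        b, _ = pul.detect_puls(shuffled, sets)
        key = lambda c: (c.contig_id, c.tandem.susc_orf)
        for x, y in zip(sorted(a, key=key), sorted(b, key=key)):
            assert x.locus_genes == y.locus_genes
            assert x.funnel_stage == y.funnel_stage


class TestCallPuls:
    def _stages(self, sets):
        orfs, truth = syn.plant_pul_contigs(syn.decoy_library(), sets=sets)
        candidates, funnel = pul.detect_puls(orfs, sets)
        return {c.contig_id: c for c in candidates}, truth, funnel

    def test_called_pul_requires_three_locus_cazymes(self, sets):
        byc, _, _ = self._stages(sets)
        assert byc["pul|true_basic"].funnel_stage == "called_pul"
        assert byc["pul|decoy_too_few_cazymes"].funnel_stage != "called_pul"

    def test_opposite_strand_veto(self, sets):
        byc, _, _ = self._stages(sets)
        cand = byc["pul|decoy_strand_veto"]
        assert cand.funnel_stage != "called_pul"
        assert cand.rejection_reason == "opposite_strand_cazyme"

    def test_decoy_library_matches_truth_exactly(self, sets):
        byc, truth, _ = self._stages(sets)
        assert set(byc) == set(truth)
        for contig, expected in truth.items():
            cand = byc[contig]
            assert (cand.funnel_stage == "called_pul") == expected["should_call"], contig
            assert cand.funnel_stage == expected["expected_stage"], contig
            if not expected["should_call"]:
                assert cand.rejection_reason == expected["reason"], contig


class TestFunnel:
    def test_empty_input_all_zero(self):
        summary = pul.summarize_funnel([])
        assert summary.as_dict() == {
            "tandems": 0, "small_contig": 0, "big_contig": 0,
            "enough_cazymes": 0, "called_pul": 0, "per_phylum": {},
        }

    def test_monotone_counts_on_decoys(self, sets):
        orfs, _ = syn.plant_pul_contigs(syn.decoy_library(), sets=sets)
        _, funnel = pul.detect_puls(orfs, sets)
        assert funnel.n_tandems >= funnel.n_big_contig
        assert funnel.n_big_contig >= funnel.n_enough_cazymes
        assert funnel.n_enough_cazymes >= funnel.n_called

    def test_all_small_contigs(self, sets):
        layout = syn.PulLayout(
            "only_pair", "+",
            [syn.PulGene("susC", "+"), syn.PulGene("susD", "+", 50)],
            should_call=False,
        )
        orfs, _ = syn.plant_pul_contigs([layout], sets=sets)
        _, funnel = pul.detect_puls(orfs, sets)
        assert funnel.n_tandems == 1 and funnel.n_big_contig == 0

    def test_per_phylum_counts(self, sets):
        orfs, _ = syn.plant_pul_contigs(
            syn.decoy_library(), sets=sets,
            taxonomy={"superkingdom": "Bacteria", "phylum": "Bacteroidetes"},
        )
        _, funnel = pul.detect_puls(orfs, sets)
        assert funnel.per_phylum == {"Bacteroidetes": funnel.n_tandems}

    def test_contig_taxonomy_majority_and_ties(self):
        genes = [
            gene("a", 1, 10, tax={"phylum": "A"}),
            gene("b", 20, 30, tax={"phylum": "A"}),
            gene("c", 40, 50, tax={"phylum": "B"}),
        ]
        assert pul.contig_taxonomy(genes)["phylum"] == "A"
        genes[1].taxonomy["phylum"] = "B"  # now tied 1-2? A:1 B:2
        assert pul.contig_taxonomy(genes)["phylum"] == "B"
        genes[2].taxonomy["phylum"] = "A"  # A:2 B:1
        assert pul.contig_taxonomy(genes)["phylum"] == "A"
        tied = [gene("x", 1, 10, tax={"phylum": "A"}),
                gene("y", 20, 30, tax={"phylum": "B"})]
        assert "phylum" not in pul.contig_taxonomy(tied)


def random_contig(rng, contig_id, sets):
    """A random gene neighborhood with sus/cazyme roles sprinkled in."""
    n_genes = int(rng.integers(2, 13))
    genes = []
    cursor = int(rng.integers(1, 500))
    for i in range(n_genes):
        length = int(rng.integers(300, 2500))
        strand = "+" if rng.random() < 0.7 else "-"
        roll = rng.random()
        kwargs = {}
        if roll < 0.25:
            kwargs["pfam"] = {"PF00593"}
        elif roll < 0.5:
            kwargs["pfam"] = {"PF07980"}
        elif roll < 0.75:
            kwargs["cazy"] = {"GH16"}
        genes.append(
            gene(f"{contig_id}|g{i}", cursor, cursor + length - 1,
                 strand=strand, contig=contig_id, **kwargs)
        )
        gap = int(rng.integers(0, 300)) - (50 if rng.random() < 0.1 else 0)
        cursor += length + max(gap, -min(50, length - 1)) + 0
        cursor = max(cursor, genes[-1].start + 1)
    return genes


class TestOracleEquivalence:
    def test_incremental_extension_matches_window_oracle(self, sets):
        """0 disagreements between greedy extension and brute-force windows
        over 1,000 random synthetic contigs."""
        rng = np.random.default_rng(2024)
        disagreements = 0
        n_tandems = 0
        for i in range(1000):
            genes = random_contig(rng, f"rc{i}", sets)
            for tandem in pul.find_tandems(genes, sets):
                n_tandems += 1
                cand = pul.extend_locus(genes, tandem, sets)
                got = [orf_id for orf_id, _ in cand.locus_genes]
                expected = locus_window_oracle(
                    genes, tandem.susc_orf, tandem.susd_orf, tandem.strand
                )
                if got != expected:
                    disagreements += 1
        assert n_tandems > 100  # the random generator must exercise the rule
        assert disagreements == 0
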