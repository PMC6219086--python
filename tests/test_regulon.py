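import numpy as np
import pytest

from netmotif.genome_io import GeneAnnotation, Genome
from netmotif.motif_core import DiscoveredMotif, Occurrence, PWM
from netmotif.regulon import (
    PipelineParams,
    aggregate,
    expand_until_convergence,
    flanking_genes,
    reject_genic,
    run_once,
)


def occ(start, width=14, strand=1, p=1e-6, q=1e-4, seq=None):
    return Occurrence(
        start=start, strand=strand, sequence=seq or "A" * width,
        score=10.0, pvalue=p, qvalue=q,
    )


def toy_motif(tags):
    pwm = PWM(np.full((14, 4), 0.25))
    return DiscoveredMotif(
        pwm=pwm, evalue=0.1,
        site_scores=[(t, float(10 - i)) for i, t in enumerate(tags)],
    )


@pytest.fixture
def annotated_genome():
    # layout: [0,1000) intergenic, gplus 1000..1500 (+), intergenic,
    # gminus 2000..2500 (-), intergenic to 3500
    return Genome(
        id="toy",
        sequence="ACGT" * 875,
        genes=[
            GeneAnnotation("gplus", 1000, 1500, 1),
            GeneAnnotation("gminus", 2000, 2500, -1),
        ],
    )


class TestRejectGenic:
    def test_inside_gene_removed(self, annotated_genome):
        assert reject_genic([occ(1200)], annotated_genome) == []

    def test_intergenic_kept(self, annotated_genome):
        kept = reject_genic([occ(100)], annotated_genome)
        assert len(kept) == 1

    def test_one_nt_overlap_removed(self, annotated_genome):
        # window [987, 1001) overlaps gene start 1000 by exactly 1 nt
        assert reject_genic([occ(987)], annotated_genome) == []
        # window [986, 1000) touches but does not overlap
        assert len(reject_genic([occ(986)], annotated_genome)) == 1

    def test_order_preserved(self, annotated_genome):
        occs = [occ(100, p=1e-8), occ(1200, p=1e-7), occ(300, p=1e-6)]
        kept = reject_genic(occs, annotated_genome)
        assert [o.start for o in kept] == [100, 300]


class TestFlankingGenes:
    def test_faces_plus_gene_with_relative_position(self, annotated_genome):
        # occurrence at 950..964, + strand gene starts at 1000 to its right
        downstream, upstream, rel = flanking_genes(occ(950), annotated_genome)
        assert downstream == "gplus"
        assert upstream is None
        assert rel == 950 - 1000 == -50

    def test_faces_minus_gene(self, annotated_genome):
        # occurrence right of gminus end (2500): gminus faces away? no --
        # gminus runs -, its biological start is at 2500, occurrence at 2600
        downstream, upstream, rel = flanking_genes(occ(2600), annotated_genome)
        assert downstream == "gminus"
        assert rel == 2500 - (2600 + 14) == -114

    def test_between_convergent_pair_nearer_wins(self):
        genome = Genome(
            id="conv",
            sequence="A" * 3000,
            genes=[GeneAnnotation("left", 0, 1000, 1), GeneAnnotation("right", 2000, 3000, -1)],
        )
        # neither faces the gap; occurrence at 1100 is nearer to left
        downstream, upstream, _ = flanking_genes(occ(1100), genome)
        assert downstream == "left" and upstream == "right"

    def test_between_divergent_pair_nearer_start_wins(self):
        genome = Genome(
            id="div",
            sequence="A" * 3000,
            genes=[GeneAnnotation("left", 0, 1000, -1), GeneAnnotation("right", 2000, 3000, 1)],
        )
        # both face the gap; starts are at 1000 (left, -) and 2000 (right, +)
        downstream, _, _ = flanking_genes(occ(1040), genome)  # 40 nt from left start
        assert downstream == "left"
        downstream, _, _ = flanking_genes(occ(1930), genome)  # 56 nt from right start
        assert downstream == "right"

    def test_contig_edge_flank_is_none(self, annotated_genome):
        downstream, upstream, _ = flanking_genes(occ(3000), annotated_genome)
        assert downstream == "gminus" or upstream is None

    def test_genic_occurrence_is_contract_violation(self, annotated_genome):
        with pytest.raises(ValueError):
            flanking_genes(occ(1100), annotated_genome)


class TestAggregate:
    def test_hit_count_merging_keeps_best_p(self, annotated_genome):
        motif = toy_motif(["gplus"])
        occs = [occ(950, p=1e-8), occ(900, p=1e-6)]
        rows = aggregate(occs, annotated_genome, motif)
        assert len(rows) == 1
        assert rows[0].hit_count == 2
        assert rows[0].pvalue == 1e-8
        assert rows[0].relative_position == -50

    def test_absent_gene_gets_minus_one(self, annotated_genome):
        motif = toy_motif(["somethingelse"])
        rows = aggregate([occ(950, p=1e-8)], annotated_genome, motif)
        assert rows[0].index_downstream == -1

    def test_known_gene_gets_list_index(self, annotated_genome):
        motif = toy_motif(["other", "gplus"])
        rows = aggregate([occ(950, p=1e-8)], annotated_genome, motif)
        assert rows[0].index_downstream == 1

    def test_hit_count_conservation(self, annotated_genome):
        motif = toy_motif(["gplus", "gminus"])
        occs = [occ(950, p=1e-9), occ(900, p=1e-8), occ(2600, p=1e-7), occ(100, p=1e-6)]
        rows = aggregate(occs, annotated_genome, motif)
        assert sum(r.hit_count for r in rows) == len(occs)

    def test_unsorted_input_rejected(self, annotated_genome):
        motif = toy_motif(["gplus"])
        with pytest.raises(ValueError, match="sorted"):
            aggregate([occ(950, p=1e-6), occ(900, p=1e-8)], annotated_genome, motif)

    def test_rows_in_creation_order(self, annotated_genome):
        motif = toy_motif(["gplus", "gminus"])
        occs = [occ(2600, p=1e-9), occ(950, p=1e-8)]
        rows = aggregate(occs, annotated_genome, motif)
        assert [r.downstream_gene for r in rows] == ["gminus", "gplus"]


class TestRunOnce:
    def test_planted_regulon_all_indices_found(self, regulon_fixture):
        genome, regulon, _, _ = regulon_fixture
        params = PipelineParams(nmotifs=1, seed=2)
        result = run_once(genome, set(regulon), params)
        assert result.status == "ok"
        table = result.tables[0]
        top = table[: len(regulon)]
        assert {r.downstream_gene for r in top} == set(regulon)
        assert all(r.index_downstream >= 0 for r in top)

    def test_single_gene_selection_gives_status(self, regulon_fixture):
        genome, regulon, _, _ = regulon_fixture
        result = run_once(genome, {sorted(regulon)[0]}, PipelineParams(nmotifs=1))
        assert result.status != "ok"
        assert result.tables == []

    def test_determinism(self, regulon_fixture):
        genome, regulon, _, _ = regulon_fixture
        params = PipelineParams(nmotifs=1, seed=9, widths=(14,))
        a = run_once(genome, set(regulon), params)
        b = run_once(genome, set(regulon), params)
        assert [
            (r.downstream_gene, r.pvalue, r.hit_count) for r in a.tables[0]
        ] == [(r.downstream_gene, r.pvalue, r.hit_count) for r in b.tables[0]]


class TestExpansion:
    def test_max_iter_zero_checks_without_expanding(self, regulon_fixture):
        genome, regulon, _, _ = regulon_fixture
        half = set(sorted(regulon)[:6])
        params = PipelineParams(nmotifs=1, seed=5, widths=(14,))
        state = expand_until_convergence(genome, half, top_k=20, max_iter=0, params=params)
        assert state.iteration == 0
        assert state.selection == half

    def test_already_converged_fixed_point(self, regulon_fixture):
        genome, regulon, _, _ = regulon_fixture
        params = PipelineParams(nmotifs=1, seed=5, widths=(14,))
        full = expand_until_convergence(
            genome, set(regulon), top_k=12, max_iter=3, params=params
        )
        if full.converged:
            again = expand_until_convergence(
                genome, full.selection, top_k=12, max_iter=3, params=params
            )
            assert again.converged
            assert again.selection == full.selection
            assert again.iteration == 0

    def test_selection_monotone_and_bounded(self, regulon_fixture):
        genome, regulon, _, _ = regulon_fixture
        half = set(sorted(regulon)[:6])
        params = PipelineParams(nmotifs=1, seed=5, widths=(14,))
        state = expand_until_convergence(genome, half, top_k=20, max_iter=4, params=params)
        assert state.iteration <= 4
        assert all(
            state.history[i] <= state.history[i + 1] for i in range(len(state.history) - 1)
        )
        assert half <= state.selection
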