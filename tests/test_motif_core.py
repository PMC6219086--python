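from itertools import product

import numpy as np
import pytest

from netmotif.genome_io import Genome, MarkovBackground, revcomp
from netmotif.motif_core import (
    PWM,
    MotifInputError,
    bh_qvalues,
    consensus,
    discover_zoops,
    motif_evalue,
    scan,
    score_distribution,
)
from netmotif.motif_core import SCORE_SCALE
from netmotif.synthetic_data import (
    PlantedMotifSpec,
    generate_genome,
    plant_motif,
    strong_planted_fixture,
)
from netmotif.genome_io import extract_upstream


def random_pwm(width, seed):
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.ones(4), size=width)
    return PWM(probs)


def brute_force_tail(pwm, background):
    """Enumerate all 4^w words; exact Pr(score >= s) for every word score."""
    dist = score_distribution(pwm, background)
    bg = background.marginal
    scores, weights = [], []
    for word in product(range(4), repeat=pwm.width):
        s = sum(int(dist.score_matrix[k, b]) for k, b in enumerate(word))
        p = np.prod([bg[b] for b in word])
        scores.append(s)
        weights.append(p)
    scores = np.array(scores)
    weights = np.array(weights)
    return dist, scores, weights


class TestScoreDistribution:
    def test_width1_point_mass(self):
        pwm = PWM(np.array([[1.0, 0.0, 0.0, 0.0]]))
        dist = score_distribution(pwm, MarkovBackground.uniform(0))
        assert dist.pvalue(dist.max_score) == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("width", [2, 3, 4, 5, 6])
    def test_dp_equals_enumeration(self, width):
        pwm = random_pwm(width, seed=width)
        bg = MarkovBackground(0, np.full((1, 4), 0.25), np.array([0.4, 0.1, 0.2, 0.3]))
        dist, scores, weights = brute_force_tail(pwm, bg)
        for s in np.unique(scores):
            exact = weights[scores >= s].sum()
            assert dist.pvalue(int(s)) == pytest.approx(exact, abs=1e-12)

    def test_total_mass(self):
        dist = score_distribution(random_pwm(7, seed=1), MarkovBackground.uniform(0))
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_background_guard(self):
        bad = MarkovBackground.uniform(0)
        bad.marginal = np.array([0.5, 0.5, 0.0, 0.0])
        with pytest.raises(ValueError, match="zero-probability"):
            score_distribution(random_pwm(4, seed=2), bad)


class TestBhQvalues:
    def test_single(self):
        assert bh_qvalues([0.04], m=1) == [pytest.approx(0.04)]

    def test_hand_example(self):
        # m*p/rank = (0.03, 0.03, 0.03) after the step-up minimum
        assert bh_qvalues([0.01, 0.02, 0.03], m=3) == pytest.approx([0.03, 0.03, 0.03])

    def test_m_larger_than_list(self):
        assert bh_qvalues([0.001], m=100) == [pytest.approx(0.1)]

    def test_non_decreasing(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=50))
        q = bh_qvalues(list(p), m=200)
        assert all(q[i] <= q[i + 1] + 1e-15 for i in range(len(q) - 1))

    def test_clipped_at_one(self):
        assert bh_qvalues([0.9, 0.95], m=100)[0] == 1.0

    def test_errors(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.5, 0.1], m=2)  # not ascending
        with pytest.raises(ValueError):
            bh_qvalues([-0.1], m=1)
        with pytest.raises(ValueError):
            bh_qvalues([0.1, 0.2], m=1)  # m too small


class TestConsensus:
    def test_certain_column(self):
        pwm = PWM(np.array([[1.0, 0, 0, 0]]))
        assert consensus(pwm) == "A"

    def test_uniform_column(self):
        pwm = PWM(np.array([[0.25, 0.25, 0.25, 0.25]]))
        assert consensus(pwm) == "N"

    def test_spaced_palindrome_pattern_reproduced(self):
        pattern = "GGGNCNNNNGNCCC"
        pwm = PWM.from_consensus(pattern, strength=0.94)
        assert consensus(pwm) == pattern


@pytest.fixture(scope="module")
def planted():
    genome = generate_genome(10, 200, 150, seed=21)
    regulon = frozenset(g.locus_tag for g in genome.genes)
    spec = PlantedMotifSpec(
        consensus="GGGACTTAAGTCCC", regulon=regulon,
        offset_range=(10, 80), mutation_rate=0.0,
    )
    genome, sites = plant_motif(genome, spec, seed=22)
    pwm = PWM.from_consensus("GGGACTTAAGTCCC", strength=0.94)
    bg = MarkovBackground.uniform(0)
    return genome, sites, pwm, bg


class TestScan:
    def test_planted_positions_recovered(self, planted):
        genome, sites, pwm, bg = planted
        occurrences = scan(genome, pwm, bg, p_threshold=1e-4)
        starts = {occ.start for occ in occurrences}
        for site in sites:
            assert site.start in starts

    def test_zero_threshold_empty(self, planted):
        genome, _, pwm, bg = planted
        assert scan(genome, pwm, bg, p_threshold=0.0) == []

    def test_sorted_by_pvalue(self, planted):
        genome, _, pwm, bg = planted
        occurrences = scan(genome, pwm, bg, p_threshold=1e-3)
        pvals = [occ.pvalue for occ in occurrences]
        assert pvals == sorted(pvals)

    def test_palindromic_pwm_strand_symmetry(self, planted):
        genome, _, pwm, bg = planted
        occurrences = scan(genome, pwm, bg, p_threshold=1e-4)
        plus = {(o.start, o.score) for o in occurrences if o.strand == 1}
        minus = {(o.start, o.score) for o in occurrences if o.strand == -1}
        assert plus == minus  # the planted word is its own reverse complement

    def test_revcomp_genome_same_score_multiset(self, planted):
        genome, _, pwm, bg = planted
        occ_f = scan(genome, pwm, bg, p_threshold=1e-3)
        flipped = Genome(id="rc", sequence=revcomp(genome.sequence), genes=[])
        occ_r = scan(flipped, pwm, bg, p_threshold=1e-3)
        assert sorted((o.score, o.pvalue) for o in occ_f) == pytest.approx(
            sorted((o.score, o.pvalue) for o in occ_r)
        )

    def test_qvalues_within_unit_interval_and_ordered(self, planted):
        genome, _, pwm, bg = planted
        occurrences = scan(genome, pwm, bg, p_threshold=1e-3)
        qvals = [o.qvalue for o in occurrences]
        assert all(0 < q <= 1 for q in qvals)
        assert qvals == sorted(qvals)


@pytest.fixture(scope="module")
def upstream():
    genome, sites, planted = strong_planted_fixture(seed=3)
    ups = extract_upstream(genome, {g.locus_tag for g in genome.genes})
    return ups, planted


class TestDiscoverZoops:
    def test_planted_recovery_single_seed(self, upstream):
        ups, planted = upstream
        motifs = discover_zoops(ups, nmotifs=1, widths=(12, 14, 16), seed=3)
        cons = consensus(motifs[0].pwm)
        dist = min(
            sum(a != b for a, b in zip(cons, planted)) if len(cons) == len(planted) else 99,
            sum(a != b for a, b in zip(revcomp(cons), planted)) if len(cons) == len(planted) else 99,
        )
        assert dist <= 1

    def test_site_scores_one_entry_per_input(self, upstream):
        ups, _ = upstream
        motifs = discover_zoops(ups, nmotifs=1, widths=(14,), seed=3)
        scores = motifs[0].site_scores
        assert sorted(tag for tag, _ in scores) == sorted(tag for tag, _ in ups)
        numeric = [s for _, s in scores if s is not None]
        assert numeric == sorted(numeric, reverse=True)

    def test_empty_input_is_error(self):
        with pytest.raises(MotifInputError):
            discover_zoops([])

    def test_single_sequence_is_error(self):
        with pytest.raises(MotifInputError):
            discover_zoops([("only", "ACGT" * 20)])

    def test_zero_evalue_threshold_returns_nothing(self, upstream):
        ups, _ = upstream
        assert discover_zoops(ups, nmotifs=1, widths=(14,), seed=3,
                              evalue_threshold=0.0) == []

    def test_determinism(self, upstream):
        ups, _ = upstream
        a = discover_zoops(ups, nmotifs=1, widths=(14,), seed=5)
        b = discover_zoops(ups, nmotifs=1, widths=(14,), seed=5)
        assert np.allclose(a[0].pwm.probs, b[0].pwm.probs)
        assert a[0].evalue == b[0].evalue
        assert a[0].site_scores == b[0].site_scores


class TestMotifEvalue:
    def test_planted_motif_significant(self, upstream):
        ups, planted = upstream
        pwm = PWM.from_consensus(planted, strength=0.94)
        assert motif_evalue(pwm, ups, seed=1) < 1.0

    def test_uninformative_motif_not_significant(self, upstream):
        ups, _ = upstream
        flat = PWM(np.full((14, 4), 0.25))
        assert motif_evalue(flat, ups, seed=1) >= 1.0

    def test_determinism(self, upstream):
        ups, planted = upstream
        pwm = PWM.from_consensus(planted, strength=0.94)
        assert motif_evalue(pwm, ups, seed=7) == motif_evalue(pwm, ups, seed=7)
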