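"""Weighting, PSPM estimation, bit scores, exact p-values and scanning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cepkit.formats_io import AA_ALPHABET, AA_TO_INDEX, tree_from_string
from cepkit.motif_model import (
    Pspm,
    WeightedDomain,
    aa_max_gc,
    assign_weights,
    build_pspm,
    family_logo_stats,
    scan_orf,
    score_pvalue,
    score_window,
    scores_to_pvalues,
    uniform_background,
)
from cepkit.synthetic_data import _sample_from_pspm, default_generating_pspm

DOM = "DFRPTAPGHSPGVGH"


def _wd(seq=DOM, org="o1", orf="orf1", asm="a1"):
    return WeightedDomain(seq, 1.0, org, orf, asm)


# ------------------------------------------------------------------ weighting

class TestAssignWeights:
    def test_two_assemblies_symmetric(self):
        tree = tree_from_string("(o1,o2);")
        out = assign_weights(
            [_wd(org="o1", asm="a1"), _wd(org="o2", asm="a2", orf="orfB")], tree
        )
        assert [d.weight for d in out] == [0.5, 0.5]

    def test_three_level_equalization_hand_masses(self):
        # assembly A: ORF1 with 2 domains, ORF2 with 1; assembly B: 1 ORF/domain
        tree = tree_from_string("(o1,o2);")
        domains = [
            _wd(org="o1", asm="A", orf="ORF1"),
            _wd(org="o1", asm="A", orf="ORF1"),
            _wd(org="o1", asm="A", orf="ORF2"),
            _wd(org="o2", asm="B", orf="ORF3"),
        ]
        out = assign_weights(domains, tree)
        # pre-normalization masses per unit assembly: A (0.25, 0.25, 0.5), B (1.0);
        # the uniform depth-1 decay cancels, normalization halves everything
        assert np.allclose([d.weight for d in out], [0.125, 0.125, 0.25, 0.5])

    def test_depth_decay_ratio(self):
        # leaf at depth 3 vs depth 1, decay 0.8 -> multiplier ratio 0.8^2 = 0.64
        tree = tree_from_string("(((deep,x),y),shallow);")
        out = assign_weights(
            [_wd(org="deep", asm="a1"), _wd(org="shallow", asm="a2", orf="o2")],
            tree,
            decay=0.8,
        )
        w = {d.organism: d.weight for d in out}
        assert w["deep"] / w["shallow"] == pytest.approx(0.8**3 / 0.8**1)

    def test_sum_to_one_and_order_invariance(self):
        tree = tree_from_string("((o1,o2),o3);")
        domains = [
            _wd(org="o1", asm="a1", orf=f"orf{i}") for i in range(3)
        ] + [
            _wd(org="o2", asm="a2"),
            _wd(org="o3", asm="a3"),
            _wd(org="o3", asm="a3"),
        ]
        fwd = assign_weights(domains, tree)
        rev = assign_weights(domains[::-1], tree)
        assert sum(d.weight for d in fwd) == pytest.approx(1.0)
        key = lambda d: (d.assembly_id, d.orf_id, d.sequence)
        assert {key(d): d.weight for d in fwd} == {key(d): d.weight for d in rev}

    def test_missing_organism_listed(self):
        tree = tree_from_string("(o1,o2);")
        with pytest.raises(ValueError, match="ghost"):
            assign_weights([_wd(org="ghost")], tree)


# ---------------------------------------------------------------- build_pspm

class TestBuildPspm:
    def test_single_domain_one_hot(self):
        p = build_pspm([_wd()], pseudocount=0.0)
        for i, a in enumerate(DOM):
            assert p.probabilities[i, AA_TO_INDEX[a]] == pytest.approx(1.0)

    def test_two_domains_half_half(self):
        other = "A" + DOM[1:]
        p = build_pspm([_wd(), _wd(other, orf="orf2")], pseudocount=0.0)
        assert p.probabilities[0, AA_TO_INDEX["D"]] == pytest.approx(0.5)
        assert p.probabilities[0, AA_TO_INDEX["A"]] == pytest.approx(0.5)

    def test_sampling_recovery(self, rng):
        # 100 draws from a sharp 4-letter-per-row model: each estimated row
        # within 0.1 total variation of the generator (multinomial error)
        probs = np.zeros((15, 20))
        for i in range(15):
            probs[i, (i % 5)] = 0.85
            probs[i, 5:8] = 0.05
        sharp = Pspm(probs, uniform_background())
        doms = [
            WeightedDomain(_sample_from_pspm(sharp, rng), 1.0, "o", f"f{i}", "a")
            for i in range(100)
        ]
        est = build_pspm(doms, pseudocount=0.0)
        tv = 0.5 * np.abs(est.probabilities - sharp.probabilities).sum(axis=1)
        assert tv.max() < 0.1

    def test_sampling_convergence_large_n(self, pspm, rng):
        doms = [
            WeightedDomain(_sample_from_pspm(pspm, rng), 1.0, "o", f"f{i}", "a")
            for i in range(10_000)
        ]
        est = build_pspm(doms, pseudocount=0.0)
        tv = 0.5 * np.abs(est.probabilities - pspm.probabilities).sum(axis=1)
        assert tv.max() < 0.02

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            build_pspm([])


# -------------------------------------------------------------------- scoring

def test_score_background_rows_is_zero():
    p = Pspm(np.full((15, 20), 0.05), uniform_background())
    assert score_window(p, "ACDEFGHIKLMNPQR") == pytest.approx(0.0)


def test_score_window_hand_summed_log_odds():
    # width-3 toy vs uniform background, summed on a calculator
    probs = np.full((3, 20), (1 - 0.8) / 19)
    for i, a in enumerate("ACD"):
        probs[i, AA_TO_INDEX[a]] = 0.8
    p = Pspm(probs, uniform_background())
    expected = 3 * math.log2(0.8 / 0.05)
    assert score_window(p, "ACD") == pytest.approx(expected)
    off = 2 * math.log2(0.8 / 0.05) + math.log2((0.2 / 19) / 0.05)
    assert score_window(p, "ACA") == pytest.approx(off)


def test_score_window_length_mismatch():
    p = Pspm(np.full((15, 20), 0.05), uniform_background())
    with pytest.raises(ValueError):
        score_window(p, "ACDE")


# ------------------------------------------------------------ exact p-values

def _toy_two_col():
    probs = np.zeros((2, 20))
    probs[0, :4] = [0.4, 0.3, 0.2, 0.1]
    probs[1, :4] = [0.7, 0.1, 0.1, 0.1]
    bg = np.zeros(20)
    bg[:4] = 0.25
    return Pspm(probs, bg)


class TestScorePvalue:
    def test_brute_force_enumeration_width2(self):
        """DP tail equals exhaustive enumeration of all 16 windows."""
        p = _toy_two_col()
        s = p.score_matrix()
        items = [(s[0, a] + s[1, b], 0.0625) for a in range(4) for b in range(4)]
        levels = sorted({round(x, 12) for x, _ in items})
        mids = [(a + b) / 2 for a, b in zip(levels, levels[1:])]
        for t in mids:
            exact = sum(w for x, w in items if x >= t)
            assert score_pvalue(p, t) == pytest.approx(exact, abs=1e-12)

    def test_extremes(self):
        p = _toy_two_col()
        s = p.score_matrix()
        smin = np.nansum(np.nanmin(np.where(np.isfinite(s), s, np.nan), axis=1))
        smax = np.nansum(np.nanmax(np.where(np.isfinite(s), s, np.nan), axis=1))
        assert score_pvalue(p, smin) == 1.0
        assert score_pvalue(p, smax + 0.01) == 0.0

    def test_monotone_in_threshold(self, pspm):
        ts = np.linspace(-40, 50, 400)
        ps = [score_pvalue(pspm, t) for t in ts]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_nonfinite_threshold_error(self, pspm):
        with pytest.raises(ValueError):
            score_pvalue(pspm, float("nan"))

    def test_halving_granularity_stable_decisions(self, pspm, rng):
        """Halving the bin width must not flip accept/reject at 6e-11."""
        seqs = [_sample_from_pspm(pspm, rng) for _ in range(50)]
        seqs += ["".join(rng.choice(list(AA_ALPHABET), size=15)) for _ in range(50)]
        scores = np.array([score_window(pspm, s) for s in seqs])
        g = (52.0 - -60.0) / 2**14
        p1 = scores_to_pvalues(pspm, scores, granularity=g)
        p2 = scores_to_pvalues(pspm, scores, granularity=g / 2)
        assert np.array_equal(p1 <= 6e-11, p2 <= 6e-11)

    def test_null_scores_stochastically_uniform(self, pspm, rng):
        """P-values of background draws must not be anti-conservative."""
        seq = "".join(rng.choice(list(AA_ALPHABET), size=10_000 + 14))
        scores = np.array(
            [score_window(pspm, seq[i : i + 15]) for i in range(0, 10_000, 7)]
        )
        pvals = scores_to_pvalues(pspm, scores)
        grid = np.array([0.01, 0.05, 0.1, 0.25, 0.5])
        emp = np.array([(pvals <= q).mean() for q in grid])
        assert (emp <= grid + 0.03).all()


# ------------------------------------------------------------------- scanning

class TestScanOrf:
    def test_planted_hit_recovered(self, pspm, rng):
        dom = _sample_from_pspm(pspm, rng)
        flank = "".join(rng.choice(list("GSTNDE"), size=30))
        hits = scan_orf(pspm, flank + dom + flank)
        assert [h.offset for h in hits] == [30]
        assert hits[0].sequence == dom

    def test_two_planted_domains_sorted(self, pspm, rng):
        d1, d2 = (_sample_from_pspm(pspm, rng) for _ in range(2))
        orf = "A" * 20 + d1 + "G" * 7 + d2 + "A" * 5
        hits = scan_orf(pspm, orf)
        assert [h.offset for h in hits] == [20, 42]

    def test_null_background_no_hits(self, pspm, rng):
        seq = "".join(rng.choice(list(AA_ALPHABET), size=10_000))
        assert scan_orf(pspm, seq) == []

    def test_short_orf_empty(self, pspm):
        assert scan_orf(pspm, "ACDEFGHIKL") == []

    def test_pvalue_monotone_in_score(self, pspm, rng):
        seq = "".join(rng.choice(list(AA_ALPHABET), size=2000))
        scores = np.array([score_window(pspm, seq[i : i + 15]) for i in range(1986)])
        pvals = scores_to_pvalues(pspm, scores)
        order = np.argsort(scores)
        assert (np.diff(pvals[order]) <= 1e-15).all()


def test_iterative_rebuild_fixed_point(pspm, rng):
    """build -> scan -> reweight -> rebuild stabilizes when the generator
    is the true model: the re-estimated matrix stops moving within 3 rounds."""
    doms = [
        WeightedDomain(_sample_from_pspm(pspm, rng), 1.0, "o1", f"orf{i}", "a1")
        for i in range(400)
    ]
    current = build_pspm(doms)
    deltas = []
    for _ in range(3):
        hits = []
        for d in doms:
            for h in scan_orf(current, d.sequence):
                hits.append(
                    WeightedDomain(h.sequence, 1.0, d.organism, d.orf_id, d.assembly_id)
                )
        nxt = build_pspm(hits)
        deltas.append(np.abs(nxt.probabilities - current.probabilities).max())
        current = nxt
    assert deltas[-1] < 1e-12  # identical domain set -> identical matrix


# ----------------------------------------------------- logo stats and codon GC

def test_family_logo_stats_identical_column():
    doms = [_wd(), _wd(orf="orf2")]
    freqs, info = family_logo_stats(doms)
    assert freqs[0, AA_TO_INDEX["D"]] == pytest.approx(1.0)
    assert info[0] == pytest.approx(math.log2(20))


def test_weighted_vs_unweighted_frequencies():
    # two assemblies; a1 has two domains in one ORF, a2 has one
    tree = tree_from_string("(o1,o2);")
    other = "A" + DOM[1:]
    domains = [
        _wd(DOM, org="o1", asm="a1", orf="orf1"),
        _wd(DOM, org="o1", asm="a1", orf="orf1"),
        _wd(other, org="o2", asm="a2", orf="orf2"),
    ]
    weighted = assign_weights(domains, tree)
    freqs, _ = family_logo_stats(weighted)
    # equal assembly mass: D and A split position 1 half-half despite 2:1 counts
    assert freqs[0, AA_TO_INDEX["D"]] == pytest.approx(0.5)
    assert freqs[0, AA_TO_INDEX["A"]] == pytest.approx(0.5)


@pytest.mark.parametrize(
    "aa,expected", [("G", 3), ("F", 1), ("K", 1), ("P", 3), ("A", 3), ("W", 2)]
)
def test_aa_max_gc(aa, expected):
    assert aa_max_gc(aa) == expected


def test_aa_max_gc_unknown():
    with pytest.raises(ValueError):
        aa_max_gc("B")
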