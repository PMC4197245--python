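"""Distances, IOPDs, Tukey comparisons, trimming and sitewise dN/dS."""

import itertools
import math
import warnings

import numpy as np
import pytest
from scipy import stats

from cepkit import _jtt
from cepkit.evolution_stats import (
    PairwiseAlignment,
    align_pair,
    compute_iopds,
    logit_tukey,
    ml_distance,
    pair_codon_counts,
    pairwise_ng86,
    rank_tukey,
    sitewise_dnds,
    trim_columns,
)
from cepkit.synthetic_data import simulate_codon_msa


# ------------------------------------------------------------------ JTT model

def test_transition_matrix_matches_scipy_expm():
    """Eigendecomposition route equals an independent matrix exponential."""
    from scipy.linalg import expm

    from cepkit._jtt import rate_matrix, transition_matrix

    q = rate_matrix()
    for t in (0.05, 0.3, 1.0):
        assert np.abs(transition_matrix(t) - expm(q * t)).max() < 1e-10


def test_log_odds_matrix_symmetric_positive_diagonal():
    s = _jtt.log_odds_matrix()
    assert np.allclose(s, s.T)
    assert (np.diag(s) > 0).all()


# ------------------------------------------------------------------ alignment

class TestAlignPair:
    def test_identical_sequences_gapless(self):
        aln = align_pair("ACDEFGHIKL", "ACDEFGHIKL")
        assert aln.seq_a == aln.seq_b == "ACDEFGHIKL"

    def test_single_gap_hand_scored(self):
        aln = align_pair("ACDE", "ACE")
        assert (aln.seq_a, aln.seq_b.count("-")) == ("ACDE", 1)
        s = _jtt.log_odds_matrix(1.0)
        idx = _jtt.JTT_ORDER.index
        best = max(
            s[idx("A"), idx("A")] + s[idx("C"), idx("C")] + s[idx("E"), idx("E")],
            s[idx("A"), idx("A")] + s[idx("C"), idx("C")] + s[idx("E"), idx("D")],
        ) - 11.0  # one opened gap, no extensions
        assert aln.score == pytest.approx(best)

    def test_score_symmetric(self):
        a, b = "MKKLLAQAGDSTEN", "MKRLLAQAGSTEN"
        assert align_pair(a, b).score == pytest.approx(align_pair(b, a).score)

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            align_pair("", "ACD")


# ------------------------------------------------------------------ distances

class TestMlDistance:
    def test_identical_sequences_at_lower_bound(self):
        a = _jtt.sample_equilibrium(100, np.random.default_rng(0))
        d = ml_distance(PairwiseAlignment(a, a, 0.0))
        assert d.distance == pytest.approx(1e-6)
        assert not d.saturated

    def test_simulation_recovery_t03(self):
        rng = np.random.default_rng(42)
        ests = []
        for _ in range(20):
            a = _jtt.sample_equilibrium(500, rng)
            b = _jtt.evolve(a, 0.3, rng)
            ests.append(ml_distance(PairwiseAlignment(a, b, 0.0)).distance)
        assert abs(np.mean(ests) - 0.3) < 0.03

    def test_monotone_in_divergence(self):
        rng = np.random.default_rng(7)
        means = []
        for t in (0.1, 0.5, 1.0):
            vals = []
            for _ in range(10):
                a = _jtt.sample_equilibrium(400, rng)
                b = _jtt.evolve(a, t, rng)
                vals.append(ml_distance(PairwiseAlignment(a, b, 0.0)).distance)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_gap_only_overlap_errors(self):
        with pytest.raises(ValueError, match="no_overlap"):
            ml_distance(PairwiseAlignment("A--", "-CC", 0.0))

    def test_gapped_columns_excluded(self):
        aln = PairwiseAlignment("AAAA-K", "AAAAL-", 0.0)
        assert ml_distance(aln).n_sites == 4


# ---------------------------------------------------------------------- IOPDs

def test_iopd_pair_counting():
    records = [
        ("g1", "asm1", "FamX", "MKKLLAQAGDSTEN"),
        ("g2", "asm1", "FamX", "MKRLLAQAGSSTEN"),
        ("g3", "asm1", "FamX", "MRKLLAQAGDSTHN"),
        ("g4", "asm2", "FamX", "MKKLLAQAGDSTEN"),
        ("g5", "asm2", "FamX", "MKRLLAQAGSSTEN"),
        ("g6", "asm3", "FamY", "MKKLLAQAGDSTEN"),
    ]
    iopds = compute_iopds(records)
    # asm1 -> C(3,2)=3 pairs, asm2 -> 1, asm3 alone -> none; no cross-assembly
    assert len(iopds["FamX"].distances) == 4
    assert "FamY" not in iopds


def test_iopd_direction_tracks_divergence(pspm):
    from cepkit.synthetic_data import SimConfig, simulate_family_contrast

    hi, lo = simulate_family_contrast(
        SimConfig(seed=21, family="Hi", within_genome_divergence=0.8),
        SimConfig(seed=22, family="Lo", within_genome_divergence=0.15),
    )
    records = []
    for res in (hi, lo):
        canon = res.truth[res.truth.locus_class == "canonical"]
        for _, row in canon.iterrows():
            records.append(
                (f"{row.assembly_id}:{row.cds_start}", row.assembly_id,
                 row.family, row.prepropeptide)
            )
    iopds = compute_iopds(records)
    assert np.median(iopds["Hi"].distances) > np.median(iopds["Lo"].distances)


# ---------------------------------------------------------------------- Tukey

class TestRankTukey:
    def test_identical_groups_p_one(self):
        g = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
        assert rank_tukey(g).loc["a", "b"] == pytest.approx(1.0)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(3)
        groups = {
            "a": rng.normal(size=40),
            "b": rng.normal(size=40),
            "c": rng.normal(2.0, size=40),
        }
        p = rank_tukey(groups)
        assert p.loc["c", "a"] < 0.05 and p.loc["c", "b"] < 0.05
        assert p.loc["a", "b"] > 0.05

    def test_against_direct_studentized_range(self):
        """Tukey p equals the studentized-range tail computed from scratch."""
        groups = {
            "g1": [24.5, 23.5, 26.4, 27.1, 29.9],
            "g2": [28.4, 34.2, 29.5, 32.2, 30.1],
            "g3": [26.1, 28.3, 24.3, 26.2, 27.8],
        }
        arrays = [np.asarray(v, float) for v in groups.values()]
        n = 5
        k = 3
        grand = np.concatenate(arrays)
        msw = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (len(grand) - k)
        res = stats.tukey_hsd(*arrays)
        for i, j in itertools.combinations(range(k), 2):
            q = abs(arrays[i].mean() - arrays[j].mean()) / math.sqrt(msw / n)
            p_direct = stats.studentized_range.sf(q, k, len(grand) - k)
            assert res.pvalue[i, j] == pytest.approx(p_direct, abs=1e-6)

    def test_requires_two_groups_of_two(self):
        with pytest.raises(ValueError):
            rank_tukey({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            rank_tukey({"a": [1.0, 2.0], "b": [1.0]})


class TestLogitTukey:
    def test_logit_of_half_is_zero(self):
        assert math.log(0.5 / 0.5) == 0.0  # the transform's anchor
        g = {"a": [0.5] * 5, "b": [0.5] * 5}
        assert logit_tukey(g, adjust=False).loc["a", "b"] == pytest.approx(1.0)

    def test_gc_shift_detected(self):
        rng = np.random.default_rng(9)
        g = {
            "hi": np.clip(rng.normal(0.65, 0.05, 40), 0.01, 0.99),
            "lo": np.clip(rng.normal(0.45, 0.05, 40), 0.01, 0.99),
        }
        assert logit_tukey(g).loc["hi", "lo"] < 0.001

    def test_monotone_group_ordering_preserved(self):
        rng = np.random.default_rng(10)
        g = {
            "low": rng.uniform(0.2, 0.4, 30),
            "mid": rng.uniform(0.4, 0.6, 30),
            "high": rng.uniform(0.6, 0.8, 30),
        }
        means = {k: np.mean(np.log(np.array(v) / (1 - np.array(v)))) for k, v in g.items()}
        assert means["low"] < means["mid"] < means["high"]

    def test_boundary_values_require_adjust(self):
        g = {"a": [0.0, 0.5, 0.6], "b": [0.4, 0.5, 0.6]}
        with pytest.raises(ValueError):
            logit_tukey(g, adjust=False)
        assert logit_tukey(g, adjust=True).shape == (2, 2)


# ------------------------------------------------------------------- trimming

class TestTrimColumns:
    def test_gapless_unchanged(self):
        msa = ["ACDEF", "ACDEF", "ACDDF"]
        trimmed, kept = trim_columns(msa)
        assert trimmed == msa and kept == [0, 1, 2, 3, 4]

    def test_all_gap_column_removed(self):
        msa = ["AC-EF", "AC-EF", "AC-DF"]
        trimmed, kept = trim_columns(msa)
        assert trimmed == ["ACEF", "ACEF", "ACDF"] and kept == [0, 1, 3, 4]

    def test_bimodal_gap_distribution_cut_at_drop(self):
        # four clean columns, three ragged ones (>= half gaps)
        rows = [
            "ACDE-K-",
            "ACDE--L",
            "ACDEF--",
            "ACDE---",
        ]
        trimmed, kept = trim_columns(rows)
        assert kept == [0, 1, 2, 3]

    def test_all_removed_errors(self):
        with pytest.raises(ValueError, match="empty_after_trim"):
            trim_columns(["---", "---"])


# ----------------------------------------------------------------- sitewise dN/dS

class TestPairCodonCounts:
    def test_synonymous_only_pair(self):
        s, n, sd, nd = pair_codon_counts("GGA", "GGC")
        assert (sd, nd) == (1.0, 0.0)

    def test_nonsynonymous_only_pair(self):
        s, n, sd, nd = pair_codon_counts("AAA", "GAA")  # K -> E
        assert (sd, nd) == (0.0, 1.0)

    def test_hand_counted_site_table(self):
        """Leu/Phe toy: expected sites and pathway counts done by hand."""
        # TTT/TTC (Phe) and TTA/TTG (Leu): per-codon synonymous sites are
        # 1/3, 1/3, 2/3, 2/3 (stop-adjacent positions renormalized)
        assert pair_codon_counts("TTT", "TTC")[:2] == (pytest.approx(1 / 3), pytest.approx(8 / 3))
        assert pair_codon_counts("TTA", "TTG")[0] == pytest.approx(2 / 3)
        pooled = np.zeros(4)
        codons = ["TTT", "TTC", "TTA", "TTG"]
        for c1, c2 in itertools.combinations(codons, 2):
            pooled += pair_codon_counts(c1, c2)
        # hand-pooled expected synonymous sites: 1/3 + 4*(1/2) + 2/3 = 3
        assert pooled[0] == pytest.approx(3.0)
        assert pooled[1] == pytest.approx(15.0)
        # observed: TTT-TTC and TTA-TTG synonymous, the other four not
        assert pooled[2] == pytest.approx(2.0)
        assert pooled[3] == pytest.approx(4.0)

    def test_against_biopython_ng86(self):
        """Whole-sequence dN/dS near Biopython's NG86 (stop conventions differ)."""
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        msa = simulate_codon_msa([1.0] * 60, 2, seed=3, proposals_per_codon=0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dn_b, ds_b = cal_dn_ds(CodonSeq(msa[0]), CodonSeq(msa[1]), method="NG86")
        dn, ds = pairwise_ng86(msa[0], msa[1])
        assert dn == pytest.approx(dn_b, rel=0.10)
        assert ds == pytest.approx(ds_b, rel=0.10)


class TestSitewiseDnds:
    def test_all_synonymous_site_is_zero(self):
        msa = ["GGAAAA", "GGCAAA", "GGGAAA", "GGTAAA"]
        prof = sitewise_dnds(msa, bootstrap_reps=50, seed=1)
        assert prof.omega[0] == 0.0

    def test_only_nonsynonymous_changes_inf_sentinel(self):
        msa = ["AAA", "GAA", "CAA", "AAA"]  # K/E/Q, no synonymous changes anywhere
        prof = sitewise_dnds(msa, bootstrap_reps=50, seed=1)
        assert math.isinf(prof.omega[0])
        assert not prof.constrained[0]

    def test_no_changes_site_na_with_wide_interval(self):
        msa = ["ATGGGA", "ATGGGC", "ATGGGT", "ATGGGG"]
        prof = sitewise_dnds(msa, bootstrap_reps=50, seed=1)
        assert math.isnan(prof.omega[0])
        assert prof.lower[0] == 0.0 and math.isinf(prof.upper[0])
        assert not prof.constrained[0]

    def test_interval_contains_point_estimate(self):
        msa = simulate_codon_msa([0.5] * 30, 8, seed=4)
        prof = sitewise_dnds(msa, bootstrap_reps=200, seed=2)
        finite = np.isfinite(prof.omega)
        assert (prof.lower[finite] <= prof.omega[finite] + 1e-9).all()
        assert (prof.omega[finite] <= prof.upper[finite] + 1e-9).all()

    def test_requires_four_sequences_and_frame(self):
        with pytest.raises(ValueError):
            sitewise_dnds(["AAA", "AAA", "AAA"])
        with pytest.raises(ValueError):
            sitewise_dnds(["AAAA", "AAAA", "AAAA", "AAAA"])
        with pytest.raises(ValueError, match="stop"):
            sitewise_dnds(["TAA", "AAA", "AAA", "AAA"])

    def test_constraint_flags_track_selection(self):
        omega = np.array([0.2] * 15 + [1.0] * 15)
        flags = []
        for seed in (5, 6):
            msa = simulate_codon_msa(omega, 20, seed=seed)
            prof = sitewise_dnds(msa, bootstrap_reps=200, seed=9)
            flags.append(prof.constrained)
        flags = np.vstack(flags)
        assert flags[:, :15].mean() > 0.6
        assert flags[:, 15:].mean() < 0.15
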