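"""Molecular-evolution statistics: ML distances, diversity, selection, GC.

* Pairwise amino-acid distances are maximum-likelihood estimates under
  the JTT substitution model: the branch length t maximizing
  sum_sites log(pi_a * P(b|a,t)) over gap-free aligned columns.
* Sequence diversity is summarized as intra-organism pairwise distances
  (IOPDs): distances between genes (or domains) of the *same* assembly,
  aggregated by plant family.
* Family contrasts use Tukey's HSD on rank-transformed distances (the
  distance distributions are multimodal and skewed) and on
  logit-transformed GC contents.
* Sitewise dN/dS uses a pathway-counting (NG86-style) estimator pooled
  over sequence pairs, with bootstrap percentile intervals; a site is
  flagged "constrained" when the interval's upper bound is below 1.
"""

from __future__ import annotations

import functools
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from scipy import optimize, stats

from . import _jtt

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------

def _jtt_alignment_matrix() -> substitution_matrices.Array:
    """JTT-derived log-odds scores (half-bits at t=1) as a biopython matrix."""
    s = _jtt.log_odds_matrix(1.0)
    arr = substitution_matrices.Array(alphabet=_jtt.JTT_ORDER + "X", dims=2)
    for i, a in enumerate(_jtt.JTT_ORDER):
        for j, b in enumerate(_jtt.JTT_ORDER):
            arr[a, b] = s[i, j]
    return arr


def _make_aligner(mode: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _jtt_alignment_matrix()
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass
class PairwiseAlignment:
    seq_a: str  # aligned, with '-'
    seq_b: str
    score: float


def align_pair(
    aa_seq_a: str,
    aa_seq_b: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Global (Needleman-Wunsch) affine-gap alignment with JTT log-odds scores.

    Gap penalties are in half-bit units of the derived matrix. The
    highest-scoring alignment is chosen deterministically.
    """
    if not aa_seq_a or not aa_seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner("global", gap_open, gap_extend)
    aln = aligner.align(aa_seq_a, aa_seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    return PairwiseAlignment(seq_a=a, seq_b=b, score=aln.score)


@dataclass
class PairwiseDistance:
    gene_id_a: str
    gene_id_b: str
    distance: float
    n_sites: int
    saturated: bool = False


_T_MIN, _T_MAX = 1e-6, 10.0


def ml_distance(
    alignment: PairwiseAlignment,
    gene_id_a: str = "a",
    gene_id_b: str = "b",
) -> PairwiseDistance:
    """ML branch length between two aligned AA sequences under JTT.

    Gapped or ambiguous columns are excluded. The likelihood is optimized
    over t in [1e-6, 10] by bracketed scalar search (tolerance 1e-6); a
    maximum at the upper boundary is reported with ``saturated=True``.
    """
    pairs = [
        (a, b)
        for a, b in zip(alignment.seq_a, alignment.seq_b)
        if a in _jtt.JTT_ORDER and b in _jtt.JTT_ORDER
    ]
    if not pairs:
        raise ValueError("no_overlap: zero gap-free aligned columns")
    counts = np.zeros((20, 20))
    for a, b in pairs:
        counts[_jtt.JTT_ORDER.index(a), _jtt.JTT_ORDER.index(b)] += 1
    log_pi = np.log(_jtt.JTT_FREQS)

    def neg_loglik(t: float) -> float:
        p = _jtt.transition_matrix(t)
        with np.errstate(divide="ignore"):
            ll = counts * (log_pi[:, np.newaxis] + np.log(p))
        return -np.sum(ll[counts > 0])

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(_T_MIN, _T_MAX), method="bounded",
        options={"xatol": 1e-6},
    )
    t_hat = float(res.x)
    # the bounded method never evaluates exactly at the ends; snap to a
    # boundary when the objective there is at least as good
    if neg_loglik(_T_MIN) <= res.fun:
        t_hat = _T_MIN
    saturated = t_hat > _T_MAX - 1e-3
    return PairwiseDistance(
        gene_id_a=gene_id_a,
        gene_id_b=gene_id_b,
        distance=t_hat,
        n_sites=len(pairs),
        saturated=saturated,
    )


def pairwise_distance(seq_a: str, seq_b: str, **kw) -> PairwiseDistance:
    """Convenience: align then estimate the ML distance."""
    return ml_distance(align_pair(seq_a, seq_b), **kw)


# ---------------------------------------------------------------------------
# IOPDs
# ---------------------------------------------------------------------------

@dataclass
class IopdSet:
    family: str
    distances: list[float] = field(default_factory=list)


def compute_iopds(
    records: Iterable[tuple[str, str, str, str]],
    level: str = "gene",
) -> dict[str, IopdSet]:
    """Intra-assembly pairwise distances aggregated by family.

    ``records`` are (gene_id, assembly_id, family, sequence) tuples; the
    sequence is the prepropeptide at ``level="gene"`` or the 15-mer at
    ``level="domain"``. Only pairs within one assembly contribute;
    assemblies with fewer than two records contribute nothing.
    """
    if level not in {"gene", "domain"}:
        raise ValueError("level must be 'gene' or 'domain'")
    by_assembly: dict[str, list[tuple[str, str, str]]] = {}
    for gene_id, assembly_id, family, seq in records:
        by_assembly.setdefault(assembly_id, []).append((gene_id, family, seq))
    out: dict[str, IopdSet] = {}
    for assembly_id, items in by_assembly.items():
        for (id_a, fam, seq_a), (id_b, _, seq_b) in itertools.combinations(items, 2):
            d = pairwise_distance(seq_a, seq_b, gene_id_a=id_a, gene_id_b=id_b)
            out.setdefault(fam, IopdSet(family=fam)).distances.append(d.distance)
    return out


def iopd_table(iopds: Mapping[str, IopdSet]) -> pd.DataFrame:
    """Density-plot-ready long-format export."""
    rows = [
        {"family": s.family, "distance": d}
        for s in iopds.values()
        for d in s.distances
    ]
    return pd.DataFrame(rows, columns=["family", "distance"])


# ---------------------------------------------------------------------------
# Tukey HSD on transformed data
# ---------------------------------------------------------------------------

def _tukey(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(names) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # identical groups: no evidence of difference
        p = np.ones((len(names), len(names)))
    else:
        p = stats.tukey_hsd(*arrays).pvalue
    return pd.DataFrame(p, index=names, columns=names)


def rank_tukey(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey HSD on midrank-transformed pooled values.

    Rank transformation makes the comparison robust to the multimodality,
    skew and variance heterogeneity typical of distance distributions.
    Returns the full matrix of adjusted p-values.
    """
    names = list(groups)
    sizes = [len(groups[n]) for n in names]
    pooled = np.concatenate([np.asarray(groups[n], dtype=float) for n in names])
    ranks = stats.rankdata(pooled)  # average ranks for ties
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    return _tukey(dict(zip(names, split)))


def logit_tukey(
    gc_groups: Mapping[str, Sequence[float]],
    adjust: bool = True,
) -> pd.DataFrame:
    """Tukey HSD on logit-transformed proportions (e.g. GC contents).

    With ``adjust``, the standard small-sample smoothing
    p <- (p*(n-1) + 0.5)/n is applied per group so boundary values 0 and 1
    become finite log-odds; without it, boundary values are an error.
    """
    transformed: dict[str, np.ndarray] = {}
    for name, values in gc_groups.items():
        v = np.asarray(values, dtype=float)
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"group {name!r}: proportions must lie in [0,1]")
        if adjust:
            n = len(v)
            v = (v * (n - 1) + 0.5) / n
        elif np.any((v <= 0) | (v >= 1)):
            raise ValueError(
                f"group {name!r}: values at 0 or 1 require adjust=True"
            )
        transformed[name] = np.log(v / (1 - v))
    return _tukey(transformed)


# ---------------------------------------------------------------------------
# alignment column trimming
# ---------------------------------------------------------------------------

def trim_columns(
    msa: Sequence[str], mode: str = "gappyout_like"
) -> tuple[list[str], list[int]]:
    """Remove gappy columns by a data-driven gap-score threshold.

    Approximates gap-based trimming ("gappyout"-like): per-column gap
    scores (1 - gap fraction) are sorted descending and the threshold is
    placed at the steepest drop between consecutive distinct values;
    columns whose score falls strictly below the pre-drop value are
    excised. A gapless alignment is returned unchanged. Returns the
    trimmed rows and the kept column indices.
    """
    if mode != "gappyout_like":
        raise ValueError(f"unknown mode {mode!r}")
    ncol = len(msa[0])
    if any(len(row) != ncol for row in msa):
        raise ValueError("alignment is not rectangular")
    gap_frac = np.array(
        [sum(row[c] == "-" for row in msa) / len(msa) for c in range(ncol)]
    )
    scores = 1.0 - gap_frac
    distinct = np.unique(scores)[::-1]  # descending
    if distinct.size == 1:
        kept = list(range(ncol)) if distinct[0] > 0 else []
    else:
        drops = distinct[:-1] - distinct[1:]
        cut = distinct[int(np.argmax(drops))]  # keep scores >= pre-drop value
        kept = [c for c in range(ncol) if scores[c] >= cut]
    if not kept:
        raise ValueError("empty_after_trim: all columns removed")
    trimmed = ["".join(row[c] for c in kept) for row in msa]
    return trimmed, kept


# ---------------------------------------------------------------------------
# sitewise dN/dS
# ---------------------------------------------------------------------------

_STOPS = set(standard_dna_table.stop_codons)
_FWD = standard_dna_table.forward_table


def _translate_codon(codon: str) -> str | None:
    if codon in _STOPS:
        return None
    return _FWD.get(codon)


@functools.lru_cache(maxsize=None)
def _syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """NG86 expected synonymous/non-synonymous site counts for one codon.

    At each codon position the three possible single-nucleotide changes
    are classified; mutations to stop codons are excluded from the
    denominator at that position.
    """
    aa = _translate_codon(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon}")
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            maa = _translate_codon(mutant)
            if maa is None:
                continue
            valid += 1
            if maa == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@functools.lru_cache(maxsize=None)
def _pathway_changes(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/non-synonymous differences over mutational pathways.

    Pathways passing through stop codons are skipped (all-blocked pairs
    fall back to averaging over every pathway).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            aa1, aa2 = _translate_codon(cur), _translate_codon(nxt)
            if aa2 is None or aa1 is None:
                blocked = True
                break
            if aa1 == aa2:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            results.append((sd, nd))
    if not results:  # every pathway crosses a stop: count nucleotide-wise
        for order in itertools.permutations(diff):
            cur = c1
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                aa1, aa2 = _translate_codon(cur), _translate_codon(nxt)
                if aa1 is not None and aa2 is not None and aa1 == aa2:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            results.append((sd, nd))
    sd = float(np.mean([r[0] for r in results]))
    nd = float(np.mean([r[1] for r in results]))
    return sd, nd


def pair_codon_counts(c1: str, c2: str) -> tuple[float, float, float, float]:
    """(S, N, Sd, Nd) for one codon pair: expected sites and observed changes."""
    s1, n1 = _syn_nonsyn_sites(c1)
    s2, n2 = _syn_nonsyn_sites(c2)
    sd, nd = _pathway_changes(c1, c2)
    return (s1 + s2) / 2.0, (n1 + n2) / 2.0, sd, nd


def _jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction of a proportion of differences."""
    if p <= 0:
        return 0.0
    if p >= 0.75:
        return float("inf")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _omega_from_counts(S, N, Sd, Nd) -> float:
    """dN/dS from pooled counts; NaN if no data, inf if dS is zero with dN>0."""
    if S <= 0 or N <= 0:
        return float("nan")
    if Sd == 0 and Nd == 0:
        return float("nan")
    ds = _jc_correct(Sd / S)
    dn = _jc_correct(Nd / N)
    if ds == 0:
        return float("inf") if dn > 0 else float("nan")
    if math.isinf(ds):
        return 0.0 if not math.isinf(dn) else float("nan")
    return dn / ds


@dataclass
class DnDsProfile:
    group_id: str
    omega: np.ndarray  # per aligned codon site; NaN = no substitutions
    lower: np.ndarray
    upper: np.ndarray
    constrained: np.ndarray  # bool: upper < 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_id": self.group_id,
                "site": np.arange(1, len(self.omega) + 1),
                "omega": self.omega,
                "lower": self.lower,
                "upper": self.upper,
                "constrained": self.constrained,
            }
        )


def _bca_interval(
    estimate: np.ndarray, boot: np.ndarray, jack: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site BCa bootstrap interval (bias correction from the bootstrap
    CDF at the point estimate, acceleration from the jackknife skewness)."""
    z_lo = stats.norm.ppf((1 - level) / 2)
    z_hi = stats.norm.ppf(1 - (1 - level) / 2)
    n_sites = estimate.size
    lower = np.full(n_sites, np.nan)
    upper = np.full(n_sites, np.nan)
    with np.errstate(invalid="ignore"):
        for k in range(n_sites):
            b = boot[:, k]
            b = b[~np.isnan(b)]
            if b.size < 20 or not np.isfinite(estimate[k]):
                if b.size:
                    lower[k] = np.percentile(b, 2.5)
                    upper[k] = np.percentile(b, 97.5)
                continue
            prop = np.mean(b < estimate[k]) + 0.5 * np.mean(b == estimate[k])
            z0 = stats.norm.ppf(np.clip(prop, 1e-4, 1 - 1e-4))
            jk = jack[:, k]
            jk = jk[np.isfinite(jk)]
            if jk.size < 3:
                accel = 0.0
            else:
                d = jk.mean() - jk
                denom = (d**2).sum() ** 1.5
                accel = (d**3).sum() / (6 * denom) if denom > 0 else 0.0
            q_lo = stats.norm.cdf(z0 + (z0 + z_lo) / (1 - accel * (z0 + z_lo)))
            q_hi = stats.norm.cdf(z0 + (z0 + z_hi) / (1 - accel * (z0 + z_hi)))
            lower[k] = np.percentile(b, 100 * np.clip(q_lo, 0.001, 0.999))
            upper[k] = np.percentile(b, 100 * np.clip(q_hi, 0.001, 0.999))
    return lower, upper


def pairwise_ng86(codon_seq_a: str, codon_seq_b: str) -> tuple[float, float]:
    """Whole-sequence (dN, dS) for one pair by pathway counting + JC correction."""
    if len(codon_seq_a) != len(codon_seq_b) or len(codon_seq_a) % 3:
        raise ValueError("sequences must be equal-length codon sequences")
    S = N = Sd = Nd = 0.0
    for k in range(len(codon_seq_a) // 3):
        c1 = codon_seq_a[3 * k : 3 * k + 3]
        c2 = codon_seq_b[3 * k : 3 * k + 3]
        if "-" in c1 + c2 or any(nt not in "ACGT" for nt in c1 + c2):
            continue
        s, n, sd, nd = pair_codon_counts(c1, c2)
        S += s
        N += n
        Sd += sd
        Nd += nd
    return _jc_correct(Nd / N), _jc_correct(Sd / S)


def sitewise_dnds(
    codon_msa: Sequence[str],
    bootstrap_reps: int = 1000,
    seed: int | None = None,
    group_id: str = "group",
) -> DnDsProfile:
    """Per-site dN/dS with bootstrap intervals over sequences.

    Expected synonymous/non-synonymous sites and pathway-averaged observed
    changes are counted for every codon site of every sequence pair and
    pooled. dN is computed per site; dS — the synonymous rate, a
    site-independent neutral clock — is pooled over the whole alignment,
    so each site's ratio is its non-synonymous rate relative to the
    alignment-wide synonymous rate (mirroring how model-based per-site
    dN/dS machinery shares the synonymous rate across sites). Both rates
    receive a Jukes-Cantor correction.

    The (lower, upper) interval is a 95% bias-corrected accelerated
    (BCa) bootstrap interval over resamples of the *sequences* (pairs
    are not independent — each sequence participates in many; plain
    percentile intervals undercover for this skewed ratio statistic); a
    site is flagged constrained when the upper bound is below 1. A site with no observed
    changes anywhere gets a NaN estimate and an uninformative (0, inf)
    interval; if the alignment has no synonymous changes at all, sites
    with non-synonymous changes get the +inf sentinel. Gapped or
    ambiguous codons are skipped pairwise. Requires >= 4 in-frame
    sequences without internal stops.
    """
    n_seqs = len(codon_msa)
    if n_seqs < 4:
        raise ValueError("need at least 4 sequences")
    length = len(codon_msa[0])
    if length % 3 or any(len(s) != length for s in codon_msa):
        raise ValueError("codon alignment must be rectangular with length % 3 == 0")
    n_sites = length // 3
    for seq in codon_msa:
        for k in range(n_sites):
            if seq[3 * k : 3 * k + 3] in _STOPS:
                raise ValueError(f"internal stop codon at site {k + 1}")
    pairs = list(itertools.combinations(range(n_seqs), 2))
    col_of = {p: j for j, p in enumerate(pairs)}
    counts = np.zeros((n_sites, len(pairs), 4))  # (S, N, Sd, Nd)
    for j, (i1, i2) in enumerate(pairs):
        for k in range(n_sites):
            c1 = codon_msa[i1][3 * k : 3 * k + 3]
            c2 = codon_msa[i2][3 * k : 3 * k + 3]
            if "-" in c1 + c2 or any(nt not in "ACGT" for nt in c1 + c2):
                continue
            counts[k, j] = pair_codon_counts(c1, c2)

    def site_omegas(seq_idx) -> np.ndarray:
        cols = [
            col_of[(min(a, b), max(a, b))]
            for a, b in itertools.combinations(seq_idx, 2)
            if a != b
        ]
        pooled = counts[:, cols].sum(axis=1)  # n_sites x 4
        tot = pooled.sum(axis=0)
        ds = _jc_correct(tot[2] / tot[0]) if tot[0] > 0 else float("nan")
        out = np.empty(n_sites)
        for k in range(n_sites):
            S, N, Sd, Nd = pooled[k]
            if N <= 0 or (Sd == 0 and Nd == 0):
                out[k] = float("nan")
                continue
            dn = _jc_correct(Nd / N)
            if math.isinf(ds):  # saturated synonymous rate
                out[k] = 0.0 if np.isfinite(dn) else float("nan")
            elif math.isnan(ds) or ds == 0:
                out[k] = float("inf") if dn > 0 else float("nan")
            else:
                out[k] = dn / ds if np.isfinite(dn) else float("inf")
        return out

    omega = site_omegas(range(n_seqs))
    rng = np.random.default_rng(seed)
    boot = np.empty((bootstrap_reps, n_sites))
    for r in range(bootstrap_reps):
        boot[r] = site_omegas(rng.integers(0, n_seqs, size=n_seqs))
    jack = np.array(
        [site_omegas([i for i in range(n_seqs) if i != j]) for j in range(n_seqs)]
    )
    lower, upper = _bca_interval(omega, boot, jack)
    finite = np.isfinite(omega)  # the interval always brackets the estimate
    lower[finite] = np.minimum(lower[finite], omega[finite])
    upper[finite] = np.maximum(upper[finite], omega[finite])
    none_observed = np.isnan(omega)
    lower[none_observed] = 0.0
    upper[none_observed] = float("inf")
    upper[np.isnan(upper) & ~none_observed] = float("inf")
    lower[np.isnan(lower) & ~none_observed] = 0.0
    constrained = np.where(np.isnan(upper), False, upper < 1.0)
    return DnDsProfile(
        group_id=group_id,
        omega=omega,
        lower=lower,
        upper=upper,
        constrained=constrained,
    )
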