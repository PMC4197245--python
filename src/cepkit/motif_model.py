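"""Weighted position-specific probability matrices and motif scanning.

The motif model is a width-15, ungapped per-position AA probability matrix
(PSPM) estimated from a *weighted* set of peptide-domain instances. The
weighting has two stages:

1. Equalization — every genome assembly receives equal mass, shared
   equally among its ORFs, shared equally among the domains of each ORF.
   This stops domain-rich genes and gene-rich genomes from dominating.
2. Lineage decay — each domain's weight is multiplied by ``decay**depth``
   where ``depth`` counts internal nodes from the species-tree root down
   to the domain's organism (root included). Densely sampled lineages sit
   deeper in the tree and are discounted; the default decay of 0.8
   corresponds to a 20% reduction per internal node.

Candidate 15-mers are scored in bits (sum of log2 probability/background
ratios) and assigned *exact* tail p-values under the background model by
dynamic programming over discretized per-position score distributions —
the same semantics as FIMO-style motif scanning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .formats_io import AA_TO_INDEX, MotifRecord, SpeciesTree

DEFAULT_P_CUTOFF = 6e-11
MOTIF_WIDTH = 15

_NEG_INF = float("-inf")


@dataclass
class WeightedDomain:
    """A 15-mer domain instance with provenance and hierarchical weight."""

    sequence: str
    weight: float
    organism: str
    orf_id: str
    assembly_id: str

    def __post_init__(self) -> None:
        if len(self.sequence) != MOTIF_WIDTH:
            raise ValueError(f"domain {self.sequence!r} is not {MOTIF_WIDTH} AA")
        if any(a not in AA_TO_INDEX for a in self.sequence):
            raise ValueError(f"domain {self.sequence!r} has non-standard letters")
        if not self.weight > 0:
            raise ValueError("domain weight must be positive")


@dataclass
class DomainHit:
    """A motif match within an ORF's AA sequence."""

    orf_id: str
    offset: int
    sequence: str
    bit_score: float
    p_value: float


@dataclass
class Pspm:
    """A position-specific probability matrix with background model."""

    probabilities: np.ndarray  # width x 20
    background: np.ndarray  # 20
    pseudocount: float = 0.0
    motif_id: str = "motif"
    source_nsites: float = 0.0

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[1] != 20:
            raise ValueError("probabilities must be width x 20")
        if np.any(np.abs(self.probabilities.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("PSPM rows must sum to 1 within 1e-9")
        if self.pseudocount > 0 and np.any(self.probabilities <= 0):
            raise ValueError("pseudocount > 0 implies strictly positive entries")
        self._cache: dict = {}

    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    def score_matrix(self) -> np.ndarray:
        """Per-position log2(p/bg) scores; -inf where p = 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log2(self.probabilities) - np.log2(self.background)

    def to_motif_record(self) -> MotifRecord:
        return MotifRecord(
            motif_id=self.motif_id,
            width=self.width,
            probabilities=self.probabilities,
            background=self.background,
            source_nsites=self.source_nsites,
        )

    @classmethod
    def from_motif_record(cls, rec: MotifRecord, pseudocount: float = 0.0) -> "Pspm":
        return cls(
            probabilities=rec.probabilities,
            background=rec.background,
            pseudocount=pseudocount,
            motif_id=rec.motif_id,
            source_nsites=rec.source_nsites,
        )


def uniform_background() -> np.ndarray:
    return np.full(20, 0.05)


# ---------------------------------------------------------------------------
# weighting
# ---------------------------------------------------------------------------

def assign_weights(
    domains: Iterable[WeightedDomain],
    species_tree: SpeciesTree | None,
    decay: float = 0.8,
) -> list[WeightedDomain]:
    """Apply two-stage weighting; output weights sum to 1.

    Stage 1 equalizes mass across assemblies, across ORFs within an
    assembly and across domains within an ORF. Stage 2 multiplies each
    domain's weight by ``decay**depth(organism)`` using the species tree
    (pass ``None`` to skip the decay stage), then renormalizes. Input
    weights are ignored; the result is independent of input order.
    """
    if not 0 < decay <= 1:
        raise ValueError("decay must lie in (0, 1]")
    domains = list(domains)
    if not domains:
        raise ValueError("no domains to weight")
    if species_tree is not None:
        missing = sorted(
            {d.organism for d in domains} - species_tree.leaves
        )
        if missing:
            raise ValueError(
                f"organisms absent from species tree: {missing}"
            )
    orfs_per_assembly: dict[str, set[str]] = {}
    domains_per_orf: dict[tuple[str, str], int] = {}
    for d in domains:
        orfs_per_assembly.setdefault(d.assembly_id, set()).add(d.orf_id)
        key = (d.assembly_id, d.orf_id)
        domains_per_orf[key] = domains_per_orf.get(key, 0) + 1

    n_assemblies = len(orfs_per_assembly)
    out = []
    for d in domains:
        mass = (
            1.0
            / n_assemblies
            / len(orfs_per_assembly[d.assembly_id])
            / domains_per_orf[(d.assembly_id, d.orf_id)]
        )
        if species_tree is not None:
            mass *= decay ** species_tree.depth(d.organism)
        out.append(
            WeightedDomain(
                sequence=d.sequence,
                weight=mass,
                organism=d.organism,
                orf_id=d.orf_id,
                assembly_id=d.assembly_id,
            )
        )
    total = sum(d.weight for d in out)
    for d in out:
        d.weight /= total
    return out


# ---------------------------------------------------------------------------
# PSPM estimation and scoring
# ---------------------------------------------------------------------------

def build_pspm(
    weighted_domains: Sequence[WeightedDomain],
    pseudocount: float | None = None,
    background: np.ndarray | None = None,
) -> Pspm:
    """Estimate a PSPM by weighted column counting.

    ``probabilities[i, a] = (sum of weights with letter a at position i
    + pseudocount * background[a]) / (total weight + pseudocount)``.

    ``pseudocount=None`` selects the conventional Dirichlet smoothing of
    0.01 per source site (0.01 * len(weighted_domains)).
    """
    if not weighted_domains:
        raise ValueError("cannot build a PSPM from zero domains")
    widths = {len(d.sequence) for d in weighted_domains}
    if widths != {MOTIF_WIDTH}:
        raise ValueError(f"all domains must have width {MOTIF_WIDTH}")
    if background is None:
        background = uniform_background()
    if pseudocount is None:
        pseudocount = 0.01 * len(weighted_domains)
    counts = np.zeros((MOTIF_WIDTH, 20))
    for d in weighted_domains:
        for i, a in enumerate(d.sequence):
            counts[i, AA_TO_INDEX[a]] += d.weight
    total = sum(d.weight for d in weighted_domains)
    probs = (counts + pseudocount * background[np.newaxis, :]) / (total + pseudocount)
    probs /= probs.sum(axis=1, keepdims=True)
    return Pspm(
        probabilities=probs,
        background=np.asarray(background, dtype=float),
        pseudocount=pseudocount,
        source_nsites=len(weighted_domains),
    )


def score_window(pspm: Pspm, window: str) -> float:
    """Bit score of a single window: sum of log2(p_i(a_i)/bg(a_i)).

    Letters outside the 20-AA alphabet (X from ambiguous codons) and
    zero-probability cells score -inf.
    """
    if len(window) != pspm.width:
        raise ValueError(
            f"window length {len(window)} != motif width {pspm.width}"
        )
    s = pspm.score_matrix()
    total = 0.0
    for i, a in enumerate(window):
        idx = AA_TO_INDEX.get(a)
        if idx is None:
            return _NEG_INF
        total += s[i, idx]
    return total


def _score_distribution(pspm: Pspm, granularity: float | None):
    """Discretized null distribution of window scores.

    Returns (granularity, min_k, tail, smin, smax) where ``tail[j]`` is the
    background probability that the integer-discretized score is >= min_k+j,
    and smin/smax are the exact achievable score extremes (finite part).
    """
    key = ("dist", granularity)
    if key in pspm._cache:
        return pspm._cache[key]
    s = pspm.score_matrix()
    finite = np.where(np.isfinite(s), s, np.nan)
    smin = np.nansum(np.nanmin(finite, axis=1))
    smax = np.nansum(np.nanmax(finite, axis=1))
    if granularity is None:
        span = max(smax - smin, 1e-9)
        granularity = span / 2**14
    # per-position scores round UP: every window's discretized sum is >= its
    # exact score, so reported p-values are conservative (never understate)
    k = np.where(np.isfinite(s), np.ceil(s / granularity), 0).astype(np.int64)
    kmin = int(np.where(np.isfinite(s), k, np.iinfo(np.int64).max).min(axis=1).sum())
    kmax = int(np.where(np.isfinite(s), k, np.iinfo(np.int64).min).max(axis=1).sum())
    size = kmax - kmin + 1
    pmf = np.zeros(size)
    pmf[0] = 1.0  # offset: index 0 == running minimum score
    base = 0
    for i in range(pspm.width):
        row_k = k[i]
        row_min = int(row_k[np.isfinite(s[i])].min())
        new = np.zeros(size)
        for a in range(20):
            if not np.isfinite(s[i, a]) or pspm.background[a] == 0:
                continue
            shift = int(row_k[a]) - row_min
            new[shift:] += pspm.background[a] * pmf[: size - shift if shift else size]
        pmf = new
        base += row_min
    # tail[j] = P(K >= kmin + j); pmf index j corresponds to score kmin + j
    tail = np.cumsum(pmf[::-1])[::-1]
    result = (granularity, kmin, tail, smin, smax)
    pspm._cache[key] = result
    return result


def score_pvalue(
    pspm: Pspm, threshold_score: float, granularity: float | None = None
) -> float:
    """Exact tail probability P(score >= threshold) for a background 15-mer.

    Computed by dynamic programming over per-position score distributions
    discretized at ``granularity`` bits (default: score range / 2**14, at
    least ten thousand bins). Thresholds at or below the minimum achievable
    score give exactly 1.0; above the maximum, exactly 0.0.
    """
    if not np.isfinite(threshold_score):
        raise ValueError("threshold must be finite")
    g, kmin, tail, smin, smax = _score_distribution(pspm, granularity)
    if threshold_score <= smin:
        return 1.0
    if threshold_score > smax:
        return 0.0
    idx = int(math.ceil(threshold_score / g - 1e-9)) - kmin
    if idx <= 0:
        return 1.0
    if idx >= tail.size:
        return 0.0
    return float(tail[idx])


def scores_to_pvalues(
    pspm: Pspm, scores: np.ndarray, granularity: float | None = None
) -> np.ndarray:
    """Vectorized p-value lookup; monotone non-increasing in score."""
    g, kmin, tail, smin, smax = _score_distribution(pspm, granularity)
    scores = np.asarray(scores, dtype=float)
    neginf = ~np.isfinite(scores)
    idx = np.ceil(np.where(neginf, 0.0, scores) / g - 1e-9).astype(np.int64) - kmin
    idx = np.clip(idx, 0, tail.size)
    padded = np.append(tail, 0.0)
    p = padded[idx]
    p[scores <= smin] = 1.0
    p[scores > smax] = 0.0
    p[neginf] = 1.0
    return p


def _window_scores(pspm: Pspm, aa_seq: str) -> np.ndarray:
    """Bit scores of every window of the motif width (vectorized)."""
    w = pspm.width
    n = len(aa_seq) - w + 1
    if n <= 0:
        return np.empty(0)
    s = pspm.score_matrix()
    idx = np.array([AA_TO_INDEX.get(a, -1) for a in aa_seq], dtype=np.int64)
    # letters outside the alphabet score -inf
    col = np.where(idx >= 0, idx, 0)
    windows = np.lib.stride_tricks.sliding_window_view(col, w)
    bad = np.lib.stride_tricks.sliding_window_view(idx < 0, w).any(axis=1)
    scores = s[np.arange(w)[np.newaxis, :], windows].sum(axis=1)
    scores[bad] = _NEG_INF
    return scores


def scan_orf(
    pspm: Pspm,
    orf_aa_sequence: str,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    orf_id: str = "",
    granularity: float | None = None,
) -> list[DomainHit]:
    """Scan an ORF AA sequence for motif hits at the p-value cutoff.

    Overlapping hits are resolved greedily by descending bit score (ties
    to the leftmost offset); survivors are returned sorted by offset.
    Sequences shorter than the motif width yield an empty list.
    """
    if not 0 < p_cutoff < 1:
        raise ValueError("p_cutoff must lie in (0, 1)")
    scores = _window_scores(pspm, orf_aa_sequence)
    if scores.size == 0:
        return []
    pvals = scores_to_pvalues(pspm, scores, granularity)
    cand = np.nonzero(pvals <= p_cutoff)[0]
    order = sorted(cand, key=lambda i: (-scores[i], i))
    taken: list[int] = []
    for i in order:
        if all(abs(i - j) >= pspm.width for j in taken):
            taken.append(i)
    return [
        DomainHit(
            orf_id=orf_id,
            offset=int(i),
            sequence=orf_aa_sequence[i : i + pspm.width],
            bit_score=float(scores[i]),
            p_value=float(pvals[i]),
        )
        for i in sorted(taken)
    ]


# ---------------------------------------------------------------------------
# logo statistics and codon GC
# ---------------------------------------------------------------------------

def family_logo_stats(
    weighted_domains: Sequence[WeightedDomain],
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted per-position AA frequencies and information content.

    Returns (frequencies: width x 20, information: width) with information
    content in bits: log2(20) minus the column's Shannon entropy.
    """
    if not weighted_domains:
        raise ValueError("empty domain set")
    freqs = np.zeros((MOTIF_WIDTH, 20))
    for d in weighted_domains:
        for i, a in enumerate(d.sequence):
            if a not in AA_TO_INDEX:
                raise ValueError(f"unknown amino acid {a!r}")
            freqs[i, AA_TO_INDEX[a]] += d.weight
    freqs /= freqs.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = np.log2(20) + plogp.sum(axis=1)
    return freqs, info


_STANDARD_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _STANDARD_CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in standard_dna_table.forward_table.items():
            _STANDARD_CODONS.setdefault(aa, []).append(codon)
    return _STANDARD_CODONS


def aa_max_gc(aa: str) -> int:
    """Maximum G+C count over the standard codons encoding an amino acid."""
    table = _codon_table()
    if aa not in table:
        raise ValueError(f"unknown amino acid {aa!r}")
    return max(c.count("G") + c.count("C") for c in table[aa])
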