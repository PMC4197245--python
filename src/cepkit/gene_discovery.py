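"""Discovery of canonical secreted-peptide genes in genome assemblies.

A canonical gene here is a single-exon gene whose translated product
(the prepropeptide) carries an N-terminal secretion signal (NSS), a
variable region, one or more 15-residue peptide domains, and an optional
short C-terminal extension ending at the stop codon.

Discovery proceeds in four stages:

1. six-frame ORF extraction — maximal stop-free runs of >= 50 AA;
2. motif scanning of each ORF with a PSPM at an exact-p-value cutoff;
3. start-codon selection — every in-frame Met or Leu codon upstream of
   the first domain is a candidate start; the candidate whose downstream
   prefix scores highest under a signal-peptide scorer wins, provided the
   score exceeds the cutoff (default 0.400, strict);
4. architecture parsing — segment lengths are measured from the scorer's
   cleavage-site call and the domain/stop positions.

The external signal-peptide predictor used in the original workflow is
abstracted behind the :class:`SignalScorer` contract; a deterministic
heuristic scorer (charge / hydrophobic core / small-residue cleavage
rule) is provided, and precomputed scores can be supplied instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

from Bio.Seq import Seq

from .formats_io import GenomeAssembly
from .motif_model import DEFAULT_P_CUTOFF, DomainHit, Pspm, scan_orf

logger = logging.getLogger(__name__)

MET_CODONS = {"ATG"}
LEU_CODONS = {"TTA", "TTG", "CTT", "CTC", "CTA", "CTG"}
DEFAULT_START_CODONS = MET_CODONS | LEU_CODONS

#: Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

_SMALL_RESIDUES = set("AGSCT")
_POSITIVE_RESIDUES = set("KR")


@dataclass
class Orf:
    """A maximal stop-free open reading frame in one of six frames.

    ``start``/``end`` are the 0-based half-open nucleotide span of the AA
    run on the *forward* strand of the contig; ``nt_seq`` holds the
    coding-strand nucleotides of that span (reverse-complemented for -).
    """

    orf_id: str
    contig_id: str
    strand: str
    frame: int
    start: int
    end: int
    aa_seq: str
    nt_seq: str

    def __post_init__(self) -> None:
        if self.end - self.start != 3 * len(self.aa_seq):
            raise ValueError(f"{self.orf_id}: span does not cover the AA run")


@dataclass
class CepGene:
    """A discovered gene with its four-segment architecture.

    ``cds_start``/``cds_end`` delimit the coding sequence (stop codon
    excluded) on the forward strand, 0-based half-open. ``domain_offsets``
    are AA indices within the prepropeptide.
    """

    gene_id: str
    orf: Orf
    start_offset: int
    nss_len: int
    var_len: int
    domain_offsets: list[int]
    cterm_len: int
    signal_score: float
    cds: str
    prepropeptide: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.nss_len < 1 or self.var_len < 0 or not self.domain_offsets:
            raise ValueError(f"{self.gene_id}: invalid segment lengths")
        last_end = self.domain_offsets[-1] + 15
        if self.cterm_len != len(self.prepropeptide) - last_end:
            raise ValueError(f"{self.gene_id}: segments do not tile the peptide")
        if str(Seq(self.cds).translate()) != self.prepropeptide:
            raise ValueError(f"{self.gene_id}: CDS does not translate to peptide")

    @property
    def contig_id(self) -> str:
        return self.orf.contig_id

    @property
    def strand(self) -> str:
        return self.orf.strand

    @property
    def lacks_cterm_extension(self) -> bool:
        return self.cterm_len == 0


class SignalScorer(Protocol):
    """Pluggable contract for N-terminal secretion-signal scoring."""

    name: str

    def score(self, prefix: str) -> float:
        """Deterministic signal likelihood in [0, 1]; higher = more signal-like."""
        ...

    def cleavage_site(self, prefix: str) -> int:
        """Predicted NSS length (cleavage after this many residues)."""
        ...


@dataclass
class Rejection:
    orf_id: str
    reason: str


@dataclass
class DiscoveryConfig:
    min_orf_len: int = 50
    p_cutoff: float = DEFAULT_P_CUTOFF
    signal_cutoff: float = 0.400
    start_codons: frozenset = frozenset(DEFAULT_START_CODONS)
    scorer: SignalScorer | None = None


# ---------------------------------------------------------------------------
# ORF extraction
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _translate_frame(nt: str) -> str:
    """Translate full codons; codons containing N become X; stops are '*'."""
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


def extract_orfs(
    assembly: GenomeAssembly, min_orf_len: int = 50
) -> list[Orf]:
    """Extract maximal stop-free runs of >= ``min_orf_len`` AA in all six frames.

    Runs abutting contig ends are emitted without requiring flanking stop
    codons; N-containing codons translate to X and do not terminate runs.
    The length threshold is inclusive.
    """
    orfs: list[Orf] = []
    for contig_id, contig in assembly.sequences:
        length = len(contig)
        for strand in "+-":
            work = contig if strand == "+" else _revcomp(contig)
            for frame in range(3):
                aa = _translate_frame(work[frame:])
                pos = 0
                for run in aa.split("*"):
                    if len(run) >= min_orf_len:
                        w_start = frame + 3 * pos
                        w_end = w_start + 3 * len(run)
                        if strand == "+":
                            f_start, f_end = w_start, w_end
                        else:
                            f_start, f_end = length - w_end, length - w_start
                        orf_id = (
                            f"{assembly.assembly_id}|{contig_id}|"
                            f"{strand}{frame}|{f_start}"
                        )
                        orfs.append(
                            Orf(
                                orf_id=orf_id,
                                contig_id=contig_id,
                                strand=strand,
                                frame=frame,
                                start=f_start,
                                end=f_end,
                                aa_seq=run,
                                nt_seq=work[w_start:w_end],
                            )
                        )
                    pos += len(run) + 1
    return orfs


# ---------------------------------------------------------------------------
# signal-peptide scoring
# ---------------------------------------------------------------------------

class HeuristicSignalScorer:
    """Deterministic sequence-property stand-in for a trained NSS predictor.

    Combines three classic signal-peptide features of the prefix:

    * n-region — count of positively charged residues (K/R) in residues 1-5;
    * h-region — maximal mean Kyte-Doolittle hydropathy over 8-residue
      windows within residues 6-20;
    * c-region — small residues (A/G/S/C/T) at the -3 and -1 positions of
      the best candidate cleavage site, searched over NSS lengths 15-30.

    The weighted sum is mapped through a logistic to [0, 1]. Prefixes
    shorter than 15 residues score 0.
    """

    name = "heuristic"

    #: logistic weights: intercept, n-charge, h-hydropathy, c-small-count
    weights = (-6.0, 1.0, 1.2, 1.0)

    def _features(self, prefix: str) -> tuple[float, float, int, int]:
        n_pos = sum(1 for a in prefix[:5] if a in _POSITIVE_RESIDUES)
        region = prefix[5:20]
        best_h = max(
            (
                sum(KYTE_DOOLITTLE.get(a, 0.0) for a in region[i : i + 8]) / 8.0
                for i in range(len(region) - 7)
            ),
            default=-4.5,
        )
        best_c, best_site = -1, min(15, len(prefix))
        for site in range(15, min(30, len(prefix)) + 1):
            small = int(prefix[site - 3] in _SMALL_RESIDUES) + int(
                prefix[site - 1] in _SMALL_RESIDUES
            )
            if small > best_c:
                best_c, best_site = small, site
        return n_pos, best_h, max(best_c, 0), best_site

    def score(self, prefix: str) -> float:
        if len(prefix) < 15:
            return 0.0
        n_pos, best_h, best_c, _ = self._features(prefix)
        w0, w1, w2, w3 = self.weights
        z = w0 + w1 * n_pos + w2 * best_h + w3 * best_c
        return 1.0 / (1.0 + math.exp(-z))

    def cleavage_site(self, prefix: str) -> int:
        if len(prefix) < 15:
            return min(len(prefix), 15)
        return self._features(prefix)[3]


def heuristic_signal_scorer() -> HeuristicSignalScorer:
    return HeuristicSignalScorer()


class TableSignalScorer:
    """Signal scorer backed by externally computed per-prefix scores.

    Allows precomputed predictions from the original external tool to be
    used without re-running it: ``scores`` maps an AA prefix (or its
    leading 40 residues) to (score, cleavage length).
    """

    name = "external-tsv"

    def __init__(self, scores: dict[str, tuple[float, int]]):
        self._scores = scores

    def _key(self, prefix: str) -> str:
        return prefix[:40]

    def score(self, prefix: str) -> float:
        entry = self._scores.get(self._key(prefix))
        return entry[0] if entry else 0.0

    def cleavage_site(self, prefix: str) -> int:
        entry = self._scores.get(self._key(prefix))
        return entry[1] if entry else min(len(prefix), 20)


# ---------------------------------------------------------------------------
# start selection and architecture parsing
# ---------------------------------------------------------------------------

def find_start(
    orf: Orf,
    domain_hit: DomainHit,
    scorer: SignalScorer,
    score_cutoff: float = 0.400,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
) -> tuple[int, float] | Rejection:
    """Choose the start codon maximizing the signal score of its prefix.

    Candidates are AA positions before the first domain whose codon is
    ATG or any Leu codon. The maximum-scoring candidate is accepted only
    if its score strictly exceeds ``score_cutoff``; ties break to the
    5'-most candidate (longest NSS).
    """
    start_codons = set(start_codons)
    candidates = [
        j
        for j in range(domain_hit.offset)
        if orf.nt_seq[3 * j : 3 * j + 3] in start_codons
    ]
    if not candidates:
        return Rejection(orf.orf_id, "no_start")
    scored = [(scorer.score(orf.aa_seq[j:]), j) for j in candidates]
    best_score, best_j = max(scored, key=lambda t: (t[0], -t[1]))
    if not best_score > score_cutoff:
        return Rejection(orf.orf_id, "no_signal")
    return best_j, best_score


def parse_architecture(
    orf: Orf,
    start: int,
    domain_hits: Sequence[DomainHit],
    scorer: SignalScorer,
    signal_score: float | None = None,
    gene_id: str | None = None,
) -> CepGene | Rejection:
    """Assemble a :class:`CepGene` from a chosen start and domain hits.

    The NSS length is the scorer's cleavage-site call on the prepropeptide;
    the variable region runs from the NSS end to the first domain, and the
    C-terminal extension from the last domain end to the stop. A domain
    overlapping the NSS region is a rejection, not an error.
    """
    hits = sorted(domain_hits, key=lambda h: h.offset)
    prepro = orf.aa_seq[start:]
    rel = [h.offset - start for h in hits]
    if rel[0] < 0:
        raise ValueError("start must precede the first domain hit")
    nss_len = scorer.cleavage_site(prepro)
    if rel[0] < nss_len:
        return Rejection(orf.orf_id, "domain_in_signal")
    cds = orf.nt_seq[3 * start :]
    if orf.strand == "+":
        cds_start, cds_end = orf.start + 3 * start, orf.end
    else:
        cds_start, cds_end = orf.start, orf.end - 3 * start
    if signal_score is None:
        signal_score = scorer.score(prepro)
    return CepGene(
        gene_id=gene_id or f"{orf.orf_id}|g",
        orf=orf,
        start_offset=start,
        nss_len=nss_len,
        var_len=rel[0] - nss_len,
        domain_offsets=rel,
        cterm_len=len(prepro) - (rel[-1] + 15),
        signal_score=signal_score,
        cds=cds,
        prepropeptide=prepro,
        cds_start=cds_start,
        cds_end=cds_end,
    )


# ---------------------------------------------------------------------------
# end-to-end discovery
# ---------------------------------------------------------------------------

def discover_genes(
    assembly: GenomeAssembly,
    pspm: Pspm,
    config: DiscoveryConfig | None = None,
    return_rejections: bool = False,
):
    """Run the full discovery pipeline on one assembly.

    Composition of ORF extraction, motif scanning, start selection and
    architecture parsing. Duplicate genes reachable from overlapping ORFs
    (identical forward-strand CDS span and strand) are kept once; output
    is ordered by (contig, position, strand).
    """
    config = config or DiscoveryConfig()
    scorer = config.scorer or heuristic_signal_scorer()
    genes: dict[tuple, CepGene] = {}
    rejections: list[Rejection] = []
    for orf in extract_orfs(assembly, config.min_orf_len):
        hits = scan_orf(
            pspm, orf.aa_seq, p_cutoff=config.p_cutoff, orf_id=orf.orf_id
        )
        if not hits:
            continue
        res = find_start(
            orf, hits[0], scorer, config.signal_cutoff, config.start_codons
        )
        if isinstance(res, Rejection):
            rejections.append(res)
            continue
        start, sig = res
        gene = parse_architecture(orf, start, hits, scorer, signal_score=sig)
        if isinstance(gene, Rejection):
            rejections.append(gene)
            continue
        key = (gene.contig_id, gene.strand, gene.cds_start, gene.cds_end)
        genes.setdefault(key, gene)
    ordered = sorted(
        genes.values(), key=lambda g: (g.contig_id, g.cds_start, g.strand)
    )
    for i, g in enumerate(ordered, start=1):
        g.gene_id = f"{assembly.assembly_id}_g{i:03d}"
    for r in rejections:
        logger.debug("rejected %s: %s", r.orf_id, r.reason)
    if return_rejections:
        return ordered, rejections
    return ordered


def gc_content(cds: str) -> float:
    """GC fraction of a nucleotide sequence; N excluded from both sides.

    Returns NaN for an empty or all-N sequence.
    """
    if not cds:
        raise ValueError("empty sequence")
    counted = [c for c in cds.upper() if c != "N"]
    if not counted:
        return float("nan")
    gc = sum(1 for c in counted if c in "GC")
    return gc / len(counted)
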