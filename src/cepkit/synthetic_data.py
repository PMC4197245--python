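"""Synthetic genomes with planted secreted-peptide genes and ground truth.

The generator emulates the genomic structure the discovery pipeline
assumes: single-exon genes comprising an N-terminal secretion signal
(NSS), a variable region, one or more 15-residue peptide domains and an
optional short C-terminal extension, embedded on either strand in random
intergenic background, alongside three decoy classes:

* ``groupII_decoy`` — a gene whose domain is diverged enough that its
  scan p-value exceeds the detection threshold (motif-like but rejected,
  mirroring the distant "group II" relatives of the family);
* ``no_nss_decoy`` — a domain-bearing ORF whose N-terminal region cannot
  satisfy the signal scorer;
* ``no_domain_decoy`` — a secretion signal with no peptide domain.

Orthologous gene sets share a common ancestral sequence and evolve along
the species tree under the JTT model, so reciprocal-best-hit orthology,
intra-organism distances and family contrasts all have known truth.
All randomness flows from the single mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _jtt
from .formats_io import AA_ALPHABET, GenomeAssembly, SpeciesTree, tree_from_string
from .gene_discovery import (
    HeuristicSignalScorer,
    Rejection,
    find_start,
    heuristic_signal_scorer,
)
from .motif_model import (
    DEFAULT_P_CUTOFF,
    Pspm,
    WeightedDomain,
    build_pspm,
    scan_orf,
    score_window,
    scores_to_pvalues,
    uniform_background,
)

#: representative 15-mer variants around the family consensus, used to seed
#: the default generating PSPM (synthetic consensus variants, not survey data)
SEED_DOMAINS = [
    "DFRPTAPGHSPGVGH",
    "AFRPTSPGHSPGVGH",
    "DFRPTTPGHSPGIGH",
    "GFRPTAPGHSPGVGH",
    "DFRPTNPGHSPGVGH",
    "DFKPTAPGHSPGVGH",
    "DFRPTASGHSPGIGH",
    "DFRPTTPGHSPGMGH",
    "SFRPTAPGHSPGVGH",
    "DYRPTAPGHSPGVGH",
    "DFRPTSPGNSPGVGH",
    "DFRPTAPGHSPAVGH",
]

_CODONS_FOR: dict[str, list[str]] = {}
_STOP_CODONS = ("TAA", "TGA", "TAG")
_MAX_TRIES = 10_000


def _codons_for(aa: str) -> list[str]:
    if not _CODONS_FOR:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, a in standard_dna_table.forward_table.items():
            _CODONS_FOR.setdefault(a, []).append(codon)
        for lst in _CODONS_FOR.values():
            lst.sort()
    return _CODONS_FOR[aa]


def default_generating_pspm(pseudocount: float = 0.15) -> Pspm:
    """Sharp motif model built from the seed consensus variants."""
    domains = [
        WeightedDomain(s, 1.0, "seed", f"orf{i}", "seed")
        for i, s in enumerate(SEED_DOMAINS)
    ]
    return build_pspm(domains, pseudocount=pseudocount * len(domains))


@dataclass
class SimConfig:
    """Parameters of one simulated plant family.

    Divergences are in expected substitutions per site: orthologous gene
    sets within a genome descend from a family founder at
    ``within_genome_divergence``, and each species' copy descends from
    its set ancestor at ``ortholog_divergence``. Decoy counts are per
    species. ``gc3_bias`` > 0 biases synonymous codon choice toward G/C
    third positions (codon weight exp(bias * GC3)).
    """

    seed: int
    n_species: int = 4
    tree_shape: str = "caterpillar"  # star | caterpillar
    n_ortholog_sets: int = 5
    family: str = "FamA"
    within_genome_divergence: float = 0.4
    ortholog_divergence: float = 0.05
    multi_domain_prob: float = 0.15
    no_cterm_prob: float = 0.058
    n_groupII: int = 2
    n_no_nss: int = 2
    n_no_domain: int = 2
    spacer_length: int = 400
    background_gc: float = 0.40
    gc3_bias: float = 0.0
    p_canonical_max: float = DEFAULT_P_CUTOFF
    p_decoy_min: float = 1e-8

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("multi_domain_prob", "no_cterm_prob", "background_gc"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.tree_shape not in {"star", "caterpillar"}:
            raise ValueError("tree_shape must be 'star' or 'caterpillar'")


@dataclass
class SimResult:
    assemblies: list[GenomeAssembly]
    species_tree: SpeciesTree
    truth: pd.DataFrame
    pspm: Pspm


def _species_names(config: SimConfig) -> list[str]:
    return [f"{config.family}_sp{i + 1}" for i in range(config.n_species)]


def _build_tree(config: SimConfig) -> SpeciesTree:
    names = _species_names(config)
    if config.tree_shape == "star" or len(names) == 2:
        newick = "(" + ",".join(names) + ");"
    else:
        newick = names[0]
        for name in names[1:]:
            newick = f"({newick},{name})"
        newick += ";"
    return tree_from_string(newick, strict_root=False)


def _random_background(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ATGC"))[rng.choice(4, size=length, p=p)])


def _sample_from_pspm(pspm: Pspm, rng: np.random.Generator) -> str:
    return "".join(
        AA_ALPHABET[rng.choice(20, p=pspm.probabilities[i])]
        for i in range(pspm.width)
    )


def _pvalue(pspm: Pspm, domain: str) -> float:
    return float(scores_to_pvalues(pspm, np.array([score_window(pspm, domain)]))[0])


def _rejection_sample(draw, accept, what: str):
    for _ in range(_MAX_TRIES):
        x = draw()
        if accept(x):
            return x
    raise RuntimeError(
        f"rejection sampling for {what} failed after {_MAX_TRIES} tries; "
        "adjust the simulation parameters"
    )


def _sample_nss(rng: np.random.Generator, scorer: HeuristicSignalScorer) -> str:
    """An NSS template scoring > 0.8 under the heuristic scorer."""

    def draw() -> str:
        n_hydro = int(rng.integers(9, 13))
        core = "".join(rng.choice(list("LIVF"), size=n_hydro))
        mid = rng.choice(list("QNST"))
        return "M" + "".join(rng.choice(list("KR"), size=2)) + core + "A" + mid + "A"

    return _rejection_sample(draw, lambda s: scorer.score(s + "G" * 10) > 0.8, "NSS")


def _sample_var(rng: np.random.Generator, length: int) -> str:
    """Variable-region AAs; composition avoids strongly signal-like runs."""
    return "".join(rng.choice(list("ADEGHNPQSTVKRY"), size=length))


def _back_translate(aa: str, rng: np.random.Generator, gc3_bias: float) -> str:
    out = []
    for a in aa:
        codons = _codons_for(a)
        if gc3_bias:
            w = np.array(
                [np.exp(gc3_bias * (c[2] in "GC")) for c in codons], dtype=float
            )
            w /= w.sum()
            out.append(codons[rng.choice(len(codons), p=w)])
        else:
            out.append(codons[rng.integers(len(codons))])
    return "".join(out)


def _perturbed_pspm(pspm: Pspm, rng: np.random.Generator) -> Pspm:
    """Diverged motif model used to draw group-II-like decoy domains."""
    probs = 0.45 * pspm.probabilities + 0.55 * uniform_background()[np.newaxis, :]
    return Pspm(probabilities=probs / probs.sum(axis=1, keepdims=True),
                background=pspm.background, pseudocount=pspm.pseudocount)


def _evolved_domain(
    ancestor: str,
    t: float,
    pspm: Pspm,
    rng: np.random.Generator,
    p_max: float,
) -> str:
    return _rejection_sample(
        lambda: _jtt.evolve(ancestor, t, rng),
        lambda d: _pvalue(pspm, d) <= p_max,
        "canonical domain",
    )


def simulate_dataset(config: SimConfig, pspm: Pspm | None = None) -> SimResult:
    """Generate assemblies, a species tree and a planted-locus truth table.

    Every canonical locus's domains score at or below the scan threshold
    under the generating PSPM; every group-II decoy domain scores above
    ``p_decoy_min`` (both rejection-sampled). Canonical prepropeptides are
    additionally validated against the scanning and start-selection
    primitives so the truth table records the architecture the pipeline
    should report.
    """
    rng = np.random.default_rng(config.seed)
    pspm = pspm or default_generating_pspm()
    scorer = heuristic_signal_scorer()
    tree = _build_tree(config)
    species = _species_names(config)

    # family founder gene; every ortholog set descends from it at the
    # within-genome divergence, so intra-genome distances track the knob
    # across the whole prepropeptide, not just the domain
    founder_domain = _rejection_sample(
        lambda: _sample_from_pspm(pspm, rng),
        lambda d: _pvalue(pspm, d) <= config.p_canonical_max,
        "founder domain",
    )
    founder_nss = _sample_nss(rng, scorer)
    founder_var = _sample_var(rng, int(rng.integers(8, 26)))
    founder_cterm = "".join(rng.choice(list("ADEGNQST"), size=int(rng.integers(3, 9))))
    sets = []
    for s in range(config.n_ortholog_sets):
        t = config.within_genome_divergence
        nss = _rejection_sample(
            lambda: "M" + _jtt.evolve(founder_nss[1:], t, rng),
            lambda x: scorer.score(x + "G" * 10) > 0.8,
            "set NSS",
        )
        sets.append(
            {
                "set_id": f"{config.family}_og{s + 1}",
                "nss": nss,
                "var": _jtt.evolve(founder_var, t, rng),
                "domain": _evolved_domain(
                    founder_domain, t, pspm, rng, config.p_canonical_max
                ),
                "n_domains": 2 if rng.random() < config.multi_domain_prob else 1,
                "spacer": int(rng.integers(5, 11)),
                "cterm": (
                    ""
                    if rng.random() < config.no_cterm_prob
                    else _jtt.evolve(founder_cterm, t, rng)
                ),
            }
        )

    decoy_pspm = _perturbed_pspm(pspm, rng)
    assemblies: list[GenomeAssembly] = []
    truth_rows: list[dict] = []

    for organism in species:
        loci: list[dict] = []
        for st in sets:
            prepro, dom_offsets = _canonical_prepropeptide(
                st, config, pspm, scorer, rng
            )
            loci.append(
                {
                    "class": "canonical",
                    "prepro": prepro,
                    "domain_offsets": dom_offsets,
                    "ortho_set": st["set_id"],
                }
            )
        for _ in range(config.n_groupII):
            loci.append(_groupII_decoy(config, pspm, decoy_pspm, scorer, rng))
        for _ in range(config.n_no_nss):
            loci.append(_no_nss_decoy(config, pspm, scorer, rng))
        for _ in range(config.n_no_domain):
            loci.append(_no_domain_decoy(config, scorer, rng))

        contig_parts: list[str] = []
        pos = 0
        contig_id = "chr1"
        order = rng.permutation(len(loci))
        for locus_idx in order:
            locus = loci[locus_idx]
            bg = _random_background(
                rng, config.spacer_length + int(rng.integers(0, 120)),
                config.background_gc,
            )
            contig_parts.append(bg)
            pos += len(bg)
            cds = _back_translate(locus["prepro"], rng, config.gc3_bias)
            # upstream in-frame pad keeps even short genes inside a stop-free
            # run of >= 50 AA, as in real genomic context; its residues have
            # no Met/Leu codons so start-codon selection is unaffected
            pad_len = max(0, 52 - len(locus["prepro"])) + int(rng.integers(0, 11))
            pad = _back_translate(
                "".join(rng.choice(list("DENGSPQT"), size=pad_len)), rng, 0.0
            )
            construct = (
                _STOP_CODONS[rng.integers(3)]
                + pad
                + cds
                + _STOP_CODONS[rng.integers(3)]
            )
            strand = "+" if rng.random() < 0.5 else "-"
            insert = construct if strand == "+" else _revcomp(construct)
            cds_off = 3 + len(pad)  # offset of the CDS within the construct
            if strand == "+":
                cds_start = pos + cds_off
            else:
                cds_start = pos + len(construct) - cds_off - len(cds)
            cds_end = cds_start + len(cds)
            contig_parts.append(insert)
            pos += len(insert)
            scorer_nss = scorer.cleavage_site(locus["prepro"])
            offsets = locus["domain_offsets"]
            truth_rows.append(
                {
                    "assembly_id": organism,
                    "organism": organism,
                    "family": config.family,
                    "contig": contig_id,
                    "strand": strand,
                    "cds_start": cds_start,
                    "cds_end": cds_end,
                    "locus_class": locus["class"],
                    "ortho_set": locus.get("ortho_set", ""),
                    "nss_len": scorer_nss if locus["class"] != "no_nss_decoy" else 0,
                    "var_len": (offsets[0] - scorer_nss) if offsets else 0,
                    "n_domains": len(offsets),
                    "cterm_len": (
                        len(locus["prepro"]) - (offsets[-1] + 15) if offsets else 0
                    ),
                    "domain_offsets": ";".join(str(o) for o in offsets),
                    "prepropeptide": locus["prepro"],
                    "cds": cds,
                }
            )
        tail = _random_background(rng, config.spacer_length, config.background_gc)
        contig_parts.append(tail)
        assemblies.append(
            GenomeAssembly(
                assembly_id=organism,
                organism=organism,
                family=config.family,
                sequences=[(contig_id, "".join(contig_parts))],
            )
        )

    truth = pd.DataFrame(truth_rows)
    truth = truth.sort_values(
        ["assembly_id", "contig", "cds_start"], kind="mergesort"
    ).reset_index(drop=True)
    return SimResult(
        assemblies=assemblies, species_tree=tree, truth=truth, pspm=pspm
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _canonical_prepropeptide(st, config, pspm, scorer, rng):
    """A species copy of a set's gene; validated against the discovery rules."""

    def draw():
        nss = st["nss"]
        var = _jtt.evolve(st["var"], config.ortholog_divergence, rng)
        domains = [
            _evolved_domain(
                st["domain"], config.ortholog_divergence, pspm, rng,
                config.p_canonical_max,
            )
        ]
        if st["n_domains"] == 2:
            domains.append(
                _evolved_domain(
                    st["domain"], config.ortholog_divergence + 0.2, pspm, rng,
                    config.p_canonical_max,
                )
            )
        cterm = (
            _jtt.evolve(st["cterm"], config.ortholog_divergence, rng)
            if st["cterm"]
            else ""
        )
        parts = [nss, var]
        offsets = []
        cursor = len(nss) + len(var)
        for k, dom in enumerate(domains):
            if k:
                spacer = _sample_var(rng, st["spacer"])
                parts.append(spacer)
                cursor += len(spacer)
            parts.append(dom)
            offsets.append(cursor)
            cursor += 15
        parts.append(cterm)
        return "".join(parts), offsets

    def accept(item) -> bool:
        prepro, offsets = item
        if scorer.score(prepro) <= 0.8:
            return False
        hits = scan_orf(pspm, prepro, p_cutoff=config.p_canonical_max)
        if [h.offset for h in hits] != offsets:
            return False
        if scorer.cleavage_site(prepro) > offsets[0]:
            return False
        fake_orf = _FakeOrf(prepro)
        res = find_start(fake_orf, hits[0], scorer)
        return res == (0, scorer.score(prepro))

    return _rejection_sample(draw, accept, "canonical gene")


class _FakeOrf:
    """In-memory ORF wrapping a bare peptide (for validating start selection
    and architecture parsing without a genomic context)."""

    def __init__(self, prepro: str):
        self.orf_id = "sim"
        self.contig_id = "sim"
        self.strand = "+"
        self.frame = 0
        self.start = 0
        self.end = 3 * len(prepro)
        self.aa_seq = prepro
        rng = np.random.default_rng(0)
        self.nt_seq = _back_translate(prepro, rng, 0.0)


def _groupII_decoy(config, pspm, decoy_pspm, scorer, rng):
    """Signal + diverged domain whose p-value exceeds the decoy floor."""
    nss = _sample_nss(rng, scorer)
    var = _sample_var(rng, int(rng.integers(8, 26)))

    def draw():
        return _sample_from_pspm(decoy_pspm, rng)

    domain = _rejection_sample(
        draw, lambda d: _pvalue(pspm, d) > config.p_decoy_min, "group II domain"
    )

    def accept_locus(p):
        return not scan_orf(pspm, p, p_cutoff=config.p_canonical_max)

    prepro = _rejection_sample(
        lambda: nss + _sample_var(rng, int(rng.integers(8, 26))) + domain + "GSNAE",
        accept_locus,
        "group II locus",
    )
    return {"class": "groupII_decoy", "prepro": prepro, "domain_offsets": []}


def _no_nss_decoy(config, pspm, scorer, rng):
    """A genuine domain downstream of a prefix no start codon can rescue."""

    def draw():
        prefix_len = int(rng.integers(25, 40))
        prefix = "M" + "".join(rng.choice(list("DENGSPQT"), size=prefix_len))
        domain = _rejection_sample(
            lambda: _sample_from_pspm(pspm, rng),
            lambda d: _pvalue(pspm, d) <= config.p_canonical_max,
            "decoy domain",
        )
        return prefix + domain + "GSNAE"

    def accept(prepro) -> bool:
        hits = scan_orf(pspm, prepro, p_cutoff=config.p_canonical_max)
        if len(hits) != 1:
            return False
        fake = _FakeOrf(prepro)
        res = find_start(fake, hits[0], scorer)
        return isinstance(res, Rejection)

    prepro = _rejection_sample(draw, accept, "no-NSS decoy")
    hits = scan_orf(pspm, prepro, p_cutoff=config.p_canonical_max)
    return {
        "class": "no_nss_decoy",
        "prepro": prepro,
        "domain_offsets": [hits[0].offset],
    }


def _no_domain_decoy(config, scorer, rng):
    nss = _sample_nss(rng, scorer)
    tail = _sample_var(rng, int(rng.integers(20, 40)))
    return {"class": "no_domain_decoy", "prepro": nss + tail, "domain_offsets": []}


# ---------------------------------------------------------------------------
# codon alignments with known selection
# ---------------------------------------------------------------------------

def simulate_codon_msa(
    omega_per_site,
    n_seqs: int,
    seed: int,
    proposals_per_codon: float = 0.7,
) -> list[str]:
    """Indel-free codon alignment evolved under per-site selection.

    Each sequence descends independently from a random non-stop ancestral
    codon sequence. Per codon, a Poisson(``proposals_per_codon``) number
    of mutations is proposed, each drawn uniformly from the codon's
    non-stop single-nucleotide neighbors (mutations to stop codons are
    lethal and never observed). Synonymous proposals are always accepted;
    non-synonymous proposals are accepted with probability
    ``omega_per_site[k]`` — the classic mutation-selection interpretation
    of dN/dS.
    """
    from Bio.Data.CodonTable import standard_dna_table

    rng = np.random.default_rng(seed)
    omega = np.asarray(omega_per_site, dtype=float)
    sense = sorted(standard_dna_table.forward_table)
    ancestor = [sense[rng.integers(len(sense))] for _ in range(len(omega))]

    neighbors: dict[str, list[str]] = {}
    for codon in sense:
        neighbors[codon] = [
            codon[:pos] + nt + codon[pos + 1 :]
            for pos in range(3)
            for nt in "ACGT"
            if nt != codon[pos]
            and codon[:pos] + nt + codon[pos + 1 :]
            not in standard_dna_table.stop_codons
        ]

    def mutate(codon: str, w: float) -> str:
        for _ in range(rng.poisson(proposals_per_codon)):
            cand = neighbors[codon][rng.integers(len(neighbors[codon]))]
            syn = (
                standard_dna_table.forward_table[cand]
                == standard_dna_table.forward_table[codon]
            )
            if syn or rng.random() < w:
                codon = cand
        return codon

    return [
        "".join(mutate(c, w) for c, w in zip(ancestor, omega))
        for _ in range(n_seqs)
    ]


# ---------------------------------------------------------------------------
# paired-family datasets
# ---------------------------------------------------------------------------

def simulate_family_contrast(
    config_hi: SimConfig, config_lo: SimConfig, pspm: Pspm | None = None
) -> tuple[SimResult, SimResult]:
    """Two families differing (only) in within-genome divergence.

    The families must carry distinct names so downstream grouping keeps
    them apart; their true IOPD distributions differ by the configured
    divergence shift.
    """
    if config_hi.family == config_lo.family:
        raise ValueError("the two families must have distinct names")
    pspm = pspm or default_generating_pspm()
    return simulate_dataset(config_hi, pspm), simulate_dataset(config_lo, pspm)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_dataset(result: SimResult, outdir) -> None:
    """Write FASTA assemblies, the newick tree and the truth TSV."""
    from .formats_io import write_fasta, write_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for asm in result.assemblies:
        write_fasta(asm, outdir / f"{asm.assembly_id}.fa")
    (outdir / "species_tree.nwk").write_text(result.species_tree.as_newick() + "\n")
    write_table(result.truth, outdir / "truth.tsv")
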