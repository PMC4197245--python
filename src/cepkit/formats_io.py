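"""Readers and writers for every external format the pipeline touches.

Covers nucleotide FASTA genome assemblies, rooted newick species trees,
the MEME minimal motif format (v4) for position-specific probability
matrices, and TSV/CSV exports of supplementary gene/domain tables.

Conventions used throughout: sequence coordinates are 0-based, half-open;
strand is "+" or "-"; nucleotide alphabet is {A,C,G,T,N} with every other
IUPAC code normalized to N on read (a count of normalized characters is
logged).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Residue order used for all motif matrices (MEME's protein alphabet order).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

_NT_VALID = set("ACGTN")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeAssembly:
    """A genome assembly: ordered contigs of {A,C,G,T,N} nucleotides."""

    assembly_id: str
    sequences: list[tuple[str, str]]
    organism: str = ""
    family: str = ""

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.sequences]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate contig id {dup!r} in {self.assembly_id}")
        for cid, seq in self.sequences:
            if not seq:
                raise ValueError(f"empty sequence for contig {cid!r}")
            bad = set(seq) - _NT_VALID
            if bad:
                raise ValueError(f"contig {cid!r} contains invalid characters {bad}")

    def contig(self, contig_id: str) -> str:
        for cid, seq in self.sequences:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)


class SpeciesTree:
    """A rooted species tree with organism-labelled leaves.

    ``depth(label)`` counts the internal nodes on the root-to-leaf path,
    with the root itself counted as an internal node; this is the quantity
    the lineage-decay weighting exponentiates.
    """

    def __init__(self, tree: dendropy.Tree, strict_root: bool = True):
        root = tree.seed_node
        if strict_root and len(root.child_nodes()) > 2:
            raise ValueError(
                "tree root has more than two children (unrooted convention); "
                "supply a rooted (bifurcating-root) tree, or pass "
                "strict_root=False for an intentional polytomy"
            )
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dup = next(lb for lb in labels if labels.count(lb) > 1)
            raise ValueError(f"duplicate leaf label {dup!r}")
        self._tree = tree
        self._depths: dict[str, int] = {}
        for leaf in tree.leaf_node_iter():
            d = 0
            node = leaf.parent_node
            while node is not None:
                d += 1
                node = node.parent_node
            self._depths[leaf.taxon.label] = d

    @property
    def leaves(self) -> set[str]:
        return set(self._depths)

    def depth(self, organism: str) -> int:
        if organism not in self._depths:
            raise KeyError(f"organism {organism!r} not a leaf of the species tree")
        return self._depths[organism]

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class MotifRecord:
    """A fixed-width, ungapped AA motif as per-position probabilities."""

    motif_id: str
    width: int
    probabilities: np.ndarray  # width x 20, rows sum to 1
    background: np.ndarray  # 20-vector summing to 1
    source_nsites: float = 0.0

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probabilities.shape != (self.width, 20):
            raise ValueError(
                f"probability matrix shape {self.probabilities.shape} does not "
                f"match width {self.width}"
            )
        if np.any(self.probabilities < 0) or np.any(self.probabilities > 1):
            raise ValueError("probabilities must lie in [0,1]")
        bad = np.nonzero(np.abs(self.probabilities.sum(axis=1) - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValueError(f"probability row {bad[0]} does not sum to 1")
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError("background frequencies do not sum to 1")


@dataclass
class SuppGeneRecord:
    """One row of a supplementary gene table: a gene and its architecture."""

    gene_id: str
    organism: str
    family: str
    sequence: str
    nss_len: int
    var_len: int
    n_domains: int
    cterm_len: int

    def __post_init__(self) -> None:
        if self.n_domains < 1:
            raise ValueError(f"{self.gene_id}: domain count must be >= 1")
        core = self.nss_len + self.var_len + 15 * self.n_domains + self.cterm_len
        spacer_total = len(self.sequence) - core
        if spacer_total < 0 or (self.n_domains == 1 and spacer_total != 0):
            raise ValueError(
                f"{self.gene_id}: segment lengths do not tile the "
                f"{len(self.sequence)}-AA sequence"
            )


@dataclass
class SuppDomainRecord:
    """One row of a supplementary domain table."""

    sequence: str
    bit_score: float
    gene_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.sequence) != 15:
            raise ValueError(f"domain sequence {self.sequence!r} is not 15 AA")
        if not self.gene_ids:
            raise ValueError(f"domain {self.sequence!r} has no associated genes")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, assembly_id: str | None = None, organism: str = "",
               family: str = "") -> GenomeAssembly:
    """Read a nucleotide FASTA file into a :class:`GenomeAssembly`.

    Lowercase letters are uppercased; any character outside {A,C,G,T,N}
    (ambiguity codes, gaps, ...) becomes N, with the total count logged.
    Raises on empty files and duplicate contig ids.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    seen: set[str] = set()
    sequences: list[tuple[str, str]] = []
    n_normalized = 0
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq).upper()
        cleaned = "".join(c if c in _NT_VALID else "N" for c in raw)
        n_normalized += sum(1 for a, b in zip(raw, cleaned) if a != b)
        sequences.append((rec.id, cleaned))
    if n_normalized:
        logger.info("%s: normalized %d non-ACGTN characters to N", path, n_normalized)
    return GenomeAssembly(
        assembly_id=assembly_id or path.stem,
        sequences=sequences,
        organism=organism,
        family=family,
    )


def write_fasta(assembly: GenomeAssembly, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=cid, description="")
        for cid, seq in assembly.sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_aa_fasta(entries: Iterable[tuple[str, str]], path) -> None:
    """Write (id, AA sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_meme_motif(path) -> MotifRecord:
    """Parse the first motif from a MEME minimal motif format file.

    If the file lacks a background-frequency line a uniform background is
    assumed (logged as a warning). Width mismatches between the declared
    ``w=`` and the matrix, and rows not summing to ~1, are errors. Rows are
    renormalized exactly on read, so write/read round-trips are stable.
    """
    lines = Path(path).read_text().splitlines()
    background = None
    motif_id = None
    width = None
    nsites = 0.0
    rows: list[list[float]] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            vals: list[float] = []
            i += 1
            while i < len(lines) and vals.__len__() < 40:
                parts = lines[i].split()
                if not parts or parts[0] == "MOTIF":
                    break
                vals.extend(parts)
                if len(vals) >= 40:
                    break
                i += 1
            pairs = vals[:40]
            letters = pairs[0::2]
            freqs = [float(x) for x in pairs[1::2]]
            bg = np.zeros(20)
            for letter, f in zip(letters, freqs):
                bg[AA_TO_INDEX[letter]] = f
            background = bg
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
        elif line.startswith("letter-probability matrix"):
            m_w = re.search(r"\bw=\s*(\d+)", line)
            m_n = re.search(r"\bnsites=\s*([\d.eE+-]+)", line)
            width = int(m_w.group(1)) if m_w else 0
            nsites = float(m_n.group(1)) if m_n else 0.0
            i += 1
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                rows.append([float(x) for x in lines[i].split()])
                i += 1
            break
        i += 1
    if motif_id is None or width is None:
        raise ValueError(f"{path}: not a MEME minimal motif file")
    if len(rows) != width:
        raise ValueError(
            f"{path}: declared w={width} but matrix has {len(rows)} rows"
        )
    mat = np.array(rows, dtype=float)
    if mat.shape[1] != 20:
        raise ValueError(f"{path}: expected 20 columns, got {mat.shape[1]}")
    sums = mat.sum(axis=1)
    bad = np.nonzero(np.abs(sums - 1.0) > 1e-4)[0]
    if bad.size:
        raise ValueError(f"{path}: matrix row {bad[0]} sums to {sums[bad[0]]:.6f}")
    mat /= sums[:, np.newaxis]
    if background is None:
        logger.warning("%s: no background line; assuming uniform background", path)
        background = np.full(20, 0.05)
    return MotifRecord(
        motif_id=motif_id,
        width=width,
        probabilities=mat,
        background=background,
        source_nsites=nsites,
    )


def write_meme_motif(motif: MotifRecord, path) -> None:
    """Write a motif in MEME minimal motif format v4 (12-decimal precision)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + AA_ALPHABET + "\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(
                f"{a} {f:.12f}" for a, f in zip(AA_ALPHABET, motif.background)
            )
            + "\n\n"
        )
        fh.write(f"MOTIF {motif.motif_id}\n")
        fh.write(
            f"letter-probability matrix: alength= 20 w= {motif.width} "
            f"nsites= {motif.source_nsites:g} E= 0\n"
        )
        for row in motif.probabilities:
            fh.write(" ".join(f"{x:.12f}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# supplementary tables
# ---------------------------------------------------------------------------

#: default column-name maps for TSV/CSV exports of the supplementary tables
DEFAULT_GENE_COLUMNS = {
    "gene_id": "gene_id",
    "organism": "organism",
    "family": "family",
    "sequence": "sequence",
    "nss_len": "nss_len",
    "var_len": "var_len",
    "n_domains": "n_domains",
    "cterm_len": "cterm_len",
}
DEFAULT_DOMAIN_COLUMNS = {
    "sequence": "sequence",
    "bit_score": "bit_score",
    "gene_ids": "gene_ids",  # comma/semicolon-separated list
}


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", comment="#")


def read_supp_tables(
    gene_table_path,
    domain_table_path,
    gene_columns: dict[str, str] | None = None,
    domain_columns: dict[str, str] | None = None,
) -> tuple[list[SuppGeneRecord], list[SuppDomainRecord], list[str]]:
    """Read gene and domain table exports.

    ``gene_columns``/``domain_columns`` map our field names to the column
    names used in the export, so layout drift does not require code
    changes. Rows violating type invariants raise with their row number;
    domain rows referencing absent gene ids produce warnings (returned as
    the third element), not errors.
    """
    gmap = {**DEFAULT_GENE_COLUMNS, **(gene_columns or {})}
    dmap = {**DEFAULT_DOMAIN_COLUMNS, **(domain_columns or {})}
    gdf = _read_table(gene_table_path)
    ddf = _read_table(domain_table_path)

    genes: list[SuppGeneRecord] = []
    for i, row in gdf.iterrows():
        try:
            genes.append(
                SuppGeneRecord(
                    gene_id=str(row[gmap["gene_id"]]),
                    organism=str(row[gmap["organism"]]),
                    family=str(row[gmap["family"]]),
                    sequence=str(row[gmap["sequence"]]),
                    nss_len=int(row[gmap["nss_len"]]),
                    var_len=int(row[gmap["var_len"]]),
                    n_domains=int(row[gmap["n_domains"]]),
                    cterm_len=int(row[gmap["cterm_len"]]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"gene table row {i}: {exc}") from exc

    known_ids = {g.gene_id for g in genes}
    warnings: list[str] = []
    domains: list[SuppDomainRecord] = []
    for i, row in ddf.iterrows():
        raw_ids = str(row[dmap["gene_ids"]]).replace(";", ",")
        ids = {s.strip() for s in raw_ids.split(",") if s.strip()}
        try:
            rec = SuppDomainRecord(
                sequence=str(row[dmap["sequence"]]),
                bit_score=float(row[dmap["bit_score"]]),
                gene_ids=ids,
            )
        except ValueError as exc:
            raise ValueError(f"domain table row {i}: {exc}") from exc
        missing = ids - known_ids
        if missing:
            msg = f"domain table row {i}: unknown gene ids {sorted(missing)}"
            warnings.append(msg)
            logger.warning(msg)
        domains.append(rec)
    logger.info(
        "read %d gene records and %d domain records", len(genes), len(domains)
    )
    return genes, domains, warnings


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def _parse_newick(**kwargs) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            schema="newick", preserve_underscores=True, **kwargs
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate leaf label in tree: {exc}") from exc


def read_newick(path, strict_root: bool = True) -> SpeciesTree:
    """Read a single rooted newick tree; leaf labels are organism ids."""
    return SpeciesTree(_parse_newick(path=str(path)), strict_root=strict_root)


def tree_from_string(newick: str, strict_root: bool = True) -> SpeciesTree:
    return SpeciesTree(_parse_newick(data=newick), strict_root=strict_root)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a TSV result table with a provenance header comment."""
    with open(path, "w") as fh:
        if meta:
            items = " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
            fh.write(f"# cepkit {items}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
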