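"""End-to-end orchestration: discover -> weight/rebuild -> analyze.

The pipeline runs the survey stages in order on a set of genome
assemblies: gene discovery with an input motif model, weighted PSPM
re-estimation from the discovered domains, intra-organism distance
(IOPD) aggregation, orthology clustering, sitewise dN/dS on orthologous
groups, and GC-content comparison. Every output table carries a header
comment with the tool version, a hash of the merged configuration and
the seed, and the run directory contains a manifest with per-file
checksums, so a rerun with identical inputs is byte-identical and
verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .evolution_stats import (
    compute_iopds,
    iopd_table,
    logit_tukey,
    rank_tukey,
    sitewise_dnds,
    trim_columns,
)
from .formats_io import (
    GenomeAssembly,
    SpeciesTree,
    read_fasta,
    read_meme_motif,
    read_newick,
    write_meme_motif,
    write_table,
)
from .gene_discovery import DiscoveryConfig, discover_genes, gc_content
from .motif_model import (
    DEFAULT_P_CUTOFF,
    Pspm,
    WeightedDomain,
    assign_weights,
    build_pspm,
)
from .orthology import (
    build_rbh_graph,
    groups_table,
    prune_to_cliques,
    similarity_scores,
)

logger = logging.getLogger(__name__)

STAGES = ("discover", "pspm", "iopd", "ortho", "dnds", "gc")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, completed: list[str], cause: Exception):
        self.stage = stage
        self.completed = completed
        super().__init__(
            f"stage {stage!r} failed after completing {completed}: {cause}"
        )


@dataclass
class PipelineConfig:
    """Thresholds, paths and toggles for one pipeline run.

    ``genomes`` maps assembly ids to FASTA paths; ``organisms`` and
    ``families`` give per-assembly metadata (defaulting to the assembly
    id and "unknown"). Assemblies may instead be passed in memory via
    :func:`run_pipeline`'s ``assemblies`` argument.
    """

    out_dir: str
    seed: int = 1
    pspm_path: str | None = None
    tree_path: str | None = None
    genomes: dict[str, str] = field(default_factory=dict)
    organisms: dict[str, str] = field(default_factory=dict)
    families: dict[str, str] = field(default_factory=dict)
    min_orf: int = 50
    p_cutoff: float = DEFAULT_P_CUTOFF
    signal_cutoff: float = 0.400
    decay: float = 0.8
    min_group_size: int = 4
    bootstrap_reps: int = 400
    stages: tuple = STAGES
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must lie in (0, 1)")
        if not 0 <= self.signal_cutoff <= 1:
            raise ValueError("signal_cutoff must lie in [0, 1]")
        if not 0 < self.decay <= 1:
            raise ValueError("decay must lie in (0, 1]")
        if self.min_orf < 1 or self.min_group_size < 2:
            raise ValueError("min_orf >= 1 and min_group_size >= 2 required")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _meta(config: PipelineConfig) -> dict:
    return {
        "version": __version__,
        "config": config.config_hash(),
        "seed": config.seed,
    }


def mafft_available() -> bool:
    return shutil.which("mafft") is not None


def mafft_align(sequences: dict[str, str]) -> dict[str, str]:
    """Multiple AA alignment via the mafft CLI (L-INS-i for small sets)."""
    if not mafft_available():
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fa"
        inp.write_text(
            "".join(f">{name}\n{seq}\n" for name, seq in sequences.items())
        )
        proc = subprocess.run(
            ["mafft", "--localpair", "--maxiterate", "1000", "--quiet", str(inp)],
            capture_output=True,
            text=True,
            check=True,
        )
    out: dict[str, str] = {}
    name = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name:
            out[name] += line.strip().upper()
    if set(out) != set(sequences):
        raise RuntimeError("mafft returned a different sequence set")
    return out


def thread_codons(aligned_aa: str, cds: str) -> str:
    """Map a gapped AA sequence back onto its codons ('---' per gap)."""
    out = []
    k = 0
    for a in aligned_aa:
        if a == "-":
            out.append("---")
        else:
            out.append(cds[3 * k : 3 * k + 3])
            k += 1
    return "".join(out)


def run_pipeline(
    config: PipelineConfig,
    assemblies: list[GenomeAssembly] | None = None,
    pspm: Pspm | None = None,
    species_tree: SpeciesTree | None = None,
) -> Path:
    """Execute the configured stages; returns the run directory.

    Inputs may be given as paths in the config or as in-memory objects.
    Stage outputs are TSVs in ``out_dir``; a failure halts the run with
    the failing stage's name and the list of completed stages.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = _meta(config)

    if assemblies is None:
        assemblies = [
            read_fasta(
                path,
                assembly_id=aid,
                organism=config.organisms.get(aid, aid),
                family=config.families.get(aid, "unknown"),
            )
            for aid, path in config.genomes.items()
        ]
    if pspm is None:
        if config.pspm_path is None:
            raise ValueError("no PSPM given (pspm_path or pspm argument)")
        pspm = Pspm.from_motif_record(read_meme_motif(config.pspm_path))
    if species_tree is None and config.tree_path:
        species_tree = read_newick(config.tree_path, strict_root=False)

    completed: list[str] = []
    state: dict = {"genes": {}, "groups": []}

    def run_stage(name, fn):
        if name not in config.stages:
            return
        try:
            fn()
        except Exception as exc:  # halt with provenance
            raise PipelineError(name, completed, exc) from exc
        completed.append(name)

    def stage_discover():
        rows = []
        domain_rows = []
        for asm in assemblies:
            genes = discover_genes(
                asm,
                pspm,
                DiscoveryConfig(
                    min_orf_len=config.min_orf,
                    p_cutoff=config.p_cutoff,
                    signal_cutoff=config.signal_cutoff,
                ),
            )
            state["genes"][asm.assembly_id] = (asm, genes)
            for g in genes:
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "assembly_id": asm.assembly_id,
                        "organism": asm.organism,
                        "family": asm.family,
                        "contig": g.contig_id,
                        "strand": g.strand,
                        "cds_start": g.cds_start,
                        "cds_end": g.cds_end,
                        "nss_len": g.nss_len,
                        "var_len": g.var_len,
                        "n_domains": len(g.domain_offsets),
                        "cterm_len": g.cterm_len,
                        "signal_score": round(g.signal_score, 6),
                        "prepropeptide": g.prepropeptide,
                        "cds": g.cds,
                    }
                )
                for off in g.domain_offsets:
                    domain_rows.append(
                        {
                            "gene_id": g.gene_id,
                            "offset": off,
                            "domain": g.prepropeptide[off : off + 15],
                        }
                    )
        write_table(pd.DataFrame(rows), out / "genes.tsv", meta)
        write_table(pd.DataFrame(domain_rows), out / "domains.tsv", meta)

    def stage_pspm():
        domains = []
        for asm, genes in state["genes"].values():
            for g in genes:
                for off in g.domain_offsets:
                    domains.append(
                        WeightedDomain(
                            sequence=g.prepropeptide[off : off + 15],
                            weight=1.0,
                            organism=asm.organism,
                            orf_id=g.gene_id,
                            assembly_id=asm.assembly_id,
                        )
                    )
        if not domains:
            raise ValueError("no domains discovered; cannot rebuild PSPM")
        weighted = assign_weights(domains, species_tree, decay=config.decay)
        rebuilt = build_pspm(weighted)
        rebuilt.motif_id = "reweighted"
        write_meme_motif(rebuilt.to_motif_record(), out / "pspm.meme")

    def stage_iopd():
        for level in ("gene", "domain"):
            records = []
            for asm, genes in state["genes"].values():
                for g in genes:
                    if level == "gene":
                        records.append(
                            (g.gene_id, asm.assembly_id, asm.family, g.prepropeptide)
                        )
                    else:
                        for i, off in enumerate(g.domain_offsets):
                            records.append(
                                (
                                    f"{g.gene_id}.d{i + 1}",
                                    asm.assembly_id,
                                    asm.family,
                                    g.prepropeptide[off : off + 15],
                                )
                            )
            iopds = compute_iopds(records, level=level)
            write_table(iopd_table(iopds), out / f"iopd_{level}.tsv", meta)
            usable = {f: s.distances for f, s in iopds.items() if len(s.distances) >= 2}
            if len(usable) >= 2:
                p = rank_tukey(usable)
                write_table(
                    p.reset_index(names="family"),
                    out / f"iopd_{level}_tukey.tsv",
                    meta,
                )

    def stage_ortho():
        prepro = {}
        for asm, genes in state["genes"].values():
            if genes:
                prepro.setdefault(asm.organism, {}).update(
                    {g.gene_id: g.prepropeptide for g in genes}
                )
        if len(prepro) < 2:
            write_table(pd.DataFrame(columns=["group_id", "gene_id", "organism"]),
                        out / "groups.tsv", meta)
            return
        matrix = similarity_scores(prepro)
        groups = prune_to_cliques(
            build_rbh_graph(matrix), min_group_size=config.min_group_size
        )
        state["groups"] = groups
        state["organism_of"] = matrix.organism_of
        write_table(groups_table(groups, matrix.organism_of), out / "groups.tsv", meta)

    def stage_dnds():
        gene_by_id = {
            g.gene_id: g
            for _, genes in state["genes"].values()
            for g in genes
        }
        frames = []
        for grp in state["groups"]:
            seqs = {gid: gene_by_id[gid].prepropeptide for gid in grp.members}
            lengths = {len(s) for s in seqs.values()}
            aligned = (
                {k: v for k, v in seqs.items()}
                if len(lengths) == 1
                else mafft_align(seqs)
            )
            names = sorted(aligned)
            trimmed, kept = trim_columns([aligned[n] for n in names])
            codon_rows = []
            for n, row in zip(names, trimmed):
                full = thread_codons(aligned[n], gene_by_id[n].cds)
                codon_rows.append("".join(full[3 * c : 3 * c + 3] for c in kept))
            profile = sitewise_dnds(
                codon_rows,
                bootstrap_reps=config.bootstrap_reps,
                seed=config.seed,
                group_id=f"group{grp.group_id}",
            )
            frames.append(profile.to_frame())
        table = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(
                columns=["group_id", "site", "omega", "lower", "upper", "constrained"]
            )
        )
        write_table(table, out / "dnds.tsv", meta)

    def stage_gc():
        rows = []
        by_family: dict[str, list[float]] = {}
        for asm, genes in state["genes"].values():
            for g in genes:
                gc = gc_content(g.cds)
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "family": asm.family,
                        "gc_content": round(gc, 6),
                    }
                )
                by_family.setdefault(asm.family, []).append(gc)
        write_table(pd.DataFrame(rows), out / "gc.tsv", meta)
        usable = {f: v for f, v in by_family.items() if len(v) >= 2}
        if len(usable) >= 2:
            p = logit_tukey(usable)
            write_table(p.reset_index(names="family"), out / "gc_tukey.tsv", meta)

    run_stage("discover", stage_discover)
    run_stage("pspm", stage_pspm)
    run_stage("iopd", stage_iopd)
    run_stage("ortho", stage_ortho)
    run_stage("dnds", stage_dnds)
    run_stage("gc", stage_gc)

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "completed_stages": completed,
        "config": dataclasses.asdict(config),
        "checksums": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.meme"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
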