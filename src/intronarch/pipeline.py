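"""End-to-end orchestration: annotations + alignments -> report bundle.

Stages: parse annotations, extract intron sites, read alignments,
compute well-aligned masks, project sites into homologized positions,
classify clade sharing for the focal and comparator species, select
ancient introns and summarize their lengths, build the intron
presence/absence NJ tree and compare it with the reference phylogeny.
Every tunable is echoed into the JSON report; reruns with an identical
config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import pandas as pd
import yaml

from .alignment import AlignmentError, MaskParams, read_alignment, well_aligned_mask
from .evolution import (
    CladePartition,
    ancient_sites,
    length_summary,
    sharing_proportions,
)
from .gene_models import intron_sites_of, parse_gff3
from .homology import PresenceMatrix, build_presence_matrix, project_sites
from .trees import (
    distance_matrix,
    neighbor_joining,
    robinson_foulds,
    root_on_outgroup,
    total_dollo_losses,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "ConfigError", "DataError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """The run configuration is not usable."""


class DataError(ValueError):
    """An input file is inconsistent with the configuration."""


@dataclass
class RunConfig:
    """Pipeline configuration (typically loaded from YAML).

    Paths are resolved relative to ``base_dir`` (the config file's
    directory when loaded from disk).
    """

    annotations: Mapping[str, str]
    orthologs: str
    alignments_dir: str
    reference_tree: str
    clades: Mapping[str, list]
    focal: str
    comparator: str
    out_dir: str
    proteins: Mapping[str, str] | None = None
    alignment_pattern: str = "{group}.afa"
    outgroup_clade: str = "outgroups"
    ingroup_clade: str = "insects"
    mask: Mapping[str, float] = field(default_factory=dict)
    tolerance: int = 0
    distance_method: str = "jaccard"
    require_universal: bool = True
    strict_parsing: bool = False
    seed: int = 0
    base_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(base_dir=str(path.parent), **raw)

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else Path(self.base_dir) / p

    def mask_params(self) -> MaskParams:
        return MaskParams(**dict(self.mask))

    def partition(self) -> CladePartition:
        return CladePartition.from_dict(self.clades)

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        for members in self.clades.values():
            out.extend(members)
        return out


def validate_config(config: RunConfig) -> list[str]:
    """Return findings (empty iff the config is runnable)."""
    findings: list[str] = []
    try:
        part = config.partition()
    except ValueError as exc:
        findings.append(str(exc))
        part = None
    species = set(config.species)
    for sp in (config.focal, config.comparator):
        if sp not in species:
            findings.append(f"species {sp} not in any clade")
    if part is not None:
        for clade in (config.outgroup_clade, config.ingroup_clade):
            if clade not in part.clades:
                findings.append(f"clade {clade} not defined in partition")
    for sp in species - set(config.annotations):
        findings.append(f"species {sp} has no annotation path")
    for sp, rel in config.annotations.items():
        if sp not in species:
            findings.append(f"annotated species {sp} absent from partition")
        elif not config.resolve(rel).exists():
            findings.append(f"annotation not found: {rel}")
    for rel in (config.orthologs, config.reference_tree):
        if not config.resolve(rel).exists():
            findings.append(f"file not found: {rel}")
    if not config.resolve(config.alignments_dir).is_dir():
        findings.append(f"alignment directory not found: {config.alignments_dir}")
    try:
        config.mask_params()
    except (TypeError, ValueError) as exc:
        findings.append(f"bad mask parameters: {exc}")
    return findings


@dataclass
class RunResult:
    """In-memory pipeline outputs (also written under out_dir)."""

    matrix: PresenceMatrix
    proportions: dict[str, pd.DataFrame]
    ancient_keys: pd.Index
    ancient_summary: pd.DataFrame
    intron_tree: dendropy.Tree
    rooted_newick: str
    rf_to_reference: int
    dollo_losses: int
    report: dict


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunResult:
    """Run all stages and write the report bundle to ``config.out_dir``."""
    findings = validate_config(config)
    if findings:
        raise ConfigError("; ".join(findings))
    part = config.partition()
    species = config.species
    out = Path(config.resolve(config.out_dir))
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # stage 1: gene models + intron sites
    sites_by_species_gene: dict[str, dict[str, list]] = {}
    proteins_len: dict[str, dict[str, int]] = {}
    skipped_genes = 0
    for sp in species:
        result = parse_gff3(
            config.resolve(config.annotations[sp]), sp, strict=config.strict_parsing
        )
        skipped_genes += sum(result.skipped.values())
        per_gene = {m.gene_id: intron_sites_of(m) for m in result}
        sites_by_species_gene[sp] = per_gene
        proteins_len[sp] = {m.gene_id: m.protein_length for m in result}
        logger.info("%s: %d genes, %d skipped", sp, len(result), sum(result.skipped.values()))
    counts["genes_parsed"] = sum(len(v) for v in proteins_len.values())
    counts["genes_skipped"] = skipped_genes

    # optional protein FASTA cross-check
    protein_seqs: dict[str, dict[str, str]] = {}
    if config.proteins:
        from Bio import SeqIO

        for sp, rel in config.proteins.items():
            recs = {r.id: str(r.seq) for r in SeqIO.parse(str(config.resolve(rel)), "fasta")}
            for gid, plen in proteins_len[sp].items():
                if gid in recs and len(recs[gid]) != plen:
                    raise DataError(
                        f"{sp}/{gid}: protein length {len(recs[gid])} != "
                        f"gene model {plen}"
                    )
            protein_seqs[sp] = recs

    # stage 2: ortholog table
    ortho = pd.read_csv(config.resolve(config.orthologs), sep="\t", dtype=str)
    if ortho.empty:
        raise DataError("ortholog table is empty")
    missing_cols = set(species) - set(ortho.columns)
    if missing_cols:
        raise DataError(f"ortholog table lacks species columns {sorted(missing_cols)}")

    mask_params = config.mask_params()
    projections = []
    n_groups_used = 0
    n_groups_skipped = 0
    excluded_sites = 0
    for _, row in ortho.iterrows():
        group_id = row["group_id"]
        genes = {sp: row[sp] for sp in species if pd.notna(row.get(sp))}
        if config.require_universal and len(genes) < len(species):
            n_groups_skipped += 1
            continue
        gene_to_species = {g: sp for sp, g in genes.items()}
        aln_path = config.resolve(config.alignments_dir) / config.alignment_pattern.format(
            group=group_id
        )
        expected = {
            sp: protein_seqs[sp][genes[sp]]
            for sp in genes
            if sp in protein_seqs and genes[sp] in protein_seqs[sp]
        } or None
        try:
            group = read_alignment(str(aln_path), group_id, gene_to_species, expected)
        except FileNotFoundError:
            raise DataError(f"alignment file missing for group {group_id}: {aln_path}")
        mask = well_aligned_mask(group, mask_params)
        group_sites = {
            sp: sites_by_species_gene[sp].get(genes[sp], []) for sp in genes
        }
        proj = project_sites(group, group_sites, mask, tolerance=config.tolerance)
        excluded_sites += proj.n_excluded_mask
        projections.append(proj)
        n_groups_used += 1
    counts["groups_analyzed"] = n_groups_used
    counts["groups_skipped_nonuniversal"] = n_groups_skipped
    counts["sites_excluded_by_mask"] = excluded_sites
    logger.info(
        "%d groups analyzed (%d skipped), %d sites excluded by mask",
        n_groups_used, n_groups_skipped, excluded_sites,
    )

    matrix = build_presence_matrix(projections, species)
    counts["intron_positions"] = matrix.n_sites
    matrix.to_tsv(out / "presence_matrix.tsv")
    matrix.lengths_to_tsv(out / "intron_lengths.tsv")

    # stage 3: sharing classes
    proportions = {}
    prop_frames = []
    for who in (config.focal, config.comparator):
        tab = sharing_proportions(matrix, part, who)
        proportions[who] = tab
        prop_frames.append(tab.assign(focal=who).reset_index())
    pd.concat(prop_frames, ignore_index=True)[
        ["focal", "sharing_class", "count", "fraction"]
    ].to_csv(out / "sharing_proportions.tsv", sep="\t", index=False)

    # stage 4: ancient introns + lengths
    keys = ancient_sites(
        matrix, part, config.focal, config.comparator,
        outgroup_clade=config.outgroup_clade, ingroup_clade=config.ingroup_clade,
    )
    summary = length_summary(matrix, keys, species, config.focal)
    summary.reset_index().to_csv(out / "ancient_length_summary.tsv", sep="\t", index=False)
    lengths = matrix.lengths.set_index(matrix.lengths.columns[:3].tolist())
    lengths[lengths.index.isin(set(keys))].reset_index().to_csv(
        out / "ancient_lengths.tsv", sep="\t", index=False
    )
    counts["ancient_introns"] = len(keys)

    # stage 5: intron tree
    D = distance_matrix(matrix, method=config.distance_method)
    D.to_csv(out / "distance_matrix.tsv", sep="\t")
    tree = neighbor_joining(D)
    reference = dendropy.Tree.get(
        path=str(config.resolve(config.reference_tree)), schema="newick"
    )
    reference.is_rooted = True  # the reference phylogeny is rooted; Dollo needs it
    rf = robinson_foulds(tree, reference)
    rooted = root_on_outgroup(tree, sorted(part.clades[config.outgroup_clade]))
    nwk = tree.as_string(schema="newick", suppress_rooting=True)
    rooted_nwk = rooted.as_string(schema="newick", suppress_rooting=True)
    (out / "intron_tree.nwk").write_text(nwk)
    (out / "intron_tree_rooted.nwk").write_text(rooted_nwk)
    dollo = total_dollo_losses(reference, matrix)
    counts["dollo_losses_total"] = dollo

    outputs = [
        "presence_matrix.tsv", "intron_lengths.tsv", "sharing_proportions.tsv",
        "ancient_length_summary.tsv", "ancient_lengths.tsv", "distance_matrix.tsv",
        "intron_tree.nwk", "intron_tree_rooted.nwk",
    ]
    report = {
        "parameters": {
            "mask": {
                "min_ungapped_fraction": mask_params.min_ungapped_fraction,
                "window": mask_params.window,
                "min_mean_identity": mask_params.min_mean_identity,
            },
            "tolerance": config.tolerance,
            "distance_method": config.distance_method,
            "require_universal": config.require_universal,
            "denominator": "focal-present positions in analyzed groups",
            "quartile_convention": "linear interpolation (type 7)",
            "focal": config.focal,
            "comparator": config.comparator,
            "clades": {k: sorted(v) for k, v in config.clades.items()},
            "seed": config.seed,
        },
        "counts": counts,
        "rf_to_reference": rf,
        "sharing_fractions": {
            who: {cls: float(t.at[cls, "fraction"]) for cls in t.index}
            for who, t in proportions.items()
        },
        "outputs": {name: _checksum(out / name) for name in outputs},
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return RunResult(
        matrix=matrix,
        proportions=proportions,
        ancient_keys=keys,
        ancient_summary=summary,
        intron_tree=tree,
        rooted_newick=rooted_nwk,
        rf_to_reference=rf,
        dollo_losses=dollo,
        report=report,
    )
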