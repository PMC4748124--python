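"""Forward simulation of gene-structure evolution on a species tree.

The generator emulates the statistical structure of a comparative
intron-architecture study: universal single-copy ortholog groups whose
intron complement evolves by lineage-specific loss (and optionally
gain) along a rooted species tree, with per-lineage intron-length
distributions (long tick/vertebrate introns versus short pancrustacean
ones) and amino-acid substitution on the encoded proteins.

Intron slots are the codon boundaries of a root protein of length L:
boundary index b in 1..L-1 with phase p in {0,1,2}, i.e. the intron
interrupts the coding sequence after c = 3b + p coding nucleotides.  At
the root each boundary carries an intron with probability p0 (phase
uniform); along a branch of length t each present intron is lost with
probability 1 - exp(-mu*m*t) and each empty slot gains one with
probability 1 - exp(-lambda*m*t), where m is a per-clade rate
multiplier (e.g. elevated loss in Pancrustacea).  A single event per
slot per branch is allowed — an approximation to the full jump process
that is accurate for small rate*t and keeps the generator deterministic
under one RNG stream.

The emitted files (GFF3 + genome FASTA + protein FASTA per species,
aligned FASTA per group, ortholog table, reference Newick) exercise the
whole pipeline, and the truth tables give every stage an exact oracle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evolution import UNIQUE, WIDESPREAD, CladePartition, exclusive
from .gene_models import CdsSegment, GeneModel
from .homology import KEY_COLUMNS, PresenceMatrix
from . import gff3io

__all__ = ["SimulationConfig", "TruthSet", "simulate", "write_truthset", "default_config"]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
# fixed codon per amino acid: back-translation needs no codon-usage model
CODONS = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_CODON_ARR = np.array([list(CODONS[a]) for a in AA_ALPHABET])
NT = np.array(list("ACGT"))

DEFAULT_TREE = (
    "(((cnid1:0.30,cnid2:0.30):0.20,(vert1:0.20,vert2:0.20):0.30):0.15,"
    "(tick:0.40,(daphnia:0.30,(insect1:0.20,(insect2:0.15,insect3:0.15):0.10):0.15):0.20):0.15);"
)
DEFAULT_CLADES = {
    "chelicerata": ["tick"],
    "crustaceans": ["daphnia"],
    "insects": ["insect1", "insect2", "insect3"],
    "outgroups": ["cnid1", "cnid2", "vert1", "vert2"],
}
# log-normal intron length models: medians one decade apart
# (tick/outgroups ~400 nt, pancrustaceans ~40 nt)
_LONG = (float(np.log(400.0)), 0.6)
_SHORT = (float(np.log(40.0)), 0.6)
DEFAULT_LENGTH_MODELS = {
    "tick": _LONG, "cnid1": _LONG, "cnid2": _LONG, "vert1": _LONG, "vert2": _LONG,
    "daphnia": _SHORT, "insect1": _SHORT, "insect2": _SHORT, "insect3": _SHORT,
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated data set (seed mandatory)."""

    seed: int
    tree: str = DEFAULT_TREE
    clades: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CLADES.items()}
    )
    focal: str = "tick"
    comparator: str = "daphnia"
    outgroup_clade: str = "outgroups"
    ingroup_clade: str = "insects"
    n_groups: int = 500
    L: int = 300
    p0: float = 0.4
    gain_rate: float = 0.0
    loss_rate: float = 0.12
    # clade label -> {"species": [...], "factor": x}: the factor applies to
    # the stem edge of the species' MRCA and every edge below it
    rate_multipliers: Mapping[str, Mapping] = field(
        default_factory=lambda: {
            "pancrustacea": {
                "species": ["daphnia", "insect1", "insect2", "insect3"],
                "factor": 8.0,
            }
        }
    )
    length_models: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_MODELS)
    )
    subst_rate: float = 0.05
    indel_rate: float = 0.0      # per terminal branch per group: deletion prob
    indel_mean_len: int = 5
    flank: int = 50
    write_genomes: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must be in [0, 1]")
        if min(self.gain_rate, self.loss_rate, self.subst_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.L < 10:
            raise ValueError("root protein length L must be >= 10")

    @property
    def species(self) -> list[str]:
        out: list[str] = []
        for members in self.clades.values():
            out.extend(members)
        return out

    def partition(self) -> CladePartition:
        return CladePartition.from_dict(self.clades)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["clades"] = {k: list(v) for k, v in self.clades.items()}
        d["length_models"] = {k: list(v) for k, v in self.length_models.items()}
        d["rate_multipliers"] = {
            k: {"species": list(v["species"]), "factor": v["factor"]}
            for k, v in self.rate_multipliers.items()
        }
        return d


def default_config(seed: int, **overrides) -> SimulationConfig:
    """The package's default nine-species study condition."""
    return SimulationConfig(seed=seed, **overrides)


@dataclass
class TruthSet:
    """Simulation output plus exact ground truth for every stage."""

    config: SimulationConfig
    tree: dendropy.Tree
    species: list[str]
    group_ids: list[str]
    presence: np.ndarray      # bool (n_species, n_groups, L-1, 3)
    lengths: np.ndarray       # int32, 0 where absent
    proteins: np.ndarray      # int8 (n_species, n_groups, L), AA_ALPHABET index
    deleted: np.ndarray       # bool (n_species, n_groups, L)
    events: pd.DataFrame      # group_id, boundary, phase, edge, event

    def protein_seq(self, species: str, group_index: int) -> str:
        s = self.species.index(species)
        aa = self.proteins[s, group_index]
        keep = ~self.deleted[s, group_index]
        return "".join(AA_ALPHABET[i] for i in aa[keep])

    def aligned_row(self, species: str, group_index: int) -> str:
        s = self.species.index(species)
        aa = self.proteins[s, group_index]
        dele = self.deleted[s, group_index]
        return "".join(
            "-" if d else AA_ALPHABET[i] for i, d in zip(aa, dele)
        )

    def gene_id(self, species: str, group_id: str) -> str:
        return f"{species}_{group_id}"

    # -- truth tables -------------------------------------------------

    def truth_presence_matrix(self) -> PresenceMatrix:
        """Truth in the pipeline's own presence-matrix format.

        Keys use the boundary's alignment column, which (no insertions)
        equals the root boundary index.
        """
        n_sp, n_g, n_b, _ = self.presence.shape
        any_present = self.presence.any(axis=0)  # (n_groups, L-1, 3)
        g_idx, b_idx, p_idx = np.nonzero(any_present)
        # boundary axis index k corresponds to boundary index k+1
        index = pd.MultiIndex.from_arrays(
            [
                np.array(self.group_ids, dtype=object)[g_idx],
                b_idx + 1,
                p_idx,
            ],
            names=KEY_COLUMNS,
        )
        data = self.presence[:, g_idx, b_idx, p_idx].T.astype(np.int8)
        presence = pd.DataFrame(data, index=index, columns=self.species).sort_index()
        rows = []
        for s, sp in enumerate(self.species):
            gs, bs, ps = np.nonzero(self.presence[s])
            for g, b, p in zip(gs.tolist(), bs.tolist(), ps.tolist()):
                rows.append(
                    (self.group_ids[g], b + 1, p, sp, int(self.lengths[s, g, b, p]))
                )
        lengths = pd.DataFrame(
            rows, columns=KEY_COLUMNS + ["species", "genomic_length"]
        )
        return PresenceMatrix(presence=presence, lengths=lengths)

    def truth_classes(self, focal: str) -> pd.Series:
        """True sharing class of every focal-present key."""
        part = self.config.partition()
        matrix = self.truth_presence_matrix()
        pres = matrix.presence
        sub = pres[pres[focal] == 1]
        focal_clade = part.clade_of(focal)
        labels = []
        for _, row in sub.iterrows():
            sharing = set()
            for name, members in part.clades.items():
                others = members - {focal} if name == focal_clade else members
                if any(row[sp] for sp in others):
                    sharing.add(name)
            if not sharing:
                labels.append(UNIQUE)
            elif len(sharing) == 1:
                labels.append(exclusive(sharing.pop()))
            else:
                labels.append(WIDESPREAD)
        return pd.Series(labels, index=sub.index, name="sharing_class")

    # -- gene models --------------------------------------------------

    def gene_models(self, species: str) -> tuple[list[GeneModel], dict[str, str]]:
        """Gene models (and proteins) implied by the truth arrays.

        Deterministic coordinate geometry: flank + exon/intron
        alternation; genes on even group indices sit on '+', odd on '-'.
        """
        s = self.species.index(species)
        models = []
        proteins = {}
        for g, gid in enumerate(self.group_ids):
            geom = self._gene_geometry(s, g)
            strand = "+" if g % 2 == 0 else "-"
            contig = f"ctg_{gid}"
            total = geom["total"]
            segs = []
            for a, b in geom["exons"]:
                if strand == "+":
                    segs.append(CdsSegment(contig, a, b, "+"))
                else:
                    segs.append(CdsSegment(contig, total - b, total - a, "-"))
            model = GeneModel(
                gene_id=self.gene_id(species, gid),
                species_id=species,
                segments=tuple(segs),
            )
            models.append(model)
            proteins[model.gene_id] = self.protein_seq(species, g)
        return models, proteins

    def _gene_geometry(self, s: int, g: int) -> dict:
        """Sense-strand coordinates of exons/introns for one gene."""
        cfg = self.config
        dele = self.deleted[s, g]
        keep = ~dele
        # new residue index of original residue r
        new_index = np.cumsum(keep) - 1
        slots = []
        bs, ps = np.nonzero(self.presence[s, g])
        for b, p in zip(bs.tolist(), ps.tolist()):
            # axis index b is boundary b+1: the intron precedes residue b+1
            bp = int(new_index[b + 1])
            slots.append((3 * bp + p, int(self.lengths[s, g, b, p])))
        slots.sort()
        coding_len = 3 * int(keep.sum())
        exons = []
        introns = []
        pos = cfg.flank
        prev_c = 0
        for c, ilen in slots:
            exons.append((pos, pos + (c - prev_c)))
            pos += c - prev_c
            introns.append((pos, pos + ilen))
            pos += ilen
            prev_c = c
        exons.append((pos, pos + (coding_len - prev_c)))
        pos += coding_len - prev_c
        total = pos + cfg.flank
        return {"exons": exons, "introns": introns, "total": total, "coding_len": coding_len}


def _edge_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def _resolve_multipliers(tree: dendropy.Tree, config: SimulationConfig) -> dict:
    """Per-edge rate factor from the configured clade multipliers."""
    factors = {node: 1.0 for node in tree.preorder_node_iter()}
    for name, spec in config.rate_multipliers.items():
        taxa = [tree.taxon_namespace.get_taxon(t) for t in spec["species"]]
        if any(t is None for t in taxa):
            missing = [s for s, t in zip(spec["species"], taxa) if t is None]
            raise ValueError(f"multiplier {name}: unknown species {missing}")
        mrca = tree.mrca(taxa=taxa)
        for node in mrca.preorder_iter():
            factors[node] *= float(spec["factor"])
    return factors


def simulate(config: SimulationConfig) -> TruthSet:
    """Run the forward simulation; bit-identical for equal config+seed."""
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    tree.is_rooted = True
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    species = config.species
    if set(species) != leaves:
        raise ValueError(
            f"clade partition species {sorted(set(species) ^ leaves)} "
            f"do not match tree leaves"
        )
    if len(leaves) < 4:
        raise ValueError("tree must have >= 4 leaves")
    # stable internal labels for the event log
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.taxon is None and node.label is None:
            node.label = f"node{i}"

    rng = np.random.default_rng(config.seed)
    n_g, L = config.n_groups, config.L
    n_b = L - 1
    factors = _resolve_multipliers(tree, config)

    # root state: one intron per boundary w.p. p0, phase uniform
    root_present = rng.random((n_g, n_b)) < config.p0
    root_phase = rng.integers(0, 3, size=(n_g, n_b))
    state0 = np.zeros((n_g, n_b, 3), dtype=bool)
    gg, bb = np.nonzero(root_present)
    state0[gg, bb, root_phase[gg, bb]] = True
    root_aa = rng.integers(0, 20, size=(n_g, L), dtype=np.int8)

    states: dict[dendropy.Node, np.ndarray] = {tree.seed_node: state0}
    seqs: dict[dendropy.Node, np.ndarray] = {tree.seed_node: root_aa}
    event_rows: list[tuple] = []
    group_ids = [f"OG{g:05d}" for g in range(n_g)]

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        m = factors[node]
        p_loss = 1.0 - np.exp(-config.loss_rate * m * t)
        p_gain = 1.0 - np.exp(-config.gain_rate * m * t)
        parent_state = states[node.parent_node]
        u = rng.random(parent_state.shape)
        child = np.where(parent_state, u >= p_loss, u < p_gain)
        delta = child != parent_state
        if delta.any():
            label = _edge_label(node)
            for g, b, p in zip(*np.nonzero(delta)):
                event_rows.append(
                    (
                        group_ids[g],
                        int(b) + 1,
                        int(p),
                        label,
                        "loss" if parent_state[g, b, p] else "gain",
                    )
                )
        states[node] = child

        p_mut = 1.0 - np.exp(-config.subst_rate * t)
        parent_aa = seqs[node.parent_node]
        mut = rng.random(parent_aa.shape) < p_mut
        offsets = rng.integers(1, 20, size=parent_aa.shape, dtype=np.int8)
        seqs[node] = np.where(mut, (parent_aa + offsets) % 20, parent_aa).astype(np.int8)

        if not node.is_leaf():
            # free parent arrays lazily is unnecessary at this scale
            pass

    sp_index = {sp: i for i, sp in enumerate(species)}
    presence = np.zeros((len(species), n_g, n_b, 3), dtype=bool)
    proteins = np.zeros((len(species), n_g, L), dtype=np.int8)
    leaf_nodes = {}
    for lf in tree.leaf_node_iter():
        s = sp_index[lf.taxon.label]
        presence[s] = states[lf]
        proteins[s] = seqs[lf]
        leaf_nodes[lf.taxon.label] = lf

    # per-species intron lengths (drawn in fixed species order)
    lengths = np.zeros_like(presence, dtype=np.int32)
    for s, sp in enumerate(species):
        meanlog, sdlog = config.length_models[sp]
        draw = rng.lognormal(meanlog, sdlog, size=(n_g, n_b, 3))
        lengths[s] = np.where(presence[s], np.maximum(4, np.rint(draw)), 0).astype(
            np.int32
        )

    # optional terminal-branch deletions (exercise gaps + the mask)
    deleted = np.zeros((len(species), n_g, L), dtype=bool)
    if config.indel_rate > 0:
        for s, sp in enumerate(species):
            hit = rng.random(n_g) < config.indel_rate
            starts = rng.integers(1, L - 1, size=n_g)
            lens = 1 + rng.geometric(1.0 / config.indel_mean_len, size=n_g)
            for g in np.nonzero(hit)[0]:
                a = int(starts[g])
                bnd = min(L - 1, a + int(lens[g]))
                deleted[s, g, a:bnd] = True
        # an intron slot survives only if both flanking residues survive
        for s in range(len(species)):
            for g in range(n_g):
                if not deleted[s, g].any():
                    continue
                for b in range(1, L):
                    if deleted[s, g, b - 1] or deleted[s, g, min(b, L - 1)]:
                        if presence[s, g, b - 1].any():
                            presence[s, g, b - 1] = False
                            lengths[s, g, b - 1] = 0
        # NB boundary arrays are indexed b-1 (boundaries run 1..L-1)

    events = pd.DataFrame(
        event_rows, columns=["group_id", "boundary", "phase", "edge", "event"]
    )

    # shift boundary axis so that axis index k corresponds to boundary k+1
    return TruthSet(
        config=config,
        tree=tree,
        species=list(species),
        group_ids=group_ids,
        presence=presence,
        lengths=lengths,
        proteins=proteins,
        deleted=deleted,
        events=events,
    )


# ---------------------------------------------------------------------------
# emission

def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(NT[rng.integers(0, 4, size=n)])


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def write_truthset(ts: TruthSet, out_dir) -> dict:
    """Write the full file bundle and return the manifest dict.

    Layout: annotations/<sp>.gff3, genomes/<sp>.fa, proteins/<sp>.fa,
    alignments/<group>.afa, orthologs.tsv, tree.nwk, truth/*.tsv,
    run.yaml (a ready-to-run pipeline config), manifest.json.
    Deterministic: same TruthSet (config+seed) gives byte-identical
    files.
    """
    out = Path(out_dir)
    for sub in ("annotations", "genomes", "proteins", "alignments", "truth"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    cfg = ts.config
    fill_rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(1)[0]
    )

    files: list[Path] = []

    # per-species annotation, genome, proteins
    for sp in ts.species:
        s = ts.species.index(sp)
        models, prots = ts.gene_models(sp)
        gff_path = out / "annotations" / f"{sp}.gff3"
        gff3io.write_gff3(models, gff_path)
        files.append(gff_path)

        prot_path = out / "proteins" / f"{sp}.fa"
        with open(prot_path, "w") as fh:
            SeqIO.write(
                [SeqRecord(Seq(seq), id=gid, description="") for gid, seq in prots.items()],
                fh,
                "fasta",
            )
        files.append(prot_path)

        if cfg.write_genomes:
            genome_path = out / "genomes" / f"{sp}.fa"
            with open(genome_path, "w") as fh:
                for g, gid in enumerate(ts.group_ids):
                    geom = ts._gene_geometry(s, g)
                    aa = ts.protein_seq(sp, g)
                    cds = "".join(CODONS[a] for a in aa)
                    parts = [_random_nt(fill_rng, cfg.flank)]
                    prev = 0
                    cpos = 0
                    for (ea, eb), (ia, ib) in zip(geom["exons"], geom["introns"]):
                        elen = eb - ea
                        parts.append(cds[cpos : cpos + elen])
                        cpos += elen
                        ilen = ib - ia
                        parts.append("GT" + _random_nt(fill_rng, ilen - 4) + "AG")
                    parts.append(cds[cpos:])
                    parts.append(_random_nt(fill_rng, cfg.flank))
                    sense = "".join(parts)
                    contig = sense if g % 2 == 0 else _revcomp(sense)
                    fh.write(f">ctg_{gid}\n")
                    for k in range(0, len(contig), 60):
                        fh.write(contig[k : k + 60] + "\n")
            files.append(genome_path)

    # per-group alignments (true alignment: no insertions, gaps = deletions)
    for g, gid in enumerate(ts.group_ids):
        path = out / "alignments" / f"{gid}.afa"
        with open(path, "w") as fh:
            for sp in ts.species:
                fh.write(f">{ts.gene_id(sp, gid)}\n{ts.aligned_row(sp, g)}\n")
        files.append(path)

    # ortholog table
    ortho = pd.DataFrame(
        {
            "group_id": ts.group_ids,
            **{sp: [ts.gene_id(sp, gid) for gid in ts.group_ids] for sp in ts.species},
        }
    )
    ortho_path = out / "orthologs.tsv"
    ortho.to_csv(ortho_path, sep="\t", index=False)
    files.append(ortho_path)

    tree_path = out / "tree.nwk"
    tree_path.write_text(cfg.tree.strip() + "\n")
    files.append(tree_path)

    # truth tables
    matrix = ts.truth_presence_matrix()
    matrix.to_tsv(out / "truth" / "presence.tsv")
    matrix.lengths_to_tsv(out / "truth" / "lengths.tsv")
    files += [out / "truth" / "presence.tsv", out / "truth" / "lengths.tsv"]
    for who in (cfg.focal, cfg.comparator):
        classes = ts.truth_classes(who)
        p = out / "truth" / f"classes_{who}.tsv"
        classes.reset_index().to_csv(p, sep="\t", index=False)
        files.append(p)
    ev_path = out / "truth" / "events.tsv"
    ts.events.to_csv(ev_path, sep="\t", index=False)
    files.append(ev_path)

    # ready-to-run pipeline config
    run_cfg = {
        "annotations": {sp: f"annotations/{sp}.gff3" for sp in ts.species},
        "proteins": {sp: f"proteins/{sp}.fa" for sp in ts.species},
        "orthologs": "orthologs.tsv",
        "alignments_dir": "alignments",
        "alignment_pattern": "{group}.afa",
        "reference_tree": "tree.nwk",
        "clades": {k: list(v) for k, v in cfg.clades.items()},
        "focal": cfg.focal,
        "comparator": cfg.comparator,
        "outgroup_clade": cfg.outgroup_clade,
        "ingroup_clade": cfg.ingroup_clade,
        "out_dir": "results",
        "seed": cfg.seed,
    }
    import yaml

    run_path = out / "run.yaml"
    run_path.write_text(yaml.safe_dump(run_cfg, sort_keys=True))
    files.append(run_path)

    manifest = {
        "config": cfg.to_jsonable(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_jsonable(), sort_keys=True).encode()
        ).hexdigest(),
        "files": {
            str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(files)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
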