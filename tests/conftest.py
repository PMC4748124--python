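"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities by enumeration or
nucleotide-level walking, independent of the package's own arithmetic,
so tests compare two routes to the same answer.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from intronarch.gene_models import CdsSegment, GeneModel
from intronarch.pipeline import RunConfig, run_pipeline
from intronarch.simulate import default_config, simulate, write_truthset


# ---------------------------------------------------------------------------
# oracles

def walk_introns(model: GeneModel) -> list[tuple[int, int, int]]:
    """Nucleotide-walking intron oracle: (protein_index, phase, length).

    Walks the spliced transcript one genomic position at a time in
    transcription order, counting coding nucleotides, and measures each
    intron as the count of genomic positions strictly between adjacent
    segments.
    """
    out = []
    coding = 0
    prev_last = None
    for seg in model.segments:
        if seg.strand == "+":
            positions = list(range(seg.start, seg.end))
        else:
            positions = list(range(seg.end - 1, seg.start - 1, -1))
        if prev_last is not None:
            lo, hi = sorted((prev_last, positions[0]))
            gap = sum(1 for _ in range(lo + 1, hi))
            out.append((coding // 3, coding % 3, gap))
        for _ in positions:
            coding += 1
        prev_last = positions[-1]
    return out


def random_gene_model(rng: np.random.Generator, gene_id: str = "g") -> GeneModel:
    """A random valid gene model: 1-8 exons, random strand and gaps."""
    n_exons = int(rng.integers(1, 9))
    exon_lens = rng.integers(3, 60, size=n_exons)
    total = int(exon_lens.sum())
    exon_lens[-1] += (3 - total % 3) % 3  # coding length divisible by 3
    gaps = rng.integers(1, 500, size=n_exons - 1) if n_exons > 1 else []
    strand = "+" if rng.random() < 0.5 else "-"
    pos = int(rng.integers(0, 1000))
    segs = []
    for i, ln in enumerate(exon_lens):
        segs.append(CdsSegment("chr1", pos, pos + int(ln), strand))
        if i < n_exons - 1:
            pos += int(ln) + int(gaps[i])
    if strand == "-":
        segs.reverse()
    return GeneModel(gene_id=gene_id, species_id="sp", segments=tuple(segs))


def classify_by_enumeration(presence: dict, clades: dict, focal: str) -> str:
    """Set-enumeration classification oracle, independent of classify_site."""
    present = {sp for sp, v in presence.items() if v}
    assert focal in present
    shared_clades = []
    for name, members in clades.items():
        if (set(members) - {focal}) & (present - {focal}):
            shared_clades.append(name)
    if len(shared_clades) == 0:
        return "UNIQUE"
    if len(shared_clades) == 1:
        return f"EXCLUSIVE:{shared_clades[0]}"
    return "WIDESPREAD"


def dollo_by_subset_search(tree, present: set) -> int:
    """Exhaustive minimal-loss search on a small rooted tree.

    Finds the MRCA of the present leaves by scanning all nodes, then the
    smallest set of subtrees below it whose leaves are exactly the
    absent leaves.
    """
    def leafset(node):
        return {lf.taxon.label for lf in node.leaf_iter()}

    candidates = [n for n in tree.preorder_node_iter() if present <= leafset(n)]
    mrca = min(candidates, key=lambda n: len(leafset(n)))
    absent = leafset(mrca) - present
    below = [n for n in mrca.preorder_iter() if n is not mrca]
    for k in range(0, len(below) + 1):
        for combo in itertools.combinations(below, k):
            covered = set()
            for n in combo:
                covered |= leafset(n)
            if covered == absent:
                return k
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# simulation fixtures

@pytest.fixture(scope="session")
def small_truthset():
    """A quick 20-group simulation used across unit tests."""
    return simulate(default_config(seed=11, n_groups=20, L=60))


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_truthset):
    out = tmp_path_factory.mktemp("small_bundle")
    manifest = write_truthset(small_truthset, out)
    return out, manifest


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """The package's reference study condition, simulated and analyzed.

    Nine species, 500 universal single-copy groups, root protein length
    300, p0=0.4, loss-only evolution with an 8x loss multiplier on the
    pancrustacean clade, seed 42.
    """
    cfg = default_config(seed=42)
    ts = simulate(cfg)
    out = tmp_path_factory.mktemp("full_bundle")
    write_truthset(ts, out)
    rc = RunConfig.from_yaml(out / "run.yaml")
    result = run_pipeline(rc)
    return ts, result
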