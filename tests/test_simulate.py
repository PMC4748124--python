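"""Forward simulator: truth consistency, determinism, emitted files."""

import json

import numpy as np
import pandas as pd
import pytest
from Bio import SeqIO

from intronarch.evolution import WIDESPREAD, exclusive, sharing_proportions
from intronarch.gene_models import intron_sites_of, parse_gff3
from intronarch.pipeline import RunConfig, run_pipeline
from intronarch.simulate import (
    SimulationConfig,
    default_config,
    simulate,
    write_truthset,
)

SYM_TREE = "((tick:0.3,daphnia:0.3):0.2,(ins1:0.3,out1:0.3):0.2);"
SYM_KW = dict(
    tree=SYM_TREE,
    clades={
        "chelicerata": ["tick"], "crustaceans": ["daphnia"],
        "insects": ["ins1"], "outgroups": ["out1"],
    },
    length_models={sp: (np.log(100.0), 0.5) for sp in ["tick", "daphnia", "ins1", "out1"]},
    rate_multipliers={},
)


def test_no_evolution_limit_is_all_widespread():
    cfg = default_config(seed=3, n_groups=10, L=40, loss_rate=0.0, gain_rate=0.0,
                        p0=0.5, subst_rate=0.0)
    ts = simulate(cfg)
    m = ts.truth_presence_matrix()
    # every species inherits the root complement unchanged
    assert (m.presence.sum(axis=1) == len(ts.species)).all()
    tab = sharing_proportions(m, cfg.partition(), cfg.focal)
    assert tab.at[WIDESPREAD, "fraction"] == 1.0


def test_losses_confined_to_multiplied_clade():
    cfg = SimulationConfig(
        seed=17, n_groups=30, L=50, p0=0.6, gain_rate=0.0, loss_rate=0.5,
        subst_rate=0.0,
        tree=SYM_TREE,
        clades=SYM_KW["clades"],
        length_models=SYM_KW["length_models"],
        rate_multipliers={
            # zero out every edge outside the crustacean+insect pair
            "left": {"species": ["tick", "daphnia"], "factor": 0.0},
            "right_only": {"species": ["ins1", "out1"], "factor": 1.0},
        },
        focal="tick", comparator="daphnia",
    )
    # zero the left half entirely; the right half keeps rate 0.5 on its
    # stem and terminal edges, so absences can appear only in ins1/out1
    ts = simulate(cfg)
    m = ts.truth_presence_matrix()
    assert (m.presence["tick"] == 1).all()
    assert (m.presence["daphnia"] == 1).all()
    assert (m.presence[["ins1", "out1"]].to_numpy() == 0).any()
    losers = set(ts.events["edge"]) if len(ts.events) else set()
    assert {"tick", "daphnia"}.isdisjoint(losers)


def test_same_seed_is_byte_identical(tmp_path):
    manifests = []
    for d in ("a", "b"):
        cfg = default_config(seed=9, n_groups=8, L=40)
        ts = simulate(cfg)
        manifests.append(write_truthset(ts, tmp_path / d))
    assert manifests[0] == manifests[1]


def test_per_branch_loss_fraction_matches_expectation():
    """Observed terminal-branch loss fraction within 3 binomial SE."""
    cfg = SimulationConfig(
        seed=23, n_groups=60, L=80, p0=0.8, gain_rate=0.0, loss_rate=0.4,
        subst_rate=0.0, **SYM_KW, focal="tick", comparator="daphnia",
    )
    ts = simulate(cfg)
    # with loss only, a site absent in tick but present in daphnia was
    # present at their ancestor and lost on tick's terminal branch (t=0.3)
    pres = ts.truth_presence_matrix().presence
    both_parent = pres[(pres["daphnia"] == 1)]
    lost = (both_parent["tick"] == 0).sum()
    n = len(both_parent)
    p_exp = 1 - np.exp(-0.4 * 0.3)
    # daphnia-present conditions on survival there; tick losses independent
    se = np.sqrt(p_exp * (1 - p_exp) / n)
    assert abs(lost / n - p_exp) < 3 * se


def test_symmetric_tree_gives_symmetric_exclusive_fractions():
    cfg = SimulationConfig(
        seed=31, n_groups=150, L=80, p0=0.5, gain_rate=0.0, loss_rate=0.35,
        subst_rate=0.0, **SYM_KW, focal="tick", comparator="daphnia",
    )
    ts = simulate(cfg)
    m = ts.truth_presence_matrix()
    part = cfg.partition()
    t = sharing_proportions(m, part, "tick")
    d = sharing_proportions(m, part, "daphnia")
    f_t = t.at[exclusive("outgroups"), "fraction"]
    f_d = d.at[exclusive("outgroups"), "fraction"]
    n = min(t["count"].sum(), d["count"].sum())
    se = np.sqrt(2 * f_t * (1 - f_t) / n)
    assert abs(f_t - f_d) < 4 * max(se, 1e-3)


def test_median_length_recovery_within_five_percent():
    # needs a few thousand introns per species for a stable sample median
    ts = simulate(default_config(seed=19, n_groups=100, L=100))
    m = ts.truth_presence_matrix()
    cfg = ts.config
    for sp in ts.species:
        vals = m.lengths.loc[m.lengths["species"] == sp, "genomic_length"]
        target = float(np.exp(cfg.length_models[sp][0]))
        assert abs(vals.median() - target) / target < 0.05


class TestEmittedFiles:
    def test_gff3_round_trip_reproduces_truth_sites(self, small_truthset, small_bundle):
        out, _ = small_bundle
        ts = small_truthset
        sp = ts.config.focal
        models, proteins = ts.gene_models(sp)
        parsed = {m.gene_id: m for m in parse_gff3(out / "annotations" / f"{sp}.gff3", sp)}
        assert set(parsed) == {m.gene_id for m in models}
        for m in models:
            assert parsed[m.gene_id].segments == m.segments
            got = intron_sites_of(parsed[m.gene_id])
            assert got == intron_sites_of(m)
            assert parsed[m.gene_id].protein_length == len(proteins[m.gene_id])

    def test_introns_bounded_by_gt_ag(self, small_truthset, small_bundle):
        out, _ = small_bundle
        ts = small_truthset
        sp = ts.species[0]
        genome = {r.id: str(r.seq) for r in SeqIO.parse(str(out / "genomes" / f"{sp}.fa"), "fasta")}
        models, _ = ts.gene_models(sp)
        n_checked = 0
        for model in models[:10]:
            for site in intron_sites_of(model):
                seq_id, start, end, strand = site.genomic_span
                seq = genome[seq_id][start:end]
                if strand == "-":
                    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                    seq = "".join(comp[b] for b in reversed(seq))
                assert seq.startswith("GT") and seq.endswith("AG")
                n_checked += 1
        assert n_checked > 0

    def test_manifest_covers_all_files(self, small_bundle):
        out, manifest = small_bundle
        disk = json.loads((out / "manifest.json").read_text())
        assert disk == manifest
        for rel in manifest["files"]:
            assert (out / rel).exists()

    def test_pipeline_on_emitted_files_reproduces_truth(self, small_truthset, small_bundle):
        out, _ = small_bundle
        result = run_pipeline(RunConfig.from_yaml(out / "run.yaml"))
        truth = small_truthset.truth_presence_matrix()
        pd.testing.assert_frame_equal(
            result.matrix.presence, truth.presence, check_dtype=False
        )


def test_deletion_mode_produces_gaps_and_consistent_models(tmp_path):
    cfg = default_config(seed=13, n_groups=12, L=60, indel_rate=0.3)
    ts = simulate(cfg)
    rows = [ts.aligned_row(sp, g) for sp in ts.species for g in range(12)]
    assert any("-" in r for r in rows)
    out = tmp_path / "indel"
    write_truthset(ts, out)
    result = run_pipeline(RunConfig.from_yaml(out / "run.yaml"))
    truth = ts.truth_presence_matrix()
    # masking may drop sites near gaps but never invents new ones
    assert set(result.matrix.presence.index) <= set(truth.presence.index)
    common = result.matrix.presence.index
    pd.testing.assert_frame_equal(
        result.matrix.presence,
        truth.presence.loc[common].astype(result.matrix.presence.dtypes),
    )
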