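"""Intron-position homology across species.

Two introns in orthologous genes are called homologous when they fall at
the same alignment boundary with the same phase.  Each site is projected
to the alignment column of its protein_index residue; sites are admitted
only when the flanking residue columns are inside the well-aligned mask.
An optional column tolerance merges nearby same-phase boundaries by
single-linkage clustering (off by default: exact position homology is
the reproducible null).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import AlignedGroup, WellAlignedMask, residue_column
from .gene_models import IntronSite

__all__ = [
    "IntronPositionKey",
    "PresenceMatrix",
    "ProjectionResult",
    "project_sites",
    "build_presence_matrix",
]

KEY_COLUMNS = ["group_id", "boundary_after_column", "phase"]


@dataclass(frozen=True, order=True)
class IntronPositionKey:
    """Homologized intron position: (group, alignment boundary, phase)."""

    group_id: str
    boundary_after_column: int
    phase: int


@dataclass
class PresenceMatrix:
    """Presence/absence of homologized intron positions across species.

    ``presence``: DataFrame indexed by (group_id, boundary_after_column,
    phase) with one 0/1 column per species.  ``lengths``: long-format
    DataFrame (key columns + species + genomic_length) with one row per
    present cell.
    """

    presence: pd.DataFrame
    lengths: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def n_sites(self) -> int:
        return len(self.presence)

    def keys(self) -> list[IntronPositionKey]:
        return [IntronPositionKey(*idx) for idx in self.presence.index]

    def to_tsv(self, path) -> None:
        self.presence.reset_index().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, lengths_path=None) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t").set_index(KEY_COLUMNS)
        lengths = (
            pd.read_csv(lengths_path, sep="\t")
            if lengths_path is not None
            else pd.DataFrame(columns=KEY_COLUMNS + ["species", "genomic_length"])
        )
        return cls(presence=df, lengths=lengths)

    def lengths_to_tsv(self, path) -> None:
        self.lengths.to_csv(path, sep="\t", index=False)


@dataclass
class ProjectionResult:
    """Per-group projection outcome: admitted rows plus exclusion counts."""

    group_id: str
    presence: dict[IntronPositionKey, dict[str, int]]
    lengths: dict[tuple[IntronPositionKey, str], int]
    n_admitted: int = 0
    n_excluded_mask: int = 0


def _merge_keys(
    cols_by_phase: Mapping[int, list[int]], tolerance: int
) -> dict[int, dict[int, int]]:
    """Single-linkage merge of boundary columns per phase.

    Returns phase -> {column -> representative column}; the
    representative is the smallest column of the cluster, making the
    merge independent of input order.
    """
    rep: dict[int, dict[int, int]] = {}
    for phase, cols in cols_by_phase.items():
        uniq = sorted(set(cols))
        mapping: dict[int, int] = {}
        cluster_rep = None
        prev = None
        for c in uniq:
            if cluster_rep is None or c - prev > tolerance:
                cluster_rep = c
            mapping[c] = cluster_rep
            prev = c
        rep[phase] = mapping
    return rep


def project_sites(
    group: AlignedGroup,
    sites_by_species: Mapping[str, Sequence[IntronSite]],
    mask: WellAlignedMask,
    tolerance: int = 0,
) -> ProjectionResult:
    """Project intron sites onto alignment columns and homologize them.

    A site with protein_index i maps to boundary_after_column =
    residue_column(i).  It is admitted only if that column and, when
    residue i+1 exists in the row, the column of residue i+1 are both
    mask-true.  Admitted sites sharing phase and (within ``tolerance``
    columns, single-linkage) boundary collapse to one key.
    """
    if mask.group_id != group.group_id:
        raise ValueError("mask/group mismatch")
    raw: list[tuple[str, int, int, int]] = []  # species, column, phase, length
    n_excluded = 0
    for sp, sites in sites_by_species.items():
        n_res = len(group.degapped(sp))
        for site in sites:
            if site.protein_index >= n_res:
                raise IndexError(
                    f"group {group.group_id}, {sp}: site at residue "
                    f"{site.protein_index} beyond row length {n_res}"
                )
            col = residue_column(group, sp, site.protein_index)
            ok = bool(mask.mask[col])
            if ok and site.protein_index + 1 < n_res:
                ok = bool(mask.mask[residue_column(group, sp, site.protein_index + 1)])
            if not ok:
                n_excluded += 1
                continue
            raw.append((sp, col, site.phase, site.genomic_length))

    cols_by_phase: dict[int, list[int]] = {}
    for _, col, phase, _ in raw:
        cols_by_phase.setdefault(phase, []).append(col)
    rep = (
        _merge_keys(cols_by_phase, tolerance)
        if tolerance > 0
        else {p: {c: c for c in cs} for p, cs in cols_by_phase.items()}
    )

    presence: dict[IntronPositionKey, dict[str, int]] = {}
    lengths: dict[tuple[IntronPositionKey, str], int] = {}
    for sp, col, phase, glen in raw:
        key = IntronPositionKey(group.group_id, rep[phase][col], phase)
        presence.setdefault(key, {})[sp] = 1
        lengths[(key, sp)] = glen
    return ProjectionResult(
        group_id=group.group_id,
        presence=presence,
        lengths=lengths,
        n_admitted=len(raw),
        n_excluded_mask=n_excluded,
    )


def build_presence_matrix(
    projections: Iterable[ProjectionResult], species: Sequence[str]
) -> PresenceMatrix:
    """Concatenate per-group projections into one presence matrix.

    Rows are ordered by (group_id, boundary column, phase).  Every
    species of the configured set gets a 0/1 in every row (universal
    single-copy groups); species without the intron score 0.
    """
    species = list(species)
    keys: list[IntronPositionKey] = []
    rows: list[list[int]] = []
    length_rows: list[tuple] = []
    for proj in projections:
        for key in sorted(proj.presence):
            vec = proj.presence[key]
            keys.append(key)
            rows.append([vec.get(sp, 0) for sp in species])
            for sp in species:
                if sp in vec:
                    length_rows.append(
                        (
                            key.group_id,
                            key.boundary_after_column,
                            key.phase,
                            sp,
                            proj.lengths[(key, sp)],
                        )
                    )
    index = pd.MultiIndex.from_tuples(
        [(k.group_id, k.boundary_after_column, k.phase) for k in keys],
        names=KEY_COLUMNS,
    ) if keys else pd.MultiIndex.from_arrays([[], [], []], names=KEY_COLUMNS)
    presence = pd.DataFrame(
        np.asarray(rows, dtype=np.int8).reshape(len(keys), len(species)),
        index=index,
        columns=species,
    ).sort_index()
    lengths = pd.DataFrame(
        length_rows, columns=KEY_COLUMNS + ["species", "genomic_length"]
    )
    return PresenceMatrix(presence=presence, lengths=lengths)
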