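"""Ortholog protein alignments and the well-aligned column mask.

The package consumes precomputed multiple alignments of universal
single-copy orthologs; it does not align.  Intron positions are only
compared within "well-aligned" regions: columns that are sufficiently
ungapped and sit in a locally conserved window.  The criterion is an
explicit, configurable policy of this package (gap fraction + windowed
mean pairwise identity) and is echoed into every report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from Bio import SeqIO

__all__ = [
    "AlignedGroup",
    "AlignmentError",
    "MaskParams",
    "WellAlignedMask",
    "read_alignment",
    "well_aligned_mask",
    "residue_column",
]

GAP = "-"


class AlignmentError(ValueError):
    """Alignment fails a structural or consistency check."""


@dataclass(frozen=True)
class MaskParams:
    """Well-aligned criterion.

    min_ungapped_fraction: minimum fraction of rows without a gap at the
        column.
    window: length (columns) of the identity window centred on the column,
        clipped at the alignment ends.
    min_mean_identity: minimum mean pairwise identity within the window;
        a pair contributes matches / comparable-columns over columns where
        both rows are ungapped, and pairs with no comparable column are
        ignored (a window with no comparable pair scores 0).
    """

    min_ungapped_fraction: float = 0.75
    window: int = 10
    min_mean_identity: float = 0.5

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0.0 <= self.min_ungapped_fraction <= 1.0:
            raise ValueError("min_ungapped_fraction must be in [0, 1]")
        if not 0.0 <= self.min_mean_identity <= 1.0:
            raise ValueError("min_mean_identity must be in [0, 1]")


class AlignedGroup:
    """One ortholog group's protein alignment: species -> aligned row."""

    def __init__(self, group_id: str, rows: Mapping[str, str]):
        if not rows:
            raise AlignmentError(f"group {group_id}: empty alignment")
        lengths = {len(s) for s in rows.values()}
        if len(lengths) > 1:
            raise AlignmentError(
                f"group {group_id}: ragged row lengths {sorted(lengths)}"
            )
        self.group_id = group_id
        self.rows: dict[str, str] = dict(rows)
        self.n_columns = lengths.pop()
        self._res2col: dict[str, np.ndarray] = {}

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def degapped(self, species: str) -> str:
        return self.rows[species].replace(GAP, "")

    def _column_map(self, species: str) -> np.ndarray:
        m = self._res2col.get(species)
        if m is None:
            arr = np.frombuffer(self.rows[species].encode("ascii"), dtype=np.uint8)
            m = np.flatnonzero(arr != ord(GAP))
            self._res2col[species] = m
        return m


def read_alignment(
    path_or_handle,
    group_id: str,
    gene_to_species: Mapping[str, str],
    proteins: Mapping[str, str] | None = None,
) -> AlignedGroup:
    """Read an aligned FASTA for one ortholog group.

    FASTA record ids are gene ids; ``gene_to_species`` (one row of the
    ortholog table) resolves them to species.  When ``proteins`` maps
    species to expected protein sequences, each degapped row is checked
    against it.
    """
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        sp = gene_to_species.get(rec.id)
        if sp is None:
            raise AlignmentError(
                f"group {group_id}: sequence {rec.id} not in ortholog table"
            )
        if sp in rows:
            raise AlignmentError(f"group {group_id}: duplicate species {sp}")
        rows[sp] = str(rec.seq)
    group = AlignedGroup(group_id, rows)
    if proteins is not None:
        for sp, expected in proteins.items():
            if sp in group.rows and group.degapped(sp) != expected:
                raise AlignmentError(
                    f"group {group_id}, species {sp}: degapped alignment row "
                    f"does not match the gene model protein"
                )
    return group


@dataclass(frozen=True)
class WellAlignedMask:
    group_id: str
    mask: np.ndarray  # bool, one per column
    params: MaskParams

    def __len__(self) -> int:
        return len(self.mask)


def _encoded(group: AlignedGroup) -> np.ndarray:
    """(n_rows, n_columns) uint8 matrix of the alignment."""
    return np.vstack(
        [np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in group.rows.values()]
    )


def well_aligned_mask(group: AlignedGroup, params: MaskParams | None = None) -> WellAlignedMask:
    """Compute the boolean well-aligned mask for an alignment.

    Column k is kept iff its ungapped-row fraction meets the gap
    threshold and the mean pairwise identity in the window centred on k
    meets the identity threshold.  Deterministic in the alignment and
    parameters; invariant under row reordering.
    """
    params = params or MaskParams()
    mat = _encoded(group)
    n_rows, n_cols = mat.shape
    ungapped = mat != ord(GAP)

    frac_ok = ungapped.sum(axis=0) / n_rows >= params.min_ungapped_fraction

    if n_rows < 2:
        # no pair to compare: identity criterion scores 0 per policy
        ident_ok = np.zeros(n_cols, dtype=bool) if params.min_mean_identity > 0 else np.ones(n_cols, dtype=bool)
        return WellAlignedMask(group.group_id, frac_ok & ident_ok, params)

    ii, jj = np.triu_indices(n_rows, k=1)
    comparable = ungapped[ii] & ungapped[jj]          # (n_pairs, n_cols)
    matches = comparable & (mat[ii] == mat[jj])

    # windowed sums via cumulative sums, window clipped at the ends
    w = params.window
    lo = np.maximum(0, np.arange(n_cols) - (w - 1) // 2)
    hi = np.minimum(n_cols, np.arange(n_cols) + w // 2 + 1)
    cmp_c = np.concatenate(
        [np.zeros((len(ii), 1), dtype=np.int64), np.cumsum(comparable, axis=1)], axis=1
    )
    mat_c = np.concatenate(
        [np.zeros((len(ii), 1), dtype=np.int64), np.cumsum(matches, axis=1)], axis=1
    )
    win_cmp = cmp_c[:, hi] - cmp_c[:, lo]             # (n_pairs, n_cols)
    win_match = mat_c[:, hi] - mat_c[:, lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        pair_ident = np.where(win_cmp > 0, win_match / np.maximum(win_cmp, 1), np.nan)
    any_pair = np.any(win_cmp > 0, axis=0)
    mean_ident = np.zeros(n_cols)
    mean_ident[any_pair] = np.nanmean(pair_ident[:, any_pair], axis=0)
    ident_ok = mean_ident >= params.min_mean_identity

    return WellAlignedMask(group.group_id, frac_ok & ident_ok, params)


def residue_column(group: AlignedGroup, species: str, residue_index: int) -> int:
    """Alignment column holding the given 0-based residue of a species."""
    m = group._column_map(species)
    if not 0 <= residue_index < len(m):
        raise IndexError(
            f"residue {residue_index} out of range for {species} "
            f"(degapped length {len(m)}) in group {group.group_id}"
        )
    return int(m[residue_index])


def mask_intervals(mask: WellAlignedMask) -> list[tuple[int, int]]:
    """Mask-true runs as 0-based half-open column intervals (BED-like)."""
    out = []
    m = mask.mask
    start = None
    for k, v in enumerate(m):
        if v and start is None:
            start = k
        elif not v and start is not None:
            out.append((start, k))
            start = None
    if start is not None:
        out.append((start, len(m)))
    return out
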