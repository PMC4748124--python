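"""Clade-sharing classification of intron positions and length summaries.

Relative to a focal species, every intron position present in the focal
falls in exactly one class:

  UNIQUE          no other species carries it
  EXCLUSIVE:<X>   shared only with clade X (one non-focal clade)
  WIDESPREAD      shared with two or more non-focal clades

The focal's own clade minus the focal counts as "another clade" when
non-empty.  Ancient introns are positions present in the focal, a
designated comparator, at least one outgroup species and at least one
ingroup (insect) species — positions predating the clade radiation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import KEY_COLUMNS, PresenceMatrix

__all__ = [
    "CladePartition",
    "SharingClass",
    "classify_site",
    "sharing_proportions",
    "ancient_sites",
    "length_summary",
]

UNIQUE = "UNIQUE"
WIDESPREAD = "WIDESPREAD"


def exclusive(clade: str) -> str:
    return f"EXCLUSIVE:{clade}"


SharingClass = str  # UNIQUE | EXCLUSIVE:<clade> | WIDESPREAD


@dataclass(frozen=True)
class CladePartition:
    """Named, disjoint species sets covering all configured species."""

    clades: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, members in self.clades.items():
            if not members:
                raise ValueError(f"clade {name} is empty")
            dup = seen & set(members)
            if dup:
                raise ValueError(f"species {sorted(dup)} in more than one clade")
            seen |= set(members)

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[str]]) -> "CladePartition":
        return cls({name: frozenset(v) for name, v in d.items()})

    @property
    def species(self) -> frozenset[str]:
        return frozenset().union(*self.clades.values())

    def clade_of(self, species: str) -> str:
        for name, members in self.clades.items():
            if species in members:
                return name
        raise KeyError(f"species {species} not in partition")


def classify_site(
    presence: Mapping[str, int], partition: CladePartition, focal: str
) -> SharingClass:
    """Classify one presence vector relative to the focal species.

    The classes are exhaustive and mutually exclusive for any vector in
    which the focal is present.
    """
    if not presence.get(focal, 0):
        raise ValueError(f"focal species {focal} absent from presence vector")
    unknown = set(presence) - set(partition.species)
    if unknown:
        raise KeyError(f"species {sorted(unknown)} not in partition")
    focal_clade = partition.clade_of(focal)
    sharing: set[str] = set()
    for name, members in partition.clades.items():
        others = members - {focal} if name == focal_clade else members
        if any(presence.get(sp, 0) for sp in others):
            sharing.add(name)
    if not sharing:
        return UNIQUE
    if len(sharing) == 1:
        return exclusive(sharing.pop())
    return WIDESPREAD


def _class_labels(
    matrix: PresenceMatrix, partition: CladePartition, focal: str
) -> pd.Series:
    """Vectorised classification of all focal-present rows."""
    pres = matrix.presence
    if focal not in pres.columns:
        raise KeyError(f"focal species {focal} not scored in matrix")
    sub = pres[pres[focal] == 1]
    focal_clade = partition.clade_of(focal)
    n_sharing = np.zeros(len(sub), dtype=np.int32)
    only: np.ndarray = np.full(len(sub), "", dtype=object)
    for name, members in partition.clades.items():
        others = sorted((members - {focal}) if name == focal_clade else members)
        cols = [sp for sp in others if sp in sub.columns]
        if not cols:
            continue
        hit = sub[cols].to_numpy().any(axis=1)
        first = n_sharing == 0
        only[first & hit] = name
        n_sharing += hit
    labels = np.where(
        n_sharing == 0,
        UNIQUE,
        np.where(n_sharing == 1, [exclusive(c) if c else "" for c in only], WIDESPREAD),
    )
    return pd.Series(labels, index=sub.index, name="sharing_class")


def sharing_proportions(
    matrix: PresenceMatrix, partition: CladePartition, focal: str
) -> pd.DataFrame:
    """Count and fraction of each sharing class among focal-present sites.

    The denominator is the number of homologized positions present in
    the focal species (within the analyzed groups).  Fractions sum to 1.
    """
    labels = _class_labels(matrix, partition, focal)
    if labels.empty:
        raise ValueError(f"no sites present in focal species {focal}")
    order = [UNIQUE] + [
        exclusive(c)
        for c in partition.clades
        if c != partition.clade_of(focal) or len(partition.clades[c]) > 1
    ] + [WIDESPREAD]
    counts = labels.value_counts().reindex(order, fill_value=0)
    out = pd.DataFrame(
        {"count": counts, "fraction": counts / counts.sum()}
    )
    out.index.name = "sharing_class"
    return out


def ancient_sites(
    matrix: PresenceMatrix,
    partition: CladePartition,
    focal: str,
    comparator: str,
    outgroup_clade: str = "outgroups",
    ingroup_clade: str = "insects",
) -> pd.Index:
    """Keys of ancient intron positions.

    Present in focal AND comparator AND >=1 species of the outgroup
    clade AND >=1 species of the ingroup clade.
    """
    for clade in (outgroup_clade, ingroup_clade):
        if clade not in partition.clades:
            raise KeyError(f"clade {clade} not in partition")
    if comparator not in partition.species:
        raise KeyError(f"comparator {comparator} not in partition")
    pres = matrix.presence
    sel = (pres[focal] == 1) & (pres[comparator] == 1)
    for clade in (outgroup_clade, ingroup_clade):
        cols = [sp for sp in sorted(partition.clades[clade]) if sp in pres.columns]
        sel &= pres[cols].to_numpy().any(axis=1)
    return pres.index[sel]


def length_summary(
    matrix: PresenceMatrix, keys: pd.Index, species: Sequence[str], focal: str
) -> pd.DataFrame:
    """Per-species intron length distribution over a key subset.

    Quartiles use linear interpolation (the type-7 convention, stated in
    output metadata).  ``median_ratio_vs_focal`` is focal median divided
    by the species median; a species with no lengths in the subset gets
    n=0 and null statistics rather than NaN arithmetic downstream.
    """
    lengths = matrix.lengths.set_index(KEY_COLUMNS)
    key_set = set(keys)
    sub = lengths[lengths.index.isin(key_set)]
    rows = []
    by_species = {
        sp: g["genomic_length"].to_numpy() for sp, g in sub.groupby("species")
    }
    focal_median = (
        float(np.median(by_species[focal])) if focal in by_species and len(by_species[focal]) else None
    )
    for sp in species:
        vals = by_species.get(sp, np.array([]))
        if len(vals) == 0:
            rows.append((sp, 0, None, None, None, None, None))
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
        ratio = focal_median / med if focal_median else None
        rows.append((sp, len(vals), q1, med, q3, float(np.log10(med)), ratio))
    # object dtype keeps the explicit None marker for empty subsets
    out = pd.DataFrame(
        rows,
        columns=["species", "n", "q1", "median", "q3", "log10_median", "focal_median_ratio"],
        dtype=object,
    ).set_index("species")
    out["n"] = out["n"].astype(int)
    out.attrs["quartile_convention"] = "linear interpolation (type 7)"
    return out
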