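"""Coding gene models and intron sites.

A gene model is the ordered set of CDS segments of one representative
transcript.  Introns are derived objects: one per junction between
consecutive CDS segments, located in protein coordinates by the pair
(protein_index, phase) where, with ``c`` the number of coding nucleotides
upstream of the junction in transcription order,

    protein_index = c // 3        phase = c % 3

Phase follows the GFF3 convention (phase 0 = intron between codons).
Internal genomic coordinates are 0-based half-open; GFF3 I/O converts
to and from the 1-based inclusive convention.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gffutils

logger = logging.getLogger(__name__)

__all__ = [
    "CdsSegment",
    "GeneModel",
    "IntronSite",
    "GeneModelError",
    "ParseResult",
    "parse_gff3",
    "intron_sites_of",
]


class GeneModelError(ValueError):
    """A gene model violates a structural invariant (strict mode)."""


@dataclass(frozen=True, order=True)
class CdsSegment:
    """One CDS segment, 0-based half-open genomic coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad segment coordinates [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene: CDS segments in transcription order.

    Transcription order is ascending genomic start on '+' and descending
    on '-'.  ``coding_length`` must be divisible by 3 (enforced by the
    parser in strict mode).
    """

    gene_id: str
    species_id: str
    segments: tuple[CdsSegment, ...]

    @property
    def seq_id(self) -> str:
        return self.segments[0].seq_id

    @property
    def strand(self) -> str:
        return self.segments[0].strand

    @property
    def coding_length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def protein_length(self) -> int:
        return self.coding_length // 3

    def problems(self) -> list[str]:
        """Invariant violations, empty when the model is valid."""
        out: list[str] = []
        if not self.segments:
            return ["no CDS segments"]
        if len({s.seq_id for s in self.segments}) > 1:
            out.append("segments on multiple sequences")
        if len({s.strand for s in self.segments}) > 1:
            out.append("mixed strands")
            return out
        if self.coding_length % 3 != 0:
            out.append(f"coding length {self.coding_length} not divisible by 3")
        order = self.segments if self.strand == "+" else self.segments[::-1]
        for a, b in zip(order, order[1:]):
            if a.end > b.start:
                out.append(f"overlapping/misordered segments at {a.end}>{b.start}")
                break
        return out


@dataclass(frozen=True)
class IntronSite:
    """An intron interrupting coding sequence.

    ``protein_index``/``phase`` locate the intron in protein coordinates
    (see module docstring); ``genomic_span`` is the excised genomic
    interval, 0-based half-open on the given strand.
    """

    gene_id: str
    species_id: str
    protein_index: int
    phase: int
    genomic_length: int
    genomic_span: tuple[str, int, int, str]

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase {self.phase} not in {{0,1,2}}")
        if self.genomic_length <= 0:
            raise ValueError("non-positive intron length")


def intron_sites_of(model: GeneModel) -> list[IntronSite]:
    """Derive the ordered intron sites of a valid gene model.

    One site per junction between consecutive CDS segments in
    transcription order; a single-segment model yields no sites.
    """
    sites: list[IntronSite] = []
    c = 0
    for up, down in zip(model.segments, model.segments[1:]):
        c += up.length
        if model.strand == "+":
            gap = (up.end, down.start)
        else:
            gap = (down.end, up.start)
        sites.append(
            IntronSite(
                gene_id=model.gene_id,
                species_id=model.species_id,
                protein_index=c // 3,
                phase=c % 3,
                genomic_length=gap[1] - gap[0],
                genomic_span=(model.seq_id, gap[0], gap[1], model.strand),
            )
        )
    return sites


@dataclass
class ParseResult:
    """Models plus a skip log (lenient mode) from one annotation file."""

    models: list[GeneModel]
    skipped: Counter = field(default_factory=Counter)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.models)

    def __len__(self) -> int:
        return len(self.models)


_TRANSCRIPT_TYPES = ("mRNA", "transcript")


def _segments_from_cds(cds_features, gene_id: str) -> tuple[CdsSegment, ...]:
    segs = [
        CdsSegment(f.seqid, f.start - 1, f.end, f.strand) for f in cds_features
    ]
    if not segs:
        return ()
    segs.sort(key=lambda s: s.start)
    if segs[0].strand == "-":
        segs.reverse()
    return tuple(segs)


def parse_gff3(path, species_id: str, strict: bool = True) -> ParseResult:
    """Parse a GFF3 annotation into one :class:`GeneModel` per gene.

    Multi-transcript genes are reduced to the mRNA with the longest
    total CDS (ties broken lexicographically by transcript ID).  In
    strict mode a structurally invalid gene raises
    :class:`GeneModelError` naming the gene; in lenient mode it is
    skipped and tallied in ``ParseResult.skipped``.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=False,
        merge_strategy="create_unique",
    )
    result = ParseResult(models=[])
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, level=1, featuretype=_TRANSCRIPT_TYPES))
        if transcripts:
            # longest-CDS representative, lexicographic tie-break
            scored = []
            for t in transcripts:
                cds = list(db.children(t, featuretype="CDS"))
                scored.append((sum(f.end - f.start + 1 for f in cds), t.id, cds))
            scored.sort(key=lambda x: (-x[0], x[1]))
            cds_features = scored[0][2]
        else:
            cds_features = list(db.children(gene, featuretype="CDS"))
        segments = _segments_from_cds(cds_features, gene.id)
        model = GeneModel(gene_id=gene.id, species_id=species_id, segments=segments)
        problems = model.problems()
        if problems:
            if strict:
                raise GeneModelError(f"gene {gene.id}: {'; '.join(problems)}")
            result.skipped[problems[0]] += 1
            continue
        result.models.append(model)
    if result.skipped:
        logger.info(
            "%s: skipped %d genes (%s)",
            species_id,
            sum(result.skipped.values()),
            dict(result.skipped),
        )
    return result
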