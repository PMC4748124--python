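"""GFF3 emission for gene models.

Writes gene/mRNA/CDS features, converting the package's 0-based
half-open coordinates back to GFF3's 1-based inclusive convention.
The CDS ``phase`` column is the number of bases to skip to reach the
next full codon (GFF3 semantics), derived from cumulative coding
length in transcription order.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from .gene_models import GeneModel

__all__ = ["write_gff3"]


def write_gff3(models: Iterable[GeneModel], path, source: str = "intronarch") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for model in models:
            start = min(s.start for s in model.segments) + 1
            end = max(s.end for s in model.segments)
            seq_id, strand = model.seq_id, model.strand
            gid = model.gene_id
            fh.write(
                f"{seq_id}\t{source}\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}\n"
            )
            tid = f"{gid}.t1"
            fh.write(
                f"{seq_id}\t{source}\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={tid};Parent={gid}\n"
            )
            c = 0
            for k, seg in enumerate(model.segments):
                phase = (3 - c % 3) % 3
                fh.write(
                    f"{seq_id}\t{source}\tCDS\t{seg.start + 1}\t{seg.end}\t.\t"
                    f"{strand}\t{phase}\tID={tid}.cds{k};Parent={tid}\n"
                )
                c += seg.length
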