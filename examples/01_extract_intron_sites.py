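"""Parse a GFF3 gene model and derive its intron sites.

A two-exon gene on the minus strand: the intron interrupts the coding
sequence after 12 coding nucleotides, i.e. between codons at protein
residue 4 (phase 0), and spans 10 bp of genome.
"""

import tempfile
from pathlib import Path

from intronarch import intron_sites_of, parse_gff3

GFF = """##gff-version 3
scf1\tdemo\tgene\t101\t131\t.\t-\t.\tID=gene1
scf1\tdemo\tmRNA\t101\t131\t.\t-\t.\tID=gene1.t1;Parent=gene1
scf1\tdemo\tCDS\t120\t131\t.\t-\t0\tID=c1;Parent=gene1.t1
scf1\tdemo\tCDS\t101\t109\t.\t-\t0\tID=c2;Parent=gene1.t1
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "demo.gff3"
    path.write_text(GFF)
    (model,) = parse_gff3(path, species_id="demo_species").models

print(f"gene {model.gene_id}: {len(model.segments)} CDS segments, "
      f"{model.coding_length} coding nt -> {model.protein_length} residues")
for site in intron_sites_of(model):
    print(f"  intron after residue {site.protein_index}, phase {site.phase}, "
          f"{site.genomic_length} bp at {site.genomic_span}")
# protein_index/phase place the intron in protein coordinates so it can be
# compared across species through an ortholog alignment.
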