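"""Homologize intron positions across species and classify their sharing.

Three species share one ancient intron position; the tick carries a
second position shared only with the outgroup — the signature this
package quantifies.
"""

from intronarch import (
    AlignedGroup,
    CladePartition,
    IntronSite,
    MaskParams,
    build_presence_matrix,
    project_sites,
    sharing_proportions,
    well_aligned_mask,
)


def site(sp, idx, phase):
    return IntronSite(gene_id=f"{sp}_g", species_id=sp, protein_index=idx,
                      phase=phase, genomic_length=100,
                      genomic_span=("c", 0, 100, "+"))


group = AlignedGroup("og1", {
    "tick":    "MKLVSTAD",
    "insect1": "MKLVSTAD",
    "out1":    "MKLVSTAD",
})
mask = well_aligned_mask(group, MaskParams(0.5, 4, 0.5))
sites = {
    "tick":    [site("tick", 3, 0), site("tick", 6, 1)],
    "insect1": [site("insect1", 3, 0)],
    "out1":    [site("out1", 3, 0), site("out1", 6, 1)],
}
proj = project_sites(group, sites, mask)
matrix = build_presence_matrix([proj], ["tick", "insect1", "out1"])
print("presence matrix:")
print(matrix.presence)

partition = CladePartition.from_dict(
    {"chelicerata": ["tick"], "insects": ["insect1"], "outgroups": ["out1"]}
)
print("\nsharing classes for the tick:")
print(sharing_proportions(matrix, partition, "tick"))
# The (boundary 3, phase 0) position is WIDESPREAD (insect + outgroup);
# the (boundary 6, phase 1) position is EXCLUSIVE:outgroups — retained by
# tick and outgroup but lost from the insect lineage.
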