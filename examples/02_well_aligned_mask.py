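"""Compute the well-aligned column mask of a small protein alignment.

Columns are kept when they are mostly ungapped and sit in a locally
conserved window; intron positions are only compared inside these
regions.
"""

from intronarch import AlignedGroup, MaskParams, well_aligned_mask
from intronarch.alignment import mask_intervals

rows = {
    "tick":    "MKLVSTQRWHE-AD",
    "daphnia": "MKLVSTNEYAEKAD",
    "insect1": "MKLVSTHKFCD-AD",
}
group = AlignedGroup("og_demo", rows)
params = MaskParams(min_ungapped_fraction=0.75, window=6, min_mean_identity=0.5)
mask = well_aligned_mask(group, params)

print("alignment columns:", group.n_columns)
print("mask:", "".join("+" if m else "." for m in mask.mask))
print("well-aligned intervals (0-based half-open):", mask_intervals(mask))
# '+' columns pass both the gap and the windowed-identity filter; the
# divergent middle of the alignment is excluded from intron comparison.
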