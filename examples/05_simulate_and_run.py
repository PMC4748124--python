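"""Simulate a nine-species data set and run the full pipeline on it.

A scaled-down version of the package's reference study condition:
loss-only intron evolution with an 8x loss multiplier on the
pancrustacean clade (daphnia + insects), long introns in the tick and
the outgroups, short introns in pancrustaceans.
"""

import tempfile
from pathlib import Path

from intronarch import RunConfig, default_config, run_pipeline, simulate, write_truthset

cfg = default_config(seed=42, n_groups=60, L=120)
truth = simulate(cfg)

with tempfile.TemporaryDirectory() as tmp:
    bundle = Path(tmp) / "bundle"
    write_truthset(truth, bundle)
    result = run_pipeline(RunConfig.from_yaml(bundle / "run.yaml"))

    print(f"intron positions: {result.matrix.n_sites}")
    for who in (cfg.focal, cfg.comparator):
        frac = result.proportions[who].at["EXCLUSIVE:outgroups", "fraction"]
        print(f"{who}: EXCLUSIVE:outgroups = {100 * frac:.1f}%")
    print(f"RF(intron tree, reference) = {result.rf_to_reference}")
    s = result.ancient_summary
    print(f"ancient introns (focal n={s.at[cfg.focal, 'n']}): "
          f"median length tick {s.at[cfg.focal, 'median']:.0f} nt "
          f"vs daphnia {s.at[cfg.comparator, 'median']:.0f} nt")
# The tick shares an order of magnitude more intron positions exclusively
# with the outgroups than the crustacean does, the intron-only tree matches
# the reference topology, and ancient tick introns are ~10x longer.
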