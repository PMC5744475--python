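"""Dry-storage decay and the half-life/regulation association.

Decays an equal-abundance transcript pool for 12 h of dry storage with
renormalization (equal-RNA-loading emulation), calls apparent up/down
regulation, and shows that apparent up-regulation concentrates in the
stable half-life bins — the mechanism by which pure mRNA turnover can
masquerade as differential regulation in dry seeds.
"""

import numpy as np
import pandas as pd

import dryseed as ds

rng = np.random.default_rng(4)
ids = [f"At9g{i:05d}" for i in range(500)]
half_lives = pd.Series(rng.lognormal(np.log(4), 0.8, size=500), index=ids)

a0 = pd.Series(100.0, index=ids)
at = ds.simulate_dry_storage_decay(a0, half_lives, t=12.0, renormalize=True)
logfc = np.log2(at / a0)

pair = ds.GeneSetPair(up=set(logfc.index[logfc > 0]), down=set(logfc.index[logfc < 0]))
assoc = ds.stability_association(pair, half_lives)
print(f"apparent regulation after 12 h storage: {len(pair.up)} up, {len(pair.down)} down")
print("up-fraction per half-life bin (unstable -> stable):")
print(assoc.table[["n_up", "n_down", "up_fraction"]].round(3).to_string())
print("up_fraction rises monotonically with stability: turnover alone "
      "produces the up=stable / down=unstable pattern")

ordered = ds.order_by_half_life(list(pair.up)[:5], half_lives)
print(f"\nheatmap row order (most stable first): {ordered}")
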