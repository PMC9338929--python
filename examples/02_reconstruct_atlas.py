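"""Reconstruct a single-cell spatial atlas from spot data.

After deconvolution, each spot's proportions are converted to integer cell
counts, matching reference cells are selected by least-squares fit to the
spot profile, and every selected cell is placed inside the spot with the
sector/radius sampler (placements never exceed half the distance to the
chosen neighbor spot).
"""

import numpy as np
import spacomm as sp

scenario = sp.SyntheticScenario(seed=0, cells_per_type=60, n_genes=120)
st, coords, labels = sp.generate_spatial(scenario)
spots = sp.simulate_spots(st, coords, labels, bin_size=0.25)

ref, ref_labels = sp.generate_reference(scenario)
cfg = sp.RunConfig(rng_seed=0, M=10, min_genes=10, n_restarts=20)
atlas, composition = sp.reconstruct(
    spots.expression, sp.SpatialCoordinates(spots.coords.reset_index()),
    ref, ref_labels, cfg, mode="spot")

print(f"placed {len(atlas.placements)} cells over "
      f"{atlas.placements['source_spot'].nunique()} spots")
print(atlas.placements.head(4).round(3).to_string(index=False))

# each placement stays within its spot's neighborhood
d = np.hypot(
    atlas.placements["x"].to_numpy()
    - spots.coords.loc[atlas.placements["source_spot"], "x"].to_numpy(),
    atlas.placements["y"].to_numpy()
    - spots.coords.loc[atlas.placements["source_spot"], "y"].to_numpy())
print(f"max displacement from spot center: {d.max():.3f} "
      f"(bin size {spots.bin_size})")
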