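"""Compute molecular descriptors and render 2D feature maps.

Builds descriptor vectors for a handful of small molecules with RDKit,
fits a descriptor->lattice layout from their correlation structure, and
renders one grid image per molecule.  Correlated descriptors end up in
neighboring cells, which is the property the convolutional encoder
exploits.
"""

import numpy as np
import pandas as pd

from molmm import compute_descriptors, descriptor_registry, fit_layout, \
    render_batch
from molmm.synthetic import enumerate_smiles

smiles = enumerate_smiles(40)
registry = descriptor_registry()
table = pd.DataFrame([compute_descriptors(s, registry) for s in smiles],
                     index=smiles)
# drop descriptors that are constant over this reference set
table = table.loc[:, table.std() > 0]
print(f"{table.shape[1]} informative descriptors for {len(smiles)} molecules")

layout = fit_layout(table, seed=0, method="cmds", category_of=registry)
print(f"layout grid: {layout.grid_shape}, "
      f"{len(layout.descriptor_names)} cells occupied")

fmaps = render_batch(table, layout)
print(f"rendered feature maps: {fmaps.shape}")
ethanol = smiles.index("CCO")
print(f"ethanol map occupies {np.count_nonzero(fmaps[ethanol])} cells, "
      f"values clipped to [{fmaps.min():.1f}, {fmaps.max():.1f}]")
# each nonzero cell holds one robust-scaled descriptor value; cell
# positions are identical across molecules, so maps are comparable.
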