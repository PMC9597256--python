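"""Monodomain activation of the fibered LA from a Bachmann's-bundle stimulus.

The anisotropic conductivity tensor sigma = sigma_f f(x)f + sigma_s s(x)s +
sigma_n n(x)n carries the fiber architecture into the wave dynamics; the
local activation time (LAT) map shows the circumferential (Bachmann's
bundle) and septoatrial activation pathways, and the appendage activates
from its ostium toward its tip.
"""

import numpy as np

from atriafiber import (AnatomyConfig, EPParameters, assign_frames,
                        assign_regions, build_bc_tables, compute_cv,
                        compute_fields, conductivity_tensor,
                        default_threshold_table, find_bb_stimulus_site,
                        generate_idealized_la, simulate_monodomain)

mesh = generate_idealized_la(AnatomyConfig(refine_levels=3))
fields = compute_fields(mesh, build_bc_tables(mesh))
table = default_threshold_table()
labeling = assign_regions(fields, table)
frame = assign_frames(fields, labeling, table)

params = EPParameters(dt=0.05, t_end=250.0)
params.stim_nodes = find_bb_stimulus_site(mesh, fields, radius=2.5)
tensors = conductivity_tensor(frame, params)
result = simulate_monodomain(mesh, tensors, params=params)

lat = result.lat
cv = compute_cv(mesh, lat)
print(f"activated nodes: {np.isfinite(lat).mean():.1%}")
print(f"latest activation: {np.nanmax(lat):.1f} ms")
print(f"LAA tip LAT:     {lat[mesh.landmarks['laa_tip']]:.1f} ms")
print(f"median CV:       {np.nanmedian(cv):.2f} mm/ms")
# the tip activates after the ostium: ostium-to-tip route through the
# circumferential appendage fibers
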