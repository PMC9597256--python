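# Full-pipeline config for `atriafiber run --config examples/case.yaml --out results/`
#
# Stages: synthesize the tagged idealized LA, solve the seven harmonic
# fields, assign the 17 regions and two-layer fiber frames, then run the
# monodomain activation study from the Bachmann's-bundle site.

anatomy:
  n_left_pvs: 2          # 2 separate left PVs; 1 = common trunk
  n_right_pvs: 2         # 2..4 (accessories get pv_racc<N> tags)
  wall_thickness: 2.0    # mm
  refine_levels: 3       # icosphere subdivisions (4 = default production)
  n_layers: 3            # elements through the wall

fields:
  laa_interval: [0.0, 0.05]   # phi1 range defining the LAA node set
  fo_interval: [0.95, 1.0]    # phi1 range defining the FO node set
  phi4_laa: 0.5               # alternative reading: 1.0
  phi4_fo: 0.5                # alternative reading: 0.0

regions: default         # or a path to a threshold-table YAML

ep:
  enabled: true
  dt: 0.05               # ms
  t_end: 250.0           # ms
  stim:
    amplitude: 1000.0    # uA/cm^3
    duration_ms: 2.0
    radius: 2.5          # mm; site auto-selected at the Bachmann's bundle
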