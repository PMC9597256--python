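# Default 17-region threshold table for the synthetic idealized LA.
#
# Ordered: sequential subtraction makes earlier rows win ties.  Regions
# common to both layers come first, then the epicardial anterior split,
# the endocardial anterior split, the left lateral ridge, and the
# posterior wall; the final row is the unconstrained lateral-wall
# catch-all that closes the partition.
#
# Thresholds are anatomy-dependent tuning constants calibrated once for
# the default synthetic anatomy (the semi-automated workflow: solve the
# fields, then set thresholds).  Frame rules: branch f = projected
# gradient is the fiber direction (longitudinal/oblique); branch n =
# fiber runs along the field's level sets (circumferential).
#
# Field meanings: phi1 appendage->septum, phi2 left->right, phi3
# inferior->superior PVs, phi4 MV->PVs, phi6 anterior-wall sweep.

- label: A
  description: anterior floor (circumferential along the MV ring)
  layer: both
  constraints: [{field: 4, alpha: 0.8}, {field: 3, alpha: 0.5}]
  rule: {branch: n, gradient: 4}
- label: B
  description: posterior floor (circumferential along the MV ring)
  layer: both
  constraints: [{field: 4, alpha: 0.8}, {field: 3, beta: 0.5}]
  rule: {branch: n, gradient: 4}
- label: C
  description: appendage (circumferential around the ostium-tip axis)
  layer: both
  constraints: [{field: 1, beta: 0.47}]
  rule: {branch: n, gradient: 1}
- label: D
  description: fossa ovalis, endocardial layer (circumferential)
  layer: endo
  constraints: [{field: 1, alpha: 0.75}]
  rule: {branch: n, gradient: 1}
- label: E
  description: fossa ovalis, epicardial layer (longitudinal)
  layer: epi
  constraints: [{field: 1, alpha: 0.75}]
  rule: {branch: f, gradient: 1}
- label: F
  description: right inferior PV, epicardial layer (longitudinal)
  layer: epi
  constraints: [{field: 4, beta: 0.15}, {field: 2, alpha: 0.5}, {field: 3, beta: 0.45}]
  rule: {branch: f, gradient: 4}
- label: G
  description: right PVs (circumferential around the ostia)
  layer: both
  constraints: [{field: 4, beta: 0.15}, {field: 2, alpha: 0.5}]
  rule: {branch: n, gradient: 4}
- label: H
  description: left PVs (circumferential; trunk variant swaps to grad phi6)
  layer: both
  constraints: [{field: 4, beta: 0.15}, {field: 2, beta: 0.5}]
  rule: {branch: n, gradient: 3}
- label: I
  description: Bachmann's bundle, epicardial anterior band (circumferential)
  layer: epi
  constraints: [{field: 3, alpha: 0.5}, {field: 4, alpha: 0.45, beta: 0.8}]
  rule: {branch: n, gradient: 4}
- label: J
  description: left roof, epicardial layer (oblique)
  layer: epi
  constraints: [{field: 3, alpha: 0.65}, {field: 2, beta: 0.5}]
  rule: {branch: f, gradient: 6}
- label: L
  description: right roof, epicardial layer (longitudinal)
  layer: epi
  constraints: [{field: 3, alpha: 0.65}, {field: 2, alpha: 0.5}]
  rule: {branch: f, gradient: 3}
- label: P
  description: posterior septum, epicardial layer (longitudinal)
  layer: epi
  constraints: [{field: 3, beta: 0.45}, {field: 2, alpha: 0.72}]
  rule: {branch: f, gradient: 4}
- label: N
  description: anterior-lateral wall, endocardial layer (circumferential)
  layer: endo
  constraints: [{field: 3, alpha: 0.5}, {field: 2, beta: 0.35}]
  rule: {branch: n, gradient: 4}
- label: O
  description: anterior wall, endocardial layer (oblique septoatrial bundle)
  layer: endo
  constraints: [{field: 3, alpha: 0.5}]
  rule: {branch: f, gradient: 6}
- label: K
  description: left lateral ridge, both layers (circumferential strands)
  layer: both
  constraints: [{field: 2, beta: 0.2}]
  rule: {branch: n, gradient: 2}
- label: Q
  description: posterior wall (longitudinal septopulmonary bundle)
  layer: both
  constraints: [{field: 3, beta: 0.45}]
  rule: {branch: f, gradient: 4}
- label: R
  description: lateral wall (circumferential; terminal catch-all)
  layer: both
  constraints: []
  rule: {branch: n, gradient: 4}
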