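# Bundled 14-segment anthropometric table (adult female, de Leva-style
# adjusted Zatsiorsky fractions).  mass_fraction is segment mass over body
# mass; com_fraction locates the segment CoM along the proximal->distal axis
# spanned by the endpoint markers (0 = proximal point, 1 = distal point).
# Mass fractions are renormalized to sum to exactly 1 at load time.
# Endpoints listed with two markers are taken at the marker midpoint.
segments:
  trunk:
    mass_fraction: 0.4257
    com_fraction: 0.585
    proximal: [L_greater_trochanter, R_greater_trochanter]
    distal: [L_acromion, R_acromion]
    parent: null
  head:
    mass_fraction: 0.0668
    com_fraction: 0.55
    proximal: [L_acromion, R_acromion]
    distal: [head_vertex]
    parent: trunk
  L_upper_arm:
    mass_fraction: 0.0255
    com_fraction: 0.5754
    proximal: [L_acromion]
    distal: [L_elbow]
    parent: trunk
  R_upper_arm:
    mass_fraction: 0.0255
    com_fraction: 0.5754
    proximal: [R_acromion]
    distal: [R_elbow]
    parent: trunk
  L_forearm:
    mass_fraction: 0.0138
    com_fraction: 0.4559
    proximal: [L_elbow]
    distal: [L_wrist]
    parent: L_upper_arm
  R_forearm:
    mass_fraction: 0.0138
    com_fraction: 0.4559
    proximal: [R_elbow]
    distal: [R_wrist]
    parent: R_upper_arm
  L_hand:
    mass_fraction: 0.0056
    com_fraction: 0.7474
    proximal: [L_wrist]
    distal: [L_finger3]
    parent: L_forearm
  R_hand:
    mass_fraction: 0.0056
    com_fraction: 0.7474
    proximal: [R_wrist]
    distal: [R_finger3]
    parent: R_forearm
  L_thigh:
    mass_fraction: 0.1478
    com_fraction: 0.3612
    proximal: [L_greater_trochanter]
    distal: [L_knee]
    parent: trunk
  R_thigh:
    mass_fraction: 0.1478
    com_fraction: 0.3612
    proximal: [R_greater_trochanter]
    distal: [R_knee]
    parent: trunk
  L_shank:
    mass_fraction: 0.0481
    com_fraction: 0.4416
    proximal: [L_knee]
    distal: [L_malleolus]
    parent: L_thigh
  R_shank:
    mass_fraction: 0.0481
    com_fraction: 0.4416
    proximal: [R_knee]
    distal: [R_malleolus]
    parent: R_thigh
  L_foot:
    mass_fraction: 0.0129
    com_fraction: 0.4014
    proximal: [L_heel]
    distal: [L_toe]
    parent: L_shank
  R_foot:
    mass_fraction: 0.0129
    com_fraction: 0.4014
    proximal: [R_heel]
    distal: [R_toe]
    parent: R_shank
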