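# Protocol presets: acquisition geometry the analyzer expects per protocol.
# acr_standard follows the ACR accreditation axial protocol (11 analysis
# slices, 5 mm thickness, 5 mm gap, 25 cm FOV, 256 x 256).  sim_head and
# sim_body mirror the radiotherapy-simulation commissioning protocols
# (2.5 mm x 42 contiguous head slices; 5 mm x 21 contiguous body slices at
# 42 cm FOV).
acr_standard:
  slices: 11
  thickness_mm: 5.0
  gap_mm: 5.0
  fov_mm: 250.0
  matrix: [256, 256]
  roles: [S1, S2, S3, S4, S5, S6, S7, S8, S9, S10, S11]
sim_head:
  slices: 42
  thickness_mm: 2.5
  gap_mm: 0.0
  fov_mm: 250.0
  matrix: [320, 256]
  roles: [S1, S2, S3, S4, S5, S6, S7, S8, S9, S10, S11]
sim_body:
  slices: 21
  thickness_mm: 5.0
  gap_mm: 0.0
  fov_mm: 420.0
  matrix: [352, 352]
  roles: [S1, S2, S3, S4, S5, S6, S7, S8, S9, S10, S11]
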