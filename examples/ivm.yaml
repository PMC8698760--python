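# Fully-resolved bench configuration (every value shown equals the package
# default, so `btace-flow solve --config examples/ivm.yaml --out results/`
# reproduces the stock circuit).  Geometry is in millimetres.
fluid: water          # or blood_mimic, or {density: 1050, viscosity: 0.0035}

artery:
  tree:               # main bifurcating tree, per generation
    pha:        {length_mm: 30, diameter_mm: 4.0}
    lobar:      {length_mm: 30, diameter_mm: 3.0}
    sectional:  {length_mm: 25, diameter_mm: 2.2}
    segmental:  {length_mm: 25, diameter_mm: 1.6}
  collaterals:        # set a level to null to remove it
    ca:         {length_mm: 15, diameter_mm: 2.0}   # communicating arcade (RHA-LHA)
    sectional:  {length_mm: 12, diameter_mm: 1.5}   # same-generation, hilar-plexus-like
    segmental:  {length_mm: 10, diameter_mm: 1.2}   # S7-S6 (and mirrored S2-S3)
    attach_fractions: [0.3333333333333333, 0.6666666666666666]

ivm:
  outlet_tube_lr: {length_mm: 40, diameter_mm: 1.2}  # outlet -> lower reservoir
  outlet_tube_ur: {length_mm: 40, diameter_mm: 1.2}  # outlet -> upper reservoir
  inflow_tube:    {length_mm: 300, diameter_mm: 4.0} # pump -> artery inlet
  z_lr_mm: 80        # lower (tumour) reservoir free surface
  z_ur_mm: 110       # upper (normal-tissue) reservoir free surface
  h_pump_mm: 200     # pump head

scenario:
  tumors: [S7]       # Case 1; use [S5, S7] for Case 2

occlusion:
  site: c            # microballoon at catheter location 1 ('b' = location 2)
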