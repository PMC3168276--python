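# Default model parameters: 4 mm spherical tumor in host tissue, with the
# vascular-normalized tumor column for antiangiogenic-therapy scenarios.
# Units: mm, s, mmHg, ug/mm^3.
geometry:
  R: 4.0
  r_max: 5.0
  n_grid: 2001

tissues:
  host:
    K: 2.5e-5        # hydraulic conductivity, mm^2/s/mmHg
    Lp: 3.6e-7       # vascular hydraulic permeability, mm/s/mmHg
    SV: 17.4         # vessel surface per tissue volume, /mm
    pv: 20.0         # vascular pressure, mmHg
    sigma: 0.91      # osmotic reflection coefficient
    pi_v: 20.0       # plasma osmotic pressure, mmHg
    pi_i: 10.0       # interstitial osmotic pressure, mmHg
  tumor:
    K: 2.5e-5
    Lp: 1.86e-5
    SV: 16.5
    pv: 20.0
    sigma: 8.7e-5
    pi_v: 19.8
    pi_i: 17.3
  normalized:
    K: 2.5e-5
    Lp: 3.7e-6
    SV: 15.2
    pv: 20.0
    sigma: 2.1e-3
    pi_v: 19.2
    pi_i: 15.1

factors:
  pro:               # proangiogenic family (VEGF-like)
    host:
      D: 4.0e-5      # diffusion, mm^2/s
      k: 2.0e-4      # deactivation, /s
      g: 2.0e-4      # production, ug/mm^3/s
    tumor:
      D: 5.5e-5
      k: 1.99e-4
      g: 12.0e-4
    normalized:
      D: 5.5e-5
      k: 1.99e-4
      g: 12.0e-4
  anti:              # antiangiogenic family (endostatin-like)
    host:
      D: 3.25e-5
      k: 1.5e-4
      g: 1.5e-4
    tumor:
      D: 4.0e-5
      k: 1.1e-4
      g: 7.0e-4
    normalized:
      D: 4.0e-5
      k: 1.1e-4
      g: 7.0e-4
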