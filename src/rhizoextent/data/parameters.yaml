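# Default parameter set for the maize rhizosphere transport model.
# Every physical quantity carries an explicit unit string which is validated
# at load time; loaders convert everything to the internal cm / s / mol system.

measured:                       # substrate- and experiment-specific values
  loam:
    a_primary:  {value: 0.05,      unit: cm}        # primary root radius
    a_tip:      {value: 0.0095,    unit: cm}        # lateral root tip radius
    theta:      {value: 0.22,      unit: cm3 cm-3}  # volumetric water content
    RL_tot:     {value: 10917,     unit: cm}        # total root length, day 21
    RWU21:      {value: 73.3,      unit: cm3 d-1}   # root water uptake day 20->21
    Jw_daily:   {value: 5.38e-7,   unit: cm s-1}    # daily-mean water flux to root
    c_tot_ini:
      Ca: {value: 1.27e-4, unit: mol cm-3}
      S:  {value: 1.37e-5, unit: mol cm-3}
      P:  {value: 2.99e-6, unit: mol cm-3}
    l_rh:       {value: 230,       unit: um}        # mean root hair length
    N_hairs:    {value: 165,       unit: cm-1}      # hairs per unit root length
  sand:
    a_primary:  {value: 0.05,      unit: cm}
    a_tip:      {value: 0.0445,    unit: cm}
    theta:      {value: 0.18,      unit: cm3 cm-3}
    RL_tot:     {value: 3388,      unit: cm}
    RWU21:      {value: 68.6,      unit: cm3 d-1}
    Jw_daily:   {value: 1.04e-6,   unit: cm s-1}
    c_tot_ini:
      Ca: {value: 7.47e-6, unit: mol cm-3}
      S:  {value: 5.65e-6, unit: mol cm-3}
      P:  {value: 4.07e-6, unit: mol cm-3}
    l_rh:       {value: 244,       unit: um}
    N_hairs:    {value: 164,       unit: cm-1}

literature:                     # nutrient constants and reaction parameters
  D:                            # liquid diffusion coefficients
    Ca: {value: 7.92e-6, unit: cm2 s-1}
    S:  {value: 6.00e-6, unit: cm2 s-1}
    P:  {value: 6.90e-6, unit: cm2 s-1}
  b:                            # soil buffer powers (solid:solution partition)
    loam: {Ca: 2,   S: 2,    P: 239}
    sand: {Ca: 0.3, S: 0.35, P: 41.3}
  Fm:                           # maximum root uptake rates
    Ca: {value: 1.00e-12, unit: mol cm-2 s-1}
    S:  {value: 3.00e-13, unit: mol cm-2 s-1}
    P:  {value: 3.26e-12, unit: mol cm-2 s-1}
  Km:                           # half-saturation concentrations
    Ca: {value: 4.00e-6, unit: mol cm-3}
    S:  {value: 1.00e-8, unit: mol cm-3}
    P:  {value: 5.80e-9, unit: mol cm-3}
  k_reaction:   {value: 2,       unit: l mol-1 min-1}  # gypsum precipitation rate
  Ksp_CaSO4:    {value: 2.4e-5,  unit: mol2 l-2}       # gypsum solubility product
  rh_lifetime:  {value: 2,       unit: d}              # functional hair lifetime
  a_h:          {value: 0.0004,  unit: cm}             # root hair radius
  L_char:       {value: 1,       unit: cm}             # characteristic root length

model:
  f_impedance:  {value: 0.3,  unit: "-"}   # diffusion impedance factor
  R_out:        {value: 6.0,  unit: cm}    # outer radius of the radial domain
  extent_threshold: {value: 0.8, unit: umol cm-3}  # rhizosphere deviation threshold

column:                          # growth column geometry (half-mean distance)
  inner_diameter: {value: 7,  unit: cm}
  fill_height:    {value: 23, unit: cm}
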