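# Default configuration of the stratified subtropical column run.
#
# Provenance of each value:
#   [culture]    derived from published culture measurements (main-text values)
#   [theory]     fixed by the redox/allometric theory in this package
#   [printed]    printed model constant (g_max = K_g = 1, zeta = 0.5, y_D = 0.14)
#   [calibrated] not printed in the main text; field-plausible default
#                calibrated to the stratified subtropical regime
name: subtropical_stratified
experiment: both_differences   # both_differences | yield_only | affinity_only | no_difference
grid:
  h: 2000.0                    # m, domain height
  dz: 5.0                      # m, cell height
physics:
  k_max: 0.002                 # m2/s, surface diffusivity      [calibrated]
  k_min: 1.0e-05               # m2/s, background diffusivity   [calibrated]
  z_mld: 20.0                  # m, mixed-layer decay scale     [calibrated]
  k_w: 0.04                    # 1/m, attenuation by water      [calibrated]
  k_chl: 0.02                  # m2/mgChl, attenuation by Chl   [calibrated]
  i_max: 1400.0                # umol photons/m2/s              [calibrated]
  diel: false
  w_s: 10.0                    # m/d, detritus sinking          [calibrated]
ecosystem:
  f: 0.03                      # electron fraction to synthesis [culture]
  biomass_c: 5                 # C5H7O2N, d = 20                [theory]
  biomass_h: 7
  biomass_o: 2
  biomass_n: 1
  aoo_vmax: 50.82              # mol NH4+/mol N/d               [culture]
  aoo_k_um: 0.133              # uM                             [culture]
  noo_volume_factor: 10.0      # relative NOO cell volume       [culture]
  phyto_diameter_um: 0.6       # Prochlorococcus-like           [culture]
  phyto_phi: 0.06              # mol C/mol photons              [calibrated]
  phyto_a_chl: 0.02            # m2/mgChl                       [calibrated]
  phyto_theta_max: 0.05        # gChl/gC                        [calibrated]
  phyto_cn_ratio: 6.6          # mol C/mol N
  het_vmax_d: 1.0              # 1/d                            [calibrated]
  het_k_d_um: 0.02             # uM                             [calibrated]
  het_y_d: 0.14                # mol biomass/mol D              [printed]
  g_max: 1.0                   # 1/d                            [printed]
  k_g_um: 1.0                  # uM                             [printed]
  zeta: 0.5                    # grazer N growth efficiency     [printed]
  m_z_per_um_day: 1.0          # 1/(uM d)                       [calibrated]
  m_b: 0.01                    # 1/d                            [calibrated]
  tau: 0.8                     #                                [calibrated]
  a_e: -4000.0                 # K                              [calibrated]
  t0: 293.15                   # K                              [calibrated]
  nitrifier_temperature_exempt: true
integration:
  dt: null                     # days; null = automatic stability bound
  tolerance: 0.001             # 1/d
  max_time: 20000.0            # days
  check_interval: 20.0         # days
  window: 3
  clip: true
  average_window: 1000.0       # days
initial:
  no3_deep_um: 20.0
  nitracline_top_m: 150.0
  nitracline_m: 400.0
  biomass_um: 0.001
  no2_deep_um: 0.06
  nh4_deep_um: 0.004
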