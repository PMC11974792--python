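optics:
  center_nm: 1030.0
  fwhm_nm: 180.0
  support_nm:
  - 900.0
  - 1160.0
  rep_rate_mhz: 20.0
  grid:
    lambda_min_nm: 850.0
    lambda_max_nm: 1250.0
    n_points: 2048
  tod_a3_fs3: 15000.0
photocycle:
  action_spectra:
    R:
      peak_nm: 480.0
      fwhm_nm: 70.0
    E:
      peak_nm: 460.0
      fwhm_nm: 70.0
    M:
      peak_nm: 560.0
      fwhm_nm: 70.0
  eta_RM: 2.3981531389432105
  eta_EM: 2.3981531389432105
  eta_ME: 2.3981531389432105
  k_MR: 0.2431109786263738
  k_ER: 0.02
  p_ref_mw: 20.0
cells:
  hek:
    mode: sustained
    k_drive: 0.5545347967296246
    k_clear: 0.04033305041963732
    tau_adapt: 3.2
    tau_recover: 20.0
    gain_g: 1.0
    f0: 1000.0
  iprgc:
    mode: adapting
    k_drive: 0.5964495904763409
    k_clear: 1.0
    tau_adapt: 1.8437278029382174
    tau_recover: 20.0
    adapt_floor: 0.08
    gain_g: 1.0
    f0: 4000.0
  iprgc_gain_sigma_log: 0.4
imaging:
  background: 100.0
  frame_rate: 1.63
  photon_gain: 1.0
  read_noise_sigma: 10.0
  raster_duty: 0.02
  hek_calbryte_baseline: 1000.0
  iprgc_calbryte_baseline: 4000.0
  gfp_brightness: 800.0
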