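{
 "version": 1,
 "n_features": 161,
 "features": [
  "s1_x_grav_mean",
  "s1_x_grav_median",
  "s1_x_grav_sd",
  "s1_x_grav_cv",
  "s1_x_grav_p25",
  "s1_x_grav_p75",
  "s1_x_grav_min",
  "s1_x_grav_max",
  "s1_x_mov_skew",
  "s1_x_mov_kurtosis",
  "s1_x_mov_energy",
  "s1_x_mov_specmag_mean",
  "s1_x_mov_specmag_sd",
  "s1_x_mov_dom_freq",
  "s1_x_mov_dom_mag",
  "s1_x_mov_spec_centroid",
  "s1_y_grav_mean",
  "s1_y_grav_median",
  "s1_y_grav_sd",
  "s1_y_grav_cv",
  "s1_y_grav_p25",
  "s1_y_grav_p75",
  "s1_y_grav_min",
  "s1_y_grav_max",
  "s1_y_mov_skew",
  "s1_y_mov_kurtosis",
  "s1_y_mov_energy",
  "s1_y_mov_specmag_mean",
  "s1_y_mov_specmag_sd",
  "s1_y_mov_dom_freq",
  "s1_y_mov_dom_mag",
  "s1_y_mov_spec_centroid",
  "s1_z_grav_mean",
  "s1_z_grav_median",
  "s1_z_grav_sd",
  "s1_z_grav_cv",
  "s1_z_grav_p25",
  "s1_z_grav_p75",
  "s1_z_grav_min",
  "s1_z_grav_max",
  "s1_z_mov_skew",
  "s1_z_mov_kurtosis",
  "s1_z_mov_energy",
  "s1_z_mov_specmag_mean",
  "s1_z_mov_specmag_sd",
  "s1_z_mov_dom_freq",
  "s1_z_mov_dom_mag",
  "s1_z_mov_spec_centroid",
  "s2_x_grav_mean",
  "s2_x_grav_median",
  "s2_x_grav_sd",
  "s2_x_grav_cv",
  "s2_x_grav_p25",
  "s2_x_grav_p75",
  "s2_x_grav_min",
  "s2_x_grav_max",
  "s2_x_mov_skew",
  "s2_x_mov_kurtosis",
  "s2_x_mov_energy",
  "s2_x_mov_specmag_mean",
  "s2_x_mov_specmag_sd",
  "s2_x_mov_dom_freq",
  "s2_x_mov_dom_mag",
  "s2_x_mov_spec_centroid",
  "s2_y_grav_mean",
  "s2_y_grav_median",
  "s2_y_grav_sd",
  "s2_y_grav_cv",
  "s2_y_grav_p25",
  "s2_y_grav_p75",
  "s2_y_grav_min",
  "s2_y_grav_max",
  "s2_y_mov_skew",
  "s2_y_mov_kurtosis",
  "s2_y_mov_energy",
  "s2_y_mov_specmag_mean",
  "s2_y_mov_specmag_sd",
  "s2_y_mov_dom_freq",
  "s2_y_mov_dom_mag",
  "s2_y_mov_spec_centroid",
  "s2_z_grav_mean",
  "s2_z_grav_median",
  "s2_z_grav_sd",
  "s2_z_grav_cv",
  "s2_z_grav_p25",
  "s2_z_grav_p75",
  "s2_z_grav_min",
  "s2_z_grav_max",
  "s2_z_mov_skew",
  "s2_z_mov_kurtosis",
  "s2_z_mov_energy",
  "s2_z_mov_specmag_mean",
  "s2_z_mov_specmag_sd",
  "s2_z_mov_dom_freq",
  "s2_z_mov_dom_mag",
  "s2_z_mov_spec_centroid",
  "s1_mag_grav_mean",
  "s1_mag_grav_median",
  "s1_mag_grav_sd",
  "s1_mag_grav_cv",
  "s1_mag_grav_p25",
  "s1_mag_grav_p75",
  "s1_mag_grav_min",
  "s1_mag_grav_max",
  "s1_mag_mov_skew",
  "s1_mag_mov_kurtosis",
  "s1_mag_mov_energy",
  "s1_mag_mov_specmag_mean",
  "s1_mag_mov_specmag_sd",
  "s1_mag_mov_dom_freq",
  "s1_mag_mov_dom_mag",
  "s1_mag_mov_spec_centroid",
  "s2_mag_grav_mean",
  "s2_mag_grav_median",
  "s2_mag_grav_sd",
  "s2_mag_grav_cv",
  "s2_mag_grav_p25",
  "s2_mag_grav_p75",
  "s2_mag_grav_min",
  "s2_mag_grav_max",
  "s2_mag_mov_skew",
  "s2_mag_mov_kurtosis",
  "s2_mag_mov_energy",
  "s2_mag_mov_specmag_mean",
  "s2_mag_mov_specmag_sd",
  "s2_mag_mov_dom_freq",
  "s2_mag_mov_dom_mag",
  "s2_mag_mov_spec_centroid",
  "corr_s1_x_s1_y",
  "corr_s1_x_s1_z",
  "corr_s1_x_s2_x",
  "corr_s1_x_s2_y",
  "corr_s1_x_s2_z",
  "corr_s1_x_s1_mag",
  "corr_s1_x_s2_mag",
  "corr_s1_y_s1_z",
  "corr_s1_y_s2_x",
  "corr_s1_y_s2_y",
  "corr_s1_y_s2_z",
  "corr_s1_y_s1_mag",
  "corr_s1_y_s2_mag",
  "corr_s1_z_s2_x",
  "corr_s1_z_s2_y",
  "corr_s1_z_s2_z",
  "corr_s1_z_s1_mag",
  "corr_s1_z_s2_mag",
  "corr_s2_x_s2_y",
  "corr_s2_x_s2_z",
  "corr_s2_x_s1_mag",
  "corr_s2_x_s2_mag",
  "corr_s2_y_s2_z",
  "corr_s2_y_s1_mag",
  "corr_s2_y_s2_mag",
  "corr_s2_z_s1_mag",
  "corr_s2_z_s2_mag",
  "corr_s1_mag_s2_mag",
  "grav_cross_mean_x",
  "grav_cross_mean_y",
  "grav_cross_mean_z",
  "s1_mag_mean",
  "s2_mag_mean"
 ]
}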