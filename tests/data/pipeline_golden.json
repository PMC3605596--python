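{
 "tirftrack_version": "0.1.0",
 "seed": 77,
 "config": {
  "field_width": 12.0,
  "field_height": 12.0,
  "pixel_size": 0.1,
  "frame_interval": 0.02,
  "n_frames": 60,
  "receptor_density": 0.4,
  "d_lat": 0.15,
  "psf_fwhm": 0.3,
  "photons_per_spot": 500.0,
  "background_mean": 20.0,
  "background_noise_sd": 3.0,
  "bleach_rate": 0.2,
  "dimer_on_rate": 0.0,
  "dimer_off_rate": 1.0,
  "dimer_capture_radius": 0.1,
  "immobile_fraction": 0.0,
  "rng_seed": 77
 },
 "n_tracks": 111,
 "density": {
  "rho_um2": 0.31666666666666665,
  "se": 0.020971762320196527,
  "method": "direct",
  "above_direct_limit": false
 },
 "mobility": {
  "d_lat_um2_s": 0.15181658472161497,
  "intercept_um2": 0.003062251644656908,
  "stderr": 0.002075752339438965,
  "motion_class": "free"
 },
 "stoichiometry": {
  "unit_intensity": 15.833233333333334,
  "type_counts": {
   "unclassified": 81,
   "type1": 29,
   "other-dimer": 1
  },
  "type_fractions": {
   "unclassified": 0.7297297297297297,
   "type1": 0.26126126126126126,
   "other-dimer": 0.009009009009009009
  }
 }
}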