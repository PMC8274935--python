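{
  "params": {
    "c1_alpha_m": 3000.000000000001,
    "c2_alpha_m": 8.0,
    "c1_beta_m": 0.03900000000000005,
    "c2_beta_m": -8.000000000000002,
    "c1_alpha_h": 1.0999999999999986e-06,
    "c2_alpha_h": -7.999999999999999,
    "c1_beta_h": 3.595919109719321,
    "c2_beta_h": 13.333333333333334
  },
  "per_dataset_sse": {
    "availability": 1.8605553792400664e-32,
    "activation": 9.003892614996856e-32,
    "t_half": 5.505196671802284e-32,
    "activation_tau": 3.418397255957718e-31
  },
  "objective": 5.055361722561638e-31,
  "converged": true,
  "start_index": 16,
  "start_objectives": [
    1.021694040230487e-30,
    1.3262682158793632e-30,
    7.004160143290307e-31,
    1.27931779941028e-30,
    7.94273241355868e-31,
    7.129246742444165e-31,
    6.198147344062553e-31,
    1.7964118397848205e-30,
    6.9259202692916375e-31,
    7.094274613808857e-31,
    13000000.300293904,
    9.060507520913716e-31,
    9.675645676852249e-30,
    1.0769730280103648e-26,
    1.09517681305793e-30,
    13000000.402761932,
    5.055361722561638e-31,
    5.620589382301396e-29,
    7.129246742444165e-31,
    9.073504918274184e-31
  ],
  "provenance": {
    "seed": 0,
    "n_starts": 20,
    "config_hash": "15d0c335030d8959",
    "dataset_provenance": [
      "synthetic fixture, seed=20210614, noiseless",
      "synthetic fixture, seed=20210614, noiseless",
      "synthetic fixture, seed=20210614, noiseless",
      "synthetic fixture, seed=20210614, noiseless"
    ],
    "note": "fit of the 8 gating coefficients to the packaged noiseless synthetic fixture (fixtures.gen_clamp_fixture with default FixtureSpec) using the default FitConfig; regenerate with scripts/refit_default_params.py"
  }
}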