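{
  "version": "1.0",
  "description": "Fitted parameter sets for the electroneutral (EN) and electrogenic (EG) respiration models. Order of the free-parameter vector: beta_ATPS, gamma_ATPS_ADP, beta_ETCP, gamma_ETCP_pmf, alpha_NaH, alpha_K, alpha_ATPuse, beta_mempot[, n_NaH]. 'reported_cost' is the published cost-function value for reference.",
  "sets": {
    "EN1": {"variant": "EN", "beta_ATPS": 1.310, "gamma_ATPS_ADP": 0.525, "beta_ETCP": 0.732, "gamma_ETCP_pmf": 0.679, "alpha_NaH": 1.562, "alpha_K": 0.971, "alpha_ATPuse": 0.911, "beta_mempot": 0.870, "reported_cost": 0.314},
    "EN2": {"variant": "EN", "beta_ATPS": 0.020, "gamma_ATPS_ADP": 0.090, "beta_ETCP": 0.046, "gamma_ETCP_pmf": 0.180, "alpha_NaH": 0.800, "alpha_K": 1.5e-08, "alpha_ATPuse": 0.600, "beta_mempot": 100.0, "reported_cost": 0.631},
    "EN3": {"variant": "EN", "beta_ATPS": 0.017, "gamma_ATPS_ADP": 0.123, "beta_ETCP": 0.048, "gamma_ETCP_pmf": 0.175, "alpha_NaH": 0.240, "alpha_K": 1.4e-08, "alpha_ATPuse": 0.771, "beta_mempot": 105.5, "reported_cost": 0.041},
    "EN4": {"variant": "EN", "beta_ATPS": 0.020, "gamma_ATPS_ADP": 0.375, "beta_ETCP": 0.101, "gamma_ETCP_pmf": 0.235, "alpha_NaH": 0.692, "alpha_K": 0.203, "alpha_ATPuse": 0.888, "beta_mempot": 100.2, "reported_cost": 0.255},
    "EN5": {"variant": "EN", "beta_ATPS": 0.042, "gamma_ATPS_ADP": 0.174, "beta_ETCP": 0.085, "gamma_ETCP_pmf": 0.355, "alpha_NaH": 3.693e-04, "alpha_K": 0.601, "alpha_ATPuse": 0.779, "beta_mempot": 105.6, "reported_cost": 0.193},
    "EG1": {"variant": "EG", "beta_ATPS": 0.835, "gamma_ATPS_ADP": 0.477, "beta_ETCP": 1.089, "gamma_ETCP_pmf": 0.635, "alpha_NaH": 1.088, "alpha_K": 1.152, "alpha_ATPuse": 1.019, "beta_mempot": 0.754, "n_NaH": 0.76, "reported_cost": 0.184},
    "EG2": {"variant": "EG", "beta_ATPS": 0.020, "gamma_ATPS_ADP": 0.090, "beta_ETCP": 0.046, "gamma_ETCP_pmf": 0.180, "alpha_NaH": 0.800, "alpha_K": 1.5e-08, "alpha_ATPuse": 0.600, "beta_mempot": 100.0, "n_NaH": 2.0, "reported_cost": 0.720},
    "EG3": {"variant": "EG", "beta_ATPS": 0.018, "gamma_ATPS_ADP": 0.108, "beta_ETCP": 0.054, "gamma_ETCP_pmf": 0.180, "alpha_NaH": 0.988, "alpha_K": 7.353e-09, "alpha_ATPuse": 0.868, "beta_mempot": 102.2, "n_NaH": 1.54, "reported_cost": 0.023},
    "EG4": {"variant": "EG", "beta_ATPS": 0.027, "gamma_ATPS_ADP": 0.204, "beta_ETCP": 0.019, "gamma_ETCP_pmf": 0.154, "alpha_NaH": 0.997, "alpha_K": 0.117, "alpha_ATPuse": 0.493, "beta_mempot": 99.44, "n_NaH": 1.90, "reported_cost": 0.295},
    "EG5": {"variant": "EG", "beta_ATPS": 0.106, "gamma_ATPS_ADP": 0.207, "beta_ETCP": 0.018, "gamma_ETCP_pmf": 0.224, "alpha_NaH": 1.055, "alpha_K": 0.139, "alpha_ATPuse": 0.809, "beta_mempot": 102.5, "n_NaH": 1.45, "reported_cost": 0.320}
  }
}
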