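{
  "version": "1.0",
  "description": "Default environment constants and initial conditions for the H. salinarum respiration models. The suspension is 1 mL of culture at OD 1; a1 is the summed cytoplasmic volume of all cells, a2 the extracellular volume. Ion totals are total moles in the suspension divided by the suspension volume. 'reference_algebraic' holds the published algebraic-variable values at the initial state, used as a consistency cross-check.",
  "environment": {
    "R": 8.314462,
    "T": 298.0,
    "F": 96485.0,
    "Pi": 0.035,
    "O2": 0.108,
    "Atot": 0.0023,
    "XH": 5.8824e-03,
    "ATPS_conc": 4.9816e-05,
    "ETCP_conc": 6.6422e-05,
    "Htot": 3.1593e-07,
    "Ktot": 0.0251,
    "Natot": 3.7974,
    "a1": 1.36e-06,
    "a2": 9.9864e-04,
    "V_susp": 1.0e-03
  },
  "initial_state": {
    "Hi": 1.0e-07,
    "ATP": 5.88e-04,
    "Ki": 2.3,
    "Nai": 1.9,
    "dPsi": 0.08
  },
  "reference_algebraic": {
    "Ho": 3.1623e-07,
    "Ko": 2.2e-02,
    "Nao": 3.8,
    "ADP": 1.712e-03,
    "pmf": 1.0956e-01,
    "dpH": -0.5,
    "dpK": 2.0193,
    "dpNa": -0.30103,
    "dmuH": 1.0572e+04,
    "dmuK": -3.8011e+03,
    "dmuNa": 9.4368e+03
  }
}
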