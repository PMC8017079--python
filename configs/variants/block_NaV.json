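{
  "data": {
    "B_T": 150.0,
    "C": 1.0,
    "C_KCa": 0.2,
    "Ca_base": 0.05,
    "Ca_out": 450.0,
    "E_Cl": -75.0,
    "E_K": -80.0,
    "E_Leak": -60.0,
    "E_Na": 86.0,
    "E_TCN": -34.0,
    "F": 96485.0,
    "K_D": 1.0,
    "P_CaH": 2.2e-05,
    "P_CaT": 0.0007,
    "R": 8.314,
    "R_c": 0.0005,
    "T": 298.0,
    "ca_frozen": false,
    "delta": 0.0003,
    "g_KCa": 10.0,
    "g_Kdr": 4500.0,
    "g_KdrS": 0.0,
    "g_Leak": 20.0,
    "g_NaV": 0.0,
    "g_TCN": 45.0,
    "gating": {
      "h_CaT": {
        "V_half": -80.0,
        "V_tau1": -81.0,
        "V_tau2": -81.0,
        "exponent": 1,
        "instantaneous": false,
        "k_tau1": 8.0,
        "k_tau2": 8.0,
        "kind": "inactivation",
        "name": "h_CaT",
        "slope": 4.0,
        "tau_amp": 2.0,
        "tau_asym": 1.0,
        "tau_base": 0.012,
        "tau_flip": false
      },
      "h_NaV": {
        "V_half": -55.0,
        "V_tau1": -65.0,
        "V_tau2": -65.0,
        "exponent": 1,
        "instantaneous": false,
        "k_tau1": 7.0,
        "k_tau2": 7.0,
        "kind": "inactivation",
        "name": "h_NaV",
        "slope": 5.5,
        "tau_amp": 0.03,
        "tau_asym": 1.0,
        "tau_base": 0.005,
        "tau_flip": false
      },
      "m_CaH": {
        "V_half": -22.0,
        "V_tau1": 0.0,
        "V_tau2": 0.0,
        "exponent": 1,
        "instantaneous": true,
        "k_tau1": 1.0,
        "k_tau2": 1.0,
        "kind": "activation",
        "name": "m_CaH",
        "slope": 4.53,
        "tau_amp": 0.0,
        "tau_asym": 1.0,
        "tau_base": 0.0,
        "tau_flip": false
      },
      "m_CaT": {
        "V_half": -56.0,
        "V_tau1": -131.0,
        "V_tau2": -15.8,
        "exponent": 2,
        "instantaneous": false,
        "k_tau1": 16.7,
        "k_tau2": 18.2,
        "kind": "activation",
        "name": "m_CaT",
        "slope": 6.2,
        "tau_amp": 0.000333,
        "tau_asym": 1.0,
        "tau_base": 0.0002,
        "tau_flip": false
      },
      "m_Kdr": {
        "V_half": -25.0,
        "V_tau1": -30.0,
        "V_tau2": -30.0,
        "exponent": 4,
        "instantaneous": false,
        "k_tau1": 25.0,
        "k_tau2": 25.0,
        "kind": "activation",
        "name": "m_Kdr",
        "slope": 11.5,
        "tau_amp": 0.0054,
        "tau_asym": 0.6,
        "tau_base": 0.0,
        "tau_flip": true
      },
      "m_NaV": {
        "V_half": -32.0,
        "V_tau1": 0.0,
        "V_tau2": 0.0,
        "exponent": 3,
        "instantaneous": true,
        "k_tau1": 1.0,
        "k_tau2": 1.0,
        "kind": "activation",
        "name": "m_NaV",
        "slope": 8.5,
        "tau_amp": 0.0,
        "tau_asym": 1.0,
        "tau_base": 0.0,
        "tau_flip": false
      }
    },
    "h_CaT_frozen": null,
    "hill_KCa": 5,
    "k_pump": 0.01,
    "kdrs_tau_factor": 11.0,
    "z_Ca": 2
  },
  "kind": "model_parameters",
  "schema": 1
}
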