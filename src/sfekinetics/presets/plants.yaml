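# Per-species extraction scenarios: operating conditions (pressure, temperature,
# CO2 flow, particle size) together with the fitted solute parameters
# (C0, q0) and mass-transfer coefficients for both model families.
#
# Units are strictly SI: F kg/s, d_p m, N kg, rho kg/m^3, C0 and q0 kg/kg,
# k m/s.  P (MPa) and T (K) are metadata.  epsilon, rho_s, rho_f and N are
# not species-specific measurements; they are the package's auxiliary
# constants (CO2 near 10 MPa / 323 K for rho_f) and can be overridden in
# any config.  r, the easily accessible fraction, is a declared default
# (0.5) used by the synthetic-curve round trips.
presets:
  - name: "Mentha pulegium"
    common_name: pennyroyal
    P_MPa: 10.0
    T_K: 323.0
    F: 4.7e-4
    d_p: 5.0e-4
    N: 0.1
    epsilon: 0.4
    rho_s: 750.0
    rho_f: 385.0
    C0: 1.40e-3
    q0: 34.37e-3
    r: 0.5
    k_s_bic: 0.89e-8
    k_f_bic: 1.95e-6
    k_s_partition: 1.50e-8
  - name: "Foeniculum vulgare"
    common_name: fennel
    P_MPa: 9.0
    T_K: 313.0
    F: 3.0e-4
    d_p: 6.0e-4
    N: 0.1
    epsilon: 0.4
    rho_s: 750.0
    rho_f: 385.0
    C0: 1.70e-3
    q0: 32.62e-3
    r: 0.5
    k_s_bic: 3.05e-8
    k_f_bic: 4.50e-6
    k_s_partition: 3.91e-8
  - name: "Coriandrum sativum"
    common_name: coriander
    P_MPa: 9.0
    T_K: 313.0
    F: 3.0e-4
    d_p: 6.0e-4
    N: 0.1
    epsilon: 0.4
    rho_s: 750.0
    rho_f: 385.0
    C0: 1.05e-3
    q0: 4.43e-3
    r: 0.5
    k_s_bic: 1.30e-8
    k_f_bic: 1.18e-6
    k_s_partition: 1.38e-8
  - name: "Satureja montana"
    common_name: winter savory
    P_MPa: 9.0
    T_K: 313.0
    F: 3.7e-4
    d_p: 6.0e-4
    N: 0.1
    epsilon: 0.4
    rho_s: 750.0
    rho_f: 385.0
    C0: 2.10e-3
    q0: 32.00e-3
    r: 0.5
    k_s_bic: 1.31e-8
    k_f_bic: 1.95e-6
    k_s_partition: 1.85e-8
  - name: "Satureja fruticosa"
    common_name: savory
    P_MPa: 9.0
    T_K: 313.0
    F: 3.0e-4
    d_p: 6.0e-4
    N: 0.1
    epsilon: 0.4
    rho_s: 750.0
    rho_f: 385.0
    C0: 1.10e-3
    q0: 17.30e-3
    r: 0.5
    k_s_bic: 0.42e-8
    k_f_bic: 0.88e-6
    k_s_partition: 0.31e-8
  - name: "Santolina chamaecyparissus"
    common_name: cotton lavender
    P_MPa: 8.0
    T_K: 313.0
    F: 3.0e-4
    d_p: 6.0e-4
    N: 0.1
    epsilon: 0.4
    rho_s: 750.0
    rho_f: 385.0
    C0: 0.70e-3
    q0: 2.50e-3
    r: 0.5
    k_s_bic: 8.43e-8
    k_f_bic: 17.62e-6
    k_s_partition: 14.88e-8
  - name: "Thymus vulgaris"
    common_name: thyme
    P_MPa: 9.0
    T_K: 313.0
    F: 3.7e-4
    d_p: 6.0e-4
    N: 0.1
    epsilon: 0.4
    rho_s: 750.0
    rho_f: 385.0
    C0: 1.00e-3
    q0: 11.27e-3
    r: 0.5
    k_s_bic: 1.26e-8
    k_f_bic: 0.60e-6
    k_s_partition: 1.53e-8
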