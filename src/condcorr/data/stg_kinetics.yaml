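# Channel kinetics and membrane/calcium constants for the generic lobster-STG
# single-compartment model (fast Na, fast/slow transient Ca, A-type K,
# Ca-dependent K, delayed-rectifier K, hyperpolarization-activated mixed-ion H,
# and ohmic leak).  Numeric tables transcribed from the model-database lineage
# for cultured stomatogastric neurons (H current from thalamic relay neurons);
# status "transcribed" marks values not re-derived here.
#
# Functional forms (V in mV, Ca in uM, tau in ms):
#   logistic:            1 / (1 + exp((V - v_half) / k))
#   logistic_ca:         (Ca / (Ca + ca_half)) * logistic(V)
#   sigmoid_offset:      a + b / (1 + exp((V - v_half) / k))
#   double_exponential:  a + b / (exp((V - v1) / k1) + exp((V - v2) / k2))
#   product_sigmoids:    (a / (1 + exp((V - v1) / k1)))
#                        * (b + c / (1 + exp((V - v2) / k2)))
# Current density: I = gbar * m^p * h^q * (V - E), gbar in mS/cm^2.

schema_version: 1
name: stg-generic
status: transcribed

membrane:
  specific_capacitance: 1.0      # uF/cm^2
  area: 6.2832e-4                # cm^2 (cylinder, 50 um diameter x 400 um)
  v_table_min: -120.0            # mV, gating-table range; clamped outside
  v_table_max: 60.0
  v_table_step: 0.01

calcium:
  tau: 200.0                     # ms, buffering time constant
  current_factor: 14.96          # uM/nA, Ca-current to concentration drive
  rest: 0.05                     # uM, steady concentration at zero Ca current
  external: 3000.0               # uM
  nernst_prefactor: 12.199       # mV = RT/2F at 10 degC; E_Ca = pref*ln(out/in)
  floor: 1.0e-4                  # uM, numerical lower bound during integration

grid:
  # 6 equidistant levels from zero to a physiologically relevant maximum,
  # one row per conductance; level i value = i * max / (n_levels - 1).
  n_levels: 6
  max:
    Na: 500.0
    CaT: 12.5
    CaS: 10.0
    A: 50.0
    KCa: 25.0
    Kd: 125.0
    H: 0.05
    leak: 0.05

channels:
  - name: Na
    reversal: 50.0
    p: 3
    q: 1
    m_inf: {form: logistic, v_half: -25.5, k: -5.29}
    h_inf: {form: logistic, v_half: -48.9, k: 5.18}
    tau_m: {form: sigmoid_offset, a: 2.64, b: -2.52, v_half: -120.0, k: -25.0}
    tau_h: {form: product_sigmoids, a: 1.34, v1: -62.9, k1: -10.0,
            b: 1.5, c: 1.0, v2: -34.9, k2: 3.6}

  - name: CaT
    reversal: calcium
    p: 3
    q: 1
    m_inf: {form: logistic, v_half: -27.1, k: -7.2}
    h_inf: {form: logistic, v_half: -32.1, k: 5.5}
    tau_m: {form: sigmoid_offset, a: 43.4, b: -42.6, v_half: -68.1, k: -20.5}
    tau_h: {form: sigmoid_offset, a: 210.0, b: -179.6, v_half: -55.0, k: -16.9}

  - name: CaS
    reversal: calcium
    p: 3
    q: 1
    m_inf: {form: logistic, v_half: -33.0, k: -8.1}
    h_inf: {form: logistic, v_half: -60.0, k: 6.2}
    tau_m: {form: double_exponential, a: 2.8, b: 14.0,
            v1: -27.0, k1: 10.0, v2: -70.0, k2: -13.0}
    tau_h: {form: double_exponential, a: 120.0, b: 300.0,
            v1: -55.0, k1: 9.0, v2: -65.0, k2: -16.0}

  - name: A
    reversal: -80.0
    p: 3
    q: 1
    m_inf: {form: logistic, v_half: -27.2, k: -8.7}
    h_inf: {form: logistic, v_half: -56.9, k: 4.9}
    tau_m: {form: sigmoid_offset, a: 23.2, b: -20.8, v_half: -32.9, k: -15.2}
    tau_h: {form: sigmoid_offset, a: 77.2, b: -58.4, v_half: -38.9, k: -26.5}

  - name: KCa
    reversal: -80.0
    p: 4
    q: 0
    m_inf: {form: logistic_ca, v_half: -28.3, k: -12.6, ca_half: 3.0}
    tau_m: {form: sigmoid_offset, a: 180.6, b: -150.2, v_half: -46.0, k: -22.7}

  - name: Kd
    reversal: -80.0
    p: 4
    q: 0
    m_inf: {form: logistic, v_half: -12.3, k: -11.8}
    tau_m: {form: sigmoid_offset, a: 14.4, b: -12.8, v_half: -28.3, k: -19.2}

  - name: H
    reversal: -20.0
    p: 1
    q: 0
    m_inf: {form: logistic, v_half: -75.0, k: 5.5}
    tau_m: {form: double_exponential, a: 0.0, b: 2.0,
            v1: -169.7, k1: -11.6, v2: 26.7, k2: 14.3}

  - name: leak
    reversal: -50.0
    p: 0
    q: 0
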