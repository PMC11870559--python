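# Lymphoma model treated with non-transduced (NT) NK cells at ETR 1:1.
grid: {width: 100, height: 100, l: 50.0, b_max: 25, dt_hours: 4.0}
duration_days: 14.0
etr: "1:1"
n_tumor_init: 1000
tumor: {p_b: 0.455, d_b: 1.0e-4, m_b: 0.1, p_mutate: 1.0e-3}
replicates: 5
cytokines:
  IL15: {half_life: 2.5, deposit_per_step: 1.0}
products:
  NT:
    kill: {mu_c: 0.5, sigma_c: 0.01, gamma: 1.0}
    proliferation: {pc: 0.3, bpc: 0.01, b50: 25, c50: 70, gamma1: 0.2, gamma2: 0.2}
    exhaustion: {s0: 5, variant: EM1}
    rates: {d_c: 0.1, d_e: 0.2, p_v: 1.0e-3, d_v: 1.0e-3,
            k_b_minus: 1.0, k_b_plus: 0.9}
    motility: {m_n: 0.9, v_n: 39.0}
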