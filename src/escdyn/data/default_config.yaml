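# Default configuration: the six-gene ESC core network with slow Nanog
# TA switching.  Rates in 1/s; times in the run section in days.
version: 1

network:
  Sox2:
    activators: [Sox2, Oct4, Nanog2]
    repressors: []
    histone_complex_rule: true
    secondary_oct4_repressor: false
    n_alleles: 2
  Oct4:
    activators: [Sox2, Oct4, Nanog2]
    repressors: [Cdx2, Gcnf]
    histone_complex_rule: true
    secondary_oct4_repressor: false
    n_alleles: 2
  Nanog:
    activators: [Sox2, Oct4, Nanog2]
    repressors: [Oct4, Gata6, Gcnf]
    histone_complex_rule: true
    secondary_oct4_repressor: true
    n_alleles: 1          # allelic silencing: one dynamic allele in ESCs
  Cdx2:
    activators: [Cdx2]
    repressors: [Oct4, Gata6]
    histone_complex_rule: false
    secondary_oct4_repressor: false
    n_alleles: 2
  Gata6:
    activators: [Gata6]
    repressors: [Nanog2, Cdx2]
    histone_complex_rule: false
    secondary_oct4_repressor: false
    n_alleles: 2
  Gcnf:
    activators: [Cdx2, Gata6, Gcnf]
    repressors: []
    histone_complex_rule: false
    secondary_oct4_repressor: false
    n_alleles: 2

parameters:
  g_full: 0.02            # synthesis rate, complete TA [1/s]
  gamma_synth: 10.0       # complete/partial synthesis ratio
  b_mean: 5.0             # mean burst size [copies]
  k_deg: 1.0e-4           # protein degradation [1/s]
  h0_bind: 1.0e-4         # binding rate per TF copy [1/(s copy)]
  f_unbind: 1.0e-2        # unbinding rate [1/s]
  K_dimer: 0.01           # Nanog dimerization constant [1/copies]
  k_ta_form1: 1.0e-3      # TA step 1, activator bound [1/s]
  k_ta_form1_basal: 1.0e-4
  k_ta_form1_rep: 1.0e-5
  k_ta_form2: 1.0e-3      # TA completion [1/s]
  k_ta_diss: 1.0e-3       # TA dissolution [1/s]
  r_on: 5.0e-6            # histone activation [1/s]
  r_on_basal: 5.0e-6      # histone activation, nothing bound [1/s]
  r_off: 5.0e-6           # histone repression [1/s]
  gene_overrides:
    Nanog:                # slow switching: dissolution at the cell-cycle
                          # frequency, completion slow, first step at k_deg
      k_ta_form1: 1.0e-4
      k_ta_form1_basal: 1.0e-5
      k_ta_form1_rep: 1.0e-6
      k_ta_form2: 2.0e-5
      k_ta_diss: 1.16e-5
    Cdx2:                 # histone activation inherently suppressed in ESCs
      r_on: 5.0e-7
      r_on_basal: 5.0e-7

run:
  cells: 200
  days: 3.0
  burn_in_days: 10.0
  record_dt: 1000.0       # seconds
  seed: 1
  mode: esc               # esc | differentiation
  oct4_synth_factor: 1.0  # 0.25 / 0.10 for the depletion experiments

score:
  peak_ratio_window: [5.0, 50.0]
  height_ratio_primary: [1.0, 5.0]
  height_ratio_secondary: [0.5, 1.0]
  zero_fraction_max: 0.02
  smoothing_decades: 0.15
  prominence_floor: 0.05

scan:
  plane: nanog-ta         # nanog-ta | synth-burst
  log_range_a: [-6.0, -3.0]
  log_range_b: [-6.0, -3.0]
  n_sets: 16
  n_cells: 50
  days: 3.0
  burn_in_days: 5.0

coarse_grain:
  occ_threshold: 0.01
  link_count_threshold: 600
  histone_genes: [Nanog, Cdx2, Gata6, Gcnf]
  bands:
    Sox2:  {edges: [10, 200],        names: ["", LS, S],        lambdas: [0, 2, 4]}
    Oct4:  {edges: [20, 200],        names: ["", LO, O],        lambdas: [0, 2, 4]}
    Nanog: {edges: [40, 400, 4000],  names: ["", LN, MN, HN],   lambdas: [0, 1, 2, 4]}
    Cdx2:  {edges: [20, 200],        names: ["", LC, C],        lambdas: [0, 2, 4]}
    Gata6: {edges: [100],            names: ["", Ga],           lambdas: [0, 4]}
    Gcnf:  {edges: [100],            names: ["", Gc],           lambdas: [0, 4]}

landscape:
  k0: null                # default: largest observed rate
  F_max: null             # default: max fitted barrier + 2
  flux_width_thresholds: [0.01, 0.1]   # thin / middle / thick line classes
  axis_weights:
    q_TE: {Cdx2: 1.0, Gcnf: 0.5}
    q_PE: {Gata6: 1.0, Gcnf: 0.5}
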