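# Default calibration for the synthetic crypt population generator.
#
# All intensity levels are in arbitrary fluorescence units anchored so that
# a transit-amplifying (TA) cell entering S phase carries DNA-bound Mcm2 of
# exactly 1.0.  Zone phase compositions are calibration constants chosen so
# that the homeostatic crypt shows the expected spatial structure: a stem
# compartment (<40 um) dominated by unlicensed-G1 cells, a licensed-G1 peak
# at 40-60 um, an S-phase-rich TA compartment, and a differentiated zone in
# which cells keep total Mcm2 and Ki67 for a while but never license.

n_cells: 10000
seed: 0
scenario: homeostasis
stem_license_factor: 2.0

crypt:
  radius_um: 15.0
  length_um: 160.0

noise_cv:
  default: 0.15
  dna_content: 0.05

channels:
  bound_background: 0.05     # DNA-bound Mcm2 of unlicensed / G2 cells
  ta_s_entry_bound: 1.0      # intensity anchor
  total_mcm2:
    stem: 2.5
    paneth: 0.02
    TA: 1.5
    differentiated: 0.8
    LRC: 0.02
  g0_total: 0.02
  g0_bound: 0.01
  ki67:
    G0: 0.02
    TRANSITION: 0.15
    UNLICENSED_G1: 1.0
    LICENSED_G1: 1.0
    S_EARLY_MID: 1.2
    LATE_S_G2: 1.2
    G2M: 1.5
  edu_positive: 1.0
  baseline: 0.02             # negative-channel floor (EdU, Lgr5, H2B-GFP)
  lgr5_positive: 1.0
  h2b_initial: 1.0
  s_boundary_fraction: 0.6   # replicated fraction splitting early/mid from late S

label_chase:
  mean_divisions:            # Poisson means per cell class over the chase
    stem: 3
    TA: 6
    differentiated: 5
    paneth: 0
    LRC: 0

zones:
  - name: stem
    range_um: [0.0, 40.0]
    weight: 0.22
    classes: {stem: 0.72, paneth: 0.22, LRC: 0.06}
    phases:
      stem:
        UNLICENSED_G1: 0.58
        LICENSED_G1: 0.12
        S_EARLY_MID: 0.09
        LATE_S_G2: 0.05
        G2M: 0.05
        TRANSITION: 0.06
        G0: 0.05
      paneth: {G0: 1.0}
      LRC: {G0: 1.0}
  - name: ta_early
    range_um: [40.0, 60.0]
    weight: 0.16
    classes: {TA: 1.0}
    phases:
      TA:
        LICENSED_G1: 0.30
        UNLICENSED_G1: 0.12
        S_EARLY_MID: 0.12
        LATE_S_G2: 0.14
        G2M: 0.12
        TRANSITION: 0.06
        G0: 0.14
  - name: ta_mid
    range_um: [60.0, 80.0]
    weight: 0.16
    classes: {TA: 1.0}
    phases:
      TA:
        LICENSED_G1: 0.16
        UNLICENSED_G1: 0.10
        S_EARLY_MID: 0.16
        LATE_S_G2: 0.22
        G2M: 0.14
        TRANSITION: 0.06
        G0: 0.16
  - name: ta_late
    range_um: [80.0, 100.0]
    weight: 0.14
    classes: {TA: 1.0}
    phases:
      TA:
        LICENSED_G1: 0.08
        UNLICENSED_G1: 0.12
        S_EARLY_MID: 0.14
        LATE_S_G2: 0.22
        G2M: 0.12
        TRANSITION: 0.10
        G0: 0.22
  - name: ta_terminal
    range_um: [100.0, 120.0]
    weight: 0.12
    classes: {TA: 1.0}
    phases:
      TA:
        # cell-cycle cohorts finish here: late S/G2 but no newly licensed
        # or early-S cells, then exit into the unlicensed/transition states
        UNLICENSED_G1: 0.22
        LATE_S_G2: 0.15
        G2M: 0.08
        TRANSITION: 0.25
        G0: 0.30
  - name: differentiated
    range_um: [120.0, 160.0]
    weight: 0.20
    classes: {differentiated: 1.0}
    phases:
      differentiated:
        G0: 0.55
        TRANSITION: 0.30
        UNLICENSED_G1: 0.15

# Scenario adjustments, applied to every zone's phase table as sequential
# probability-mass transfers {from, to, fraction} before sampling.
scenarios:
  homeostasis: {}
  egfr_inhibited:
    # acute EGFR inhibition: cycling cells arrest in unlicensed G1 with
    # 2N DNA, still expressing Mcm2 and Ki67
    transfers:
      - {from: LICENSED_G1, to: UNLICENSED_G1, fraction: 0.9}
      - {from: S_EARLY_MID, to: UNLICENSED_G1, fraction: 0.8}
      - {from: LATE_S_G2, to: UNLICENSED_G1, fraction: 0.8}
      - {from: G2M, to: UNLICENSED_G1, fraction: 0.8}
  deep_g0:
    # prolonged inhibition: Ki67 declines before total Mcm2, shifting mass
    # through the transition state into Mcm2-negative, Ki67-negative G0
    transfers:
      - {from: LICENSED_G1, to: UNLICENSED_G1, fraction: 0.9}
      - {from: S_EARLY_MID, to: UNLICENSED_G1, fraction: 0.8}
      - {from: LATE_S_G2, to: UNLICENSED_G1, fraction: 0.8}
      - {from: G2M, to: UNLICENSED_G1, fraction: 0.8}
      - {from: UNLICENSED_G1, to: TRANSITION, fraction: 0.6}
      - {from: TRANSITION, to: G0, fraction: 0.4}
  apc_mutant:
    # checkpoint loss: cells license immediately on G1 entry and may enter
    # S phase at sub-maximal DNA-bound Mcm2
    transfers:
      - {from: UNLICENSED_G1, to: LICENSED_G1, fraction: 0.97}
      - {from: TRANSITION, to: LICENSED_G1, fraction: 0.8}
    sub_maximal_s_entry: {low: 0.3, high: 1.0}
  label_chase: {}
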