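# Calibrated kinetic constants for the nine-species embryonic Cdk1 oscillator
# (Xenopus laevis early-embryo regime).
#
# The network wiring follows the interlinked-feedback architecture of the
# Pomerening/Tsai embryonic cell-cycle models: cyclin B synthesis, Cdk1
# binding, Wee1/Cdc25 control of the inhibitory Tyr-15 phosphate, CAK/PP2C
# control of the activating Thr phosphate, and the Plx1->APC negative
# feedback that destroys all cyclin-containing species.  The numerical
# values of the rate constants are a CALIBRATED set, fixed once by matching
# the well-established observables of this system:
#   * free-running limit-cycle period T = 39.2 min,
#   * period inversely proportional to the cyclin synthesis rate ks,
#   * relaxation (spike-like) active-Cdk1 waveform, active phase < 25% of T,
#   * pre-fertilization (CSF-arrested) steady state whose active-Cdk1 level
#     lies far below 1/4 of the limit-cycle peak, so a 4x activity threshold
#     is meaningful for trigger-wave spread,
#   * sustained (not damped) oscillations over a 4-fold range of ks.
# Hill midpoints/coefficients for the regulator responses are in the range
# reported for this oscillator family (sharp Cdc25 response, softer Wee1
# response).  This file is the single source of truth for the constants;
# code never hard-codes them.
#
# Units: concentrations in nM, time in minutes, unless noted.

ks: 4.153          # nM/min   cyclin B synthesis rate (wild-type; T = 39.2 min)
k_bind: 1.0        # 1/min    pseudo-first-order cyclin-Cdk1 association (Cdk1 in excess)
k_unbind: 0.01     # 1/min    complex dissociation back to free cyclin
k_cak: 0.8         # 1/min    CAK-mediated activating Thr phosphorylation
k_pp: 0.008        # 1/min    phosphatase removal of the Thr phosphate
k_wee1_basal: 0.05 # 1/min    Tyr-15 phosphorylation by inactive Wee1 (basal)
k_wee1_act: 1.5    # 1/min    additional Tyr-15 phosphorylation per unit active Wee1
k_cdc25_basal: 0.1 # 1/min    Tyr-15 dephosphorylation by inactive Cdc25 (basal)
k_cdc25_act: 4.0   # 1/min    additional Tyr-15 dephosphorylation per unit active Cdc25
kdest: 3.0         # 1/min    APC-mediated destruction rate per unit active APC
kc25_on: 1.75      # 1/min    Cdk1-driven Cdc25 activation rate constant
kc25_off: 0.3      # 1/min    Cdc25 relaxation to the inactive form
K_cdc25: 20.0      # nM       active-Cdk1 midpoint of the Cdc25 response
n_cdc25: 11.0      # -        Hill coefficient of the Cdc25 response (sharp switch)
kwee_off: 1.75     # 1/min    Cdk1-driven Wee1 inactivation rate constant
kwee_on: 0.4       # 1/min    Wee1 relaxation to the active form
K_wee1: 18.0       # nM       active-Cdk1 midpoint of the Wee1 response
n_wee1: 3.5        # -        Hill coefficient of the Wee1 response
kplx_on: 1.0       # 1/min    Cdk1-driven Plx1 activation rate constant
kplx_off: 0.3      # 1/min    Plx1 relaxation to the inactive form
K_plx: 40.0        # nM       active-Cdk1 midpoint of the Plx1 response
n_plx: 5.0         # -        Hill coefficient of the Plx1 response
kapc_on: 2.0       # 1/min    Plx1-driven APC activation rate constant
kapc_off: 0.8      # 1/min    APC relaxation to the inactive form
K_apc: 0.5         # -        active-Plx1 midpoint of the APC response (fraction of total)
n_apc: 4.0         # -        Hill coefficient of the APC response
cdc25_total: 1.0   # -        total Cdc25 pool (active + inactive), normalized
wee1_total: 1.0    # -        total Wee1 pool, normalized
plx1_total: 1.0    # -        total Plx1 pool, normalized
apc_total: 1.0     # -        total APC pool, normalized
D: 10.0            # um^2/s   protein diffusion constant, identical for all species
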