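# Default parameters for the eight sagittal-plane muscle groups (one leg).
# Values are literature-standard for planar lower-extremity gait models and
# are substitutable: load any file with the same schema via load_muscles().
#
# Units: forces N, lengths m, times s, v_CE_max in optimal fiber lengths/s.
# Moment arms are constant and signed so that positive d * F produces an
# extension moment at hip/knee and a plantarflexion moment at the ankle.
# k_SEE gives F_max at ~4.5% tendon strain; the PEE is slack up to 1.2
# optimal lengths and reaches F_max/4 at 1.6 optimal lengths.

iliopsoas:
  F_max: 4000.0
  l_CE_opt: 0.102
  width: 0.56
  v_CE_max: 10.0
  T_act: 0.01
  T_deact: 0.04
  tendon_slack_length: 0.142
  pee_slack_length: 0.1224
  k_SEE: 3.674e7
  k_PEE: 6.010e+05
  moment_arms: {hip: -0.060}
  fast_twitch_fraction: 0.50

glutei:
  F_max: 3500.0
  l_CE_opt: 0.200
  width: 0.56
  v_CE_max: 10.0
  T_act: 0.01
  T_deact: 0.04
  tendon_slack_length: 0.157
  pee_slack_length: 0.24
  k_SEE: 6.013e7
  k_PEE: 1.370e+05
  moment_arms: {hip: 0.062}
  fast_twitch_fraction: 0.45

hamstrings:
  F_max: 4000.0
  l_CE_opt: 0.104
  width: 0.56
  v_CE_max: 10.0
  T_act: 0.01
  T_deact: 0.04
  tendon_slack_length: 0.334
  pee_slack_length: 0.1248
  k_SEE: 1.771e+07
  k_PEE: 5.780e+05
  moment_arms: {hip: 0.072, knee: -0.045}
  fast_twitch_fraction: 0.40

rectus_femoris:
  F_max: 1200.0
  l_CE_opt: 0.081
  width: 0.56
  v_CE_max: 10.0
  T_act: 0.01
  T_deact: 0.04
  tendon_slack_length: 0.398
  pee_slack_length: 0.0972
  k_SEE: 3.74e6
  k_PEE: 2.860e+05
  moment_arms: {hip: -0.034, knee: 0.050}
  fast_twitch_fraction: 0.65

vasti:
  F_max: 7000.0
  l_CE_opt: 0.093
  width: 0.56
  v_CE_max: 10.0
  T_act: 0.01
  T_deact: 0.04
  tendon_slack_length: 0.223
  pee_slack_length: 0.1116
  k_SEE: 6.953e7
  k_PEE: 1.264e+06
  moment_arms: {knee: 0.042}
  fast_twitch_fraction: 0.50

gastrocnemius:
  F_max: 3500.0
  l_CE_opt: 0.055
  width: 0.56
  v_CE_max: 10.0
  T_act: 0.01
  T_deact: 0.04
  tendon_slack_length: 0.420
  pee_slack_length: 0.066
  k_SEE: 9.800e+06
  k_PEE: 1.810e+06
  moment_arms: {knee: -0.020, ankle: 0.053}
  fast_twitch_fraction: 0.45

soleus:
  F_max: 8000.0
  l_CE_opt: 0.055
  width: 0.56
  v_CE_max: 10.0
  T_act: 0.01
  T_deact: 0.04
  tendon_slack_length: 0.245
  pee_slack_length: 0.066
  k_SEE: 6.583e7
  k_PEE: 4.130e+06
  moment_arms: {ankle: 0.053}
  fast_twitch_fraction: 0.20

tibialis_anterior:
  F_max: 3000.0
  l_CE_opt: 0.082
  width: 0.56
  v_CE_max: 10.0
  T_act: 0.01
  T_deact: 0.04
  tendon_slack_length: 0.317
  pee_slack_length: 0.0984
  k_SEE: 1.474e7
  k_PEE: 6.970e+05
  moment_arms: {ankle: -0.037}
  fast_twitch_fraction: 0.25
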