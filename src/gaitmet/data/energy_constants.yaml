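# Constants of the metabolic energy-expenditure models.
#
# The four heat-rate models (BHAR04, HOUD06, UMBE03, LICH05) decompose the
# energy rate into fiber work rate plus activation, maintenance and
# shortening/lengthening heat rates.  The constants below follow the models'
# original publications where mass-specific (W per kg muscle mass) or
# force-normalized coefficients are defined; every constant is exposed here
# so a different published variant can be swapped in without code changes.

BHAR04:
  # activation heat decay with stimulation time: phi = phi_inf + exp(-t/tau)
  phi_inf: 0.06
  tau_phi: 0.25          # s
  act_slow: 40.0         # W/kg, slow-twitch activation heat coefficient
  act_fast: 133.0        # W/kg, fast-twitch activation heat coefficient
  maint_slow: 74.0       # W/kg, slow-twitch maintenance heat coefficient
  maint_fast: 111.0      # W/kg, fast-twitch maintenance heat coefficient
  short_iso: 0.16        # shortening heat ~ (0.16 F_iso + 0.18 F_CE) |v|
  short_ce: 0.18
  lengthen_ce: 0.157     # lengthening heat ~ 0.157 F_CE v

UMBE03:
  aerobic_scale: 1.5     # S, applied to all heat terms
  am_fast: 128.0         # h_AM = am_fast * ft + am_base  (W/kg)
  am_base: 25.0
  act_exp_am: 0.6        # heat scaling exponents in A = f(u, a)
  act_exp_short: 2.0
  vmax_st_ratio: 2.5     # slow-twitch v_max = v_max / ratio
  alpha_st_numer: 100.0  # alpha_S(ST) = 100 / vbar_max(ST)
  alpha_ft_numer: 153.0  # alpha_S(FT) = 153 / vbar_max
  alpha_len_orig: 4.0    # alpha_L = 4.0 * alpha_S(ST)  (original coefficient)
  alpha_len_updated: 0.3 # alpha_L = 0.3 * alpha_S(ST)  (updated coefficient)

HOUD06:
  act_coeff: 10.0        # W/kg, activation heat ~ act_coeff * a
  maint_coeff: 30.0      # W/kg, maintenance heat ~ maint_coeff * a * f_L
  short_ce: 0.25         # Hill shortening heat ~ 0.25 F_CE |v|

LICH05:
  # heat rates normalized by F_max * v_max; labile maintenance heat decays
  # with stimulation time
  maint_sustained: 0.010
  maint_labile: 0.040
  tau_labile: 0.5        # s
  short_coeff: 0.30      # shortening heat ~ 0.3 a f_L F_max |v|
  lengthen_coeff: 0.06   # lengthening heat ~ 0.06 a f_L F_max v

MINE97:
  # empirical velocity function phi(vbar), vbar = shortening-positive
  # normalized CE velocity
  num: [0.054, 0.506, 2.46]
  den: [1.0, -1.13, 12.8, -1.64]

MARG68:
  eff_shortening: 0.25   # muscles are 25% efficient when shortening
  eff_lengthening: 1.20  # and 120% efficient when lengthening

KIMR15:
  h_M: 0.054             # activation/maintenance heat rate coefficient
  h_SL_pos: 0.283        # shortening-lengthening heat rate, positive power
  h_SL_neg: 1.423        # shortening-lengthening heat rate, negative power
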