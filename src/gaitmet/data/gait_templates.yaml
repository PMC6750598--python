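# Nominal one-cycle waveform templates for the synthetic gait generator.
#
# Joint angles are truncated Fourier series over the gait cycle phase
# (0 = ipsilateral heel strike), in degrees, Winter sign convention
# (hip/knee flexion positive, ankle dorsiflexion positive):
#   theta(phi) = c[0] + sum_k c[2k-1]*cos(2 pi k phi) + c[2k]*sin(2 pi k phi)
# The coefficients encode textbook-shaped level-walking curves; speed and
# incline modulation is applied on top by the generator.

joint_angles_deg:
  hip:   [7.955, 22.645, 3.812, -2.845, -3.28, 0.742, 0.433, -0.375, -0.118]
  knee:  [22.799, -4.279, -19.744, -13.737, 9.158, 0.454, 1.883, 0.098, -0.674]
  ankle: [0.702, -2.358, 7.721, 0.925, -9.304, -2.307, -0.239, 2.444, 0.193]

# Stance fraction of the gait cycle and ground-reaction-force shape
grf:
  duty_factor: 0.60        # stance duration / cycle duration
  valley_base: 0.25        # depth of the midstance valley at 0.8 m/s
  valley_speed_gain: 0.30  # extra valley depth per (m/s) above 0.8
  fore_aft_amp: 0.10       # braking/propulsion amplitude, fraction of BW, at 1.3 m/s
  cop_travel: 0.85         # CoP ends at this fraction of the heel-to-toe line

# Linear modulation of template means with incline (deg per unit grade)
incline_shift_deg:
  hip: 50.0
  knee: 25.0
  ankle: 20.0
trunk_lean_deg: 3.0        # forward trunk lean, level walking
trunk_lean_incline_deg: 15.0
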