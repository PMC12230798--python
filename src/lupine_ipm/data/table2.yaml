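# Published fixed-effect vital-rate estimates and life-cycle constants for
# Lupinus polyphyllus grown with intact vs. autoclaved soil inoculum, by seed
# origin (invasive Finnish, native North American). Survival and flowering-shoot
# coefficients were estimated from the pooled data and are shared by all cells.
# Sizes are log-transformed plant height (log cm).
constants:
  e: 0.122        # direct establishment probability of a fresh seed
  e_sb: 0.122     # establishment probability from the seed bank
  s_sb: 0.977     # annual seed survival in the seed bank (tetrazolium viability)
seeds_per_shoot:
  invasive_FI: 79.0
  native_US: 42.0
pooled:
  survival: {intercept: 1.13, slope: 1.16}       # logit scale
  shoots: {intercept: 2.67, slope: -0.49}        # flowering shoots, linear
cells:
  invasive_FI:
    intact:
      growth: {intercept: 4.40, slope: -0.16, variance: 0.22}
      flowering: {intercept: 7.89, slope: -3.09}
      recruit_size: {mean: 2.52, variance: 0.19}
    autoclaved:
      growth: {intercept: 2.48, slope: 0.44, variance: 0.19}
      flowering: {intercept: 0.27, slope: -1.00}
      recruit_size: {mean: 2.38, variance: 0.22}
  native_US:
    intact:
      growth: {intercept: 3.06, slope: 0.19, variance: 0.36}
      flowering: {intercept: -0.15, slope: -0.42}
      recruit_size: {mean: 2.15, variance: 0.35}
    autoclaved:
      growth: {intercept: 2.91, slope: 0.26, variance: 0.30}
      flowering: {intercept: -8.38, slope: 2.45}
      recruit_size: {mean: 2.12, variance: 0.26}
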