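# Shipped defaults for the multi-clone kinetic model.
#
# constants: shared model constants. alpha_glc (the glucose threshold of the
# lactate switch) and the feed concentrations are synthetic stand-ins chosen
# on the scale of typical depletion/feeding values; fit or override them for
# real data. Volumes in L, glucose in g/L, glutamate in mM.
#
# bounds: per-parameter lower bound, default initial guess, upper bound used
# by the bounded regression. mu_max and K_glc initial guesses are normally
# produced per run by the Monod pre-regression; the values here are the
# fallback midpoints.
constants:
  alpha_glc: 0.5
  glc_F_in: 100.0
  glu_F_in: 70.0
  V0: 0.015
  lactate_switch_as_printed: false

bounds:
  mu_max:    {lb: 0.01,   ig: 0.055,    ub: 0.1}
  k_d:       {lb: 0.0001, ig: 0.016,    ub: 0.1}
  K_glc:     {lb: 0.1,    ig: 5.05,     ub: 10.0}
  m_glc:     {lb: 0.0,    ig: 0.006192, ub: 1.0}
  Y_X_glc:   {lb: 0.1,    ig: 1.0,      ub: 10.0}
  Y_X_gln:   {lb: 0.1,    ig: 0.974,    ub: 10.0}
  Y_X_glu:   {lb: 0.001,  ig: 1.0,      ub: 20.0}
  Y_lac_glc: {lb: 0.1,    ig: 0.615,    ub: 2.0}
  Y_X_amm:   {lb: 0.1,    ig: 0.67,     ub: 20.0}
  Y_gln_glu: {lb: 0.001,  ig: 0.7,      ub: 1.0}
  Y_X_lac:   {lb: 0.01,   ig: 2.7,      ub: 5.0}
  Y_P_X:     {lb: 0.0001, ig: 0.2,      ub: 1.0}
  KD_amm:    {lb: 0.0,    ig: 5.0,      ub: 100.0}
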