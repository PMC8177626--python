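# Calibrated cost-functional weights (see eyeplant.control.calibrate_weights
# and docs/methods.md).  lambda_a sets the accuracy scale; accuracy and the
# terminal stationarity conditions are additionally enforced at
# penalty_factor * lambda_a inside the solver, so the torsion-shaping weights
# (lambda_lp1/lp2, lambda_f) can be large without degrading endpoint accuracy.
# lambda_e / lambda_d / beta are tuned so that a 10 deg horizontal saccade
# has an interior cost optimum near 130 ms and the main sequence saturates.
# lambda_f multiplies the raw tension quadratic (newtons per half-radian^2).
schema: eyeplant-weights/1
lambda_a: 1.0
lambda_e: 1.0
lambda_d: 5.0
lambda_lp1: 1000.0
lambda_lp2: 1000.0
lambda_f: 1000.0
beta: 0.1
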