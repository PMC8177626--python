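schema: eyeplant-plant/1
rod_length_vertical_cm: 20.0
rod_length_lateral_cm: 28.0
chi_dyn: 0.02
chi_stat: 0.006
eps_stiction: 0.01
pretension: 0.05
dz_cm: 0.0
shift_via_points: true
dt: 0.01
n_substeps: 10
eye_radius_cm: 7.0
inertia_kgm2:
- - 0.0004759000000000001
  - -1.0000000000000002e-06
  - 1.11e-05
- - -1.0000000000000002e-06
  - 0.00043160000000000003
  - 0.0
- - 1.11e-05
  - 0.0
  - 0.0003956
muscles:
- name: MR
  q0_cm:
  - -0.7
  - 7.5
  - 0.0
  via_cm: null
  p0_cm:
  - -32.3
  - 14.0
  - 0.5
  kappa: 6.0
  driver: 2
  sin_sign: -1.0
  cos_sign: -1.0
  cos_axis: 1
  rod_length_cm: 28.0
- name: LR
  q0_cm:
  - -0.7
  - -7.5
  - 0.0
  via_cm: null
  p0_cm:
  - -32.3
  - -14.0
  - 0.5
  kappa: 6.0
  driver: 2
  sin_sign: 1.0
  cos_sign: 1.0
  cos_axis: 1
  rod_length_cm: 28.0
- name: SR
  q0_cm:
  - -0.7
  - 0.53
  - 5.3
  via_cm:
  - -20.6
  - -7.5
  - -5.3
  p0_cm:
  - -43.6
  - -8.4
  - -7.9
  kappa: 6.0
  driver: 1
  sin_sign: 1.0
  cos_sign: 1.0
  cos_axis: 2
  rod_length_cm: 20.0
- name: IR
  q0_cm:
  - -0.7
  - 0.53
  - -5.3
  via_cm:
  - -20.6
  - -7.5
  - 5.3
  p0_cm:
  - -43.6
  - -8.4
  - 12.1
  kappa: 6.0
  driver: 1
  sin_sign: -1.0
  cos_sign: -1.0
  cos_axis: 2
  rod_length_cm: 20.0
- name: SO
  q0_cm:
  - -0.7
  - -0.53
  - 5.3
  via_cm:
  - -15.0
  - 15.0
  - 6.3
  p0_cm:
  - -43.6
  - 8.4
  - 12.1
  kappa: 6.0
  driver: 3
  sin_sign: 1.0
  cos_sign: -1.0
  cos_axis: 2
  rod_length_cm: 20.0
- name: IO
  q0_cm:
  - -0.7
  - -0.53
  - -5.3
  via_cm:
  - -15.0
  - 15.0
  - -6.3
  p0_cm:
  - -43.6
  - 8.4
  - -7.9
  kappa: 6.0
  driver: 3
  sin_sign: -1.0
  cos_sign: 1.0
  cos_axis: 2
  rod_length_cm: 20.0
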