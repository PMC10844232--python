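name = "HBDI"
format = 1

[diabatic]
e_P0 = -0.018676595762290128
e_I0 = 0.018676595762290128
e_B0 = 2.5
t_PP = 0.118
t_PI = 0.42
t_IP = 0.33
t_II = 0.052
t_BP = 0.4
t_BI = 0.4
asym_I = 0.1
c_P = 0.8
c_I = 0.9
k_theta = 2.0
k_bla = 30.0
r_P = -0.025
r_I = 0.025
r_B = 0.0
v_PI0 = -0.987568381430364
v_PB0 = 0.51
v_IB0 = 0.51
b_P = 0.05
asym_twist = 1.8
b_I = 0.05

[inertia]
inertia_P = 89.2
inertia_I = 259.3
mass_theta = 1.3
mass_bla = 6.0

[reference]
e0 = -1.1219838012160024
spectral_shift = 0.379
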