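11
synthetic idealized phenolate ring (HBDI-) for rigid-rotor inertia; axis C1-C4
C    -1.400000     0.000000     0.000000
C    -0.700000    -1.212436     0.000000
C     0.700000    -1.212436     0.000000
C     1.400000    -0.000000     0.000000
C     0.700000     1.212436     0.000000
C    -0.700000     1.212436     0.000000
O     2.660000    -0.000000     0.000000
H    -1.240000    -2.147743     0.000000
H     1.240000    -2.147743     0.000000
H     1.240000     2.147743     0.000000
H    -1.240000     2.147743     0.000000
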