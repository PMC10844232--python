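14
synthetic idealized 2,3-dimethylimidazolinone ring for rigid-rotor inertia; axis C-attach to across
C    -1.190911     0.000000     0.000000
N    -0.368012    -1.132624     0.000000
C     0.963467    -0.700000     0.000000
N     0.963467     0.700000     0.000000
C    -0.368012     1.132624     0.000000
O    -0.745013     2.292913     0.000000
C    -0.819177    -2.521166     0.000000
H    -0.319177    -3.071166     0.900000
H    -0.319177    -3.071166    -0.900000
H    -1.419177    -3.071166     0.000000
C     2.144632     1.558166     0.000000
H     2.644632     2.108166     0.900000
H     2.644632     2.108166    -0.900000
H     1.544632     2.108166     0.000000
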