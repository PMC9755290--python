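label,x_mm,y_mm,z_mm
Fp1,-29.44,83.92,-6.99
Fp2,29.87,84.90,-7.08
F7,-70.26,42.47,-11.42
F3,-50.24,53.11,42.19
Fz,0.31,58.51,66.46
F4,51.84,54.30,40.81
F8,73.04,44.42,-12.00
T3,-84.16,-16.02,-9.35
C3,-65.36,-11.63,64.36
Cz,0.40,-9.17,100.24
C4,67.12,-10.90,63.58
T4,85.08,-15.02,-9.49
T5,-72.43,-73.45,-2.49
P3,-53.01,-78.79,55.94
Pz,0.32,-81.11,82.62
P4,55.67,-78.56,56.56
T6,73.06,-73.07,-2.54
O1,-29.41,-112.45,8.84
O2,29.84,-112.16,8.80
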