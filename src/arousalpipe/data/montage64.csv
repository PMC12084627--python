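name,x,y
Fp1,-0.54591,1.55626
Fz,0.00385,0.72187
F3,-0.71979,0.76087
F7,-1.46254,0.88411
FT9,-2.07367,0.35929
FC5,-1.23655,0.29856
FC1,-0.39093,0.29853
C3,-0.78851,-0.14033
T7,-1.64984,-0.31402
TP9,-1.76567,-0.95924
CP5,-1.07638,-0.62954
CP1,-0.34511,-0.45958
Pz,0.00311,-0.77623
P3,-0.57966,-0.86159
P7,-1.11986,-1.13561
O1,-0.37829,-1.44624
Oz,0.00135,-1.44391
O2,0.38445,-1.44484
P4,0.60109,-0.84829
P8,1.12800,-1.12820
TP10,1.76242,-0.96209
CP6,1.09735,-0.60715
CP2,0.37291,-0.45733
Cz,0.00399,-0.09119
C4,0.80837,-0.13128
T8,1.65461,-0.29211
FT10,2.07546,0.35444
FC6,1.24269,0.31149
FC2,0.40302,0.30632
F4,0.74077,0.77604
F8,1.46124,0.88867
Fp2,0.54744,1.55580
AF7,-1.05604,1.32048
AF3,-0.53140,1.21159
AFz,0.00331,1.15755
F1,-0.35171,0.72823
F5,-1.09323,0.81460
FT7,-1.68028,0.29373
FC3,-0.80322,0.30318
C1,-0.38160,-0.10537
C5,-1.20937,-0.20728
TP7,-1.44485,-0.78385
CP3,-0.70585,-0.52208
P1,-0.28387,-0.79867
P5,-0.85893,-0.97407
PO7,-0.75767,-1.34744
PO3,-0.42116,-1.16334
POz,0.00234,-1.11092
PO4,0.42621,-1.16860
PO8,0.76605,-1.34345
P6,0.86774,-0.97021
P2,0.31179,-0.78619
CPz,0.00362,-0.44417
CP4,0.73080,-0.51166
TP8,1.45136,-0.77269
C6,1.22348,-0.18730
C2,0.40143,-0.10255
FC4,0.81802,0.31152
FT8,1.67655,0.31592
F6,1.11174,0.81570
AF8,1.05642,1.32010
AF4,0.55091,1.19903
F2,0.37716,0.73608
FCz,0.00411,0.29960
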