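state,AR,AW,AN,AF,BR,BW,BN,BF,CR,CW,CN,CF,DR,DW,DN,DF,ER,EW,EN,EF
AR,0.2087,0.1896,0.1133,0.0496,0.0005,0.0001,0.0001,0.0000,0.0011,0.0005,0.0002,0.0002,0.0002,0.0001,0.0000,0.0000,0.0359,0.0216,0.0108,0.0036
AW,0.0092,0.3280,0.1181,0.0248,0.0005,0.0001,0.0001,0.0000,0.0011,0.0005,0.0002,0.0002,0.0002,0.0001,0.0000,0.0000,0.0359,0.0216,0.0108,0.0036
AN,0.0669,0.1642,0.2764,0.0521,0.0005,0.0001,0.0001,0.0000,0.0011,0.0005,0.0002,0.0002,0.0002,0.0001,0.0000,0.0000,0.0359,0.0216,0.0108,0.0036
AF,0.0779,0.0577,0.1383,0.2860,0.0005,0.0001,0.0001,0.0000,0.0011,0.0005,0.0002,0.0002,0.0002,0.0001,0.0000,0.0000,0.0359,0.0216,0.0108,0.0036
BR,0.0005,0.0005,0.0003,0.0001,0.2348,0.1596,0.0758,0.0267,0.0013,0.0006,0.0003,0.0002,0.0001,0.0001,0.0000,0.0000,0.0414,0.0237,0.0118,0.0039
BW,0.0005,0.0005,0.0003,0.0001,0.0915,0.2786,0.0746,0.0199,0.0013,0.0006,0.0003,0.0002,0.0001,0.0001,0.0000,0.0000,0.0414,0.0237,0.0118,0.0039
BN,0.0005,0.0005,0.0003,0.0001,0.0558,0.1304,0.2963,0.0561,0.0013,0.0006,0.0003,0.0002,0.0001,0.0001,0.0000,0.0000,0.0414,0.0237,0.0118,0.0039
BF,0.0005,0.0005,0.0003,0.0001,0.0748,0.0505,0.1115,0.3024,0.0013,0.0006,0.0003,0.0002,0.0001,0.0001,0.0000,0.0000,0.0414,0.0237,0.0118,0.0039
CR,0.0001,0.0001,0.0001,0.0000,0.0003,0.0001,0.0001,0.0000,0.4834,0.1190,0.0552,0.0330,0.0275,0.0072,0.0036,0.0018,0.0331,0.0189,0.0094,0.0031
CW,0.0001,0.0001,0.0001,0.0000,0.0003,0.0001,0.0001,0.0000,0.2341,0.3129,0.0622,0.0214,0.0275,0.0072,0.0036,0.0018,0.0331,0.0189,0.0094,0.0031
CN,0.0001,0.0001,0.0001,0.0000,0.0003,0.0001,0.0001,0.0000,0.1272,0.1297,0.3580,0.0723,0.0275,0.0072,0.0036,0.0018,0.0331,0.0189,0.0094,0.0031
CF,0.0001,0.0001,0.0001,0.0000,0.0003,0.0001,0.0001,0.0000,0.1730,0.0731,0.1175,0.3236,0.0275,0.0072,0.0036,0.0018,0.0331,0.0189,0.0094,0.0031
DR,0.0000,0.0000,0.0000,0.0000,0.0001,0.0000,0.0000,0.0000,0.0007,0.0003,0.0001,0.0001,0.6591,0.1142,0.0422,0.0235,0.0840,0.0504,0.0252,0.0084
DW,0.0000,0.0000,0.0000,0.0000,0.0001,0.0000,0.0000,0.0000,0.0007,0.0003,0.0001,0.0001,0.3022,0.3787,0.0503,0.0220,0.0840,0.0504,0.0252,0.0084
DN,0.0000,0.0000,0.0000,0.0000,0.0001,0.0000,0.0000,0.0000,0.0007,0.0003,0.0001,0.0001,0.2052,0.1350,0.4357,0.0452,0.0840,0.0504,0.0252,0.0084
DF,0.0000,0.0000,0.0000,0.0000,0.0001,0.0000,0.0000,0.0000,0.0007,0.0003,0.0001,0.0001,0.2477,0.0639,0.1156,0.4514,0.0840,0.0504,0.0252,0.0084
ER,0.0014,0.0013,0.0008,0.0004,0.0012,0.0003,0.0002,0.0001,0.0011,0.0005,0.0002,0.0002,0.0250,0.0065,0.0032,0.0011,0.4126,0.2027,0.0894,0.0292
EW,0.0014,0.0013,0.0008,0.0004,0.0012,0.0003,0.0002,0.0001,0.0011,0.0005,0.0002,0.0002,0.0250,0.0065,0.0032,0.0011,0.2196,0.3492,0.0898,0.0634
EN,0.0014,0.0013,0.0008,0.0004,0.0012,0.0003,0.0002,0.0001,0.0011,0.0005,0.0002,0.0002,0.0250,0.0065,0.0032,0.0011,0.1098,0.2026,0.2812,0.0686
EF,0.0014,0.0013,0.0008,0.0004,0.0012,0.0003,0.0002,0.0001,0.0011,0.0005,0.0002,0.0002,0.0250,0.0065,0.0032,0.0011,0.1317,0.1040,0.1341,0.2898
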