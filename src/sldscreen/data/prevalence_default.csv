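scenario,F1,F2,F3,F4,F5,F6,F7,F8,F9,F10
S3,0.45,0.64,0.52,0.32,0.39,0.59,0.48,0.41,0.39,0.36
S4,0.57,0.59,0.45,0.32,0.41,0.59,0.57,0.39,0.30,0.32
S5,0.43,0.55,0.41,0.23,0.43,0.61,0.48,0.27,0.25,0.32
S6,0.41,0.34,0.25,0.18,0.36,0.55,0.43,0.23,0.07,0.30
S7,0.48,0.39,0.34,0.20,0.36,0.50,0.39,0.30,0.20,0.30
S9,0.57,0.43,0.30,0.20,0.32,0.48,0.41,0.23,0.16,0.20
S11,0.43,0.39,0.32,0.14,0.32,0.59,0.55,0.32,0.18,0.32
S12,0.45,0.55,0.41,0.18,0.36,0.55,0.61,0.41,0.07,0.32
S13,0.55,0.36,0.25,0.02,0.36,0.48,0.30,0.25,0.02,0.23
S14,0.36,0.41,0.18,0.11,0.23,0.34,0.20,0.11,0.07,0.11
S15,0.64,0.57,0.32,0.36,0.52,0.64,0.57,0.32,0.30,0.20
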