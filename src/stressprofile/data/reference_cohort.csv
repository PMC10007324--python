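subject,rsi_pre,rsi_post
S1,0.124,0.326
S2,0.180,0.148
S3,0.217,0.369
S4,0.136,0.112
S5,0.381,0.407
S6,0.305,0.273
S7,0.267,1.000
S8,0.185,0.134
S9,0.221,0.274
S10,0.183,0.201
S11,0.310,0.223
S12,0.148,0.161
S13,0.349,0.120
S14,0.133,0.463
S15,0.161,0.172
S16,0.199,0.359
S17,0.271,0.200
S18,0.241,0.671
S19,0.368,0.515
S20,0.169,0.492
S21,0.255,0.297
S22,0.367,0.164
S23,0.388,0.327
S24,0.336,0.169
S25,0.165,0.410
S26,0.585,0.324
S27,0.301,0.273
S28,0.259,0.343
S29,0.335,0.384
S30,0.200,0.526
S31,0.168,0.456
S32,0.221,0.274
S33,0.210,0.481
S34,0.299,0.220
S35,0.161,0.254
S36,0.269,0.284
S37,0.145,0.169
S38,0.173,0.231
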