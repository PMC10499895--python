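patient,delta12,delta23,delta34,delta45,slope,r_squared,efficiency
3766,3.52,3.28,3.60,3.19,-3.418,0.999,0.961
4946,3.24,3.39,3.30,3.43,-3.334,0.995,0.995
6255,3.44,3.01,3.53,3.37,-3.317,0.999,1.002
7236,3.53,3.16,3.37,2.13,-3.160,0.993,1.072
7533,3.26,3.37,3.10,3.41,-3.257,0.979,1.028
7601,3.37,3.44,3.89,2.15,-3.375,0.988,0.978
7979,3.40,3.18,3.20,3.22,-3.242,0.998,1.035
ML2764,3.41,3.02,2.88,2.82,-3.039,0.996,1.133
ML4316,3.45,3.05,3.76,2.16,-3.226,0.990,1.042
ML4863,3.49,3.24,3.47,2.96,-3.302,0.997,1.008
ML9516,3.54,3.41,2.55,2.73,-3.042,0.994,1.132
ML11220,3.38,3.55,3.03,2.42,-3.118,0.993,1.093
ML11358,3.33,3.31,3.01,2.91,-3.144,0.989,1.080
ML11543,3.62,3.61,2.93,3.38,-3.361,0.994,0.984
ML13772,3.59,3.57,3.17,,-3.456,0.994,0.947
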