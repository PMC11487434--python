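model,Observe1,Observe2,Observe3,Automatic
1,3.57,2.69,3.11,2.62
2,12.85,12.33,12.12,11.70
3,11.31,10.85,11.87,11.40
4,12.38,12.78,10.53,11.35
5,8.95,8.81,9.23,8.99
6,7.44,7.47,7.08,6.20
7,2.44,2.64,1.92,2.01
8,2.46,3.57,3.20,2.67
9,2.20,2.30,1.67,2.09
10,2.34,1.94,1.36,2.19
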