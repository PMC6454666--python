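patient_id,SVM,L1-LR,CART,GRACE,label
1,0.7434,0.6032,0.6716,201,1
2,0.1250,0.1884,0.1890,85,0
3,0.2651,0.1798,0.1890,56,0
4,0.1735,0.3272,0.3277,92,0
5,0.1608,0.3347,0.3277,119,0
6,0.7260,0.6531,0.6716,132,0
7,0.1601,0.3104,0.3346,133,1
8,0.1171,0.1927,0.1890,137,0
9,0.4829,0.3041,0.3346,92,1
10,0.1743,0.2050,0.3277,97,0
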