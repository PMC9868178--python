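id,weight_kg,bg_mg_dl,sws_m_s,sws_sd,pr_m_s,pr_sd,suv,suv_sd
3,3.6,107,1.45,0.11,1.04,0.33,2.50,0.21
1,2.6,178,1.65,0.16,1.16,0.26,2.26,0.36
15,3.5,168,1.60,0.15,0.99,0.31,3.06,0.28
4,3.0,139,1.51,0.14,0.96,0.23,2.34,0.37
9,3.5,154,1.70,0.17,1.01,0.35,3.00,0.36
16,3.3,187,1.56,0.13,0.87,0.24,2.88,0.21
4b,3.4,140,1.39,0.10,0.84,0.22,2.73,0.18
5,3.4,158,1.41,0.13,0.88,0.28,2.74,0.16
2,3.1,184,1.70,0.12,1.21,0.39,2.82,0.10
22,3.2,132,1.65,0.14,1.06,0.29,2.89,0.18
13,3.6,191,1.64,0.16,1.03,0.28,,
7,3.2,150,1.69,0.12,1.03,0.30,,
6,3.5,135,1.57,0.15,1.09,0.44,,
14,2.9,159,1.56,0.11,1.03,0.38,,
12,3.1,123,1.64,0.12,1.02,0.29,,
8,2.9,144,1.55,0.16,0.83,0.29,,
18,3.2,,1.68,0.11,0.99,0.35,,
17,3.2,,1.71,0.16,1.00,0.44,,
19,3.2,,1.51,0.14,0.80,0.18,,
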