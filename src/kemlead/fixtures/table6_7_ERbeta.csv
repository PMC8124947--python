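ligand_id,ic50_nM,ic50_err_nM,pose_type,avg_ie,fitness,gold_rank,rmsd
15,2.52,1.3,1,-40.33,57.10,1,0.399
15,2.52,1.3,2,-30.44,52.58,3,3.526
15,2.52,1.3,3,-41.90,55.11,2,1.219
15,2.52,1.3,4,-25.86,51.85,4,3.185
25,2.8,0.1,1,-64.69,50.76,3,0.161
25,2.8,0.1,2,-54.59,49.80,6,3.430
25,2.8,0.1,3,-57.96,50.73,4,1.100
25,2.8,0.1,4,-48.19,51.87,1,3.155
27,2.3,0.1,1,-49.90,49.68,7,0.276
27,2.3,0.1,2,-56.42,50.17,3,3.570
27,2.3,0.1,3,-43.79,50.02,5,1.027
27,2.3,0.1,4,-50.99,53.05,1,3.189
29,1.4,0.6,1,-58.45,52.28,3,0.149
29,1.4,0.6,2,-37.37,51.88,5,3.390
29,1.4,0.6,3,-42.65,51.99,4,0.978
29,1.4,0.6,4,-50.74,55.15,1,3.190
40,1.6,0.7,1,-52.07,53.38,1,0.371
40,1.6,0.7,2,-52.03,49.54,7,3.452
40,1.6,0.7,3,-49.17,52.11,3,1.044
40,1.6,0.7,4,-41.80,52.68,2,3.193
44,2.3,1.7,1,-53.64,55.86,1,0.329
44,2.3,1.7,2,-42.58,49.53,5,3.515
44,2.3,1.7,3,-54.89,54.53,3,1.122
44,2.3,1.7,4,-24.37,52.34,4,3.221
57,0.5,0.5,1,-69.15,55.29,1,0.239
57,0.5,0.5,2,-36.44,47.02,9,3.499
57,0.5,0.5,3,-51.64,52.72,3,1.117
57,0.5,0.5,4,-21.68,49.41,5,3.227
62,2.1,0.9,1,-56.79,55.28,1,0.147
62,2.1,0.9,2,-26.68,53.51,5,3.420
62,2.1,0.9,3,-40.83,55.12,3,1.040
62,2.1,0.9,4,-38.80,49.52,11,3.380
68,1.2,0.7,1,-47.56,56.13,1,0.099
68,1.2,0.7,2,-2.31,47.19,9,3.393
68,1.2,0.7,3,-39.92,55.18,3,0.992
68,1.2,0.7,4,-19.58,45.38,11,3.255
70,1.1,1.6,1,-47.88,53.93,2,0.153
70,1.1,1.6,2,-38.95,51.50,7,3.147
70,1.1,1.6,3,-63.55,54.13,1,1.100
70,1.1,1.6,4,-28.36,50.32,10,3.434
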