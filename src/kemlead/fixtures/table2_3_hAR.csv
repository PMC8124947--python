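ligand_id,ic50_nM,ic50_err_nM,pose_type,avg_ie,fitness,gold_rank,rmsd
10,176,,1,-107.67,76.93,1,0.223
10,176,,2,2.35,58.51,19,2.042
16,44,,1,-89.93,80.56,1,0.263
16,44,,2,-18.68,72.97,4,2.563
19,30,,1,-121.11,87.08,1,0.137
19,30,,2,18.24,76.64,2,2.128
24,7,,1,-98.39,77.90,2,0.943
24,7,,2,-33.42,82.73,1,2.342
25,6,,1,-100.45,73.76,2,1.180
25,6,,2,-19.97,74.75,1,2.603
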