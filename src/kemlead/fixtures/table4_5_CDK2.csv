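ligand_id,ic50_nM,ic50_err_nM,pose_type,avg_ie,fitness,gold_rank,rmsd
3,5.4,1.0,1,-434.26,67.87,1,0.832
3,5.4,1.0,2,-422.08,63.07,2,4.072
3,5.4,1.0,3,-299.76,60.32,3,3.212
25,69,1,1,-304.97,62.98,1,0.944
25,69,1,2,-258.26,59.74,2,4.379
25,69,1,3,-219.28,55.47,3,2.947
28,7.0,0.1,1,-433.67,68.88,1,0.844
28,7.0,0.1,3,-334.16,56.93,10,3.221
29,56,20,1,-434.11,73.24,1,0.798
29,56,20,2,-376.89,59.73,4,3.797
29,56,20,3,-376.57,55.92,11,2.752
30,63,7,1,-398.53,66.33,1,0.811
30,63,7,2,-498.35,66.16,3,3.454
30,63,7,3,-362.61,54.99,12,2.950
33,210,40,1,-432.88,66.71,1,0.567
33,210,40,2,-414.07,63.00,4,3.680
33,210,40,3,-317.21,56.66,14,2.908
34,64,33,1,-418.00,64.60,1,0.975
34,64,33,2,-334.12,59.39,2,3.330
34,64,33,3,,55.37,6,2.875
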