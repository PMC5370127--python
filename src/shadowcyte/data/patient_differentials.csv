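sample_id,test_neu,test_mon,test_lym,ref_neu,ref_mon,ref_lym
1,61.2,21.8,17.7,68.5,11.2,20.3
2,55.2,15.1,29.7,52.6,4.9,42.5
3,67.4,5.7,27,68,5.7,26.3
4,56,6.67,37.33,55.2,9,35.8
5,66.35,11.85,21.8,60.8,4.8,34.4
6,62.77,11.7,25.53,58.9,5.6,35.5
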