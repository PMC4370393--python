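primer,sequence,n_bands,n_polymorphic,pct_polymorphic,mean_pic,mi,shannon_h
3A01,(GA)8TC,19,19,100,0.2041,3.8779,0.3171
3A21,(CA)7GTA,22,21,95.4,0.2071,4.3491,0.3351
3A42,(GACA)4C,18,17,94,0.1597,2.7149,0.2779
3A54,(AG)8GT,18,18,100,0.2458,4.4244,0.3758
3A62,(TG)7ACT,16,15,93.7,0.1703,2.5545,0.2865
3A07,(TG)7ACC,17,17,100,0.2232,3.7944,0.3858
3A39,(AG)7CTT,20,20,100,0.2783,5.566,0.3526
3A53,(AG)8CA,10,9,90,0.2332,2.0988,0.3452
3A56,(TG)7ACG,19,19,100,0.2394,4.5486,0.3719
UBC873,(GACA)4,21,21,100,0.194,4.074,0.3237
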