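id,name,icrp_id,density_mg_cm3,wH,wC,wN,wO,wP,wCa
0,air,0,1,0.0,0.0,70.0,30.0,0.0,0.0
1,cranium_cortical,26,1920,3.6,15.9,4.2,44.8,9.4,21.3
2,cranium_spongiosa,27,1245,8.1,31.7,2.8,45.1,3.7,7.8
3,mandible_cortical,39,1920,3.6,15.9,4.2,44.8,9.4,21.3
4,mandible_spongiosa,40,1189,8.7,35.7,2.6,42.9,3.0,6.3
5,cervical_spine_cortical,47,1920,3.6,15.9,4.2,44.8,9.4,21.3
6,cervical_spine_spongiosa,48,1135,9.2,35.1,2.9,45.8,2.1,4.3
8,residual_tissue_head,116,950,11.4,58.9,0.7,28.7,0.0,0.0
9,skin_head,122,1090,10.0,19.9,4.2,65.0,0.1,0.0
10,tooth,128,2750,2.2,9.5,2.9,42.1,13.7,28.9
11,air_inside_body,140,1,0.0,0.0,70.0,30.0,0.0,0.0
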