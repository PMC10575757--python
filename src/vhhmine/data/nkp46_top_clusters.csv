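rank_enriched,rank_frequent,kd_nm,cdr1,cdr2,cdr3
1,,1.1,GGTFGNYAIS,RGGGSTAA,AGGMGSTTVVVSTIPYKY
2,,8.6,GFTFSSYAIS,SSGSNTAA,VFTPTDTVVFTNKEPYNY
3,,31.7,GFTFGNYAIS,SSGDSTAA,VEADSSEVVFLSPHIYQY
4,4,2.3,GRTFGNYAIS,RSGGSTAA,NPATSTVLIVRDLGYAY
5,5,1.7,GFTFSSYAIS,GSGDSTAA,DQQPPSVAVVAARGYRY
,3,3.1,GFTFSDYAIS,SSGGNTAT,SLTYDQTTVYVSPLAYVD
,2,4.0,GRTLSSYVIS,SSGDRTAA,ALAPSGTLVVVSPLGYTY
,1,19.8,GRTFSSYAIS,SSGGSTAA,IRTPAESQVIVTLDWYRY
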