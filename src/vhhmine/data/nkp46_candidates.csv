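candidate_id,cluster_group,source,kd_nm,nll,cdr1,cdr2,cdr3
1,1,sampled,5.3,4.9,GRTFSNYAIS,RGGDNTAA,VFTPTDTVVFINKEPYNY
2,1,ngs,7.4,4.8,GFTFSSYAIS,SSGSNTAA,VFTPTDTVVFTNKGPYNY
3,1,sampled,8.1,6.2,GRTFSSYAIS,RGGDNTAA,VFTPTDTVVFINKESYNY
4,1,ngs,8.6,2.9,GFTFSSYAIS,SSGSNTAA,VFTPTDTVVFTNKEPYNY
5,1,ngs,9.4,2.5,GFTFSSYAIS,SGGDSTAA,VFTPTDTVVFTNKEPYNY
6,1,sampled,11.3,2.5,GFTFSSYAIS,SSGGSTAA,VFTPTDTVVFTNKEPYNY
7,1,ngs,11.7,2.8,GRTFSSYAIS,SSGGSTAA,VFTPTDTVVFTNKEPYNY
8,1,sampled,13.9,2.7,GFTLSSYAIS,SGGGSTAA,VFTPTDTVVFTNKEPYNY
9,1,sampled,21.9,20.8,GGTFSIYAIS,RGGSNTAA,VFTPTDTVVFINKERYNY
10,2,sampled,0.1,2.4,GGTFGSYAIS,RSGGSTAA,AGGMGSTTVVVSTIPYKY
11,2,ngs,0.8,2.3,GGTFSSYAIS,SSGGSTAA,AGGMGSTTVVVSTIPYKY
12,2,ngs,1.1,2.8,GGTFGNYAIS,RGGGSTAA,AGGMGSTTVVVSTIPYKY
13,2,ngs,1.3,2.3,GGTFSSYAIS,RSGGSTAA,AGGMGSTTVVVSTIPYKY
14,2,sampled,1.5,2.6,GGTFSNYAIS,SSGGSTAA,AGGMGSTTVVVSTIPYKY
15,2,ngs,2.3,7.1,GRTFGSYAIS,SSGDSTAA,AGGIGSSTVVVSPIPYAY
16,2,ngs,4.0,8.4,GRTLSSYVIS,SSGDRTAA,ALAPSGTLVVVSPLGYTY
17,2,sampled,4.4,2.8,GGTFGNYAIS,RGGGSTAA,AGGIGSTTVVVSTIPYKY
18,2,sampled,,17.8,GGTFGNYAIS,RGGGSTAA,AGGMGSTTVVVSTIPPKY
19,2,sampled,,17.8,GGTFGNYAIS,RGGGSTAA,AGGMGSTTEVVSTIPYKY
20,3,sampled,2.1,3.6,GGTFSDAAIS,RSGDSTAA,NPATSEVLIVRDLGYAY
21,3,ngs,2.3,3.0,GRTFGNYAIS,RSGGSTAA,NPATSTVLIVRDLGYAY
22,3,sampled,4.9,3.2,GRTFSSYAIS,SSGGNTAA,NPATSTVLIVRDLGYAY
23,3,ngs,7.2,3.6,GRTFSSYAIS,SGGGNTAA,NPATSTVLIVRDLGYAY
24,3,sampled,7.3,3.0,GFTFSSYAIS,SSGGSTAA,NPATSEVLIVRDLGYAY
25,3,ngs,7.6,2.8,GFTFSDYAIS,SSGGSTAA,NPATSTVLIVRDLGYAY
26,3,ngs,7.9,5.5,GFTFGNYAIS,RSGSSTAA,NPATSRVIIVRDLGYAY
27,3,ngs,8.0,7.2,GLTFSSYAIS,GSGDNTAA,NPATSRVIIVRELGYAY
28,3,sampled,15.5,18.7,GFTLSDYVIS,SSGGNTAA,NEATSEVLIVRDLGYAY
29,4,ngs,0.8,5.8,GRTLGNYAIS,WGGSRTAT,SLTYDQTTVYVSPLAYVD
30,4,ngs,1.3,5.0,GRTFSNYAIS,GGGGNTAT,SLTYDQTTVYVSPLAYGD
31,4,sampled,2.0,3.5,GRTLSNYAIS,SSGGSTAT,SLTYDQTTVYVSPLAYVD
32,4,sampled,2.1,4.6,GRTLSNYAIS,SGGSNTAT,SLTYDQTTVYVSPLAYVD
33,4,sampled,2.6,3.6,GRTFSSYAIS,WSGGSTAT,SLTYDQTTVYVSPLAYNN
34,4,ngs,2.8,3.8,GFTLSNYAIS,SSGDSTAT,SLTYDQTTVYVSPLAYVD
35,4,ngs,3.1,3.9,GFTFSDYAIS,SSGGNTAT,SLTYDQTTVYVSPLAYVD
36,4,ngs,3.4,3.3,GRTFSSYAIS,SSGGSTAT,SLTYDQTTVYVSPLAYVD
37,4,ngs,4.7,4.3,GFTFSSYAIS,WSGGRTAT,SLTYDQTTVYVSPLAYNN
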