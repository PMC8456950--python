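compound_id,target,ki_um,ki_sem_um,kb_um,ec50_um,emax_pct,displacement_pct
2,A2AAR,1.2,0.1,,,,
2,D2R,0.90,0.08,,9.7,93,
3,A2AAR,5.6,0.9,,,,
3,D2R,0.29,0.03,,,,
4,A2AAR,8.4,1.3,,,,
4,D2R,0.33,0.03,,,,
12,A2AAR,8.1,3.8,,,,
12,D2R,,,,,,1
13,A2AAR,,,,,,5
13,D2R,5.0,1.3,,,,
18,A2AAR,0.37,0.05,,,,
18,D2R,0.39,0.03,,26,89,
19,A2AAR,0.42,0.04,,,,
19,D2R,0.51,0.05,,23,82,
20,A2AAR,0.19,0.03,0.32,,,
20,D2R,0.34,0.03,,1.5,62,
21,A2AAR,0.63,0.08,,,,
21,D2R,0.33,0.02,,,,
22,A2AAR,0.34,0.05,,,,
22,D2R,0.34,0.04,,2.5,119,
23,A2AAR,2.9,0.6,,,,
23,D2R,0.20,0.02,,,,
24,A2AAR,11,3,,,,
24,D2R,0.82,0.18,,,,
25,A2AAR,0.99,0.24,,,,
25,D2R,0.34,0.04,,0.75,81,
26,A2AAR,0.61,0.09,3.6,,,
26,D2R,0.23,0.02,,0.99,94,
27,A2AAR,0.39,0.05,0.51,,,
27,D2R,0.53,0.18,,0.18,89,
28,A2AAR,0.47,0.11,,,,
28,D2R,0.90,0.10,,1.2,104,
29,A2AAR,0.46,0.04,1.9,,,
29,D2R,0.67,0.07,,0.98,105,
30,A2AAR,0.16,0.03,0.72,,,
30,D2R,0.37,0.03,,0.18,77,
31,A2AAR,1.6,0.3,,,,
31,D2R,0.63,0.05,,5.2,88,
32,A2AAR,0.67,0.11,,,,
32,D2R,0.88,0.11,,1.2,51,
33,A2AAR,1.1,0.2,,,,
33,D2R,2.2,0.3,,5.0,81,
37,A2AAR,0.30,0.05,,,,
37,D2R,1.3,0.2,,31,103,
39,A2AAR,1.3,0.2,,,,
39,D2R,2.0,0.3,,28,107,
40,A2AAR,0.72,0.07,,,,
40,D2R,1.9,0.3,,8.9,105,
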