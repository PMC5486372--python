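patient,n_virtual_sensors,duration_min,ripple_location,spike_concordance,resection_concordance,ripple_times,channels_with_ripples,rate_per_min,spike_resection_concordance
1,2649,14.8,L frontal + occipital,=,,24,167,1.62,
2,2447,14.8,N,,,0,0,,+
3,2480,15.3,Bilateral frontal + some widespread,=,,42,816,2.75,
4,2384,15.1,R central,+,+,6,36,0.40,+
5,2224,14.4,N,,,0,0,,-
6,2061,10.0,R centro-temporal,+,,2,21,0.20,
7,2326,18.3,N,,,0,0,,
8,2454,15.6,N,,,0,0,,=
9,2275,8.6,R temporo-occipital,+,+,1,22,0.12,+
10,2363,17.1,N,,,0,0,,=
11,2227,15.0,R frontal + L temporal,=,-,8,55,0.53,=
12,2269,15.0,R frontal + R fronto-central,+,,15,112,1.00,
13,2768,9.6,R > L parieto-occipital,+,=,29,368,3.02,=
14,2436,14.6,L fronto-temporal + R occipital,-,,3,4,0.21,
15,2778,15.0,R temporal,+,+,13,97,0.87,+
16,2313,14.5,R temporal posterior,+,=,4,12,0.28,+
17,2321,15.0,R temporal posterior,-,,1,4,0.07,
18,2060,14.7,N,,,0,0,,
19,2450,15.2,Bilateral frontal,+,,12,260,0.79,
20,2364,5.7,N,,,0,0,,-
21,2463,13.6,R parieto-occipital + some widespread,+,,109,358,8.01,
22,2788,16.5,R parietal,+,=,16,285,0.97,=
23,2564,15.2,N,,,0,0,,+
24,2393,15.0,R central + L temporal + R occipital,=,-,2,19,0.13,-
25,2663,15.0,N,,,0,0,,+
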