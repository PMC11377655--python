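node_index,label,hemisphere,subsystem
0,lh.frontalpole,left,none
1,lh.lateralorbitofrontal,left,none
2,lh.medialorbitofrontal,left,DMN
3,lh.parsorbitalis,left,none
4,lh.parstriangularis,left,none
5,lh.parsopercularis,left,none
6,lh.rostralmiddlefrontal,left,none
7,lh.caudalmiddlefrontal,left,DMN
8,lh.superiorfrontal,left,none
9,lh.precentral,left,none
10,lh.paracentral,left,none
11,lh.rostralanteriorcingulate,left,DMN
12,lh.caudalanteriorcingulate,left,DMN
13,lh.posteriorcingulate,left,DMN
14,lh.isthmuscingulate,left,none
15,lh.postcentral,left,none
16,lh.supramarginal,left,none
17,lh.superiorparietal,left,none
18,lh.inferiorparietal,left,DMN
19,lh.precuneus,left,DMN
20,lh.cuneus,left,none
21,lh.pericalcarine,left,none
22,lh.lateraloccipital,left,none
23,lh.lingual,left,none
24,lh.fusiform,left,none
25,lh.inferiortemporal,left,none
26,lh.middletemporal,left,none
27,lh.superiortemporal,left,none
28,lh.transversetemporal,left,none
29,lh.bankssts,left,none
30,lh.temporalpole,left,none
31,lh.entorhinal,left,MTL
32,lh.parahippocampal,left,MTL
33,lh.insula,left,none
34,Left-Thalamus-Proper,left,none
35,Left-Caudate,left,none
36,Left-Putamen,left,none
37,Left-Pallidum,left,none
38,Left-Accumbens-area,left,none
39,Left-Hippocampus,left,MTL
40,Left-Amygdala,left,none
41,Left-Cerebellum-Cortex,left,none
42,rh.frontalpole,right,none
43,rh.lateralorbitofrontal,right,none
44,rh.medialorbitofrontal,right,DMN
45,rh.parsorbitalis,right,none
46,rh.parstriangularis,right,none
47,rh.parsopercularis,right,none
48,rh.rostralmiddlefrontal,right,none
49,rh.caudalmiddlefrontal,right,DMN
50,rh.superiorfrontal,right,none
51,rh.precentral,right,none
52,rh.paracentral,right,none
53,rh.rostralanteriorcingulate,right,DMN
54,rh.caudalanteriorcingulate,right,DMN
55,rh.posteriorcingulate,right,DMN
56,rh.isthmuscingulate,right,none
57,rh.postcentral,right,none
58,rh.supramarginal,right,none
59,rh.superiorparietal,right,none
60,rh.inferiorparietal,right,DMN
61,rh.precuneus,right,DMN
62,rh.cuneus,right,none
63,rh.pericalcarine,right,none
64,rh.lateraloccipital,right,none
65,rh.lingual,right,none
66,rh.fusiform,right,none
67,rh.inferiortemporal,right,none
68,rh.middletemporal,right,none
69,rh.superiortemporal,right,none
70,rh.transversetemporal,right,none
71,rh.bankssts,right,none
72,rh.temporalpole,right,none
73,rh.entorhinal,right,MTL
74,rh.parahippocampal,right,MTL
75,rh.insula,right,none
76,Right-Thalamus-Proper,right,none
77,Right-Caudate,right,none
78,Right-Putamen,right,none
79,Right-Pallidum,right,none
80,Right-Accumbens-area,right,none
81,Right-Hippocampus,right,MTL
82,Right-Amygdala,right,none
83,Right-Cerebellum-Cortex,right,none
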