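label,hubness
lh.frontalpole,1.0
lh.lateralorbitofrontal,1.0
lh.medialorbitofrontal,1.0
lh.parsorbitalis,1.0
lh.parstriangularis,1.0
lh.parsopercularis,1.0
lh.rostralmiddlefrontal,1.3
lh.caudalmiddlefrontal,1.0
lh.superiorfrontal,1.8
lh.precentral,1.3
lh.paracentral,1.0
lh.rostralanteriorcingulate,1.0
lh.caudalanteriorcingulate,1.0
lh.posteriorcingulate,1.6
lh.isthmuscingulate,1.0
lh.postcentral,1.0
lh.supramarginal,1.0
lh.superiorparietal,1.4
lh.inferiorparietal,1.0
lh.precuneus,2.0
lh.cuneus,1.0
lh.pericalcarine,1.0
lh.lateraloccipital,1.2
lh.lingual,1.0
lh.fusiform,1.0
lh.inferiortemporal,1.0
lh.middletemporal,1.0
lh.superiortemporal,1.3
lh.transversetemporal,1.0
lh.bankssts,1.0
lh.temporalpole,1.0
lh.entorhinal,1.0
lh.parahippocampal,1.0
lh.insula,1.5
Left-Thalamus-Proper,2.5
Left-Caudate,1.0
Left-Putamen,1.6
Left-Pallidum,1.0
Left-Accumbens-area,1.0
Left-Hippocampus,2.2
Left-Amygdala,1.0
Left-Cerebellum-Cortex,1.0
rh.frontalpole,1.0
rh.lateralorbitofrontal,1.0
rh.medialorbitofrontal,1.0
rh.parsorbitalis,1.0
rh.parstriangularis,1.0
rh.parsopercularis,1.0
rh.rostralmiddlefrontal,1.3
rh.caudalmiddlefrontal,1.0
rh.superiorfrontal,1.8
rh.precentral,1.3
rh.paracentral,1.0
rh.rostralanteriorcingulate,1.0
rh.caudalanteriorcingulate,1.0
rh.posteriorcingulate,1.6
rh.isthmuscingulate,1.0
rh.postcentral,1.0
rh.supramarginal,1.0
rh.superiorparietal,1.4
rh.inferiorparietal,1.0
rh.precuneus,2.0
rh.cuneus,1.0
rh.pericalcarine,1.0
rh.lateraloccipital,1.2
rh.lingual,1.0
rh.fusiform,1.0
rh.inferiortemporal,1.0
rh.middletemporal,1.0
rh.superiortemporal,1.3
rh.transversetemporal,1.0
rh.bankssts,1.0
rh.temporalpole,1.0
rh.entorhinal,1.0
rh.parahippocampal,1.0
rh.insula,1.5
Right-Thalamus-Proper,2.5
Right-Caudate,1.0
Right-Putamen,1.6
Right-Pallidum,1.0
Right-Accumbens-area,1.0
Right-Hippocampus,2.2
Right-Amygdala,1.0
Right-Cerebellum-Cortex,1.0
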