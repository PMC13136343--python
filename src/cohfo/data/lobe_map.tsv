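region	lobe
Hippocampus	limbic
Amygdala	limbic
Parahippocampal gyrus	limbic
Posterior cingulate cortex	limbic
Posterior cingulate gyrus	limbic
Superior frontal gyrus	frontal
Middle frontal gyrus	frontal
Inferior frontal gyrus	frontal
Precentral gyrus	frontal
Orbitofrontal cortex	frontal
Anterior cingulate cortex	frontal
Paracentral lobule	frontal
Superior parietal gyrus	parietal
Inferior parietal gyrus	parietal
Angular gyrus	parietal
Supramarginal gyrus	parietal
Postcentral gyrus	parietal
Precuneus	parietal
Superior temporal gyrus	temporal
Middle temporal gyrus	temporal
Inferior temporal gyrus	temporal
Temporal pole	temporal
Fusiform gyrus	temporal
Heschl gyrus	temporal
Calcarine cortex	occipital
Cuneus	occipital
Lingual gyrus	occipital
Superior occipital gyrus	occipital
Middle occipital gyrus	occipital
Inferior occipital gyrus	occipital
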