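region	lobe
Frontal Pole	frontal
Insular Cortex	insular-limbic
Superior Frontal Gyrus	frontal
Middle Frontal Gyrus	frontal
Inferior Frontal Gyrus, pars triangularis	frontal
Inferior Frontal Gyrus, pars opercularis	frontal
Precentral Gyrus	frontal
Temporal Pole	temporal
Superior Temporal Gyrus, anterior division	temporal
Superior Temporal Gyrus, posterior division	temporal
Middle Temporal Gyrus, anterior division	temporal
Middle Temporal Gyrus, posterior division	temporal
Middle Temporal Gyrus, temporooccipital part	temporal
Inferior Temporal Gyrus, anterior division	temporal
Inferior Temporal Gyrus, posterior division	temporal
Inferior Temporal Gyrus, temporooccipital part	temporal
Postcentral Gyrus	parietal
Superior Parietal Lobule	parietal
Supramarginal Gyrus, anterior division	parietal
Supramarginal Gyrus, posterior division	parietal
Angular Gyrus	parietal
Lateral Occipital Cortex, superior division	occipital
Lateral Occipital Cortex, inferior division	occipital
Intracalcarine Cortex	occipital
Frontal Medial Cortex	frontal
Juxtapositional Lobule Cortex	frontal
Subcallosal Cortex	insular-limbic
Paracingulate Gyrus	insular-limbic
Cingulate Gyrus, anterior division	insular-limbic
Cingulate Gyrus, posterior division	insular-limbic
Precuneous Cortex	parietal
Cuneal Cortex	occipital
Frontal Orbital Cortex	frontal
Parahippocampal Gyrus, anterior division	insular-limbic
Parahippocampal Gyrus, posterior division	insular-limbic
Lingual Gyrus	occipital
Temporal Fusiform Cortex, anterior division	temporal
Temporal Fusiform Cortex, posterior division	temporal
Temporal Occipital Fusiform Cortex	temporal
Occipital Fusiform Gyrus	occipital
Frontal Operculum Cortex	frontal
Central Opercular Cortex	frontal
Parietal Operculum Cortex	parietal
Planum Polare	temporal
Heschl's Gyrus	temporal
Planum Temporale	temporal
Supracalcarine Cortex	occipital
Occipital Pole	occipital
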