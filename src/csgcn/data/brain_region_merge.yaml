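# Example anatomical merge map: 13 brain region labels -> overarching
# groups (basal ganglia = caudate + nucleus accumbens + putamen;
# cerebellum = cerebellum + cerebellar hemisphere; cortex = cortex +
# frontal cortex BA9 + anterior cingulate cortex BA24).  Regions whose
# unique-edge lists are empty or too small simply yield empty/flagged
# groups.
amygdala: amygdala
anterior_cingulate_cortex_BA24: cortex
caudate: basal_ganglia
cerebellar_hemisphere: cerebellum
cerebellum: cerebellum
cortex: cortex
frontal_cortex_BA9: cortex
hippocampus: hippocampus
hypothalamus: hypothalamus
nucleus_accumbens: basal_ganglia
putamen: basal_ganglia
spinal_cord_cervical_c1: spinal_cord
substantia_nigra: substantia_nigra
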