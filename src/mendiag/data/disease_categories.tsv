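category	n_diseases
Neuromuscular system disease	870
Metabolic disease	547
Growth and development abnormal	522
Eye disease	344
Bone disease	299
Mental retardation and related syndromes	241
Skin disease	238
Circulatory system diseases	224
Immune and infectious diseases	203
Deafness and related syndromes	173
Blood disease	169
Endocrine system diseases	146
Urinary system disease	111
Reproductive system diseases	73
Digestive system diseases	72
Psychiatric and behavioral abnormal	51
Cancer and Tumor Syndrome	48
Respiratory system diseases	47
Oral disease	35
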