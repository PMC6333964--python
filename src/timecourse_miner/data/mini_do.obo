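format-version: 1.2
data-version: synthetic-mini/2024
ontology: doid
remark: Synthetic miniature Disease Ontology snapshot for tests and demos. Term names, DOIDs and is_a placement follow the public Human Disease Ontology; the term set is heavily down-sampled and the definitions are omitted. Not a substitute for doid.obo.

[Term]
id: DOID:4
name: disease

[Term]
id: DOID:0050117
name: disease by infectious agent
is_a: DOID:4 ! disease

[Term]
id: DOID:934
name: viral infectious disease
is_a: DOID:0050117 ! disease by infectious agent

[Term]
id: DOID:104
name: bacterial infectious disease
is_a: DOID:0050117 ! disease by infectious agent

[Term]
id: DOID:8469
name: influenza
synonym: "flu" EXACT []
synonym: "grippe" EXACT []
is_a: DOID:934 ! viral infectious disease

[Term]
id: DOID:2945
name: severe acute respiratory syndrome
synonym: "SARS" EXACT []
is_a: DOID:934 ! viral infectious disease

[Term]
id: DOID:552
name: pneumonia
is_a: DOID:0050117 ! disease by infectious agent
is_a: DOID:850 ! lung disease

[Term]
id: DOID:14566
name: disease of cellular proliferation
is_a: DOID:4 ! disease

[Term]
id: DOID:162
name: cancer
synonym: "malignant neoplasm" EXACT []
is_a: DOID:14566 ! disease of cellular proliferation

[Term]
id: DOID:10283
name: prostate cancer
synonym: "prostate neoplasm" RELATED []
is_a: DOID:162 ! cancer

[Term]
id: DOID:1612
name: breast cancer
synonym: "breast carcinoma" RELATED []
is_a: DOID:162 ! cancer

[Term]
id: DOID:9256
name: colorectal cancer
is_a: DOID:162 ! cancer

[Term]
id: DOID:1324
name: lung cancer
is_a: DOID:162 ! cancer

[Term]
id: DOID:1240
name: leukemia
is_a: DOID:162 ! cancer

[Term]
id: DOID:7
name: disease of anatomical entity
is_a: DOID:4 ! disease

[Term]
id: DOID:1579
name: respiratory system disease
is_a: DOID:7 ! disease of anatomical entity

[Term]
id: DOID:850
name: lung disease
is_a: DOID:1579 ! respiratory system disease

[Term]
id: DOID:3083
name: chronic obstructive pulmonary disease
synonym: "COPD" EXACT []
is_a: DOID:850 ! lung disease

[Term]
id: DOID:2841
name: asthma
is_a: DOID:850 ! lung disease

[Term]
id: DOID:0014667
name: disease of metabolism
is_a: DOID:4 ! disease

[Term]
id: DOID:9351
name: diabetes mellitus
is_a: DOID:0014667 ! disease of metabolism

[Term]
id: DOID:9352
name: type 2 diabetes mellitus
synonym: "T2DM" EXACT []
synonym: "NIDDM" RELATED []
is_a: DOID:9351 ! diabetes mellitus

[Term]
id: DOID:863
name: nervous system disease
is_a: DOID:7 ! disease of anatomical entity

[Term]
id: DOID:10652
name: Alzheimer's disease
synonym: "AD" EXACT []
is_a: DOID:863 ! nervous system disease

[Term]
id: DOID:1826
name: epilepsy
is_a: DOID:863 ! nervous system disease

[Term]
id: DOID:14330
name: Parkinson's disease
synonym: "paralysis agitans" EXACT []
is_a: DOID:863 ! nervous system disease

[Term]
id: DOID:1287
name: cardiovascular system disease
is_a: DOID:7 ! disease of anatomical entity

[Term]
id: DOID:114
name: heart disease
is_a: DOID:1287 ! cardiovascular system disease

[Term]
id: DOID:10763
name: hypertension
is_a: DOID:1287 ! cardiovascular system disease

[Term]
id: DOID:9999
name: influenza-like illness
is_obsolete: true
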