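group	pt
leukemias	Acute myeloid leukaemia
leukemias	Myelodysplastic syndrome
leukemias	Leukaemia
lymphomas	T-cell lymphoma
lymphomas	Lymphoma
lymphomas	Non-Hodgkin's lymphoma
plasma cell neoplasms	Plasma cell myeloma
plasma cell neoplasms	Plasma cell myeloma recurrent
plasma cell neoplasms	Plasmacytoma
skin neoplasms malignant and unspecified	Basal cell carcinoma
skin neoplasms malignant and unspecified	Squamous cell carcinoma of skin
skin neoplasms malignant and unspecified	Malignant melanoma
skin neoplasms malignant and unspecified	Bowen's disease
gastrointestinal neoplasms malignant and unspecified	Large intestine carcinoma
gastrointestinal neoplasms malignant and unspecified	Gastric cancer
gastrointestinal neoplasms malignant and unspecified	Colon cancer
miscellaneous and site unspecified neoplasms malignant and unspecified	Metastatic squamous cell carcinoma
miscellaneous and site unspecified neoplasms malignant and unspecified	Bladder cancer
miscellaneous and site unspecified neoplasms malignant and unspecified	Prostate cancer
miscellaneous and site unspecified neoplasms malignant and unspecified	Malignant neoplasm
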