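pt
Cytokine release syndrome
Immune effector cell-associated neurotoxicity syndrome
Neurotoxicity
Fatigue
Pyrexia
Hypogammaglobulinaemia
Febrile neutropenia
Neutropenia
Thrombocytopenia
Anaemia
Leukopenia
Lymphopenia
Infection
Pneumonia
Sepsis
Hypotension
Tachycardia
Headache
Encephalopathy
Tremor
Aphasia
Delirium
Diarrhoea
Nausea
Constipation
Vomiting
Oedema peripheral
Decreased appetite
Hypophosphataemia
Hypocalcaemia
Hypomagnesaemia
Haemophagocytic lymphohistiocytosis
Aspartate aminotransferase increased
Alanine aminotransferase increased
Chills
Cough
Dyspnoea
Arthralgia
Musculoskeletal pain
Dizziness
Insomnia
Hypoxia
Hypertension
Acute kidney injury
Pancytopenia
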