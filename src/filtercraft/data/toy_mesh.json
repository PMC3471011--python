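{
  "vocabulary_id": "toy_mesh",
  "descriptors": [
    {"name": "Kidney Diseases", "tree_numbers": ["C12.777"], "entry_terms": ["Kidney Disease", "Renal Disease"]},
    {"name": "Glomerulonephritis", "tree_numbers": ["C12.777.419"], "entry_terms": ["Bright Disease"]},
    {"name": "Anti-Glomerular Basement Membrane Disease", "tree_numbers": ["C12.777.419.050"], "entry_terms": ["Goodpasture Syndrome"]},
    {"name": "Glomerulonephritis, IGA", "tree_numbers": ["C12.777.419.428"], "entry_terms": ["IgA Nephropathy", "Berger Disease"]},
    {"name": "Glomerulonephritis, Membranoproliferative", "tree_numbers": ["C12.777.419.480"], "entry_terms": ["Membranoproliferative Glomerulonephritis"]},
    {"name": "Glomerulonephritis, Membranous", "tree_numbers": ["C12.777.419.570"], "entry_terms": ["Membranous Nephropathy"]},
    {"name": "Glomerulosclerosis, Focal Segmental", "tree_numbers": ["C12.777.419.600"], "entry_terms": ["Focal Segmental Glomerulosclerosis"]},
    {"name": "Lupus Nephritis", "tree_numbers": ["C12.777.419.630", "C17.300.480.500"], "entry_terms": ["Lupus Glomerulonephritis"]},
    {"name": "Nephritis, Hereditary", "tree_numbers": ["C12.777.540"], "entry_terms": ["Alport Syndrome"]},
    {"name": "Nephrosis", "tree_numbers": ["C12.777.620"], "entry_terms": []},
    {"name": "Nephrotic Syndrome", "tree_numbers": ["C12.777.620.500"], "entry_terms": []},
    {"name": "Renal Insufficiency, Chronic", "tree_numbers": ["C12.777.700"], "entry_terms": ["Chronic Kidney Disease"]},
    {"name": "Kidney Failure, Chronic", "tree_numbers": ["C12.777.700.500"], "entry_terms": ["End-Stage Renal Disease"]},
    {"name": "Diabetic Nephropathies", "tree_numbers": ["C12.777.300", "C19.246.099.500", "C14.907.320.500"], "entry_terms": ["Diabetic Kidney Disease", "Diabetic Nephropathy"]},
    {"name": "AIDS-Associated Nephropathy", "tree_numbers": ["C12.777.050"], "entry_terms": ["HIV-Associated Nephropathy"]},
    {"name": "Balkan Nephropathy", "tree_numbers": ["C12.777.100"], "entry_terms": ["Balkan Endemic Nephropathy"]},
    {"name": "Proteinuria", "tree_numbers": ["C12.888"], "entry_terms": []},
    {"name": "Albuminuria", "tree_numbers": ["C12.888.500"], "entry_terms": []},
    {"name": "Hematuria", "tree_numbers": ["C12.889"], "entry_terms": ["Haematuria"]},
    {"name": "Kidney Glomerulus", "tree_numbers": ["A05.810.437"], "entry_terms": ["Renal Glomerulus"]},
    {"name": "Lupus Erythematosus, Systemic", "tree_numbers": ["C17.300.480"], "entry_terms": ["SLE"]},
    {"name": "Vasculitis", "tree_numbers": ["C14.907.940"], "entry_terms": []},
    {"name": "Anti-Neutrophil Cytoplasmic Antibody-Associated Vasculitis", "tree_numbers": ["C14.907.940.090"], "entry_terms": ["ANCA-Associated Vasculitis"]},
    {"name": "Granulomatosis with Polyangiitis", "tree_numbers": ["C14.907.940.090.500"], "entry_terms": ["Wegener Granulomatosis"]},
    {"name": "Microscopic Polyangiitis", "tree_numbers": ["C14.907.940.090.600"], "entry_terms": []},
    {"name": "Purpura, Schoenlein-Henoch", "tree_numbers": ["C14.907.940.560"], "entry_terms": ["Henoch-Schoenlein Purpura", "Anaphylactoid Purpura"]},
    {"name": "Diabetes Complications", "tree_numbers": ["C19.246.099"], "entry_terms": []},
    {"name": "Diabetes Mellitus", "tree_numbers": ["C19.246"], "entry_terms": []},
    {"name": "Diabetes Mellitus, Type 2", "tree_numbers": ["C19.246.300"], "entry_terms": ["Non-Insulin-Dependent Diabetes Mellitus", "Type 2 Diabetes"]},
    {"name": "Diabetes Mellitus, Type 1", "tree_numbers": ["C19.246.200"], "entry_terms": ["Insulin-Dependent Diabetes Mellitus"]},
    {"name": "Diabetic Angiopathies", "tree_numbers": ["C14.907.320"], "entry_terms": []},
    {"name": "Biopsy", "tree_numbers": ["E01.370.225"], "entry_terms": []},
    {"name": "Amyloidosis", "tree_numbers": ["C18.452.845"], "entry_terms": []}
  ]
}
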