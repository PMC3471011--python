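{
  "vocabulary_id": "toy_emtree",
  "descriptors": [
    {"name": "kidney disease", "tree_numbers": ["K01"], "entry_terms": ["renal disease"]},
    {"name": "glomerulopathy", "tree_numbers": ["K01.300"], "entry_terms": ["glomerular disease"]},
    {"name": "glomerulonephritis", "tree_numbers": ["K01.300.400"], "entry_terms": []},
    {"name": "proliferative glomerulonephritis", "tree_numbers": ["K01.300.400.600"], "entry_terms": ["membranoproliferative glomerulonephritis"]},
    {"name": "immunoglobulin a nephropathy", "tree_numbers": ["K01.300.400.440"], "entry_terms": ["iga nephropathy", "berger disease"]},
    {"name": "membranous glomerulonephritis", "tree_numbers": ["K01.300.400.500"], "entry_terms": ["membranous nephropathy"]},
    {"name": "heymann nephritis", "tree_numbers": ["K01.300.400.420"], "entry_terms": []},
    {"name": "lupus erythematosus nephritis", "tree_numbers": ["K01.300.400.460"], "entry_terms": ["lupus nephritis"]},
    {"name": "focal glomerulosclerosis", "tree_numbers": ["K01.300.450"], "entry_terms": ["focal segmental glomerulosclerosis"]},
    {"name": "nephrotic syndrome", "tree_numbers": ["K01.300.700"], "entry_terms": []},
    {"name": "diabetic nephropathy", "tree_numbers": ["K01.300.200", "D01.500.200"], "entry_terms": ["diabetic kidney disease"]},
    {"name": "kidney failure", "tree_numbers": ["K01.500"], "entry_terms": ["renal failure"]},
    {"name": "chronic kidney failure", "tree_numbers": ["K01.500.300"], "entry_terms": ["end stage renal disease"]},
    {"name": "proteinuria", "tree_numbers": ["K01.700"], "entry_terms": []},
    {"name": "microalbuminuria", "tree_numbers": ["K01.700.400"], "entry_terms": []},
    {"name": "albuminuria", "tree_numbers": ["K01.700.200"], "entry_terms": []},
    {"name": "glomerulus", "tree_numbers": ["A01.400"], "entry_terms": ["kidney glomerulus"]},
    {"name": "vasculitis", "tree_numbers": ["V01"], "entry_terms": []},
    {"name": "anaphylactoid purpura", "tree_numbers": ["V01.200"], "entry_terms": ["henoch-schoenlein purpura"]},
    {"name": "wegener granulomatosis", "tree_numbers": ["V01.500"], "entry_terms": ["granulomatosis with polyangiitis"]},
    {"name": "microscopic polyangiitis", "tree_numbers": ["V01.300"], "entry_terms": []},
    {"name": "diabetes mellitus", "tree_numbers": ["D01"], "entry_terms": []},
    {"name": "non insulin dependent diabetes mellitus", "tree_numbers": ["D01.200"], "entry_terms": ["type 2 diabetes mellitus"]},
    {"name": "insulin dependent diabetes mellitus", "tree_numbers": ["D01.100"], "entry_terms": ["type 1 diabetes mellitus"]},
    {"name": "kidney biopsy", "tree_numbers": ["P01.300"], "entry_terms": ["renal biopsy"]},
    {"name": "amyloidosis", "tree_numbers": ["M01.100"], "entry_terms": []}
  ]
}
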