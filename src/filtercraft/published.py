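"""The six published glomerular-disease search filters as executable fixtures.

One filter per database (PubMed, Ovid Medline, Embase) and optimization goal
(high sensitivity, high specificity), stored verbatim as printed apart from
documented typesetting normalizations: typographic quotes rendered as ASCII,
runs of whitespace collapsed to single spaces.  Each string parses under its
dialect and survives a to_string/parse round trip.

`PUBLISHED_PERFORMANCE` records the printed performance rows (percent, with
95% CIs elided) for the consistency checks that remain possible without the
licensed labeled corpus — e.g. recovering a row's accuracy from its
sensitivity/specificity/precision via the implied prevalence.
"""

from __future__ import annotations

from .parsers import parse
from .queryast import Query

PUBMED_HIGH_SENSITIVITY = (
    '(nephropath*[tw] OR glomerulonephrit*[tw] OR proteinuri*[tw] OR '
    'nephrotic[tw] OR glomerulosclerosis[tw] OR nephrit*[tw] OR kidney '
    'biopsy[tiab] OR renal biopsy[tiab] OR albuminuri*[tw] OR '
    'glomerulopath*[tiab] OR membranoproliferative[tw] OR '
    'mesangioproliferative[tiab] OR nephrosis[tw] OR microalbuminuri*[tiab] '
    'OR diabetic kidney[tw] OR diabetic renal[tw] OR anti-glomerular[tw] OR '
    'nephrosclerosis[tiab] OR alport*[tw] OR goodpasture*[tiab] OR minimal '
    'change[tiab] OR glomerular disease*[tiab] OR anca*[tw] OR '
    'anti-neutrophil[tw] OR polyangiitis[tw] OR polyangitis[tw] OR '
    'antineutrophil[tw] OR antiglomerular[tw] OR "Kidney '
    'Glomerulus"[majr:noexp] OR "Lupus Erythematosus, Systemic"[majr:noexp] '
    'OR "Vasculitis"[majr:noexp] OR "Purpura, Schoenlein-Henoch"[mh:noexp] '
    'OR "Anti-Neutrophil Cytoplasmic Antibody-Associated Vasculitis"[mh] OR '
    '((lupus[tw] OR vasculitis[tw] OR purpura[tw] OR granulomatosis[tw]) '
    'AND (glomerul*[tw] OR kidney[tw] OR renal[tw] OR nephrolog*[tw])) OR '
    '((chronic kidney[tiab] OR chronic renal[tiab] OR "Renal Insufficiency, '
    'Chronic"[mh]) AND ("Diabetes Mellitus, Type 2"[majr:noexp] OR "Kidney '
    'Glomerulus"[mh:noexp])) OR ("Kidney Diseases"[majr] AND (biopsy[tw] OR '
    'myeloma[tiab] OR renin-angiotensin[tw] OR hiv[tiab] OR amyloid*[tw])))'
)

PUBMED_HIGH_SPECIFICITY = (
    '(glomerulonephrit*[tw] OR nephrotic[tw] OR diabetic nephropath*[tw] OR '
    'glomerulosclerosis[tw] OR iga nephropath*[tiab] OR minimal '
    'change[tiab] OR membranoproliferative[tw] OR glomerulopath*[tiab] OR '
    'membranous nephropathy[tiab] OR antineutrophil[tw] OR nephrosis[tw] OR '
    'anca*[tw] OR diabetic kidney[tiab] OR anti-glomerular[tw] OR '
    'glomerular disease*[tiab] OR anti-neutrophil[tw] OR antiglomerular[tw] '
    'OR polyangiitis[tw] OR alport*[tw] OR mesangioproliferative[tiab] OR '
    'goodpasture*[tiab] OR immunoglobulin a nephropathy[tiab] OR '
    '"AIDS-Associated Nephropathy"[majr:noexp] OR "Purpura, '
    'Schoenlein-Henoch"[majr:noexp] OR "Nephritis, Hereditary"[majr:noexp] '
    'OR "Anti-Neutrophil Cytoplasmic Antibody-Associated Vasculitis"[majr] '
    'OR "Balkan Nephropathy"[majr:noexp] OR (diabet*[ti] AND '
    'nephropath*[ti]) OR ((kidney[tw] OR renal[tw] OR nephrit*[tw] OR '
    'nephrolog*[tw] OR glomerul*[tw]) AND (purpura[tw] OR lupus[tw] OR '
    'vasculitis[tw])) OR ((nephrit*[tw] OR "Renal Insufficiency, '
    'Chronic"[mh] OR chronic kidney[tiab] OR chronic renal[tiab]) AND '
    '("Kidney Glomerulus"[mh:noexp] OR "Diabetes Mellitus, Type '
    '2"[majr:noexp] OR microalbuminuri*[tiab] OR immunoglobulin[tiab])) OR '
    '((proteinuri*[ti] OR "Proteinuria"[majr:noexp]) AND (hematuria[tw] OR '
    'haematuria[tiab] OR glomerulo*[tw] OR amyloid*[tw] OR '
    'albuminuri*[tiab] OR inflammation[tiab] OR myeloma[tw])) OR '
    '((glomerulo*[tw] OR nephropath*[tiab] OR proteinuri*[ti] OR '
    'microalbuminuri*[ti] OR albuminuri*[ti]) AND ("Diabetes Mellitus, Type '
    '2"[majr:noexp] OR "Diabetic Angiopathies"[majr] OR overt[tiab])) OR '
    '("Kidney Diseases"[majr:noexp] AND (amyloid*[tw] OR mesangio*[tiab] OR '
    'sclerosis[tiab])))'
)

MEDLINE_HIGH_SENSITIVITY = (
    '(nephropath$.mp OR glomerulonephrit$.mp OR proteinuri$.mp OR '
    'nephrotic.mp OR glomerulosclerosis.mp OR nephrit$.mp OR renal '
    'biopsy.tw OR albuminuri$.mp OR minimal change.tw OR glomerulopath$.tw '
    'OR membranoproliferative.mp OR antineutrophil.mp OR glomerular '
    'disease$.tw OR nephrosis.mp OR microalbuminuri$.tw OR anca$.mp OR '
    '(diabetic adj (kidney or renal)).mp OR kidney biopsy.tw OR '
    'anti-glomerular.mp OR antiglomerular.mp OR anti-neutrophil.mp OR '
    'polyang?itis.mp OR alport$.mp OR mesangioproliferative.tw OR '
    'goodpasture$.tw OR nephrosclerosis.tw OR *Kidney Glomerulus/ OR *Lupus '
    'Erythematosus, Systemic/ OR *Vasculitis/ OR Purpura, Schoenlein-Henoch/ '
    'OR exp Anti-Neutrophil Cytoplasmic Antibody-Associated Vasculitis/ OR '
    '((glomerul$.mp OR kidney.mp OR renal.mp OR nephrolog$.mp) AND '
    '(lupus.mp OR purpura.mp OR vasculitis.mp OR granulomatosis.mp)) OR '
    '((chronic adj2 (kidney or renal)).mp AND (*Diabetes Mellitus, Type 2/ '
    'OR Kidney Glomerulus/)) OR (exp *Kidney Diseases/ AND (biopsy.mp OR '
    'myeloma.tw OR renin-angiotensin.mp OR hiv.tw OR amyloid$.mp)))'
)

MEDLINE_HIGH_SPECIFICITY = (
    '(glomerulonephrit$.mp OR (diabetic adj (nephropath$ or kidney)).mp OR '
    'nephrotic.mp OR glomerulosclerosis.mp OR iga nephropath$.tw OR minimal '
    'change.tw OR glomerulopath$.tw OR membranous nephropathy.tw OR '
    'membranoproliferative.mp OR antineutrophil.mp OR glomerular '
    'disease$.tw OR nephrosis.mp OR anca$.mp OR anti-glomerular.mp OR '
    'anti-neutrophil.mp OR antiglomerular.mp OR polyang?itis.mp OR '
    'alport$.mp OR mesangioproliferative.tw OR goodpasture$.tw OR '
    'immunoglobulin a nephropathy.tw OR *AIDS-Associated Nephropathy/ OR '
    '*Purpura, Schoenlein-Henoch/ OR *Nephritis, Hereditary/ OR exp '
    '*Anti-Neutrophil Cytoplasmic Antibody-Associated Vasculitis/ OR '
    '*Balkan Nephropathy/ OR (diabet$ AND nephropath$).ti OR '
    '((glomerul$.mp OR kidney.mp OR renal.mp OR nephrit$.mp OR '
    'nephrolog$.mp) AND (lupus.mp OR vasculitis.mp OR purpura.mp)) OR '
    '((nephrit$ OR (chronic adj2 (kidney or renal))).mp. AND (Kidney '
    'Glomerulus/ OR *Diabetes Mellitus, Type 2/ OR microalbuminuri$.tw. OR '
    'immunoglobulin.tw.)) OR ((proteinuri$.ti OR *Proteinuria/) AND '
    '(glomerulo$.mp OR h?ematuria.mp OR albuminuri$.tw OR inflammation.tw '
    'OR amyloid$.mp OR myeloma.mp)) OR ((glomerulo$.mp OR nephropath$.tw OR '
    'proteinuri$.ti OR microalbuminuri$.ti OR albuminuri$.ti) AND '
    '(*Diabetes Mellitus, Type 2/ OR exp *Diabetic Angiopathies/ OR '
    'overt.tw)) OR (*Kidney Diseases/ AND (amyloid$.mp OR mesangio$.tw OR '
    'sclerosis.tw)))'
)

EMBASE_HIGH_SENSITIVITY = (
    '(exp glomerulopathy/ OR ((kidney or renal) adj biopsy).mp OR (diabet$ '
    'adj (kidney or renal or nephr$)).mp OR nephrotic.tw OR nephrotic '
    'syndrome/ OR glomerulonephrit$.tw OR immunoglobulin a nephropathy/ OR '
    'glomerul$ basement membrane$.mp OR iga nephropath$.tw OR minimal '
    'change.mp OR membranoproliferative.mp OR (glomerul$ adj (nephr$ or '
    'disease$ or scleros$)).tw OR membranous nephr$.tw OR anca$.mp OR '
    'proliferative glomerulonephritis/ OR wegener granulomatosis/ OR '
    'antineutrophil.mp OR polyang?itis.mp OR *glomerulus/ OR anaphylactoid '
    'purpura/ OR alport$.mp OR hiv-associated nephropath$.tw OR '
    'anti-neutrophil.mp OR mesangioproliferative.mp OR goodpasture$.mp OR '
    '(balkan adj2 nephr$).mp OR heymann nephritis/ OR ((lupus.mp OR '
    'vasculit$.mp OR purpur$.mp OR hiv$.tw OR granulomatosis.mp) AND '
    '("Urology and nephrology".ec OR proteinuri$.mp OR nephrit$.mp)) OR '
    '((exp *diabetes mellitus/ OR diabet$.ti) AND (nephropath$.tw OR exp '
    '*proteinuria/ OR renin-angiotensin$.mp OR dialys$.tw OR *kidney '
    'failure/ OR ((kidney OR renal) adj disease$).ti OR h?emodialys$.tw)) '
    'OR (exp *kidney disease/ AND (nephropath$.ti OR exp *proteinuria/ OR '
    'renin-angiotensin$.mp OR proteinuri$.ti OR amyloid$.mp)) OR ((exp '
    'proteinuria/ OR proteinuri$.mp) AND (nephropath$.tw OR nephrit$.mp OR '
    'renin-angiotensin$.tw)))'
)

EMBASE_HIGH_SPECIFICITY = (
    '(exp *glomerulopathy/ OR nephrotic.tw OR glomerulonephrit$.tw OR '
    'diabetic nephropath$.tw OR *diabetic nephropathy/ OR glomerul$ '
    'basement membrane$.mp OR nephrotic syndrome/ OR *immunoglobulin a '
    'nephropathy/ OR iga nephropath$.tw OR minimal change.mp OR '
    'membranoproliferative.tw OR membranous nephropathy.tw OR anca$.mp OR '
    'proliferative glomerulonephritis/ OR antineutrophil.mp OR '
    'polyang?itis.mp OR *glomerulus/ OR alport$.mp OR hiv-associated '
    'nephropath$.tw OR anti-neutrophil.mp OR *anaphylactoid purpura/ OR '
    '*wegener granulomatosis/ OR goodpasture$.tw OR mesangioproliferative.tw '
    'OR (balkan adj2 nephr$).tw OR ((lupus.mp OR vasculit$.tw OR '
    'granulomatosis.mp OR purpur$.tw OR amyloid$.tw) AND (kidney biopsy/ OR '
    'proteinuri$.mp OR nephrit$.mp OR serum creatinine.tw)) OR ((exp '
    '*diabetes mellitus/ OR proteinuri$.ti OR *proteinuria/) AND (exp '
    'glomerulopathy/ OR nephropath$.tw OR *kidney failure/ OR ((kidney or '
    'renal) adj disease$).ti OR *microalbuminuria/)) OR ((exp '
    'glomerulopathy/ OR diabetic nephropath$.mp) AND (kidney biopsy/ OR '
    'mesangial$.tw OR angiotensin$.tw OR serum creatinine.tw OR '
    'albuminuri$.mp OR microalbuminuri$.mp)))'
)

PUBLISHED_FILTERS: dict[str, tuple[str, str]] = {
    # name -> (dialect, source_text)
    "pubmed_high_sensitivity": ("pubmed", PUBMED_HIGH_SENSITIVITY),
    "pubmed_high_specificity": ("pubmed", PUBMED_HIGH_SPECIFICITY),
    "medline_high_sensitivity": ("ovid_medline", MEDLINE_HIGH_SENSITIVITY),
    "medline_high_specificity": ("ovid_medline", MEDLINE_HIGH_SPECIFICITY),
    "embase_high_sensitivity": ("ovid_embase", EMBASE_HIGH_SENSITIVITY),
    "embase_high_specificity": ("ovid_embase", EMBASE_HIGH_SPECIFICITY),
}

# Printed performance rows as percent: (sensitivity, specificity, precision,
# accuracy), by (filter name, phase).  The Embase high-sensitivity
# development sensitivity cell prints "9.0" — an apparent typo for 99.0 —
# and is stored here as printed.
PUBLISHED_PERFORMANCE: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("pubmed_high_sensitivity", "development"): (96.7, 95.2, 43.4, 95.3),
    ("pubmed_high_sensitivity", "validation"): (94.8, 96.0, 28.5, 95.9),
    ("pubmed_high_specificity", "development"): (93.8, 98.4, 69.2, 98.3),
    ("pubmed_high_specificity", "validation"): (91.1, 98.5, 50.4, 98.4),
    ("medline_high_sensitivity", "development"): (96.7, 95.2, 43.4, 95.3),
    ("medline_high_sensitivity", "validation"): (94.8, 96.0, 28.6, 96.0),
    ("medline_high_specificity", "development"): (93.8, 98.4, 69.2, 98.3),
    ("medline_high_specificity", "validation"): (91.1, 98.5, 50.6, 98.4),
    ("embase_high_sensitivity", "development"): (9.0, 95.3, 43.4, 95.4),
    ("embase_high_sensitivity", "validation"): (96.4, 96.0, 29.4, 96.0),
    ("embase_high_specificity", "development"): (95.7, 98.6, 71.1, 98.5),
    ("embase_high_specificity", "validation"): (92.8, 98.6, 52.9, 98.5),
}


def published_filter_names() -> list[str]:
    return list(PUBLISHED_FILTERS)


def load_published_filter(name: str) -> Query:
    """Parse one of the six published filters by name."""
    try:
        dialect, text = PUBLISHED_FILTERS[name]
    except KeyError:
        valid = ", ".join(PUBLISHED_FILTERS)
        raise KeyError(f"unknown filter {name!r}; valid names: {valid}") from None
    return parse(text, dialect)
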