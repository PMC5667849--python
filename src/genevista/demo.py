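"""Built-in demo inputs: a 23-gene GTEx excerpt and a matching annotation file.

The expression table holds two human tissues (stomach, salivary gland)
with three replicates apiece; the annotation table holds Entrez-derived
records for two olfactory-receptor genes, one row per (gene, GO term).
Both are tiny but exercise the full CSV dialects, including all-zero
genes and genes without annotation.
"""

from __future__ import annotations

import io

from .ingest import (
    AnnotationTable,
    Dataset,
    ExpressionMatrix,
    merge,
    read_annotation_csv,
    read_expression_csv,
)

DEMO_EXPRESSION_CSV = """\
gene,STOMACH1,STOMACH2,STOMACH3,SALIVARY_GLAND1,SALIVARY_GLAND2,SALIVARY_GLAND3
A1BG,262,236,284,267,533,324
A1BG-AS1,84,91,87,75,142,133
A1CF,2,2,2,6,1,2
A2M,68603,126956,144344,245041,138640,81812
A2M-AS1,265,132,185,402,294,484
A2ML1,50,7,30,57,29,61
A2MP1,44,4,6,13,32,35
A3GALT2,5,5,7,1,1,8
A4GALT,3597,3898,4646,2722,4655,3125
A4GNT,13,2,25,23,2,24
AA06,0,0,0,0,0,0
AAAS,2284,2216,3197,3185,1568,3266
AACS,1657,1008,1785,861,2571,1164
AACSP1,0,0,2,0,0,0
AADAC,0,5,0,2,6,8
AADACL2,0,0,0,0,0,0
AADACL3,2,0,0,0,6,0
AADACL4,4,4,2,3,2,6
AADACP1,7,12,2,0,83,0
AADAT,246,421,639,574,479,543
AAED1,1074,740,1083,1033,1502,643
AAGAB,1109,1628,1740,1192,1425,1443
AAK1,1032,501,590,393,790,576
"""

DEMO_ANNOTATION_CSV = """\
geneLink,GO,Symbol,description
https://www.ncbi.nlm.nih.gov/gene/?term=219464,G-protein coupled receptor activity,OR5T2,olfactory receptor family 5 subfamily T member 2
https://www.ncbi.nlm.nih.gov/gene/?term=219464,olfactory receptor activity,OR5T2,olfactory receptor family 5 subfamily T member 2
https://www.ncbi.nlm.nih.gov/gene/?term=219464,plasma membrane,OR5T2,olfactory receptor family 5 subfamily T member 2
https://www.ncbi.nlm.nih.gov/gene/?term=219464,G-protein coupled receptor signaling pathway,OR5T2,olfactory receptor family 5 subfamily T member 2
https://www.ncbi.nlm.nih.gov/gene/?term=219464,integral component of membrane,OR5T2,olfactory receptor family 5 subfamily T member 2
https://www.ncbi.nlm.nih.gov/gene/?term=219464,detection of chemical stimulus involved in sensory perception of smell,OR5T2,olfactory receptor family 5 subfamily T member 2
https://www.ncbi.nlm.nih.gov/gene/?term=390154,G-protein coupled receptor activity,OR5T3,olfactory receptor family 5 subfamily T member 3
https://www.ncbi.nlm.nih.gov/gene/?term=390154,olfactory receptor activity,OR5T3,olfactory receptor family 5 subfamily T member 3
https://www.ncbi.nlm.nih.gov/gene/?term=390154,plasma membrane,OR5T3,olfactory receptor family 5 subfamily T member 3
https://www.ncbi.nlm.nih.gov/gene/?term=390154,G-protein coupled receptor signaling pathway,OR5T3,olfactory receptor family 5 subfamily T member 3
https://www.ncbi.nlm.nih.gov/gene/?term=390154,integral component of membrane,OR5T3,olfactory receptor family 5 subfamily T member 3
https://www.ncbi.nlm.nih.gov/gene/?term=390154,detection of chemical stimulus involved in sensory perception of smell,OR5T3,olfactory receptor family 5 subfamily T member 3
"""


def load_demo_expression() -> ExpressionMatrix:
    return read_expression_csv(io.StringIO(DEMO_EXPRESSION_CSV))


def load_demo_annotation() -> AnnotationTable:
    return read_annotation_csv(io.StringIO(DEMO_ANNOTATION_CSV))


def load_demo_dataset() -> Dataset:
    """The demo expression matrix merged with the demo annotation file.

    Note the two files share no symbols, so every expression gene carries
    empty annotation fields -- the state of any dataset browsed without an
    annotation file.
    """
    return merge(load_demo_expression(), load_demo_annotation())


def write_demo_files(expression_path, annotation_path) -> None:
    """Write the demo CSVs to disk, e.g. to seed a new project."""
    with open(expression_path, "w") as fh:
        fh.write(DEMO_EXPRESSION_CSV)
    with open(annotation_path, "w") as fh:
        fh.write(DEMO_ANNOTATION_CSV)
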