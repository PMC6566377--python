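"""Reference tabulations from the 14-species plant/algal comparison this
pipeline models.

The per-group cluster and protein counts, per-group GO-annotation counts and
the transcriptome annotation tallies are the printed inputs from which every
derived quantity (totals, Venn regions, annotation percentages) is
recomputed through the package's own tabulation and rate functions. They let
the arithmetic of the reporting layer be checked without the fourteen
proteomes themselves.
"""

from __future__ import annotations

from typing import Dict, Tuple

#: group -> (protein count, OGC count)
OGC_GROUP_COUNTS: Dict[str, Tuple[int, int]] = {
    "Chl+Cha+Emb": (115796, 5031),
    "Cha+Emb": (66491, 4174),
    "Chl+Cha": (10323, 1221),
    "Chl+Emb": (1030, 140),
    "Emb": (28954, 4849),
    "Cha": (22077, 3600),
    "ZCC": (19524, 3807),
    "KCM": (257, 66),
    "Chl": (6012, 2597),
}

#: group -> number of GO-annotated proteins (numerators of the annotation
#: percentages; denominators are the protein counts above).
GO_ANNOTATED_COUNTS: Dict[str, int] = {
    "Chl+Cha+Emb": 80871,
    "Cha+Emb": 41532,
    "Chl+Cha": 4248,
    "Chl+Emb": 907,
    "Emb": 24831,
    "Cha": 3785,
    "ZCC": 6201,
    "KCM": 85,
    "Chl": 4440,
}

#: group -> number of significantly over-represented GO terms against the
#: Chl+Cha+Emb control (the control itself is not tested).
OVERREPRESENTED_TERM_COUNTS: Dict[str, int] = {
    "Cha+Emb": 501,
    "Chl+Cha": 76,
    "Chl+Emb": 65,
    "Emb": 404,
    "Cha": 20,
    "ZCC": 42,
    "KCM": 6,
    "Chl": 54,
}

#: Transcriptome assembly/annotation tallies for the newly sequenced strain:
#: label -> (hit count, denominator count). BLASTX searches are counted per
#: transcript, BLASTP searches per predicted protein.
ASSEMBLY_ANNOTATION_COUNTS: Dict[str, Tuple[int, int]] = {
    "TAIR10_BLASTX": (25366, 66952),
    "Kni_BLASTX": (27166, 66952),
    "UniRef_BLASTP": (29133, 43573),
    "TAIR10_BLASTP": (24608, 43573),
    "Kni_BLASTP": (26516, 43573),
}

TOTAL_INPUT_PROTEINS = 646562
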