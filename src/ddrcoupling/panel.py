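"""The 14-gene DDR-collagen-MMP panel and its stage vocabulary.

The panel covers the collagen-sensing discoidin domain receptors (DDR1,
DDR2), the fibrillar collagen / matrix glycoprotein genes they bind
(COL1A1, COL1A2, COL3A1, COL5A1, COL5A2, COL11A1, FN1) and five matrix
metalloproteinases that execute collagen turnover (MMP1, MMP2, MMP7,
MMP9, MMP11).  Disease stages follow the colorectal adenoma-carcinoma
sequence: normal mucosa -> adenoma -> carcinoma.
"""

from __future__ import annotations

RECEPTOR_GENES: tuple[str, ...] = ("DDR1", "DDR2")
COLLAGEN_GENES: tuple[str, ...] = (
    "COL1A1",
    "COL1A2",
    "COL3A1",
    "COL5A1",
    "COL5A2",
    "COL11A1",
    "FN1",
)
MMP_GENES: tuple[str, ...] = ("MMP1", "MMP2", "MMP7", "MMP9", "MMP11")

#: Canonical ordering of the 14 panel genes.
PANEL_GENES: tuple[str, ...] = RECEPTOR_GENES + COLLAGEN_GENES + MMP_GENES

#: gene symbol -> functional category
GENE_CATEGORIES: dict[str, str] = {
    **{g: "receptor" for g in RECEPTOR_GENES},
    **{g: "collagen" for g in COLLAGEN_GENES},
    **{g: "mmp" for g in MMP_GENES},
}

#: Ordered disease stages of the adenoma-carcinoma sequence.
STAGES: tuple[str, ...] = ("normal", "adenoma", "carcinoma")

#: Stage transitions used for trajectory deltas/folds.
STAGE_TRANSITIONS: tuple[tuple[str, str], ...] = (
    ("normal", "adenoma"),
    ("adenoma", "carcinoma"),
)

DEFAULT_HUB = "DDR2"


def hub_targets(hub: str, genes: tuple[str, ...] = PANEL_GENES) -> tuple[str, ...]:
    """The 12 designated targets of a DDR hub: every panel gene that is
    not itself a receptor (the DDR1-DDR2 pair is excluded from hub
    coupling summaries by convention)."""
    if hub not in RECEPTOR_GENES:
        raise ValueError(f"hub must be one of {RECEPTOR_GENES}, got {hub!r}")
    return tuple(g for g in genes if g not in RECEPTOR_GENES)
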