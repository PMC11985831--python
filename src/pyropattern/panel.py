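"""Bundled 40-gene pyroptosis panel and the two-subtype differential signature.

The panel covers the inflammasome sensors (NLR family, AIM2, ZBP1), the
caspases, the gasdermin executioners, ESCRT-III membrane-repair components
(CHMP family), granzymes and interferon regulatory factors that together
define the pyroptosis transcriptional programme used for AML subtyping.
"""

from __future__ import annotations

#: 40 pyroptosis-related genes (HGNC symbols), in canonical panel order.
PYROPTOSIS_PANEL: tuple[str, ...] = (
    "AIM2", "APIP", "BAK1", "BAX", "CASP1", "CASP3", "CASP4", "CASP5",
    "CASP6", "CASP8", "CHMP2A", "CHMP2B", "CHMP3", "CHMP4A", "CHMP4B",
    "CHMP4C", "CHMP7", "DHX9", "ELANE", "GSDMA", "GSDMB", "GSDMC",
    "GSDMD", "GSDME", "GPX4", "GZMA", "GZMB", "IL18", "IL1A", "IL1B",
    "IRF1", "IRF2", "NAIP", "NLRC4", "NLRP1", "NLRP3", "NLRP9", "NOD2",
    "TP53", "ZBP1",
)

#: Panel genes up-regulated in the ELANE-low subtype (C2) of the
#: two-pattern AML stratification.
DE_UP_C2: tuple[str, ...] = (
    "AIM2", "CASP1", "GSDMA", "GZMA", "GZMB", "NLRC4", "NLRP1", "ZBP1",
    "CASP5", "CHMP2B", "CHMP3", "CHMP4A", "CHMP4C", "CHMP7", "IRF1", "IRF2",
)

#: Panel genes up-regulated in the ELANE-high subtype (C1).
DE_UP_C1: tuple[str, ...] = ("GSDMC", "ELANE", "TP53")

assert len(PYROPTOSIS_PANEL) == 40
assert len(set(PYROPTOSIS_PANEL)) == 40
assert set(DE_UP_C1) | set(DE_UP_C2) <= set(PYROPTOSIS_PANEL)
assert not set(DE_UP_C1) & set(DE_UP_C2)
assert len(DE_UP_C1) + len(DE_UP_C2) == 19
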