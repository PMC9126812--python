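"""Spatial and cellular vocabularies shared across the pipeline.

The spatial unit is the 34-region left-hemisphere Desikan-Killiany cortical
parcellation; the cellular unit is a canonical set of seven neural cell
classes resolved by single-cell studies of adult human cortex.
"""

from __future__ import annotations

#: Left-hemisphere Desikan-Killiany cortical regions, FreeSurfer label order.
DK_LEFT_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

#: Canonical ordering of the seven neural cell classes.
CELL_TYPES: tuple[str, ...] = (
    "astrocyte",
    "endothelial",
    "microglia",
    "OPC",
    "excitatory",
    "inhibitory",
    "oligodendrocyte",
)

assert len(DK_LEFT_REGIONS) == 34
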