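"""Render palettes for the synthetic micrograph generator.

One flat RGB color per tissue class and stain. The hues mimic the
classic appearance of each stain under brightfield illumination:
eosinophilic pink-red collagen in H&E, aniline-blue collagen in
Mallory's trichrome, argyrophilic near-black reticular fibers in silver
impregnation, and dark violet-brown elastic fibers in Weigert's/orcein.
Nuclei are hematoxylin-like blue-purple throughout; the background is
near-white mounting medium. The default segmentation color profiles
(:mod:`fibermorph.segmentation`) are calibrated against these palettes.
"""

from __future__ import annotations

# class -> (R, G, B), 8-bit
STAIN_PALETTES: dict[str, dict[str, tuple[int, int, int]]] = {
    "he": {
        "fiber": (214, 96, 128),
        "nucleus": (92, 64, 168),
        "artifact": (128, 150, 110),
        "background": (247, 244, 246),
    },
    "mallory": {
        "fiber": (44, 72, 180),
        "nucleus": (150, 70, 180),
        "artifact": (128, 150, 110),
        "background": (246, 245, 242),
    },
    "silver": {
        "fiber": (40, 36, 38),
        "nucleus": (100, 80, 170),
        "artifact": (128, 150, 110),
        "background": (240, 238, 235),
    },
    "weigert_orcein": {
        "fiber": (110, 60, 95),
        "nucleus": (80, 70, 170),
        "artifact": (128, 150, 110),
        "background": (246, 243, 241),
    },
}

# Fig-1-style display convention for segmented class maps.
CLASS_DISPLAY_COLORS: dict[int, tuple[int, int, int]] = {
    0: (255, 255, 255),  # background
    1: (255, 0, 0),      # fiber
    2: (0, 0, 255),      # nucleus
    3: (0, 170, 0),      # artifact / excluded structure
}
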