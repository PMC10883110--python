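"""Built-in 32-channel 10–20 montage with cortical projection metadata.

Each electrode carries the anatomical structure it projects onto, a
gyrus + Brodmann-area code, MNI-style coordinates (mm) and a lobe class.
The 16 electrodes that appear in published optimal feature subsets carry
literature cortical-projection coordinates (provenance ``"reported"``);
the remaining electrodes of the cap carry approximate standard 10–20
projection coordinates (provenance ``"approximate"``), several obtained
by left/right mirroring of a reported homologue.
"""

from __future__ import annotations

from typing import NamedTuple


class MontageEntry(NamedTuple):
    label: str
    anatomy: str
    gyrus_ba: str
    coords: tuple[float, float, float]
    lobe: str
    provenance: str


# fmt: off
_ENTRIES = [
    # frontal
    MontageEntry("FP1", "Superior Frontal Gyrus", "SFG (10L)", (-21.0, 63.0, 12.0), "frontal", "reported"),
    MontageEntry("FP2", "Superior Frontal Gyrus", "SFG (10R)", (24.0, 63.0, 13.0), "frontal", "reported"),
    MontageEntry("F7",  "Inferior Frontal Gyrus", "IFG (45L)", (-52.0, 28.0, 8.0), "frontal", "approximate"),
    MontageEntry("F3",  "Middle Frontal Gyrus",   "MFG (8L)",  (-42.0, 28.0, 44.0), "frontal", "approximate"),
    MontageEntry("FZ",  "Superior Frontal Gyrus", "SFG (6M)",  (0.0, 27.0, 61.0), "frontal", "reported"),
    MontageEntry("F4",  "Middle Frontal Gyrus",   "MFG (8R)",  (42.0, 28.0, 44.0), "frontal", "reported"),
    MontageEntry("F8",  "Inferior Frontal Gyrus", "IFG (45R)", (52.0, 28.0, 8.0), "frontal", "approximate"),
    MontageEntry("FC5", "Precentral Gyrus",       "PreG (6L)", (-59.0, 3.0, 26.0), "frontal", "reported"),
    MontageEntry("FC1", "Superior Frontal Gyrus", "SFG (6L)",  (-25.0, 0.0, 66.0), "frontal", "reported"),
    MontageEntry("FC2", "Superior Frontal Gyrus", "SFG (6R)",  (25.0, 0.0, 66.0), "frontal", "approximate"),
    MontageEntry("FC6", "Precentral Gyrus",       "PreG (6R)", (59.0, 3.0, 26.0), "frontal", "approximate"),
    # central row projects onto the postcentral bank -> parietal class
    MontageEntry("C3",  "Postcentral Gyrus",      "PoG (3L)",  (-47.0, -19.0, 53.0), "parietal", "approximate"),
    MontageEntry("CZ",  "Paracentral Lobule",     "PCL (4M)",  (0.0, -14.0, 74.0), "parietal", "approximate"),
    MontageEntry("C4",  "Postcentral Gyrus",      "PoG (3R)",  (47.0, -19.0, 53.0), "parietal", "approximate"),
    MontageEntry("T3",  "Middle Temporal Gyrus",  "MTG (21L)", (-66.0, -18.0, -8.0), "temporal", "approximate"),
    MontageEntry("T4",  "Middle Temporal Gyrus",  "MTG (21R)", (66.0, -18.0, -8.0), "temporal", "approximate"),
    MontageEntry("CP5", "Supramarginal Gyrus",    "SupG (40L)", (-62.0, -46.0, 23.0), "parietal", "reported"),
    MontageEntry("CP1", "Superior Parietal Lobule", "SPL (5L)", (-24.0, -44.0, 62.0), "parietal", "approximate"),
    MontageEntry("CP2", "Superior Parietal Lobule", "SPL (5R)", (24.0, -44.0, 62.0), "parietal", "approximate"),
    MontageEntry("CP6", "Supramarginal Gyrus",    "SupG (40R)", (62.0, -46.0, 23.0), "parietal", "approximate"),
    MontageEntry("T5",  "Middle Temporal Gyrus",  "MTG (37L)", (-57.0, -63.0, 4.0), "temporal", "reported"),
    MontageEntry("P3",  "Superior Parietal Lobule", "SPL (7L)", (-41.0, -68.0, 42.0), "parietal", "reported"),
    MontageEntry("PZ",  "Precuneus",              "PCu (7M)",  (0.0, -64.0, 56.0), "parietal", "approximate"),
    MontageEntry("P4",  "Superior Parietal Lobule", "SPL (7R)", (44.0, -66.0, 43.0), "parietal", "reported"),
    MontageEntry("T6",  "Middle Temporal Gyrus",  "MTG (37R)", (55.0, -65.0, 6.0), "temporal", "reported"),
    MontageEntry("PO7", "Middle Occipital Gyrus", "MOG (18L)", (-44.0, -82.0, 2.0), "occipital", "reported"),
    MontageEntry("PO3", "Superior Occipital Gyrus", "SOG (19L)", (-33.0, -84.0, 27.0), "occipital", "reported"),
    MontageEntry("PO4", "Superior Occipital Gyrus", "SOG (19R)", (35.0, -83.0, 26.0), "occipital", "reported"),
    MontageEntry("PO8", "Middle Occipital Gyrus", "MOG (18R)", (44.0, -82.0, 2.0), "occipital", "approximate"),
    MontageEntry("O1",  "Middle Occipital Gyrus", "MOG (18L)", (-25.0, -95.0, 6.0), "occipital", "approximate"),
    MontageEntry("OZ",  "Cuneus",                 "Cuneus (18M)", (0.0, -97.0, 9.0), "occipital", "reported"),
    MontageEntry("O2",  "Middle Occipital Gyrus", "MOG (18R)", (25.0, -95.0, 6.0), "occipital", "reported"),
]
# fmt: on

MONTAGE_32 = {e.label: e for e in _ENTRIES}
CHANNELS_32: tuple[str, ...] = tuple(e.label for e in _ENTRIES)

LOBE_COLOR_CLASS = {"frontal": 1, "parietal": 2, "temporal": 3, "occipital": 4}


def channel_positions_2d(labels) -> "list[tuple[float, float]]":
    """Planar (lateral x, anterior y) electrode positions, normalized to [-1, 1].

    Derived from the montage's projection coordinates; used to build the
    canonical microstate archetype topographies.
    """
    out = []
    for lab in labels:
        e = MONTAGE_32[lab.upper()]
        out.append((e.coords[0] / 70.0, e.coords[1] / 100.0))
    return out
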