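"""Default cortical parcellation labels.

A 72-region cortical atlas model: 36 bilateral regions of an AAL-style
cortical subset (cerebellum, basal ganglia, thalamus, amygdala, insula and
olfactory regions excluded), each present as a left ('l') and right ('r')
parcel.  The list is a packaged default, not hard-coded truth: every function
that needs ROI names accepts an explicit label list.
"""

from __future__ import annotations

_BILATERAL = [
    "Precentral",
    "SFG",            # superior frontal gyrus, dorsolateral
    "SFo",            # superior frontal gyrus, orbital part
    "MFG",            # middle frontal gyrus
    "MFo",            # middle frontal gyrus, orbital part
    "IFGop",          # inferior frontal gyrus, opercular part
    "IFGtri",         # inferior frontal gyrus, triangular part
    "IFGo",           # inferior frontal gyrus, orbital part
    "Rolandic",
    "Motor",          # supplementary motor area
    "MedSFG",         # superior frontal gyrus, medial
    "MedSFo",         # superior frontal gyrus, medial orbital
    "Rectus",         # gyrus rectus
    "ACC",            # anterior cingulate cortex
    "MCC",            # median cingulate
    "PCC",            # posterior cingulate
    "Hippocampus",
    "ParaHippocampal",
    "Calcarine",
    "Cuneus",
    "Lingual",
    "SupOcc",         # superior occipital gyrus
    "LSOcc",          # lateral superior occipital (middle occipital)
    "InfOcc",         # inferior occipital gyrus
    "Fusiform",
    "Postcentral",
    "SPL",            # superior parietal lobule
    "IPL",            # inferior parietal lobule
    "Supramarginal",
    "Angular",
    "Precuneus",
    "Paracentral",
    "Heschl",
    "STG",            # superior temporal gyrus
    "MTG",            # middle temporal gyrus
    "ITG",            # inferior temporal gyrus
]


def default_roi_labels() -> list[str]:
    """Return the packaged 72-label cortical atlas model (left/right pairs)."""
    labels = []
    for name in _BILATERAL:
        labels.append(f"l{name}")
        labels.append(f"r{name}")
    return labels


def roi_index(label: str, labels: list[str] | None = None) -> int:
    """Index of ``label`` in the atlas model (raises ``ValueError`` if absent)."""
    labels = labels if labels is not None else default_roi_labels()
    return labels.index(label)
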