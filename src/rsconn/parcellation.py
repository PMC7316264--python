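"""Default 129-ROI cortical parcellation, attentional networks and effect edges.

The label set mimics a whole-cortex anatomical parcellation at the scale
of ~18 cm^2 regions: named frontal, temporal, parietal and subcortical
parcels that take part in the attentional analysis, padded with generic
cortical parcels to a total of 129 regions.  The ventral attentional
network (VAN) has 19 members (10 right, 9 left) and the dorsal
attentional network (DAN) 6 (3 per hemisphere).
"""

from __future__ import annotations

# Nodes of the default planted subnetwork: a bilateral fronto-temporal set
# anchored on four inferior frontal gyrus parcels (two per hemisphere).
_EFFECT_NODES = (
    "R_IFG_opercularis",
    "R_IFG_triangularis",
    "R_STG_posterior",
    "R_STG_anterior",
    "R_TG_lateral",
    "R_Pallidum",
    "L_IFG_opercularis",
    "L_IFG_triangularis",
    "L_OFG_medial",
    "L_FG_anterior",
    "L_STS_posterior",
    "L_STG_posterior",
    "L_TG_lateral",
)

#: Default planted edge set: 11 fronto-temporal pairs (13 distinct nodes),
#: every pair touching an inferior frontal gyrus parcel.  Used as the
#: default Group x Timepoint effect location in the synthetic cohort.
DEFAULT_EFFECT_EDGES: tuple[tuple[str, str], ...] = (
    ("R_IFG_opercularis", "R_STG_posterior"),
    ("R_IFG_triangularis", "R_STG_posterior"),
    ("R_IFG_opercularis", "R_STG_anterior"),
    ("R_IFG_opercularis", "R_TG_lateral"),
    ("L_OFG_medial", "L_IFG_triangularis"),
    ("R_Pallidum", "L_IFG_opercularis"),
    ("L_IFG_opercularis", "L_FG_anterior"),
    ("R_IFG_opercularis", "L_STS_posterior"),
    ("R_IFG_triangularis", "L_STG_posterior"),
    ("R_IFG_opercularis", "L_STG_posterior"),
    ("R_IFG_opercularis", "L_TG_lateral"),
)

_VAN_RIGHT = (
    "R_IFG_opercularis",
    "R_IFG_triangularis",
    "R_TPJ",
    "R_IPL_supramarginal_1",
    "R_IPL_supramarginal_2",
    "R_IPL_supramarginal_3",
    "R_MFG_ventral",
    "R_insula_anterior",
    "R_frontal_operculum",
    "R_STS_anterior",
)
_VAN_LEFT = (
    "L_IFG_opercularis",
    "L_IFG_triangularis",
    "L_TPJ",
    "L_IPL_supramarginal_1",
    "L_IPL_supramarginal_2",
    "L_MFG_ventral",
    "L_insula_anterior",
    "L_frontal_operculum",
    "L_STS_anterior",
)
_DAN = (
    "R_FEF",
    "R_IPS",
    "R_SPL",
    "L_FEF",
    "L_IPS",
    "L_SPL",
)

_TEMPORAL = (
    "R_STG_posterior",
    "R_STG_anterior",
    "R_TG_lateral",
    "R_STS_posterior",
    "L_STG_posterior",
    "L_STG_anterior",
    "L_TG_lateral",
    "L_STS_posterior",
)
_FRONTAL_OTHER = (
    "L_OFG_medial",
    "R_OFG_medial",
    "L_FG_anterior",
    "R_FG_anterior",
)
_SUBCORTICAL = (
    "R_Pallidum",
    "L_Pallidum",
    "R_Thalamus",
    "L_Thalamus",
)


def default_parcellation(n_rois: int = 129) -> tuple[tuple[str, ...], dict[str, int]]:
    """Return (roi_labels, module_assignment) for the default parcellation.

    Communities: 0 = VAN, 1 = DAN, 2 = temporal, 3 = orbito/fusiform
    frontal, 4 = subcortical, then generic cortical communities of ~12
    parcels each.  With fewer than the full complement of ROIs the named
    parcels are kept first; padding labels are ``{R,L}_ctx_<k>``.
    """
    named: list[str] = []
    modules: dict[str, int] = {}
    for label in _VAN_RIGHT + _VAN_LEFT:
        named.append(label)
        modules[label] = 0
    for label in _DAN:
        named.append(label)
        modules[label] = 1
    for label in _TEMPORAL:
        named.append(label)
        modules[label] = 2
    for label in _FRONTAL_OTHER:
        named.append(label)
        modules[label] = 3
    for label in _SUBCORTICAL:
        named.append(label)
        modules[label] = 4
    if n_rois < len(named):
        raise ValueError(f"n_rois must be at least {len(named)}")
    n_pad = n_rois - len(named)
    pad_module_size = 12
    for k in range(n_pad):
        hemi = "R" if k % 2 == 0 else "L"
        label = f"{hemi}_ctx_{k:03d}"
        named.append(label)
        modules[label] = 5 + k // pad_module_size
    return tuple(named), modules


def default_networks() -> dict[str, tuple[str, ...]]:
    """Ventral (19 ROIs) and dorsal (6 ROIs) attentional network definitions."""
    return {"VAN": _VAN_RIGHT + _VAN_LEFT, "DAN": _DAN}
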