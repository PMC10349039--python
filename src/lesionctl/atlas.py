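"""Default gray-matter node space.

A 100-region, JHU-flavored label set (50 homotopic pairs) used whenever a
connectome is generated rather than read from disk.  Left-hemisphere labels
carry the ``L_`` prefix and occupy indices 0..49; the homotopic right-hemisphere
partner of index ``i`` sits at index ``i + 50``.

The names matter only as identifiers; the language regions of interest
(inferior frontal gyrus pars opercularis, superior temporal gyrus pole,
posterior superior temporal gyrus, ...) are spelled out so that downstream
statistics can refer to them by name.
"""

from __future__ import annotations

# 50 homotopic base names (one hemisphere's worth).
_BASE_REGIONS = [
    "superior_frontal_gyrus",
    "middle_frontal_gyrus",
    "middle_frontal_gyrus_posterior",
    "IFG_opercularis",
    "IFG_triangularis",
    "IFG_orbitalis",
    "precentral_gyrus",
    "postcentral_gyrus",
    "rolandic_operculum",
    "supplementary_motor_area",
    "paracentral_lobule",
    "superior_parietal_gyrus",
    "inferior_parietal_gyrus",
    "supramarginal_gyrus",
    "angular_gyrus",
    "precuneus",
    "superior_occipital_gyrus",
    "middle_occipital_gyrus",
    "inferior_occipital_gyrus",
    "cuneus",
    "calcarine_cortex",
    "lingual_gyrus",
    "fusiform_gyrus",
    "STG",
    "STG_pole",
    "posterior_STG",
    "middle_temporal_gyrus",
    "posterior_MTG",
    "MTG_pole",
    "inferior_temporal_gyrus",
    "heschl_gyrus",
    "parahippocampal_gyrus",
    "hippocampus",
    "amygdala",
    "insula",
    "anterior_cingulate_gyrus",
    "middle_cingulate_gyrus",
    "posterior_cingulate_gyrus",
    "olfactory_cortex",
    "gyrus_rectus",
    "medial_orbitofrontal_gyrus",
    "lateral_orbitofrontal_gyrus",
    "caudate_nucleus",
    "putamen",
    "globus_pallidus",
    "thalamus",
    "nucleus_accumbens",
    "mamillary_body",
    "basal_forebrain",
    "substantia_nigra",
]

#: Full 100-region label list, left block first, homotopic order preserved.
JHU_LABELS = [f"L_{r}" for r in _BASE_REGIONS] + [f"R_{r}" for r in _BASE_REGIONS]

#: Hemisphere tag per label, aligned with :data:`JHU_LABELS`.
JHU_HEMISPHERES = ["L"] * len(_BASE_REGIONS) + ["R"] * len(_BASE_REGIONS)

#: The nine pre-selected left-hemisphere language regions of interest.
LANGUAGE_ROIS = [
    "L_middle_frontal_gyrus_posterior",
    "L_IFG_opercularis",
    "L_IFG_triangularis",
    "L_angular_gyrus",
    "L_STG",
    "L_STG_pole",
    "L_middle_temporal_gyrus",
    "L_posterior_STG",
    "L_posterior_MTG",
]

#: Candidate mediator regions examined by the mediation stage.
CANDIDATE_MEDIATORS = ["L_IFG_opercularis", "L_STG_pole", "L_posterior_STG"]


def generic_labels(n_nodes: int) -> tuple[list[str], list[str]]:
    """Labels and hemisphere tags for an arbitrary even node count.

    Uses the JHU-style list when ``n_nodes == 100``; otherwise numbered
    region names with the same left-block-first homotopic layout.
    """
    if n_nodes % 2 != 0:
        raise ValueError(f"n_nodes must be even, got {n_nodes}")
    if n_nodes == 100:
        return list(JHU_LABELS), list(JHU_HEMISPHERES)
    half = n_nodes // 2
    labels = [f"L_region_{i:03d}" for i in range(half)] + [
        f"R_region_{i:03d}" for i in range(half)
    ]
    return labels, ["L"] * half + ["R"] * half
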