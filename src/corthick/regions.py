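"""The fixed 66-region cortical parcellation used throughout the package.

Thirty-three Desikan-Killiany gyral labels per hemisphere (the standard
atlas list minus the insula), prefixed ``l_``/``r_``.  Region columns of
every thickness matrix must match this list, in this order.
"""

from __future__ import annotations

DESIKAN_KILLIANY_33 = (
    "bankssts",
    "caudal_anterior_cingulate",
    "caudal_middle_frontal",
    "cuneus",
    "entorhinal",
    "frontal_pole",
    "fusiform",
    "inferior_parietal",
    "inferior_temporal",
    "isthmus_cingulate",
    "lateral_occipital",
    "lateral_orbitofrontal",
    "lingual",
    "medial_orbitofrontal",
    "middle_temporal",
    "paracentral",
    "parahippocampal",
    "pars_opercularis",
    "pars_orbitalis",
    "pars_triangularis",
    "pericalcarine",
    "postcentral",
    "posterior_cingulate",
    "precentral",
    "precuneus",
    "rostral_anterior_cingulate",
    "rostral_middle_frontal",
    "superior_frontal",
    "superior_parietal",
    "superior_temporal",
    "supramarginal",
    "temporal_pole",
    "transverse_temporal",
)

REGIONS_66: tuple[str, ...] = tuple(
    f"{hemi}_{name}" for hemi in ("l", "r") for name in DESIKAN_KILLIANY_33
)

N_REGIONS = len(REGIONS_66)


def region_index(name: str) -> int:
    """Position of a region column in the canonical ordering."""
    try:
        return REGIONS_66.index(name)
    except ValueError:
        raise KeyError(f"unknown region {name!r}; expected one of the 66 "
                       f"Desikan-Killiany labels like 'l_precentral'") from None
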