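"""Cortical region vocabulary: 31 Desikan-style parcels per hemisphere.

Region names are snake_case versions of the FreeSurfer parcel labels; a
cohort column is ``<region>_<hemisphere>``.  ``DEFAULT_ARCHETYPES`` assigns
each of the 62 regions one of six qualitative lifespan-trajectory shapes
(abrupt change near 25/40/50/70 years, multiple inflections, near-constant
rate) used by the synthetic-cohort generator; the assignment follows the
published per-region groupings where a region is named and fills the
remainder with the late-life-change shape.
"""

from __future__ import annotations

from importlib import resources

HEMISPHERES = ("left", "right")

REGION_NAMES = (
    "caudal_anterior_cingulate",
    "caudal_middle_frontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferior_parietal",
    "inferior_temporal",
    "isthmus_cingulate",
    "lateral_occipital",
    "lateral_orbitofrontal",
    "lingual",
    "medial_orbitofrontal",
    "middle_temporal",
    "parahippocampal",
    "paracentral",
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
    "transverse_temporal",
    "insula",
)


def column_name(region: str, hemisphere: str) -> str:
    if region not in REGION_NAMES:
        raise ValueError(f"unknown region: {region!r}")
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"unknown hemisphere: {hemisphere!r}")
    return f"{region}_{hemisphere}"


def split_column_name(column: str) -> tuple[str, str]:
    """Parse ``<region>_<hemisphere>`` back into its parts."""
    for hemi in HEMISPHERES:
        suffix = f"_{hemi}"
        if column.endswith(suffix):
            return column[: -len(suffix)], hemi
    raise ValueError(f"column {column!r} has no hemisphere suffix")


_ARCHETYPE_GROUPS = {
    ("left", "change25"): (
        "insula",
        "superior_parietal",
        "precentral",
        "rostral_anterior_cingulate",
        "transverse_temporal",
        "supramarginal",
    ),
    ("right", "change25"): (
        "insula",
        "superior_parietal",
        "precentral",
        "rostral_anterior_cingulate",
        "caudal_anterior_cingulate",
        "supramarginal",
    ),
    ("left", "change40"): (
        "postcentral",
        "caudal_middle_frontal",
        "middle_temporal",
    ),
    ("right", "change40"): (
        "postcentral",
        "caudal_middle_frontal",
        "lateral_orbitofrontal",
        "medial_orbitofrontal",
        "lateral_occipital",
    ),
    ("left", "change50"): (
        "inferior_parietal",
        "rostral_middle_frontal",
        "cuneus",
        "lingual",
        "pericalcarine",
    ),
    ("right", "change50"): (
        "inferior_parietal",
        "fusiform",
        "cuneus",
        "lingual",
        "middle_temporal",
    ),
    ("left", "multi"): (
        "lateral_orbitofrontal",
        "medial_orbitofrontal",
        "inferior_temporal",
        "caudal_anterior_cingulate",
        "fusiform",
        "entorhinal",
    ),
    ("right", "multi"): (
        "inferior_temporal",
        "transverse_temporal",
        "pericalcarine",
        "entorhinal",
    ),
    ("left", "constant"): (
        "isthmus_cingulate",
        "pars_triangularis",
        "pars_opercularis",
        "precuneus",
        "paracentral",
        "parahippocampal",
    ),
    ("right", "constant"): (
        "isthmus_cingulate",
        "pars_triangularis",
        "pars_opercularis",
        "precuneus",
        "paracentral",
        "parahippocampal",
    ),
}


def _build_default_archetypes() -> dict[tuple[str, str], str]:
    out: dict[tuple[str, str], str] = {}
    for (hemi, archetype), names in _ARCHETYPE_GROUPS.items():
        for name in names:
            out[(name, hemi)] = archetype
    for hemi in HEMISPHERES:
        for name in REGION_NAMES:
            out.setdefault((name, hemi), "change70")
    return out


DEFAULT_ARCHETYPES: dict[tuple[str, str], str] = _build_default_archetypes()


def fixture_path():
    """Path to the bundled 4-subject reference thickness table."""
    return resources.files("corthick") / "data" / "table1_fixture.csv"
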