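"""Deterministic TNM staging of non-small-cell lung tumors.

The TNM scheme describes a tumor by three categorical axes:

* **TU** — primary tumor size category.  Size boundaries at 1, 2, 3, 4, 5 and
  7 cm are *upper-inclusive*: a 3.0 cm tumor is TU1c, a 3.001 cm tumor is TU2a.
* **LN** — regional lymph-node involvement (LN0 … LN3).
* **DM** — distant metastasis (DM0 none, DM1 intrathoracic/pleural spread,
  DM2 distant metastasis found).

A (TU, LN, DM) triple maps to exactly one stage group out of
1A1, 1A2, 1A3, 1B, 2A, 2B, 3A, 3B, 3C, 4A, 4B.  Any DM1 maps to 4A and any
DM2 to 4B regardless of the TU/LN combination.  TU0 (no tumor) with DM0 is not
a stage; :data:`NO_TUMOR` is returned as an explicit sentinel.

Parent size categories TU1 (≤3 cm) and TU2 (3–5 cm) are groupings of their
subcategories and are never returned by :func:`tu_category`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "TU_CATEGORIES",
    "LN_CATEGORIES",
    "DM_CATEGORIES",
    "STAGE_LABELS",
    "STAGE_ORDER",
    "NO_TUMOR",
    "TNMDescriptor",
    "tu_category",
    "ln_category",
    "dm_category",
    "stage_group",
    "stage_from_measurement",
    "coarse_stage_group",
    "coarse_labels",
]

TU_CATEGORIES = ("TU0", "TU1a", "TU1b", "TU1c", "TU2a", "TU2b", "TU3", "TU4")
LN_CATEGORIES = ("LN0", "LN1", "LN2", "LN3")
DM_CATEGORIES = ("DM0", "DM1", "DM2")

STAGE_LABELS = ("1A1", "1A2", "1A3", "1B", "2A", "2B", "3A", "3B", "3C", "4A", "4B")

#: Severity order of the stage groups (index = rank).
STAGE_ORDER: Mapping[str, int] = {label: i for i, label in enumerate(STAGE_LABELS)}

#: Sentinel returned for a TU0/DM0 descriptor — "no tumor" is not a stage.
NO_TUMOR = "NO_TUMOR"

# Upper-inclusive TU size boundaries, cm.
_TU_BOUNDS_CM = ((1.0, "TU1a"), (2.0, "TU1b"), (3.0, "TU1c"),
                 (4.0, "TU2a"), (5.0, "TU2b"), (7.0, "TU3"))

LN_DESCRIPTIONS = {
    "LN0": "Absence of regional node metastasis",
    "LN1": "Metastasis in the ipsilateral peribronchial or perihilar lymph "
           "nodes and intrapulmonary nodes",
    "LN2": "Metastasis in the ipsilateral mediastinal or subcarinal lymph nodes",
    "LN3": "Metastasis in the contralateral mediastinal lymph nodes, perihilar "
           "lymph nodes, or supraclavicular nodes",
}

DM_DESCRIPTIONS = {
    "DM0": "Absence of distant metastasis",
    "DM1": "Malignant pleural/pericardial effusion or nodule, or separate tumor "
           "nodule in a contralateral lobe",
    "DM2": "Distant metastasis was found",
}

# Stage grid for DM0: row = TU subcategory, column = LN category.
_STAGE_GRID = {
    "TU1a": ("1A1", "2B", "3A", "3B"),
    "TU1b": ("1A2", "2B", "3A", "3B"),
    "TU1c": ("1A3", "2B", "3A", "3B"),
    "TU2a": ("1B", "2B", "3A", "3B"),
    "TU2b": ("2A", "2B", "3A", "3B"),
    "TU3": ("2B", "3A", "3B", "3C"),
    # TU4 genuinely repeats 3A for LN0 and LN1.
    "TU4": ("3A", "3A", "3B", "3C"),
}

#: Groupings that coarsen the 11 stage labels for classifiers with fewer
#: output classes.  Keys are the class count; values map fine label → class.
_COARSE_GROUPINGS: dict[int, Mapping[str, str]] = {
    11: {lab: lab for lab in STAGE_LABELS},
    # 1A1/1A2/1A3 merge into 1A.
    9: {lab: ("1A" if lab.startswith("1A") and lab != "1B" else lab)
        for lab in STAGE_LABELS},
    # additionally 4A/4B merge into 4.
    8: {lab: ("1A" if lab.startswith("1A") and lab != "1B"
              else "4" if lab.startswith("4") else lab)
        for lab in STAGE_LABELS},
}


@dataclass(frozen=True)
class TNMDescriptor:
    """A validated (TU, LN, DM) triple."""

    tu: str
    ln: str
    dm: str

    def __post_init__(self) -> None:
        if self.tu not in TU_CATEGORIES:
            raise ValueError(f"unknown TU category {self.tu!r}; valid: {TU_CATEGORIES}")
        if self.ln not in LN_CATEGORIES:
            raise ValueError(f"unknown LN category {self.ln!r}; valid: {LN_CATEGORIES}")
        if self.dm not in DM_CATEGORIES:
            raise ValueError(f"unknown DM category {self.dm!r}; valid: {DM_CATEGORIES}")


def tu_category(size_cm: float) -> str:
    """Map a tumor size in cm to its TU subcategory.

    All boundaries are upper-inclusive: ``tu_category(3.0) == "TU1c"`` but
    ``tu_category(3.0001) == "TU2a"``.  A size of exactly 0 means no tumor
    (TU0).  Negative sizes are rejected.
    """
    if size_cm < 0:
        raise ValueError(f"tumor size must be >= 0 cm, got {size_cm}")
    if size_cm == 0:
        return "TU0"
    for bound, cat in _TU_BOUNDS_CM:
        if size_cm <= bound:
            return cat
    return "TU4"


def _normalize_code(code: str, prefix: str) -> str:
    """Accept 'LN0', 'LN_0', 'ln0' spellings and return the canonical form."""
    return code.strip().upper().replace("_", "")


def ln_category(code: str) -> tuple[str, str]:
    """Validate a lymph-node code; return ``(canonical_code, description)``."""
    canon = _normalize_code(code, "LN")
    if canon not in LN_CATEGORIES:
        raise ValueError(f"unknown LN code {code!r}; valid codes: {list(LN_CATEGORIES)}")
    return canon, LN_DESCRIPTIONS[canon]


def dm_category(code: str) -> tuple[str, str]:
    """Validate a distant-metastasis code; return ``(canonical_code, description)``."""
    canon = _normalize_code(code, "DM")
    if canon not in DM_CATEGORIES:
        raise ValueError(f"unknown DM code {code!r}; valid codes: {list(DM_CATEGORIES)}")
    return canon, DM_DESCRIPTIONS[canon]


def stage_group(tnm: TNMDescriptor) -> str:
    """Map a TNM descriptor to its stage group.

    DM1 maps to 4A and DM2 to 4B regardless of TU/LN.  With DM0, the stage is
    the (TU, LN) grid cell.  TU0 with DM0 returns :data:`NO_TUMOR`.
    """
    if tnm.dm == "DM1":
        return "4A"
    if tnm.dm == "DM2":
        return "4B"
    if tnm.tu == "TU0":
        return NO_TUMOR
    return _STAGE_GRID[tnm.tu][LN_CATEGORIES.index(tnm.ln)]


def stage_from_measurement(measurements, ln_code: str, dm_code: str) -> tuple[TNMDescriptor, str]:
    """Compose nodule measurement → TU category with LN/DM codes → stage group.

    ``measurements`` is a :class:`~pulmostage.nodule_metrics.NoduleMeasurements`
    (or anything with an ``equivalent_diameter_mm`` attribute, in mm — the
    mm→cm conversion happens here and only here).
    """
    size_cm = float(measurements.equivalent_diameter_mm) / 10.0
    ln, _ = ln_category(ln_code)
    dm, _ = dm_category(dm_code)
    tnm = TNMDescriptor(tu=tu_category(size_cm), ln=ln, dm=dm)
    return tnm, stage_group(tnm)


def coarse_labels(n_classes: int = 9) -> tuple[str, ...]:
    """The distinct class labels of the ``n_classes``-way coarse grouping."""
    grouping = _COARSE_GROUPINGS.get(n_classes)
    if grouping is None:
        raise ValueError(f"no coarse grouping for n_classes={n_classes}; "
                         f"available: {sorted(_COARSE_GROUPINGS)}")
    seen: list[str] = []
    for lab in STAGE_LABELS:
        if grouping[lab] not in seen:
            seen.append(grouping[lab])
    return tuple(seen)


def coarse_stage_group(label: str, n_classes: int = 9) -> str:
    """Coarsen a fine stage label to the ``n_classes``-way grouping.

    The default 9-class grouping merges 1A1/1A2/1A3 into 1A and keeps every
    other label; the 8-class variant additionally merges 4A/4B into 4.
    """
    grouping = _COARSE_GROUPINGS.get(n_classes)
    if grouping is None:
        raise ValueError(f"no coarse grouping for n_classes={n_classes}; "
                         f"available: {sorted(_COARSE_GROUPINGS)}")
    if label not in grouping:
        raise ValueError(f"unknown stage label {label!r}")
    return grouping[label]
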