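"""Ordered disease-stage vocabulary for the adenoma-carcinoma sequence.

Samples are labelled with one of six histology stages ordered by severity:
normal control (NC), multiple polypoid adenoma with low-grade dysplasia (MP),
advanced adenoma with low- or high-grade dysplasia (AA_LGD / AA_HGD), and
colorectal cancer at stage I/II or III/IV (CRC_I_II / CRC_III_IV).

Marker discovery collapses these into three groups (control, advanced
adenoma, CRC); MP samples sit between control and advanced adenoma and are
excluded from discovery.
"""

from __future__ import annotations

import enum


class Stage(enum.IntEnum):
    """Six-level ordered disease stage; integer value encodes severity order."""

    NC = 0
    MP = 1
    AA_LGD = 2
    AA_HGD = 3
    CRC_I_II = 4
    CRC_III_IV = 5

    @classmethod
    def parse(cls, value: "str | Stage") -> "Stage":
        if isinstance(value, Stage):
            return value
        try:
            return cls[str(value).strip()]
        except KeyError:
            raise ValueError(
                f"unknown stage {value!r}; expected one of {[s.name for s in cls]}"
            ) from None


STAGE_ORDER: tuple[Stage, ...] = tuple(Stage)

#: Collapsed three-group design used by the progressive-marker filter.
#: MP is deliberately absent (excluded from discovery).
DISCOVERY_GROUPS: dict[str, tuple[Stage, ...]] = {
    "NC": (Stage.NC,),
    "AA": (Stage.AA_LGD, Stage.AA_HGD),
    "CRC": (Stage.CRC_I_II, Stage.CRC_III_IV),
}

DISCOVERY_GROUP_ORDER: tuple[str, ...] = ("NC", "AA", "CRC")


def collapse_stage(stage: "str | Stage") -> str | None:
    """Map a six-level stage to its discovery group name, or None for MP."""
    stage = Stage.parse(stage)
    for group, members in DISCOVERY_GROUPS.items():
        if stage in members:
            return group
    return None
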