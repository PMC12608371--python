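"""Developmental-stage vocabulary for C. elegans epidermal morphogenesis.

Epidermal morphogenesis is divided into six ordered stages, from the
mid-gastrulation period (before the dorsal epidermal cells intercalate)
through ventral enclosure, the rotation ("comma") stage, and the 1.5-fold
and 2-fold elongation stages.  The order is fixed by development itself:
an embryo never revisits an earlier stage, which is what makes
out-of-order stage calls in a timeline diagnosable as misclassifications.
"""

from __future__ import annotations

import enum


class StageLabel(enum.IntEnum):
    """Ordered epidermal-morphogenesis stages.

    The integer values encode developmental order; comparisons between
    labels therefore follow the embryo's actual progression.
    """

    BEFORE_INTERCALATION = 0
    DORSAL_INTERCALATION = 1
    VENTRAL_ENCLOSURE = 2
    ROTATION = 3
    FOLD_1_5 = 4
    FOLD_2 = 5

    @property
    def display_name(self) -> str:
        return _DISPLAY_NAMES[self]

    @property
    def column_name(self) -> str:
        """Name of this stage's probability column in timeline CSV files."""
        return _COLUMN_NAMES[self]

    def successor(self) -> "StageLabel | None":
        """Next stage in developmental order, or None for the final stage."""
        if self is StageLabel.FOLD_2:
            return None
        return StageLabel(self.value + 1)


_DISPLAY_NAMES = {
    StageLabel.BEFORE_INTERCALATION: "before intercalation",
    StageLabel.DORSAL_INTERCALATION: "dorsal intercalation",
    StageLabel.VENTRAL_ENCLOSURE: "ventral enclosure",
    StageLabel.ROTATION: "rotation",
    StageLabel.FOLD_1_5: "1.5-fold",
    StageLabel.FOLD_2: "2-fold",
}

_COLUMN_NAMES = {
    StageLabel.BEFORE_INTERCALATION: "p_before",
    StageLabel.DORSAL_INTERCALATION: "p_dorsal",
    StageLabel.VENTRAL_ENCLOSURE: "p_ventral",
    StageLabel.ROTATION: "p_rotation",
    StageLabel.FOLD_1_5: "p_fold1_5",
    StageLabel.FOLD_2: "p_fold2",
}

#: All six stages in developmental order.
ALL_STAGES: tuple[StageLabel, ...] = tuple(StageLabel)

#: The five stages entering comparative duration statistics.  The
#: before-intercalation span is tracked on every timeline but excluded from
#: group comparisons: dorsal cells have not yet specialised into epidermis,
#: so its duration says little about epidermal development, and acquisition
#: starts mid-way through it anyway.
EPIDERMAL_STAGES: tuple[StageLabel, ...] = tuple(StageLabel)[1:]

N_STAGES = len(ALL_STAGES)

#: Directory names used for stage-labelled image datasets on disk.
STAGE_DIR_NAMES = {s: s.name.lower() for s in StageLabel}


def stage_from_name(name: str) -> StageLabel:
    """Resolve a stage from an enum name, directory name, or display name."""
    key = name.strip().lower().replace("-", "_").replace(" ", "_")
    aliases = {
        "1.5_fold": StageLabel.FOLD_1_5,
        "1.5fold": StageLabel.FOLD_1_5,
        "2_fold": StageLabel.FOLD_2,
        "2fold": StageLabel.FOLD_2,
        "comma": StageLabel.ROTATION,
    }
    if key in aliases:
        return aliases[key]
    try:
        return StageLabel[key.upper()]
    except KeyError:
        raise ValueError(f"unknown stage name: {name!r}") from None
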