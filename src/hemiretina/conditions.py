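"""Condition bookkeeping for the monocular hemiretinal paradigm.

Participants view the display monocularly. A fearful face shown in the
visual field on the same side as the viewing eye lands on the temporal
half of the retina via the *nasal* visual field... more precisely: light
from the left visual field strikes the right (temporal-for-left-eye /
nasal-for-right-eye) halves of the two retinas. For a single viewing eye
the mapping is:

* left viewing eye:  left-field stimulus -> nasal hemiretina,
  right-field stimulus -> temporal hemiretina;
* right viewing eye: the mirror image (left -> temporal, right -> nasal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

SF_BANDS = ("BSF", "LSF", "HSF")
TRIAL_TYPES = ("neutral", "fear_left", "fear_right")
EXPRESSIONS = ("neutral", "fear")

ViewingEye = Literal["left", "right"]
VisualField = Literal["left", "right"]
Hemiretina = Literal["nasal", "temporal"]


def map_hemiretina(viewing_eye: ViewingEye, stimulus_field: VisualField) -> Hemiretina:
    """Hemiretina stimulated by a lateralized stimulus under monocular viewing."""
    if viewing_eye not in ("left", "right"):
        raise ValueError(f"unknown viewing eye {viewing_eye!r}")
    if stimulus_field not in ("left", "right"):
        raise ValueError(f"unknown stimulus field {stimulus_field!r}")
    if viewing_eye == "left":
        return "nasal" if stimulus_field == "left" else "temporal"
    return "temporal" if stimulus_field == "left" else "nasal"


@dataclass(frozen=True)
class ConditionLabel:
    """Full condition of one trial: viewing eye, SF block and trial type.

    ``fear_field`` / ``fear_hemiretina`` are derived: ``none`` for
    neutral-only trials, otherwise the side and hemiretina of the single
    fearful face.
    """

    viewing_eye: ViewingEye
    sf: str
    trial_type: str

    def __post_init__(self) -> None:
        if self.viewing_eye not in ("left", "right"):
            raise ValueError(f"unknown viewing eye {self.viewing_eye!r}")
        if self.sf not in SF_BANDS:
            raise ValueError(f"unknown SF band {self.sf!r}")
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")

    @property
    def fear_field(self) -> str | None:
        if self.trial_type == "fear_left":
            return "left"
        if self.trial_type == "fear_right":
            return "right"
        return None

    @property
    def fear_hemiretina(self) -> str | None:
        field = self.fear_field
        if field is None:
            return None
        return map_hemiretina(self.viewing_eye, field)

    @property
    def emotion(self) -> str:
        """Trial-level emotion factor: 'fear' iff a fearful face is present."""
        return "neutral" if self.trial_type == "neutral" else "fear"
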