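"""Pathology group labels for the six-way prostate lesion design.

The cohort design distinguishes two benign entities — benign nodular
hyperplasia (BNH) and atypical adenomatous hyperplasia (AAH) — from acinar
adenocarcinoma at Gleason patterns 2 through 5.  Carcinoma groups are
frequently pooled against the benign ones, so the label carries a
``carcinoma`` predicate.
"""

from __future__ import annotations

from enum import Enum


class GroupLabel(str, Enum):
    """One of the six pathology groups."""

    BNH = "BNH"
    AAH = "AAH"
    G2 = "G2"
    G3 = "G3"
    G4 = "G4"
    G5 = "G5"

    @property
    def carcinoma(self) -> bool:
        """True for the Gleason-pattern (adenocarcinoma) groups."""
        return self in _CARCINOMA

    def __str__(self) -> str:  # plain value in tables / file names
        return self.value


_CARCINOMA = frozenset({GroupLabel.G2, GroupLabel.G3, GroupLabel.G4, GroupLabel.G5})

#: canonical ordering used everywhere a group axis appears
ALL_GROUPS: tuple[GroupLabel, ...] = (
    GroupLabel.BNH,
    GroupLabel.AAH,
    GroupLabel.G2,
    GroupLabel.G3,
    GroupLabel.G4,
    GroupLabel.G5,
)

CARCINOMA_GROUPS: tuple[GroupLabel, ...] = tuple(g for g in ALL_GROUPS if g.carcinoma)
BENIGN_GROUPS: tuple[GroupLabel, ...] = tuple(g for g in ALL_GROUPS if not g.carcinoma)
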