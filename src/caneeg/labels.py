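"""Stimulus category labels and their species/expression decomposition.

The experiment shows eight stimulus categories: dog and human faces in three
emotional expressions each, household objects, and phase-scrambled face
images. Each face category decomposes into a species factor (dog/human) and
an expression factor (aggressive/neutral/happy); the two non-face categories
carry neither factor.
"""

from __future__ import annotations

from enum import Enum


class CategoryLabel(str, Enum):
    """One of the eight stimulus categories.

    Two-letter codes follow the conventional abbreviations: first letter is
    the expression (A/N/H = aggressive/neutral/happy), second the species
    (D/H = dog/human); ``OB`` is objects and ``S`` scrambled images.
    """

    __str__ = str.__str__  # "AD", not "CategoryLabel.AD"

    AD = "AD"
    ND = "ND"
    HD = "HD"
    AH = "AH"
    NH = "NH"
    HH = "HH"
    OB = "OB"
    S = "S"

    @property
    def species(self) -> str:
        """``"dog"``, ``"human"`` or ``"none"``."""
        if self in _DOG:
            return "dog"
        if self in _HUMAN:
            return "human"
        return "none"

    @property
    def expression(self) -> str:
        """``"aggressive"``, ``"neutral"``, ``"happy"`` or ``"none"``."""
        if self in (CategoryLabel.OB, CategoryLabel.S):
            return "none"
        return {"A": "aggressive", "N": "neutral", "H": "happy"}[self.value[0]]

    @property
    def is_face(self) -> bool:
        return self.species != "none"


_DOG = (CategoryLabel.AD, CategoryLabel.ND, CategoryLabel.HD)
_HUMAN = (CategoryLabel.AH, CategoryLabel.NH, CategoryLabel.HH)

#: All eight categories in canonical order.
ALL_CATEGORIES: tuple[CategoryLabel, ...] = tuple(CategoryLabel)

#: The six face categories (species x expression cells), dog block first.
FACE_CATEGORIES: tuple[CategoryLabel, ...] = _DOG + _HUMAN

DOG_CATEGORIES = _DOG
HUMAN_CATEGORIES = _HUMAN


def as_label(value: "str | CategoryLabel") -> CategoryLabel:
    """Coerce a string code such as ``"AD"`` to a :class:`CategoryLabel`."""
    if isinstance(value, CategoryLabel):
        return value
    try:
        return CategoryLabel(value)
    except ValueError:
        raise ValueError(
            f"unknown category {value!r}; expected one of "
            f"{[c.value for c in CategoryLabel]}"
        ) from None
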