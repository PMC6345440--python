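"""The nine colorectal tissue classes and their fixed ordering.

All activation vectors, confusion matrices and score weights in this
package are indexed by the alphabetical class-code order defined here.
"""

from __future__ import annotations

from enum import Enum

import numpy as np


class TissueClass(str, Enum):
    """Nine-class tissue taxonomy for colorectal H&E histology."""

    ADI = "ADI"
    BACK = "BACK"
    DEB = "DEB"
    LYM = "LYM"
    MUC = "MUC"
    MUS = "MUS"
    NORM = "NORM"
    STR = "STR"
    TUM = "TUM"

    @property
    def display_name(self) -> str:
        return _DISPLAY_NAMES[self]

    @property
    def index(self) -> int:
        return CLASS_CODES.index(self.value)

    @classmethod
    def from_code(cls, code: str) -> "TissueClass":
        try:
            return cls(code)
        except ValueError:
            raise ValueError(
                f"unknown tissue class {code!r}; valid codes are {CLASS_CODES}"
            ) from None


_DISPLAY_NAMES = {
    TissueClass.ADI: "adipose tissue",
    TissueClass.BACK: "background",
    TissueClass.DEB: "debris",
    TissueClass.LYM: "lymphocytes",
    TissueClass.MUC: "mucus",
    TissueClass.MUS: "smooth muscle",
    TissueClass.NORM: "normal colon mucosa",
    TissueClass.STR: "cancer-associated stroma",
    TissueClass.TUM: "colorectal adenocarcinoma epithelium",
}

#: Fixed alphabetical class order used for every vector/matrix in the package.
CLASS_CODES: tuple[str, ...] = tuple(c.value for c in TissueClass)

N_CLASSES: int = len(CLASS_CODES)

#: Default rendering palette (RGB, 0-255), one distinct color per class.
DEFAULT_PALETTE: dict[str, tuple[int, int, int]] = {
    "ADI": (255, 255, 128),
    "BACK": (128, 128, 128),
    "DEB": (128, 64, 0),
    "LYM": (0, 0, 255),
    "MUC": (0, 255, 255),
    "MUS": (255, 0, 255),
    "NORM": (0, 192, 0),
    "STR": (255, 128, 0),
    "TUM": (255, 0, 0),
}


def palette_matrix(palette: dict[str, tuple[int, int, int]] | None = None) -> np.ndarray:
    """Return the palette as a (9, 3) float array in class order.

    Raises ``ValueError`` if a class is missing from the mapping.
    """
    palette = DEFAULT_PALETTE if palette is None else palette
    missing = [c for c in CLASS_CODES if c not in palette]
    if missing:
        raise ValueError(f"palette missing classes: {missing}")
    return np.asarray([palette[c] for c in CLASS_CODES], dtype=float)
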