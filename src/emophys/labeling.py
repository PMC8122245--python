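"""Map Self-Assessment Manikin (SAM) ratings to emotion labels.

Ratings are integer (arousal, valence) pairs on a 1..9 pictorial scale.
Two labelings are provided:

* binary per axis — High iff the score is >= 5 (5 is the scale
  mid-point), independently for arousal and valence;
* four quadrants of the Arousal–Valence plane — HAHV, HALV, LALV, LAHV
  (high/low arousal crossed with high/low valence).

Two quadrant conventions exist because the source description of the
quadrant boundaries is internally inconsistent: its printed inequality
clauses assign the name HALV (nominally high-arousal / low-valence) to a
low-arousal / high-valence region.  The default ``threshold`` convention
derives the quadrant from the two binary labels, so names mean what they
say; the ``literal`` convention applies the printed clauses verbatim for
audit purposes.  Both conventions assign every cell of the 9x9 grid
exactly one label.
"""

from __future__ import annotations

from typing import NamedTuple

import pandas as pd

QUADRANTS: tuple[str, ...] = ("HAHV", "HALV", "LALV", "LAHV")
CONVENTIONS: tuple[str, ...] = ("threshold", "literal")

TASKS: tuple[str, ...] = ("quadrant", "arousal", "valence")


class SAMRating(NamedTuple):
    arousal: int
    valence: int


class EmotionLabel(NamedTuple):
    quadrant: str
    arousal_class: str  # "Low" | "High"
    valence_class: str


def _validate(arousal: int, valence: int) -> None:
    for axis, score in (("arousal", arousal), ("valence", valence)):
        if not (isinstance(score, (int,)) or float(score).is_integer()):
            raise ValueError(f"{axis} rating must be an integer, got {score!r}")
        if not 1 <= int(score) <= 9:
            raise ValueError(f"{axis} rating must be in 1..9, got {score!r}")


def binary_labels(rating: SAMRating | tuple[int, int]) -> tuple[str, str]:
    """(arousal_class, valence_class): High iff score >= 5."""
    arousal, valence = rating
    _validate(arousal, valence)
    return (
        "High" if arousal >= 5 else "Low",
        "High" if valence >= 5 else "Low",
    )


_BINARY_TO_QUADRANT = {
    ("High", "High"): "HAHV",
    ("High", "Low"): "HALV",
    ("Low", "Low"): "LALV",
    ("Low", "High"): "LAHV",
}


def quadrant_label(rating: SAMRating | tuple[int, int], convention: str = "threshold") -> str:
    """Quadrant of the Arousal–Valence plane for a SAM rating."""
    arousal, valence = rating
    _validate(arousal, valence)
    if convention == "threshold":
        return _BINARY_TO_QUADRANT[binary_labels(rating)]
    if convention == "literal":
        # the four printed clauses, applied verbatim
        if (arousal > 5 and valence >= 5) or (arousal == 5 and valence == 5):
            return "HAHV"
        if arousal <= 5 and valence > 5:
            return "HALV"
        if arousal < 5 and valence <= 5:
            return "LALV"
        if arousal >= 5 and valence < 5:
            return "LAHV"
        raise AssertionError("unreachable: clauses cover the grid")
    raise ValueError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")


def emotion_label(rating: SAMRating | tuple[int, int], convention: str = "threshold") -> EmotionLabel:
    a_cls, v_cls = binary_labels(rating)
    return EmotionLabel(quadrant_label(rating, convention), a_cls, v_cls)


def label_table(sam: pd.DataFrame, convention: str = "threshold") -> pd.DataFrame:
    """Label a table of SAM ratings.

    Parameters
    ----------
    sam
        Columns ``pid, trial, arousal, valence`` (one row per trial).

    Returns
    -------
    DataFrame with columns ``pid, trial, quadrant, arousal_class,
    valence_class``.
    """
    out = sam[["pid", "trial"]].copy()
    labels = [
        emotion_label((int(a), int(v)), convention)
        for a, v in zip(sam["arousal"], sam["valence"])
    ]
    out["quadrant"] = [lab.quadrant for lab in labels]
    out["arousal_class"] = [lab.arousal_class for lab in labels]
    out["valence_class"] = [lab.valence_class for lab in labels]
    return out


def task_labels(labels: pd.DataFrame, task: str) -> pd.Series:
    """Pick the label column for one of the three classification tasks."""
    column = {
        "quadrant": "quadrant",
        "arousal": "arousal_class",
        "valence": "valence_class",
    }
    if task not in column:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    return labels[column[task]]
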