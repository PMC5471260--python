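"""Schema and validation for the nine radiologist-scored semantic features.

Three features are binary (presence/absence), six are ordinal.  The legal
score sets:

=================  =========  =============================================
feature            scores     meaning
=================  =========  =============================================
cavitation         0/1        gas-filled cavity from central necrosis
air_bronchogram    0/1        tubular/branched air structure in the tumor
calcification      0/1        calcium layer(s) in any pattern
texture            1-3        1 non-solid/GGO, 2 part-solid, 3 solid
border_definition  1-3        1 well defined ... 3 poorly defined
contour            1-4        1 round, 2 oval, 3 somewhat irregular, 4 irregular
lobulation         1-4        1 none, 2-4 increasing undulation
spiculation        1-3        1 none, 2 fine, 3 coarse spikes
concavity          1-3        1 none, 2 slight, 3 deep surface notches
=================  =========  =============================================
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "BINARY_FEATURES",
    "CATEGORICAL_FEATURES",
    "SEMANTIC_FEATURES",
    "SCORE_RANGES",
    "SemanticRecord",
    "CohortTable",
    "validate_cohort_frame",
]

BINARY_FEATURES = ("cavitation", "air_bronchogram", "calcification")
CATEGORICAL_FEATURES = (
    "texture",
    "border_definition",
    "contour",
    "lobulation",
    "spiculation",
    "concavity",
)
SEMANTIC_FEATURES = BINARY_FEATURES + CATEGORICAL_FEATURES

#: feature -> tuple of legal integer scores
SCORE_RANGES: dict[str, tuple[int, ...]] = {
    "cavitation": (0, 1),
    "air_bronchogram": (0, 1),
    "calcification": (0, 1),
    "texture": (1, 2, 3),
    "border_definition": (1, 2, 3),
    "contour": (1, 2, 3, 4),
    "lobulation": (1, 2, 3, 4),
    "spiculation": (1, 2, 3),
    "concavity": (1, 2, 3),
}


@dataclass(frozen=True)
class SemanticRecord:
    """One subject's nine semantic scores; validated on construction."""

    subject_id: str
    cavitation: int
    air_bronchogram: int
    calcification: int
    texture: int
    border_definition: int
    contour: int
    lobulation: int
    spiculation: int
    concavity: int

    def __post_init__(self) -> None:
        for name in SEMANTIC_FEATURES:
            value = getattr(self, name)
            if isinstance(value, bool) or value != int(value):
                raise ValueError(
                    f"subject {self.subject_id!r}: {name} = {value!r} is not an integer"
                )
            if int(value) not in SCORE_RANGES[name]:
                raise ValueError(
                    f"subject {self.subject_id!r}: {name} = {value} outside the "
                    f"allowed scores {SCORE_RANGES[name]}"
                )
            object.__setattr__(self, name, int(value))

    def as_dict(self) -> dict:
        return {"subject_id": self.subject_id, **{f: getattr(self, f) for f in SEMANTIC_FEATURES}}


class CohortTable:
    """Semantic scores for a cohort, one validated row per subject.

    Wraps a :class:`pandas.DataFrame` indexed by unique ``subject_id`` with
    the nine semantic columns in canonical order.
    """

    def __init__(self, records: list[SemanticRecord]):
        if not records:
            raise ValueError("cohort must contain at least one record")
        ids = [r.subject_id for r in records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate subject_id(s): {sorted(dupes)}")
        self.frame = pd.DataFrame([r.as_dict() for r in records]).set_index("subject_id")
        self.frame = self.frame[list(SEMANTIC_FEATURES)].astype(int)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortTable":
        """Build from a DataFrame with a subject_id column or index."""
        df = frame.reset_index() if frame.index.name == "subject_id" else frame.copy()
        if "subject_id" not in df.columns:
            raise ValueError("missing subject_id column")
        missing = [c for c in SEMANTIC_FEATURES if c not in df.columns]
        if missing:
            raise ValueError(f"missing semantic column(s): {missing}")
        records = [
            SemanticRecord(subject_id=str(row["subject_id"]),
                           **{f: row[f] for f in SEMANTIC_FEATURES})
            for _, row in df.iterrows()
        ]
        return cls(records)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame.index)

    def degenerate_binary_columns(self) -> list[str]:
        """Binary features missing one of the two classes (must be flagged
        before association analysis; such columns are skipped there)."""
        return [
            f for f in BINARY_FEATURES if self.frame[f].nunique() < 2
        ]


def validate_cohort_frame(frame: pd.DataFrame) -> CohortTable:
    """Validate a raw semantic-score DataFrame; raises with subject/column detail."""
    return CohortTable.from_frame(frame)
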