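"""Behavioral design matrix for brain-behavior PLSC.

The design Y has six columns in a fixed order: z-scored age, z-scored
APOE4-carrier indicator, z-scored symptom indicator, and the three pairwise
interactions formed as elementwise products of the z-scored main effects.
Interactions are deliberately *not* re-standardized after multiplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

DESIGN_COLUMNS = (
    "age",
    "apoe4",
    "symptoms",
    "age_x_apoe4",
    "age_x_symptoms",
    "apoe4_x_symptoms",
)

#: Columns entering the aging score: age and its two interactions.
AGE_COLUMNS = ("age", "age_x_apoe4", "age_x_symptoms")
AGE_COLUMN_INDICES = tuple(DESIGN_COLUMNS.index(c) for c in AGE_COLUMNS)

_SYMPTOMATIC = {"MCI", "AD"}
_NON_SYMPTOMATIC = {"CN", "SMC"}
_ADMISSIBLE_DIAGNOSES = sorted(_SYMPTOMATIC | _NON_SYMPTOMATIC)


def encode_symptoms(diagnosis: str) -> int:
    """Binary symptom coding: MCI and AD are symptomatic (1); CN and SMC are not (0).

    Labels are case-insensitive. Unknown labels raise a ``ValidationError``
    listing the admissible set.
    """
    label = str(diagnosis).strip().upper()
    if label in _SYMPTOMATIC:
        return 1
    if label in _NON_SYMPTOMATIC:
        return 0
    raise ValidationError(
        f"unknown diagnosis {diagnosis!r}; admissible labels: {_ADMISSIBLE_DIAGNOSES}"
    )


def encode_apoe4(genotype: str) -> int:
    """Carrier coding: any genotype containing an E4 allele maps to 1, else 0."""
    return int("E4" in str(genotype).strip().upper())


def zscore(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standardize a vector to mean 0, sd 1 using the sample sd (ddof=1)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError("cannot z-score a constant (zero-variance) column")
    return (x - x.mean()) / sd


@dataclass
class BehavioralDesign:
    """Subjects x 6 behavioral matrix Y.

    Parameters
    ----------
    values : ndarray, shape (n_subjects, 6)
        Columns in :data:`DESIGN_COLUMNS` order. The three main effects are
        z-scored; interactions are products of z-scored columns.
    subject_ids : list of str
        Row labels, in the same order as the phenotype table.
    """

    values: np.ndarray
    subject_ids: list = field(default_factory=list)
    column_names: tuple = DESIGN_COLUMNS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValidationError(
                f"design matrix must be subjects x 6, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("design matrix contains non-finite values")
        if self.subject_ids and len(self.subject_ids) != self.values.shape[0]:
            raise ValidationError("subject_ids length does not match row count")
        z = self.values[:, :3]
        if np.abs(z.mean(axis=0)).max() > 1e-10:
            raise ValidationError("main-effect columns must have mean 0")
        if np.abs(z.std(axis=0, ddof=1) - 1.0).max() > 1e-10:
            raise ValidationError("main-effect columns must have unit sample sd")
        products = np.column_stack(
            [z[:, 0] * z[:, 1], z[:, 0] * z[:, 2], z[:, 1] * z[:, 2]]
        )
        if np.abs(self.values[:, 3:] - products).max() > 1e-10:
            raise ValidationError(
                "interaction columns must equal products of the z-scored main effects"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        idx = self.subject_ids if self.subject_ids else None
        return pd.DataFrame(self.values, columns=list(self.column_names), index=idx)


def build_design(cohort: pd.DataFrame) -> BehavioralDesign:
    """Build the six-column design Y from a phenotype table.

    The table needs columns ``age``, ``apoe_genotype`` (or a binary ``apoe4``),
    and ``diagnosis`` (or a binary ``symptoms``); already-binary inputs are
    accepted unchanged, so re-encoding is idempotent. Row order is preserved.

    Raises
    ------
    ValidationError
        With fewer than 3 subjects, missing values, or a zero-variance column
        (e.g. a cohort that is all carriers), for which z-scoring is undefined.
    """
    if len(cohort) < 3:
        raise ValidationError("design requires at least 3 subjects")
    if "age" not in cohort.columns:
        raise ValidationError("phenotype table lacks an 'age' column")
    age = cohort["age"].to_numpy(dtype=float)

    if "apoe4" in cohort.columns:
        carrier = cohort["apoe4"].to_numpy(dtype=float)
        if not np.isin(carrier, (0.0, 1.0)).all():
            raise ValidationError("'apoe4' column must be binary 0/1")
    elif "apoe_genotype" in cohort.columns:
        carrier = np.array([encode_apoe4(g) for g in cohort["apoe_genotype"]], float)
    else:
        raise ValidationError("phenotype table lacks 'apoe_genotype' or 'apoe4'")

    if "symptoms" in cohort.columns:
        sympt = cohort["symptoms"].to_numpy(dtype=float)
        if not np.isin(sympt, (0.0, 1.0)).all():
            raise ValidationError("'symptoms' column must be binary 0/1")
    elif "diagnosis" in cohort.columns:
        sympt = np.array([encode_symptoms(d) for d in cohort["diagnosis"]], float)
    else:
        raise ValidationError("phenotype table lacks 'diagnosis' or 'symptoms'")

    if np.isnan(age).any():
        raise ValidationError("missing ages in phenotype table")

    cols = {}
    for name, raw in (("age", age), ("apoe4", carrier), ("symptoms", sympt)):
        try:
            cols[name] = zscore(raw)
        except ValidationError as exc:
            raise ValidationError(f"column '{name}' is constant: {exc}") from None

    values = np.column_stack(
        [
            cols["age"],
            cols["apoe4"],
            cols["symptoms"],
            cols["age"] * cols["apoe4"],
            cols["age"] * cols["symptoms"],
            cols["apoe4"] * cols["symptoms"],
        ]
    )
    ids = (
        list(cohort["subject_id"]) if "subject_id" in cohort.columns
        else [str(i) for i in cohort.index]
    )
    return BehavioralDesign(values=values, subject_ids=ids)
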