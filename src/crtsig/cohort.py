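"""Containers for bulk expression cohorts and harmonized matrices.

An :class:`ExpressionCohort` holds one dataset's gene x sample matrix together
with per-sample annotation (dataset/batch label, platform class, tumor
regression grade and the derived binary response label). The harmonization
stage turns cohorts into :class:`HarmonizedMatrix` objects whose rows are
mean-centered and standardized within each source dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError

# Response labels derived from Mandard tumor regression grades.
RESPONDER = "responder"
NON_RESPONDER = "non-responder"
MID_RESPONDER = "mid-responder"
UNKNOWN = "unknown"

#: Mandard TRG -> binary response mapping: grades 1-2 respond, 3 is the
#: pathological mid-responder excluded from modeling, 4-5 do not respond.
TRG_RESPONSE_MAP = {
    1: RESPONDER,
    2: RESPONDER,
    3: MID_RESPONDER,
    4: NON_RESPONDER,
    5: NON_RESPONDER,
}

PLATFORM_INTENSITY = "intensity"
PLATFORM_COUNT = "count"

#: Columns every sample-annotation table must carry.
ANNOTATION_COLUMNS = ("batch", "platform", "trg", "response")


@dataclass
class ExpressionCohort:
    """One dataset: raw gene x sample values plus sample annotations.

    Parameters
    ----------
    name
        Dataset label (also used as the default batch label).
    expr
        Gene x sample matrix; index = gene ids, columns = sample ids.
    samples
        Annotation indexed by sample id with columns ``batch``, ``platform``
        (``intensity`` or ``count``), ``trg`` (nullable integer grade) and
        ``response``.
    """

    name: str
    expr: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.expr.index.duplicated().any():
            dupes = self.expr.index[self.expr.index.duplicated()].unique().tolist()
            raise DataError(f"cohort {self.name!r}: duplicate gene ids {dupes[:5]}")
        if self.expr.columns.duplicated().any():
            dupes = self.expr.columns[self.expr.columns.duplicated()].unique().tolist()
            raise DataError(f"cohort {self.name!r}: duplicate sample ids {dupes[:5]}")
        if not self.expr.columns.equals(self.samples.index):
            if set(self.expr.columns) != set(self.samples.index):
                raise DataError(
                    f"cohort {self.name!r}: matrix columns and annotation rows disagree"
                )
            self.samples = self.samples.loc[self.expr.columns]
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.samples.columns]
        if missing:
            raise DataError(f"cohort {self.name!r}: annotation lacks columns {missing}")
        counts = self.samples["platform"] == PLATFORM_COUNT
        if counts.any():
            block = self.expr.loc[:, counts.to_numpy()]
            if (block.to_numpy() < 0).any():
                raise DataError(f"cohort {self.name!r}: negative counts present")

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]


@dataclass
class HarmonizedMatrix:
    """Merged, per-dataset standardized expression.

    ``transform`` records the (mean, sd) used for every retained (dataset,
    gene) pair so new samples from a known dataset can be projected onto the
    harmonized scale; ``dropped_genes`` lists genes removed for zero variance
    per dataset.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    transform: pd.DataFrame  # columns: dataset, gene, mean, sd
    provenance: list[str] = field(default_factory=list)
    dropped_genes: dict[str, list[str]] = field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def batches(self) -> pd.Series:
        return self.samples["batch"]
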