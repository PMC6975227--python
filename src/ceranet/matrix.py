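"""Expression matrix container shared by all pipeline stages.

An :class:`ExpressionMatrix` is a molecules x samples table of nonnegative
expression values together with a molecule-class annotation (``mRNA``,
``lncRNA`` or ``miRNA``) and a per-sample condition label (``tumor`` or
``normal``). It is a thin, validated wrapper around a :class:`pandas.DataFrame`
so every stage speaks the same dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MOLECULE_CLASSES = ("mRNA", "lncRNA", "miRNA")
CONDITIONS = ("tumor", "normal")


@dataclass
class ExpressionMatrix:
    """Nonnegative expression values with molecule-class and condition labels.

    Parameters
    ----------
    values
        DataFrame indexed by molecule id, columns = sample ids.
    molecule_class
        Series mapping molecule id -> class in ``{"mRNA", "lncRNA", "miRNA"}``.
    sample_condition
        Series mapping sample id -> condition in ``{"tumor", "normal"}``.
    """

    values: pd.DataFrame
    molecule_class: pd.Series
    sample_condition: pd.Series
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate molecule ids in expression matrix")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if (np.asarray(v.values) < 0).any():
            raise ValueError("expression values must be nonnegative")
        self.molecule_class = self.molecule_class.reindex(v.index)
        if self.molecule_class.isna().any():
            missing = list(v.index[self.molecule_class.isna()][:5])
            raise ValueError(f"molecules without class annotation: {missing}")
        bad = set(self.molecule_class.unique()) - set(MOLECULE_CLASSES)
        if bad:
            raise ValueError(f"unknown molecule classes: {sorted(bad)}")
        self.sample_condition = self.sample_condition.reindex(v.columns)
        if self.sample_condition.isna().any():
            missing = list(v.columns[self.sample_condition.isna()][:5])
            raise ValueError(f"samples without condition label: {missing}")
        bad = set(self.sample_condition.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown sample conditions: {sorted(bad)}")
        self._validated = True

    # -- convenience accessors -------------------------------------------------

    @property
    def molecules(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def tumor_samples(self) -> pd.Index:
        return self.values.columns[self.sample_condition.values == "tumor"]

    @property
    def normal_samples(self) -> pd.Index:
        return self.values.columns[self.sample_condition.values == "normal"]

    def subset_molecules(self, ids) -> "ExpressionMatrix":
        """Row-subset preserving the given order."""
        ids = pd.Index(ids)
        unknown = ids.difference(self.molecules)
        if len(unknown):
            raise KeyError(f"unknown molecule ids: {list(unknown[:5])}")
        return ExpressionMatrix(
            self.values.loc[ids],
            self.molecule_class.loc[ids],
            self.sample_condition,
        )

    def subset_samples(self, ids) -> "ExpressionMatrix":
        ids = pd.Index(ids)
        unknown = ids.difference(self.samples)
        if len(unknown):
            raise KeyError(f"unknown sample ids: {list(unknown[:5])}")
        return ExpressionMatrix(
            self.values[ids], self.molecule_class, self.sample_condition.loc[ids]
        )

    def of_class(self, cls: str) -> "ExpressionMatrix":
        return self.subset_molecules(self.molecules[self.molecule_class.values == cls])

    def zero_fraction(self, condition: str) -> pd.Series:
        """Per-molecule fraction of zero values among samples of a condition."""
        cols = self.values.columns[self.sample_condition.values == condition]
        if len(cols) == 0:
            raise ValueError(f"no {condition} samples")
        return (self.values[cols] == 0).mean(axis=1)

    # -- I/O -------------------------------------------------------------------

    def to_tsv(self, expr_path, annotation_path=None, condition_path=None) -> None:
        """Write values (and optionally annotation/condition tables) as TSV."""
        self.values.rename_axis("molecule_id").to_csv(expr_path, sep="\t")
        if annotation_path is not None:
            self.molecule_class.rename("class").rename_axis("molecule_id").to_csv(
                annotation_path, sep="\t"
            )
        if condition_path is not None:
            self.sample_condition.rename("condition").rename_axis("sample_id").to_csv(
                condition_path, sep="\t"
            )

    @classmethod
    def from_tsv(cls, expr_path, annotation_path, condition_path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0).rename_axis(None)
        anno = pd.read_csv(annotation_path, sep="\t", index_col=0)["class"].rename_axis(None)
        cond = pd.read_csv(condition_path, sep="\t", index_col=0)["condition"].rename_axis(None)
        return cls(values, anno, cond)


def concat_matrices(matrices) -> ExpressionMatrix:
    """Stack matrices over the same samples (e.g. mRNA + lncRNA + miRNA)."""
    matrices = list(matrices)
    base = matrices[0]
    for m in matrices[1:]:
        if not base.samples.equals(m.samples):
            raise ValueError("matrices must share identical sample columns")
    return ExpressionMatrix(
        pd.concat([m.values for m in matrices]),
        pd.concat([m.molecule_class for m in matrices]),
        base.sample_condition,
    )
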