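"""Core in-memory containers shared across the pipeline.

Both omics inputs are feature-by-sample tables with a two-group design
(control ``CON`` vs treated ``RPA``).  They are thin, validated wrappers
around a :class:`pandas.DataFrame` so every stage can rely on consistent
dimensions, unique feature identifiers and exactly two group labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CONTROL_LABEL = "CON"
TREATED_LABEL = "RPA"
VALID_LABELS = (CONTROL_LABEL, TREATED_LABEL)


@dataclass
class FeatureMatrix:
    """A features x samples value matrix with per-sample group labels."""

    values: pd.DataFrame  # index = feature ids, columns = sample ids
    group_labels: pd.Series  # index = sample ids, values in {CON, RPA}

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if not isinstance(self.group_labels, pd.Series):
            self.group_labels = pd.Series(
                list(self.group_labels), index=self.values.columns
            )
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature identifiers: {list(dupes)}")
        if list(self.group_labels.index) != list(self.values.columns):
            self.group_labels = self.group_labels.reindex(self.values.columns)
        if self.group_labels.isna().any():
            missing = self.group_labels.index[self.group_labels.isna()]
            raise ValueError(f"samples without a group label: {list(missing)}")
        bad = set(self.group_labels) - set(VALID_LABELS)
        if bad:
            raise ValueError(
                f"unknown group labels {sorted(bad)}; expected {VALID_LABELS}"
            )
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("matrix contains non-finite values")

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_columns(self, label: str) -> pd.DataFrame:
        """Sub-matrix of the samples carrying ``label``."""
        if label not in VALID_LABELS:
            raise ValueError(f"unknown group label {label!r}; expected {VALID_LABELS}")
        mask = (self.group_labels == label).to_numpy()
        return self.values.loc[:, mask]

    def x_samples_by_features(self) -> np.ndarray:
        """Values as a samples x features float array (the ML orientation)."""
        return self.values.to_numpy(dtype=float).T

    def y_binary(self) -> np.ndarray:
        """Group labels as 0 (CON) / 1 (RPA)."""
        return (self.group_labels == TREATED_LABEL).to_numpy(dtype=float)


@dataclass
class ExpressionMatrix(FeatureMatrix):
    """Gene expression (FPKM-like, non-negative) for one organ."""

    organ: str = "unknown"

    def __post_init__(self) -> None:
        super().__post_init__()
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError(
                f"expression matrix for organ {self.organ!r} has negative values"
            )


@dataclass
class MetaboliteMatrix(FeatureMatrix):
    """Serum metabolite feature table (binned spectral intensities or named
    metabolites) across the two groups."""


@dataclass
class GroundTruth:
    """Identifiers of the truly perturbed features in a simulated dataset.

    ``signed_effects`` maps feature id -> signed shift actually injected
    (log2 units for expression, intensity units for metabolites).
    """

    signed_effects: dict[str, float] = field(default_factory=dict)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.signed_effects)

    @property
    def up_ids(self) -> list[str]:
        return [f for f, e in self.signed_effects.items() if e > 0]

    @property
    def down_ids(self) -> list[str]:
        return [f for f, e in self.signed_effects.items() if e < 0]


def validate_two_groups(labels: Sequence[str]) -> None:
    """Raise unless both CON and RPA are present."""
    present = set(labels)
    for needed in VALID_LABELS:
        if needed not in present:
            raise ValueError(f"group {needed!r} absent from labels")
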