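"""Mixed-type cohort tables with explicit missingness.

Values live in a float DataFrame; categorical columns hold level codes
0..n_levels-1 and missing cells hold NaN, mirrored by a boolean mask so the
sentinel can never silently leak into statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class VariableMeta:
    name: str
    label: str = ""
    vtype: str = CONTINUOUS
    n_levels: int = 0
    category: str | None = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.vtype not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown vtype {self.vtype!r}")
        if self.vtype == CATEGORICAL and self.n_levels < 2:
            raise ValueError(f"categorical variable {self.name} needs >= 2 levels")
        if self.vtype == CONTINUOUS and self.n_levels not in (0, 1):
            raise ValueError(f"continuous variable {self.name} cannot declare levels")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")

    @property
    def is_categorical(self) -> bool:
        return self.vtype == CATEGORICAL


class MixedDataset:
    """n_samples × n_variables table plus per-column metadata and missingness mask."""

    def __init__(self, values: pd.DataFrame, meta: list[VariableMeta], mask: pd.DataFrame | None = None):
        if len(meta) != values.shape[1]:
            raise ValueError("meta length must equal column count")
        names = [m.name for m in meta]
        if list(values.columns) != names:
            raise ValueError("column order must match metadata order")
        values = values.astype(float)
        if mask is None:
            mask = values.isna()
        else:
            mask = mask.astype(bool)
            if mask.shape != values.shape:
                raise ValueError("mask shape must match values")
            mask.columns = values.columns
            mask.index = values.index
        values = values.where(~mask)  # enforce the NaN sentinel under the mask
        for m in meta:
            if m.is_categorical:
                col = values[m.name].dropna()
                if len(col) and not col.isin(range(m.n_levels)).all():
                    raise ValueError(f"column {m.name} holds codes outside 0..{m.n_levels - 1}")
        self.values = values
        self.meta = list(meta)
        self.mask = mask

    # -- basics --------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    def meta_for(self, name: str) -> VariableMeta:
        return self._meta_map()[name]

    def _meta_map(self) -> dict[str, VariableMeta]:
        return {m.name: m for m in self.meta}

    def missing_fraction(self, name: str) -> float:
        if self.n_samples == 0:
            return 0.0
        return float(self.mask[name].mean())

    def is_complete(self) -> bool:
        return not bool(self.mask.values.any())

    def copy(self) -> "MixedDataset":
        return MixedDataset(self.values.copy(), list(self.meta), self.mask.copy())

    def select(self, names: list[str]) -> "MixedDataset":
        mm = self._meta_map()
        return MixedDataset(self.values[names].copy(), [mm[n] for n in names], self.mask[names].copy())

    def with_values(self, values: pd.DataFrame, mask: pd.DataFrame | None = None) -> "MixedDataset":
        return MixedDataset(values, list(self.meta), mask)

    def update_meta(self, name: str, **changes) -> None:
        self.meta = [replace(m, **changes) if m.name == name else m for m in self.meta]

    # -- typed views -----------------------------------------------------------
    @property
    def continuous_names(self) -> list[str]:
        return [m.name for m in self.meta if not m.is_categorical]

    @property
    def categorical_names(self) -> list[str]:
        return [m.name for m in self.meta if m.is_categorical]

    # -- serialization -----------------------------------------------------------
    def to_csv(self, path) -> None:
        """CSV with header row; missing cells are written as empty strings."""
        out = self.values.copy()
        for m in self.meta:
            if m.is_categorical:
                col = out[m.name]
                out[m.name] = col.map(lambda x: "" if pd.isna(x) else str(int(x)))
        out.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path, meta: list[VariableMeta]) -> "MixedDataset":
        raw = pd.read_csv(path, na_values=[""], keep_default_na=True)
        raw = raw[[m.name for m in meta]]
        return cls(raw.astype(float), meta)


def write_dictionary_tsv(meta: list[VariableMeta], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tlabel\tvtype\tn_levels\tcategory\n")
        for m in meta:
            fh.write(f"{m.name}\t{m.label}\t{m.vtype}\t{m.n_levels}\t{m.category or 'none'}\n")


def read_dictionary_tsv(path) -> list[VariableMeta]:
    meta = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["name", "label"]:
            raise ValueError("unexpected dictionary header")
        for line in fh:
            if not line.strip():
                continue
            name, label, vtype, n_levels, category = line.rstrip("\n").split("\t")
            meta.append(
                VariableMeta(
                    name=name,
                    label=label,
                    vtype=vtype,
                    n_levels=int(n_levels),
                    category=None if category == "none" else category,
                )
            )
    return meta


def one_hot(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Dense indicator matrix for integer level codes (no NaN allowed)."""
    codes = np.asarray(codes)
    if np.isnan(codes.astype(float)).any():
        raise ValueError("cannot one-hot encode missing codes")
    out = np.zeros((len(codes), n_levels))
    out[np.arange(len(codes)), codes.astype(int)] = 1.0
    return out
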