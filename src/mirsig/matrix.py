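"""Core expression-matrix container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of log2 intensities with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature identifier with one column per sample.
        All values are log2-scale intensities; missing values are not
        supported.
    sample_groups
        Series mapping each sample (column of ``values``) to its group label.
    group_order
        Ordered group identifiers. The first entry is the reference group
        against which all contrasts are formed.
    """

    values: pd.DataFrame
    sample_groups: pd.Series
    group_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature identifier: {dup!r}")
        if self.values.isna().any().any():
            raise ValueError("missing values are not supported in expression matrices")
        self.sample_groups = pd.Series(self.sample_groups)
        missing = [s for s in self.values.columns if s not in self.sample_groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.sample_groups = self.sample_groups.loc[list(self.values.columns)]
        if not self.group_order:
            seen: list[str] = []
            for g in self.sample_groups:
                if g not in seen:
                    seen.append(g)
            self.group_order = tuple(seen)
        unknown = set(self.sample_groups) - set(self.group_order)
        if unknown:
            raise ValueError(f"sample groups not listed in group_order: {sorted(unknown)}")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def reference_group(self) -> str:
        return self.group_order[0]

    def samples_in(self, group: str) -> list[str]:
        """Column names of the samples belonging to ``group``."""
        if group not in self.group_order:
            raise KeyError(f"unknown group: {group!r}")
        return [s for s, g in self.sample_groups.items() if g == group]

    def subset(self, groups: list[str]) -> "ExpressionMatrix":
        cols = [s for s in self.values.columns if self.sample_groups[s] in groups]
        return ExpressionMatrix(
            self.values[cols].copy(),
            self.sample_groups.loc[cols],
            tuple(g for g in self.group_order if g in groups),
        )
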