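"""Expression-presence classes and the cross-condition contingency table.

A gene is classified per condition by the proportion of samples in which its
TPM was exactly zero (the missing rate): constitutive when < 5% of samples
are missing, repressed when > 95% are missing, mixed otherwise. Boundary
rates of exactly 0.05 or 0.95 are mixed — the defining inequalities are
strict on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

CLASSES = ("constitutive", "mixed", "repressed")


@dataclass(frozen=True)
class ClassThresholds:
    constitutive_max_missing: float = 0.05
    repressed_min_missing: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.constitutive_max_missing < self.repressed_min_missing < 1.0):
            raise ValueError("require 0 < constitutive_max_missing < repressed_min_missing < 1")


def missing_rate(expr: ExpressionMatrix, condition: str | None = None) -> pd.Series:
    """Per-gene proportion of masked cells; replicates pooled.

    condition=None pools both conditions (one rate per gene over all
    samples), which is what the overall missingness distribution uses.
    """
    if condition is None:
        cols = np.arange(expr.n_samples)
    else:
        cols = expr.sample_columns(condition=condition)
        if cols.size == 0:
            raise ValueError(f"condition {condition!r} absent from samples")
    return pd.Series(expr.missing_mask[:, cols].mean(axis=1), index=expr.gene_ids)


def classify_gene(rate: float, th: ClassThresholds = ClassThresholds()) -> str:
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"missing rate {rate} outside [0, 1]")
    if rate < th.constitutive_max_missing:
        return "constitutive"
    if rate > th.repressed_min_missing:
        return "repressed"
    return "mixed"


def gene_class_table(
    expr: ExpressionMatrix, th: ClassThresholds = ClassThresholds()
) -> pd.DataFrame:
    """Tidy per gene x condition table: missing rate, class, mean expression.

    mean_nonzero_log2tpm averages only unmasked cells; a gene with every
    sample masked in a condition gets NaN there (explicitly undefined).
    """
    rows = []
    for cond in expr.conditions:
        cols = expr.sample_columns(condition=cond)
        mask = expr.missing_mask[:, cols]
        vals = expr.values[:, cols]
        rate = mask.mean(axis=1)
        with np.errstate(invalid="ignore"):
            mean_nz = np.where(
                (~mask).sum(axis=1) > 0,
                np.where(mask, 0.0, vals).sum(axis=1) / np.maximum((~mask).sum(axis=1), 1),
                np.nan,
            )
        for i, g in enumerate(expr.gene_ids):
            rows.append(
                {
                    "gene_id": g,
                    "condition": cond,
                    "missing_rate": float(rate[i]),
                    "gene_class": classify_gene(float(rate[i]), th),
                    "mean_nonzero_log2tpm": float(mean_nz[i]),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ContingencyTable:
    """3x3 control-class x salt-class gene counts with margins."""

    counts: pd.DataFrame  # index: control class, columns: salt class

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(index=CLASSES, columns=CLASSES).fillna(0).astype(int)

    def cell(self, control_class: str, salt_class: str) -> int:
        return int(self.counts.loc[control_class, salt_class])

    def transitions(self, a: str, b: str) -> int:
        """Genes that moved between classes a and b in either direction."""
        if a == b:
            raise ValueError("transitions are between two distinct classes")
        return self.cell(a, b) + self.cell(b, a)

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def with_margins(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["Totals"] = self.row_totals
        out.loc["Totals"] = out.sum(axis=0)
        return out

    @classmethod
    def from_cells(cls, cells: dict[tuple[str, str], int]) -> "ContingencyTable":
        df = pd.DataFrame(0, index=CLASSES, columns=CLASSES)
        for (a, b), n in cells.items():
            df.loc[a, b] = n
        return cls(df)


def cross_tabulate(class_table: pd.DataFrame) -> ContingencyTable:
    """Cross-tabulate control vs salt classes from gene_class_table output."""
    wide = class_table.pivot(index="gene_id", columns="condition", values="gene_class")
    for cond in ("control", "salt"):
        if cond not in wide.columns:
            raise ValueError(f"condition {cond!r} missing from class table")
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        raise ValueError(
            f"gene(s) classified in only one condition: {list(incomplete[:5])}"
        )
    counts = pd.crosstab(wide["control"], wide["salt"])
    return ContingencyTable(counts)
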