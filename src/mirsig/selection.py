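"""Directional calls, two-tier resistance-signature selection, classification.

A miRNA enters the resistance signature if it shows a significant change of
more than ``fold_cut`` in BOTH cell lines resistant to the same drug
(tier 1), or a significant change of at least ``fold_cut_single`` in any
single resistant line (tier 2). Calls require both the fold cut-off and the
adjusted-p cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Thresholds",
    "LINE_TO_DRUG",
    "RESISTANT_LINES",
    "REFERENCE_LINE",
    "call_direction",
    "build_call_table",
    "classify_mirnas",
    "drug_signatures",
    "apply_two_tier_selection",
    "SelectionResult",
    "selection_summary",
]

REFERENCE_LINE = "A2780"
RESISTANT_LINES = ("A2780CR1", "A2780CR2", "A2780PR1", "A2780PR2")
LINE_TO_DRUG = {
    "A2780CR1": "CIS",
    "A2780CR2": "CIS",
    "A2780PR1": "PAC",
    "A2780PR2": "PAC",
}


@dataclass(frozen=True)
class Thresholds:
    """Cut-offs for directional calls and the two selection tiers.

    ``fold_cut`` is compared strictly (>) and ``alpha`` strictly (<) by
    default; tier 2 uses a non-strict ``>= fold_cut_single``. The strictness
    flags make both conventions configurable.
    """

    fold_cut: float = 5.0
    fold_cut_single: float = 10.0
    alpha: float = 0.05
    strict_fold: bool = True
    strict_alpha: bool = True

    def __post_init__(self) -> None:
        if self.fold_cut <= 1 or self.fold_cut_single <= 1:
            raise ValueError("fold cut-offs must exceed 1")
        if self.fold_cut_single < self.fold_cut:
            raise ValueError("fold_cut_single must be >= fold_cut")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")

    def _passes_fold(self, magnitude: float, cut: float) -> bool:
        return magnitude > cut if self.strict_fold else magnitude >= cut

    def _passes_alpha(self, p_adj: float) -> bool:
        if np.isnan(p_adj):
            return False
        return p_adj < self.alpha if self.strict_alpha else p_adj <= self.alpha


def call_direction(signed_fold: float, p_adj: float, thresholds: Thresholds = Thresholds()) -> str:
    """'up' / 'down' / 'none' for one (fold, adjusted p) observation."""
    if not thresholds._passes_alpha(p_adj):
        return "none"
    if thresholds._passes_fold(signed_fold, thresholds.fold_cut):
        return "up"
    if thresholds._passes_fold(-signed_fold, thresholds.fold_cut):
        return "down"
    return "none"


def _lines_of(table: pd.DataFrame) -> list[str]:
    lines = [c[len("fold_") :] for c in table.columns if c.startswith("fold_")]
    for line in lines:
        if f"padj_{line}" not in table.columns:
            raise ValueError(f"missing adjusted-p column for line {line!r}")
    if not lines:
        raise ValueError("no fold_<line> columns found")
    return lines


def build_call_table(
    table: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Per-(miRNA, line) directional calls from a wide fold/padj table.

    ``table`` is indexed by miRNA with columns ``fold_<line>`` and
    ``padj_<line>`` for each resistant line.
    """
    lines = _lines_of(table)
    calls = {
        line: [
            call_direction(f, p, thresholds)
            for f, p in zip(table[f"fold_{line}"], table[f"padj_{line}"])
        ]
        for line in lines
    }
    out = pd.DataFrame(calls, index=table.index)
    out.index.name = table.index.name or "mirna"
    return out


def classify_mirnas(call_table: pd.DataFrame) -> pd.DataFrame:
    """Category (up_only / down_only / mixed) and number of changed lines.

    miRNAs with no non-none call get category ``none``.
    """
    categories = []
    n_changed = []
    for _, row in call_table.iterrows():
        ups = (row == "up").sum()
        downs = (row == "down").sum()
        n_changed.append(int(ups + downs))
        if ups and downs:
            categories.append("mixed")
        elif ups:
            categories.append("up_only")
        elif downs:
            categories.append("down_only")
        else:
            categories.append("none")
    return pd.DataFrame(
        {"category": categories, "n_lines_changed": n_changed}, index=call_table.index
    )


def drug_signatures(
    call_table: pd.DataFrame, line_to_drug: dict[str, str] = LINE_TO_DRUG
) -> dict[str, list[str]]:
    """Per-drug lists of miRNAs called consistently up / down in both lines.

    A miRNA may appear in both drugs' signatures (e.g. down in CIS lines,
    up in PAC lines).
    """
    drugs: dict[str, list[str]] = {}
    for line in call_table.columns:
        if line not in line_to_drug:
            raise ValueError(f"cell line {line!r} has no drug mapping")
        drugs.setdefault(line_to_drug[line], []).append(line)
    signatures: dict[str, list[str]] = {}
    for drug, lines in sorted(drugs.items()):
        for direction in ("up", "down"):
            members = [
                m
                for m, row in call_table.iterrows()
                if all(row[line] == direction for line in lines)
            ]
            signatures[f"{drug}-{direction}"] = members
    return signatures


@dataclass
class SelectionResult:
    """Outcome of the two-tier selection over one wide fold/padj table."""

    table: pd.DataFrame  # selected miRNAs: tier, category, n_lines_changed, signatures
    calls: pd.DataFrame  # full call table (all input miRNAs)
    signatures: dict[str, list[str]]
    thresholds: Thresholds = field(default_factory=Thresholds)

    @property
    def selected(self) -> list[str]:
        return list(self.table.index)


def apply_two_tier_selection(
    table: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    line_to_drug: dict[str, str] = LINE_TO_DRUG,
) -> SelectionResult:
    """Apply both selection rules to a wide per-line fold/padj table.

    Tier 1 ("two-line-same-drug"): significant |fold| beyond ``fold_cut``
    in both lines resistant to one drug. Tier 2 ("single-line-10x"):
    |fold| >= ``fold_cut_single`` with significant adjusted p in at least
    one line. A miRNA satisfying both is labeled "both".
    """
    lines = _lines_of(table)
    unmapped = [line for line in lines if line not in line_to_drug]
    if unmapped:
        raise ValueError(f"cell lines without a drug mapping: {unmapped}")
    drug_lines: dict[str, list[str]] = {}
    for line in lines:
        drug_lines.setdefault(line_to_drug[line], []).append(line)

    calls = build_call_table(table, thresholds)
    classes = classify_mirnas(calls)

    tiers = {}
    for mirna, row in table.iterrows():
        tier1 = any(
            len(dl) >= 2 and all(calls.loc[mirna, line] != "none" for line in dl)
            for dl in drug_lines.values()
        )
        tier2 = any(
            abs(row[f"fold_{line}"]) >= thresholds.fold_cut_single
            and thresholds._passes_alpha(row[f"padj_{line}"])
            for line in lines
        )
        if tier1 and tier2:
            tiers[mirna] = "both"
        elif tier1:
            tiers[mirna] = "two-line-same-drug"
        elif tier2:
            tiers[mirna] = "single-line-10x"

    signatures = drug_signatures(calls, line_to_drug)
    sig_labels = {
        m: ";".join(sorted(label for label, members in signatures.items() if m in members))
        for m in tiers
    }
    selected = pd.DataFrame(
        {
            "tier": [tiers[m] for m in tiers],
            "category": classes.loc[list(tiers), "category"].to_numpy(),
            "n_lines_changed": classes.loc[list(tiers), "n_lines_changed"].to_numpy(),
            "signatures": [sig_labels[m] for m in tiers],
        },
        index=pd.Index(list(tiers), name=calls.index.name),
    )
    return SelectionResult(
        table=selected, calls=calls, signatures=signatures, thresholds=thresholds
    )


def selection_summary(result: SelectionResult) -> dict:
    """JSON-serializable count block describing a selection result."""
    classes = classify_mirnas(result.calls)
    sel = result.table
    per_k = {
        str(k): int((sel["n_lines_changed"] == k).sum()) for k in range(0, len(result.calls.columns) + 1)
    }
    return {
        "n_input": int(len(result.calls)),
        "n_selected": int(len(sel)),
        "up_only": int((sel["category"] == "up_only").sum()),
        "down_only": int((sel["category"] == "down_only").sum()),
        "mixed": int((sel["category"] == "mixed").sum()),
        "n_lines_changed": per_k,
        "tiers": {
            tier: int((sel["tier"] == tier).sum())
            for tier in ("two-line-same-drug", "single-line-10x", "both")
        },
        "signatures": {k: sorted(v) for k, v in result.signatures.items()},
        "thresholds": {
            "fold_cut": result.thresholds.fold_cut,
            "fold_cut_single": result.thresholds.fold_cut_single,
            "alpha": result.thresholds.alpha,
            "strict_fold": result.thresholds.strict_fold,
            "strict_alpha": result.thresholds.strict_alpha,
        },
    }
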