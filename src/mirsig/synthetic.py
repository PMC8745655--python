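"""Synthetic data with known ground truth for exercising every stage.

Expression matrices follow the study design (five groups, the first being
the drug-sensitive reference, four replicates each): planted effects shift
a feature's group mean by ``log2(|fold|) * sign(fold)`` relative to the
reference, with i.i.d. Gaussian log2-scale noise on every entry. Companion
resources (target edges, inverse-regulated mRNA folds, GO annotations) are
generated from the same ground truth so the integration stage is testable
end to end, including configurable decoy edges that violate either the
sign rule or the fold cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import log2_from_signed_fold
from .integration import DEFAULT_GO_KEYWORDS, KNOWN_SOURCES, PairRecord, TargetDB
from .matrix import ExpressionMatrix
from .selection import SelectionResult

__all__ = [
    "DEFAULT_GROUPS",
    "SimulationConfig",
    "GroundTruth",
    "TargetResources",
    "RecoveryMetrics",
    "feature_names",
    "two_line_signature_config",
    "simulate_expression",
    "simulate_target_resources",
    "evaluate_recovery",
]

DEFAULT_GROUPS = ("A2780", "A2780CR1", "A2780CR2", "A2780PR1", "A2780PR2")


def feature_names(n: int) -> list[str]:
    return [f"sim-miR-{i + 1:04d}" for i in range(n)]


@dataclass
class SimulationConfig:
    """Parameters of one simulated experiment.

    ``planted_effects`` maps ``(feature, group)`` to a signed fold with
    |fold| >= 1; the first entry of ``groups`` is the reference and cannot
    carry planted effects.
    """

    n_features: int = 200
    n_replicates: int = 4
    groups: tuple[str, ...] = DEFAULT_GROUPS
    planted_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.25
    baseline_mean: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_replicates < 1:
            raise ValueError("n_features and n_replicates must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.groups) < 2:
            raise ValueError("need a reference group and at least one contrast group")
        universe = set(feature_names(self.n_features))
        for (feat, group), fold in self.planted_effects.items():
            if abs(fold) < 1:
                raise ValueError(f"planted fold for {feat!r} has |fold| < 1: {fold}")
            if group not in self.groups[1:]:
                raise ValueError(f"planted effect in unknown or reference group: {group!r}")
            if feat not in universe:
                raise ValueError(f"planted effect for unknown feature: {feat!r}")


@dataclass
class GroundTruth:
    """What was planted: DE features, true target edges, GO labels."""

    de_features: set[tuple[str, str, float]] = field(default_factory=set)
    target_edges_true: set[tuple[str, str]] = field(default_factory=set)
    go_labels: dict[str, set[str]] = field(default_factory=dict)

    @property
    def de_mirnas(self) -> set[str]:
        return {feat for feat, _, _ in self.de_features}


def two_line_signature_config(
    n_features: int = 200,
    n_planted: int = 20,
    fold: float = 10.0,
    noise_sd: float = 0.25,
    n_replicates: int = 4,
    baseline_mean: float = 7.0,
    seed: int = 0,
) -> SimulationConfig:
    """Config planting each DE miRNA in both lines resistant to one drug.

    Planted features alternate between the CIS and PAC line pairs and
    between up- and downregulation, mirroring the drug-specific signatures
    the selection stage is meant to recover.
    """
    feats = feature_names(n_features)
    if n_planted > n_features:
        raise ValueError("cannot plant more features than the universe holds")
    effects: dict[tuple[str, str], float] = {}
    cis = ("A2780CR1", "A2780CR2")
    pac = ("A2780PR1", "A2780PR2")
    for i, feat in enumerate(feats[:n_planted]):
        lines = cis if i % 2 == 0 else pac
        sign = 1.0 if (i // 2) % 2 == 0 else -1.0
        for line in lines:
            effects[(feat, line)] = sign * abs(fold)
    return SimulationConfig(
        n_features=n_features,
        n_replicates=n_replicates,
        planted_effects=effects,
        noise_sd=noise_sd,
        baseline_mean=baseline_mean,
        seed=seed,
    )


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one expression matrix (and its ground truth) from ``config``.

    Identical configs produce bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    feats = feature_names(config.n_features)
    samples = [
        f"{group}_{r + 1}" for group in config.groups for r in range(config.n_replicates)
    ]
    mean = np.full((config.n_features, len(samples)), config.baseline_mean, dtype=float)
    feat_idx = {f: i for i, f in enumerate(feats)}
    col_idx: dict[str, list[int]] = {}
    for j, s in enumerate(samples):
        col_idx.setdefault(s.rsplit("_", 1)[0], []).append(j)
    for (feat, group), fold in config.planted_effects.items():
        shift = log2_from_signed_fold(fold)
        mean[feat_idx[feat], col_idx[group]] += shift
    values = mean + rng.normal(0.0, config.noise_sd, size=mean.shape)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(feats, name="feature"), columns=samples),
        pd.Series({s: s.rsplit("_", 1)[0] for s in samples}),
        config.groups,
    )
    truth = GroundTruth(
        de_features={(f, g, fold) for (f, g), fold in config.planted_effects.items()}
    )
    return matrix, truth


@dataclass
class TargetResources:
    """Emitted integration inputs: edges, mRNA DE observations, GO table."""

    targets: pd.DataFrame  # columns: mirna, gene, source
    mrna_de: pd.DataFrame  # columns: cell_line, feature, signed_fold, p_adj
    go: pd.DataFrame  # columns: gene, term


def simulate_target_resources(
    truth: GroundTruth,
    config: SimulationConfig,
    decoy_rate: float = 0.0,
    fold_cut: float = 5.0,
    seed: int | None = None,
) -> TargetResources:
    """Generate target edges, mRNA folds and GO labels matching ``truth``.

    Every planted (miRNA, group, fold) gets one target gene whose mRNA fold
    in that cell line is opposite in sign and above the cut-off; the edge
    is recorded in ``truth.target_edges_true`` and the gene receives one of
    the default GO keywords. Decoy edges (``decoy_rate`` per planted edge,
    rounded) point at genes that violate either the sign rule or the fold
    cut-off, so the two filters are separately falsifiable.
    """
    if not truth.de_features:
        raise ValueError("ground truth contains no planted effects")
    if decoy_rate < 0:
        raise ValueError("decoy_rate must be non-negative")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    planted = sorted(truth.de_features)
    edge_rows = []
    mrna_rows = []
    go_rows = []
    keywords = list(DEFAULT_GO_KEYWORDS)
    for k, (mirna, group, fold) in enumerate(planted):
        gene = f"GENE-{mirna}-{group}"
        sign = -1.0 if fold > 0 else 1.0
        gene_fold = sign * rng.uniform(fold_cut + 1.0, fold_cut * 5.0)
        source = KNOWN_SOURCES[int(rng.integers(len(KNOWN_SOURCES)))]
        edge_rows.append({"mirna": mirna, "gene": gene, "source": source})
        mrna_rows.append(
            {
                "cell_line": group,
                "feature": gene,
                "signed_fold": gene_fold,
                "p_adj": float(rng.uniform(1e-8, 1e-4)),
            }
        )
        go_rows.append({"gene": gene, "term": keywords[k % len(keywords)]})
        go_rows.append({"gene": gene, "term": "nucleus"})
        truth.target_edges_true.add((mirna, gene))
        truth.go_labels.setdefault(gene, set()).add(keywords[k % len(keywords)])

    n_decoys = int(round(decoy_rate * len(planted)))
    for k in range(n_decoys):
        mirna, group, fold = planted[int(rng.integers(len(planted)))]
        gene = f"DECOY-{k:04d}"
        if rng.random() < 0.5:
            # same-sign fold above the cut-off: fails the inverse rule
            sign = 1.0 if fold > 0 else -1.0
            gene_fold = sign * rng.uniform(fold_cut + 1.0, fold_cut * 5.0)
        else:
            # inverse sign but below the cut-off: fails the fold rule
            sign = -1.0 if fold > 0 else 1.0
            gene_fold = sign * rng.uniform(1.0, fold_cut - 0.1)
        source = KNOWN_SOURCES[int(rng.integers(len(KNOWN_SOURCES)))]
        edge_rows.append({"mirna": mirna, "gene": gene, "source": source})
        mrna_rows.append(
            {
                "cell_line": group,
                "feature": gene,
                "signed_fold": float(gene_fold),
                "p_adj": float(rng.uniform(1e-8, 1e-4)),
            }
        )
        go_rows.append({"gene": gene, "term": keywords[k % len(keywords)]})

    return TargetResources(
        targets=pd.DataFrame(edge_rows, columns=["mirna", "gene", "source"]),
        mrna_de=pd.DataFrame(
            mrna_rows, columns=["cell_line", "feature", "signed_fold", "p_adj"]
        ),
        go=pd.DataFrame(go_rows, columns=["gene", "term"]),
    )


@dataclass
class RecoveryMetrics:
    sensitivity: float
    fdp: float
    pair_sensitivity: float
    pair_fdp: float
    tier_counts: dict[str, int]


def evaluate_recovery(
    selected: SelectionResult,
    pairs: list[PairRecord],
    truth: GroundTruth,
) -> RecoveryMetrics:
    """Sensitivity and false-discovery proportion against the ground truth.

    miRNA-level metrics compare the selected set with the planted miRNAs;
    pair-level metrics compare retained (miRNA, gene) pairs with the
    planted target edges.
    """
    universe = set(selected.calls.index)
    if truth.de_mirnas - universe:
        raise ValueError("ground-truth features missing from the analyzed universe")
    sel = set(selected.selected)
    true_mirs = truth.de_mirnas
    sensitivity = len(sel & true_mirs) / len(true_mirs) if true_mirs else 1.0
    fdp = len(sel - true_mirs) / max(1, len(sel))
    found_pairs = {(p.mirna, p.gene) for p in pairs}
    true_pairs = truth.target_edges_true
    pair_sensitivity = len(found_pairs & true_pairs) / len(true_pairs) if true_pairs else 1.0
    pair_fdp = len(found_pairs - true_pairs) / max(1, len(found_pairs))
    tier_counts = {
        tier: int((selected.table["tier"] == tier).sum())
        for tier in ("two-line-same-drug", "single-line-10x", "both")
    }
    return RecoveryMetrics(
        sensitivity=sensitivity,
        fdp=fdp,
        pair_sensitivity=pair_sensitivity,
        pair_fdp=pair_fdp,
        tier_counts=tier_counts,
    )
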