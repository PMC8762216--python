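"""Per-tissue decomposition of a fitted risk model.

The headline statistic: group every nonzero model coefficient by the tissue
of its feature (raw-SNP features form the ``no_eqtl_snps`` group) and report
the sum of absolute coefficients per group, as a fraction of the model's
total coefficient mass (L1 norm excluding the intercept, which is not
attributable to any tissue).  Ranking stability is assessed over the fold
models of a CV ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .feature_matrix import FeatureDescriptor
from .risk_model import FittedRiskModel, ModelEnsemble

NO_EQTL_GROUP = "no_eqtl_snps"


@dataclass
class ContributionGroup:
    label: str
    weight_sum: float
    fraction: float
    rank: int
    member_features: list[tuple[str, float]]


@dataclass
class ContributionReport:
    """Ordered per-group contributions; ``total_weight`` is None for an
    all-zero (empty) model."""

    groups: list[ContributionGroup]
    total_weight: float | None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.label, g.weight_sum, g.fraction, g.rank, len(g.member_features))
             for g in self.groups],
            columns=["group", "weight_sum", "fraction", "rank", "n_features"],
        )

    def members_frame(self) -> pd.DataFrame:
        rows = [(g.label, fid, coef)
                for g in self.groups for fid, coef in g.member_features]
        return pd.DataFrame(rows, columns=["group", "feature_id", "coefficient"])

    def fraction_of(self, label: str) -> float:
        for g in self.groups:
            if g.label == label:
                return g.fraction
        return 0.0

    def rank_of(self, label: str) -> int | None:
        for g in self.groups:
            if g.label == label:
                return g.rank
        return None


def _group_label(desc: FeatureDescriptor) -> str:
    return desc.tissue if desc.kind == "eqtl" else NO_EQTL_GROUP


def tissue_contributions(
    model: FittedRiskModel,
    descriptors: Iterable[FeatureDescriptor],
) -> ContributionReport:
    """Sum |coefficient| per tissue group and rank groups by weight.

    Only nonzero coefficients count; ties in weight break alphabetically by
    group label.  An all-zero model yields an empty report (no crash).
    """
    desc_map: Mapping[str, FeatureDescriptor] = {
        d.feature_id: d for d in descriptors
    }
    sums: dict[str, float] = {}
    members: dict[str, list[tuple[str, float]]] = {}
    for fid in model.feature_order:
        coef = model.coefficients[fid]
        if coef == 0.0:
            continue
        if fid not in desc_map:
            raise ValidationError(f"no descriptor for nonzero feature {fid}")
        label = _group_label(desc_map[fid])
        sums[label] = sums.get(label, 0.0) + abs(coef)
        members.setdefault(label, []).append((fid, coef))
    if not sums:
        return ContributionReport(groups=[], total_weight=None)
    total = sum(sums.values())
    ordered = sorted(sums, key=lambda g: (-sums[g], g))
    groups = [
        ContributionGroup(
            label=g, weight_sum=sums[g], fraction=sums[g] / total,
            rank=r + 1, member_features=members[g],
        )
        for r, g in enumerate(ordered)
    ]
    return ContributionReport(groups=groups, total_weight=total)


@dataclass
class StabilitySummary:
    """Distribution of per-group contribution fractions across an ensemble.

    ``fractions`` is a models x groups table (a group absent from a model —
    all its coefficients zero there — contributes fraction 0); ``table``
    summarizes mean/sd fraction and the consensus rank (by mean fraction,
    ties alphabetical); ``rank_counts`` is a groups x ranks histogram.
    """

    fractions: pd.DataFrame
    table: pd.DataFrame
    rank_counts: pd.DataFrame

    @property
    def consensus(self) -> list[str]:
        return list(self.table["group"])

    def consensus_rank_of(self, label: str) -> int | None:
        hit = self.table.loc[self.table["group"] == label, "consensus_rank"]
        return int(hit.iloc[0]) if len(hit) else None


def contribution_stability(
    ensemble: ModelEnsemble,
    descriptors: Iterable[FeatureDescriptor],
) -> StabilitySummary:
    """Summarize per-tissue fractions over every model of the ensemble."""
    if not ensemble.models:
        raise ValidationError("contribution_stability: empty ensemble")
    descriptors = list(descriptors)
    reports = [tissue_contributions(m, descriptors) for m in ensemble.models]
    labels = sorted({g.label for rep in reports for g in rep.groups})
    if not labels:
        # every fold model is empty: degenerate but well-defined summary
        empty = pd.DataFrame(columns=["group", "mean_fraction", "sd_fraction",
                                      "consensus_rank"])
        return StabilitySummary(pd.DataFrame(), empty, pd.DataFrame())
    frac = pd.DataFrame(
        [[rep.fraction_of(lab) for lab in labels] for rep in reports],
        columns=labels,
    )
    mean = frac.mean(axis=0)
    sd = frac.std(axis=0, ddof=1) if len(frac) > 1 else frac.iloc[0] * 0.0
    order = sorted(labels, key=lambda g: (-mean[g], g))
    table = pd.DataFrame({
        "group": order,
        "mean_fraction": [float(mean[g]) for g in order],
        "sd_fraction": [float(sd[g]) for g in order],
        "consensus_rank": np.arange(1, len(order) + 1),
    })
    # per-model ranks (dense over groups present in that model; absent -> no rank)
    counts = pd.DataFrame(0, index=labels, columns=range(1, len(labels) + 1))
    for rep in reports:
        for g in rep.groups:
            counts.loc[g.label, g.rank] += 1
    return StabilitySummary(fractions=frac, table=table, rank_counts=counts)
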