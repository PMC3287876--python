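"""Summary tables over one or many screening replicates.

Covers the reporting conventions of the study design: top-K membership
counts across replicates, posterior-threshold counts, and the realised
false-positive discovery rate when the simulation truth is known.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mcmc import InclusionSummary

__all__ = [
    "ScreenReport",
    "build_report",
    "top_k_membership",
    "threshold_counts",
    "fdr_at_threshold",
]


@dataclass
class ScreenReport:
    """Per-factor table plus threshold summaries for one run."""

    factors: pd.DataFrame
    thresholds: pd.DataFrame

    def write(self, factors_path, thresholds_path) -> None:
        self.factors.to_csv(factors_path, sep="\t", index=False)
        self.thresholds.to_csv(thresholds_path, sep="\t", index=False)


def build_report(
    summary: InclusionSummary,
    mafs: np.ndarray | None = None,
    gene_of: dict[str, str] | None = None,
    truth: set[str] | None = None,
    thresholds: Sequence[float] = (0.5, 0.1),
) -> ScreenReport:
    """Assemble the per-factor report (id, gene, maf, posterior, rank)."""
    df = summary.as_dataframe()
    if gene_of is not None:
        df.insert(1, "gene", [gene_of.get(f, "") for f in df["factor_id"]])
    if mafs is not None:
        df.insert(len(df.columns) - 2, "maf", np.asarray(mafs, dtype=float))
    if truth is not None:
        df["causal"] = df["factor_id"].isin(truth).astype(int)
    df = df.sort_values("rank", ignore_index=True)

    rows = []
    for t in sorted(thresholds, reverse=True):
        flagged = df[df["marginal_posterior"] > t]
        row = {"threshold": t, "n_flagged": len(flagged)}
        if truth is not None:
            tp = int(flagged["causal"].sum())
            fp = len(flagged) - tp
            row.update(
                {
                    "true_positives": tp,
                    "false_positives": fp,
                    "false_positive_discovery_rate": (
                        fp / (fp + tp) if (fp + tp) > 0 else np.nan
                    ),
                }
            )
        rows.append(row)
    return ScreenReport(factors=df, thresholds=pd.DataFrame(rows))


def top_k_membership(
    summaries: Iterable[InclusionSummary], k: int
) -> dict[str, int]:
    """How many replicates place each factor in their top-k by posterior.

    Ties at the k-th rank break deterministically by factor id (ascending).
    Only factors appearing in at least one top-k are returned.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries given")
    ids = summaries[0].factor_ids
    for s in summaries[1:]:
        if s.factor_ids != ids:
            raise ValueError("summaries are over different factor sets")
    counts: dict[str, int] = {}
    for s in summaries:
        for i in s.top(k):
            fid = s.factor_ids[i]
            counts[fid] = counts.get(fid, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def threshold_counts(summary: InclusionSummary, thresholds: Sequence[float]) -> dict[float, int]:
    """Number of factors with posterior above each threshold."""
    return {
        float(t): int((summary.probabilities > t).sum()) for t in thresholds
    }


def fdr_at_threshold(
    summary: InclusionSummary, truth: set[str], threshold: float
) -> tuple[int, int, float | None]:
    """Realised false-positive discovery rate at a posterior cutoff.

    Returns (true positives, false positives, FP/(FP+TP)); the rate is None
    when nothing exceeds the threshold.  This is the realised false-discovery
    proportion among flagged factors given known truth, not an expected FDR.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    flagged = [
        fid
        for fid, p in zip(summary.factor_ids, summary.probabilities)
        if p > threshold
    ]
    tp = sum(f in truth for f in flagged)
    fp = len(flagged) - tp
    rate = fp / (fp + tp) if flagged else None
    return tp, fp, rate
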