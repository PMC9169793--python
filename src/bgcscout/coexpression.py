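"""Bait-centric coexpression: Pearson r of cluster genes against a scaffold bait.

Each candidate cluster is summarized by correlating every member gene's
expression profile with the scaffold bait gene across the compendium (on the
log2(x+1) transform by default) and flagging members with r strictly above
the threshold (0.8 by default).  Genes with zero variance get an undefined
marker (NaN) and are never flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .induction import apply_transform
from .types import BgcscoutError, CandidateBGC, CoexpressionReport, ExpressionMatrix


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN if either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise BgcscoutError("vectors must be 1-D and of equal length")
    if len(x) < 3:
        raise BgcscoutError("need at least 3 samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise BgcscoutError("non-finite values")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def bait_coexpression(
    expr: ExpressionMatrix,
    candidate: CandidateBGC,
    threshold: float = 0.8,
    transform: str = "log2",
) -> CoexpressionReport:
    """Correlate every cluster member with the bait across all samples."""
    bait = candidate.bait
    if bait is None or bait not in expr.values.index:
        raise BgcscoutError(f"bait {bait!r} not in expression matrix")
    values = apply_transform(expr, transform)
    bait_profile = values.loc[bait].to_numpy()
    if np.std(bait_profile) == 0.0:
        raise BgcscoutError(
            f"bait {bait} has zero variance; choose another scaffold gene as bait"
        )
    r = {}
    for gene in candidate.members:
        if gene not in values.index:
            r[gene] = float("nan")
        else:
            r[gene] = pearson_r(bait_profile, values.loc[gene].to_numpy())
    r_series = pd.Series(r, name="r")
    flags = (r_series > threshold).fillna(False)
    return CoexpressionReport(
        bgc_id=candidate.bgc_id,
        bait=bait,
        r=r_series,
        flags=flags,
        n_samples=len(expr.samples),
        threshold=threshold,
    )


def coherence_summary(report: CoexpressionReport) -> dict[str, float]:
    """Cluster-coherence statistics over members, excluding the bait."""
    members = [g for g in report.r.index if g != report.bait]
    if not members:
        raise BgcscoutError("report has no non-bait members")
    r = report.r.loc[members]
    flags = report.flags.loc[members]
    finite = r.dropna()
    return {
        "n_members": float(len(members)),
        "n_coexpressed": float(int(flags.sum())),
        "fraction_coexpressed": float(flags.sum()) / len(members),
        "min_r": float(finite.min()) if len(finite) else float("nan"),
        "median_r": float(finite.median()) if len(finite) else float("nan"),
        "max_r": float(finite.max()) if len(finite) else float("nan"),
    }


def report_to_frame(report: CoexpressionReport) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bgc_id": report.bgc_id,
            "bait": report.bait,
            "gene_id": list(report.r.index),
            "r": report.r.to_numpy(),
            "coexpressed": report.flags.to_numpy(),
            "n_samples": report.n_samples,
            "threshold": report.threshold,
        }
    )
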