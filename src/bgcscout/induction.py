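"""Module eigengene computation and pathogen-induction ranking.

Each coexpression module is summarized by its eigengene — here, following
the source network's convention, the per-sample arithmetic mean of member
gene expression (on a configurable transform, log2(x+1) by default).  The
eigengene is z-scored within each study (location/scale removal, ddof=1) so
that treatment-minus-control deltas are comparable across studies of
different sequencing depth; the per-study deltas are averaged without
weights and modules are ranked by the mean delta, largest first.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    BgcscoutError,
    EigengeneProfile,
    ExpressionMatrix,
    InductionScore,
    ModuleSet,
    SampleMetadata,
)

log = logging.getLogger("bgcscout")

TRANSFORMS: dict[str, Callable[[pd.DataFrame], pd.DataFrame]] = {
    "log2": lambda v: np.log2(v + 1.0),
    "raw": lambda v: v,
}


def apply_transform(expr: ExpressionMatrix, transform: str = "log2") -> pd.DataFrame:
    try:
        return TRANSFORMS[transform](expr.values)
    except KeyError:
        raise BgcscoutError(f"unknown transform {transform!r}") from None


def compute_eigengene(
    expr: ExpressionMatrix,
    modules: ModuleSet,
    module_id: str,
    transform: str = "log2",
) -> EigengeneProfile:
    """Average member-gene expression per sample (raw eigengene variant)."""
    members = [g for g in modules.genes_in(module_id) if g in set(expr.genes)]
    if not members:
        raise BgcscoutError(f"module {module_id} has no genes in the expression matrix")
    values = apply_transform(expr, transform).loc[members].mean(axis=0)
    return EigengeneProfile(module_id=module_id, values=values, normalized=False)


def normalize_eigengene(
    profile: EigengeneProfile, metadata: SampleMetadata
) -> EigengeneProfile:
    """Z-score the eigengene within each study (mean 0, SD 1, ddof=1).

    Studies with fewer than two samples or zero variance are set to zero
    with a warning rather than producing NaNs.
    """
    values = profile.values.copy().astype(float)
    for study in metadata.study_ids:
        samples = [s for s in metadata.samples_of(study) if s in values.index]
        if not samples:
            continue
        v = values.loc[samples]
        sd = v.std(ddof=1)
        if len(samples) < 2 or not np.isfinite(sd) or sd == 0:
            log.warning(
                "module %s: study %s degenerate (n=%d); normalized values zeroed",
                profile.module_id,
                study,
                len(samples),
            )
            values.loc[samples] = 0.0
        else:
            values.loc[samples] = (v - v.mean()) / sd
    return EigengeneProfile(module_id=profile.module_id, values=values, normalized=True)


def induction_scores(
    expr: ExpressionMatrix,
    modules: ModuleSet,
    metadata: SampleMetadata,
    study_ids: Sequence[str] | None = None,
    transform: str = "log2",
) -> list[InductionScore]:
    """Rank all modules by mean treatment-minus-control eigengene delta.

    For every module: eigengene -> per-study z-score -> per-study delta
    (mean over treatment samples minus mean over control samples) ->
    unweighted mean over studies.  Rank 1 is the most induced module; ties
    break lexicographically on module id for determinism.
    """
    if study_ids is None:
        study_ids = metadata.study_ids
    for study in study_ids:
        for arm in ("treatment", "control"):
            if not metadata.samples_of(study, arm):
                raise BgcscoutError(f"study {study} has no {arm} samples")

    transformed = apply_transform(expr, transform)
    gene_set = set(expr.genes)
    scores: list[InductionScore] = []
    for module_id in modules.module_ids:
        members = [g for g in modules.genes_in(module_id) if g in gene_set]
        if not members:
            log.warning("module %s has no genes in matrix; skipped", module_id)
            continue
        eigen = EigengeneProfile(
            module_id=module_id,
            values=transformed.loc[members].mean(axis=0),
            normalized=False,
        )
        normalized = normalize_eigengene(eigen, metadata)
        deltas: dict[str, float] = {}
        for study in study_ids:
            treat = [s for s in metadata.samples_of(study, "treatment") if s in normalized.values.index]
            ctrl = [s for s in metadata.samples_of(study, "control") if s in normalized.values.index]
            deltas[study] = float(
                normalized.values.loc[treat].mean() - normalized.values.loc[ctrl].mean()
            )
        scores.append(
            InductionScore(
                module_id=module_id,
                per_study_delta=deltas,
                mean_delta=float(np.mean(list(deltas.values()))),
            )
        )
    scores.sort(key=lambda s: (-s.mean_delta, s.module_id))
    return [
        InductionScore(
            module_id=s.module_id,
            per_study_delta=s.per_study_delta,
            mean_delta=s.mean_delta,
            rank=i,
        )
        for i, s in enumerate(scores, start=1)
    ]


def select_top_modules(scores: Iterable[InductionScore], k: int = 5) -> list[str]:
    """The ``k`` most induced module ids, in rank order."""
    ranked = sorted(scores, key=lambda s: s.rank)
    if k <= 0:
        raise BgcscoutError("k must be positive")
    if k > len(ranked):
        raise BgcscoutError(f"k={k} exceeds number of modules ({len(ranked)})")
    return [s.module_id for s in ranked[:k]]


def scores_to_frame(scores: Sequence[InductionScore]) -> pd.DataFrame:
    """Flat report table: module, per-study deltas, mean delta, rank."""
    studies = sorted({st for s in scores for st in s.per_study_delta})
    rows = []
    for s in sorted(scores, key=lambda s: s.rank):
        row: dict[str, object] = {"module_id": s.module_id}
        for st in studies:
            row[f"delta_{st}"] = s.per_study_delta.get(st, float("nan"))
        row["mean_delta"] = s.mean_delta
        row["rank"] = s.rank
        rows.append(row)
    return pd.DataFrame(rows)
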