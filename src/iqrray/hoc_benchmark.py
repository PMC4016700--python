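"""Cross-species conservation benchmark for quality metrics.

The homologous-organ correlation (HOC) score uses evolutionary
conservation of expression as an external, platform-independent quality
reference: an array's ortholog-restricted gene profile is correlated
(Spearman) against every reference profile of the homologous organ in
the other species, and the highest coefficient is kept, so natural
biological variability among references does not penalize the array.

Metric evaluation then follows three steps: HOC scores are turned into
per-organ empirical quantile ranks, each quality metric (sign-adjusted
so that larger always means better) is correlated with those quantiles,
and selection efficiency measures how many of the worst-x% arrays by a
metric are also in the worst x% by HOC. Finally, collection-level
quantile thresholds (with each experiment capped to a maximum number of
arrays so that large experiments do not dominate) give absolute
pass/fail cutoffs for screening new arrays.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .errors import IntegrityError
from .expression_summary import ExpressionProfile, GeneMap, align_profiles
from .qc_metrics import QualityReport


@dataclass
class BenchmarkResult:
    hoc: dict[str, float]
    hoc_quantile: dict[str, float]
    metric_correlations: dict[str, float]
    efficiency: dict[tuple[str, float], float]
    missing_metrics: dict[str, str] = field(default_factory=dict)


@dataclass
class ThresholdTable:
    """Per-metric empirical quantile cutoffs on sign-adjusted scores."""

    metric: str
    cutoffs: dict[float, float]
    n_arrays_used: int
    arrays_used: list[str]
    seed: int
    platform_id: str = ""


# ---------------------------------------------------------------------------
# HOC
# ---------------------------------------------------------------------------


def hoc_score(
    query: ExpressionProfile,
    references: Sequence[ExpressionProfile],
    gene_map: GeneMap,
    min_genes: int = 3,
) -> float:
    """Highest Spearman correlation of the query against any reference,
    over aligned ortholog pairs. Pairings with fewer than ``min_genes``
    common genes are skipped with a warning."""
    if not references:
        raise IntegrityError("hoc_score needs at least one reference profile")
    best = None
    for ref in references:
        try:
            va, vb, pairs = align_profiles(query, ref, gene_map)
        except IntegrityError:
            pairs = []
        if len(pairs) < min_genes:
            warnings.warn(
                f"skipping reference {ref.array_id!r}: only {len(pairs)} "
                f"common ortholog pairs",
                stacklevel=2,
            )
            continue
        rho = spearmanr(va, vb).statistic
        if best is None or rho > best:
            best = rho
    if best is None:
        raise IntegrityError(
            f"no reference shares >= {min_genes} ortholog pairs with "
            f"{query.array_id!r}"
        )
    return float(best)


def hoc_scores(
    queries: Sequence[ExpressionProfile],
    references: Sequence[ExpressionProfile],
    gene_map: GeneMap,
    min_genes: int = 3,
) -> dict[str, float]:
    """HOC score per query array.

    When all queries share one gene index and all references another
    (the common case for profiles built from one platform each), the
    Spearman matrix is computed in one vectorized pass; otherwise each
    query falls back to :func:`hoc_score`.
    """
    if not queries:
        return {}
    q0, r0 = queries[0].values.index, references[0].values.index if references else None
    uniform = references and all(
        q.values.index.equals(q0) for q in queries
    ) and all(r.values.index.equals(r0) for r in references)
    if not uniform:
        return {
            q.array_id: hoc_score(q, references, gene_map, min_genes)
            for q in queries
        }
    qset, rset = set(q0), set(r0)
    qg, rg = [], []
    for ga, gb in gene_map.ortholog_pairs:
        if ga in qset and gb in rset:
            qg.append(ga)
            rg.append(gb)
        elif gb in qset and ga in rset:
            qg.append(gb)
            rg.append(ga)
    if len(qg) < min_genes:
        raise IntegrityError(
            f"references share only {len(qg)} ortholog pairs with the queries"
        )
    qmat = np.stack([q.values.reindex(qg).to_numpy(float) for q in queries])
    rmat = np.stack([r.values.reindex(rg).to_numpy(float) for r in references])
    qr = rankdata(qmat, method="average", axis=1)
    rr = rankdata(rmat, method="average", axis=1)
    qz = (qr - qr.mean(axis=1, keepdims=True)) / qr.std(axis=1, keepdims=True)
    rz = (rr - rr.mean(axis=1, keepdims=True)) / rr.std(axis=1, keepdims=True)
    rho = qz @ rz.T / qr.shape[1]
    best = rho.max(axis=1)
    return {q.array_id: float(b) for q, b in zip(queries, best)}


# ---------------------------------------------------------------------------
# quantile transform and metric evaluation
# ---------------------------------------------------------------------------


def quantile_transform(
    scores: Mapping[str, float],
    groups: Mapping[str, str],
    bins: int | None = None,
) -> dict[str, float]:
    """Within-group empirical quantile rank (midrank - 0.5) / n of each
    score, in [0, 1]; ties share a rank. ``bins=4`` gives the coarse
    quartile variant (values 0.25, 0.5, 0.75, 1.0)."""
    by_group: dict[str, list[str]] = {}
    for array_id in scores:
        if array_id not in groups:
            raise IntegrityError(f"array {array_id!r} has no group label")
        by_group.setdefault(groups[array_id], []).append(array_id)
    out: dict[str, float] = {}
    for group, ids in by_group.items():
        if len(ids) < 2:
            raise IntegrityError(
                f"group {group!r} has a single array; quantile rank undefined"
            )
        vals = np.array([scores[i] for i in ids], dtype=float)
        q = (rankdata(vals, method="average") - 0.5) / len(ids)
        if bins is not None:
            q = np.ceil(q * bins) / bins
        out.update(zip(ids, q.tolist()))
    return out


def _adjusted(value: float, direction: str) -> float:
    if direction == "ascending":
        return value
    if direction == "descending":
        return -value
    raise ValueError(f"unknown direction {direction!r}")


def metric_hoc_correlation(
    reports: Sequence[QualityReport],
    hoc_quantiles: Mapping[str, float],
    directions: Mapping[str, str] | None = None,
) -> tuple[dict[str, float], dict[str, str]]:
    """Spearman rho between each sign-adjusted metric and the HOC
    quantile, pooled across organs. Returns (rhos, missing-with-reason).
    """
    metric_names: list[str] = []
    for rep in reports:
        for m in rep.metrics:
            if m not in metric_names:
                metric_names.append(m)
    rhos: dict[str, float] = {}
    missing: dict[str, str] = {}
    for m in metric_names:
        xs, ys = [], []
        for rep in reports:
            if m not in rep.metrics or rep.array_id not in hoc_quantiles:
                continue
            direction = (directions or rep.direction).get(m)
            if direction is None:
                missing[m] = "no declared direction"
                break
            v = rep.metrics[m]
            if not math.isfinite(v):
                continue
            xs.append(_adjusted(v, direction))
            ys.append(hoc_quantiles[rep.array_id])
        if m in missing:
            continue
        if len(xs) < 3:
            missing[m] = f"only {len(xs)} arrays with both values"
            continue
        if len(set(xs)) == 1:
            missing[m] = "metric is constant; rho undefined"
            continue
        rhos[m] = float(spearmanr(xs, ys).statistic)
    return rhos, missing


def selection_efficiency(
    metric_scores: Mapping[str, float],
    hoc_quantiles: Mapping[str, float],
    cutoff: float = 0.05,
    direction: str = "ascending",
) -> float:
    """Fraction of the worst-``cutoff`` arrays by the sign-adjusted
    metric whose HOC quantile is below the same cutoff."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    ids = [i for i in metric_scores if i in hoc_quantiles]
    n_sel = int(math.floor(cutoff * len(ids)))
    if n_sel == 0:
        raise IntegrityError(
            f"cutoff {cutoff} selects no array out of {len(ids)}"
        )
    ranked = sorted(ids, key=lambda i: (_adjusted(metric_scores[i], direction), i))
    selected = ranked[:n_sel]
    hits = sum(1 for i in selected if hoc_quantiles[i] < cutoff)
    return hits / n_sel


# ---------------------------------------------------------------------------
# collection thresholds
# ---------------------------------------------------------------------------


def compute_thresholds(
    scores: Mapping[str, float],
    experiments: Mapping[str, str],
    metric: str,
    levels: Sequence[float] = (0.01, 0.05, 0.1),
    max_per_experiment: int = 10,
    seed: int = 0,
    direction: str = "ascending",
    min_arrays: int = 20,
    platform_id: str = "",
) -> ThresholdTable:
    """Empirical quantile cutoffs of the sign-adjusted score over a
    collection, with each experiment's contribution capped at
    ``max_per_experiment`` arrays (uniform seeded subsample) so large
    experiments do not bias the cutoffs."""
    rng = np.random.default_rng(seed)
    by_exp: dict[str, list[str]] = {}
    for array_id in sorted(scores):
        if array_id not in experiments:
            raise IntegrityError(f"array {array_id!r} has no experiment label")
        by_exp.setdefault(experiments[array_id], []).append(array_id)
    used: list[str] = []
    for exp in sorted(by_exp):
        ids = by_exp[exp]
        if len(ids) > max_per_experiment:
            pick = rng.choice(len(ids), size=max_per_experiment, replace=False)
            ids = [ids[i] for i in sorted(pick)]
        used.extend(ids)
    if len(used) < min_arrays:
        raise IntegrityError(
            f"only {len(used)} arrays after capping; need >= {min_arrays}"
        )
    adjusted = np.array([_adjusted(scores[i], direction) for i in used])
    cutoffs = {
        float(lv): float(np.quantile(adjusted, lv)) for lv in levels
    }
    return ThresholdTable(
        metric=metric,
        cutoffs=cutoffs,
        n_arrays_used=len(used),
        arrays_used=used,
        seed=seed,
        platform_id=platform_id,
    )


def apply_thresholds(
    reports: Sequence[QualityReport],
    thresholds: Mapping[str, float],
    metrics: Sequence[str] | None = None,
    directions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Flag arrays falling below the cutoff for ANY listed metric.

    ``thresholds`` maps metric name -> cutoff on the sign-adjusted
    scale. Returns a DataFrame (array_id, passed, failed_metrics).
    """
    names = list(metrics) if metrics is not None else list(thresholds)
    rows = []
    for rep in reports:
        reasons = []
        for m in names:
            if m not in thresholds:
                raise IntegrityError(f"no threshold for metric {m!r}")
            if m not in rep.metrics:
                continue
            direction = (directions or rep.direction).get(m, "ascending")
            if _adjusted(rep.metrics[m], direction) < thresholds[m]:
                reasons.append(m)
        rows.append((rep.array_id, not reasons, ";".join(reasons)))
    return pd.DataFrame(rows, columns=["array_id", "passed", "failed_metrics"])
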