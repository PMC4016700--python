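"""Single-array quality metrics.

These are the classical GCOS-era comparison metrics, computed on raw
cell intensities:

* ``pm_mm_ttest`` — paired t statistic of PM - MM over all probe pairs;
  specific hybridization shifts PM above MM, so larger is better.
* ``average_background`` — mean of the 2% lowest cell intensities;
  high values indicate nonspecific binding.
* ``scaling_factor`` — target constant divided by the 2% trimmed mean;
  large values flag dim arrays.
* ``rna_degradation_slope`` — OLS slope of mean PM intensity against
  the 5'->3' probe position; degradation starting at the 5' end
  depresses 5' probes, and an intact sample keeps a clear positive
  slope toward the 3' end.
* ``three_five_ratio`` — 3'/5' signal ratio of a control transcript's
  dedicated probe sets (actin, GAPDH); ratios near 1 mean intact RNA.
* ``percent_present`` — percentage of probe sets called Present by the
  reduced MAS5 detection test (discrimination score
  R = (PM - MM)/(PM + MM), one-sided Wilcoxon signed-rank of
  median R > tau at level alpha1).

Each metric carries a direction: ``ascending`` when larger values mean
better quality, ``descending`` otherwise. The benchmark uses the
direction to sign-adjust scores before comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy.stats import norm, rankdata

from . import score as _score
from .chip_model import ArrayIntensities, ChipLayout
from .errors import IntegrityError

#: direction registry: ascending = larger is better
METRIC_DIRECTIONS: dict[str, str] = {
    "iqrray": "ascending",
    "iqrray_all_probes": "ascending",
    "iqrray_pm_only": "ascending",
    "pm_mm_ttest": "ascending",
    "percent_present": "ascending",
    "rna_degradation_slope": "ascending",
    "average_background": "descending",
    "scaling_factor": "descending",
    "three_five_ratio": "descending",
}


@dataclass
class QualityReport:
    """All metric values for one array, with directionality metadata."""

    array_id: str
    metrics: dict[str, float] = field(default_factory=dict)
    direction: dict[str, str] = field(default_factory=dict)
    missing: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, value: float, direction: str) -> None:
        if direction not in ("ascending", "descending"):
            raise ValueError(f"bad direction {direction!r} for metric {name!r}")
        self.metrics[name] = float(value)
        self.direction[name] = direction


# ---------------------------------------------------------------------------
# PM/MM paired t
# ---------------------------------------------------------------------------


def pm_mm_ttest(
    array: ArrayIntensities, layout: ChipLayout, log2: bool = False
) -> float:
    """Paired t statistic of PM - MM over every PM/MM pair on the array:
    t = mean(d) / (sd(d) / sqrt(n)), sd with n - 1 denominator."""
    pm_idx, mm_idx = layout.pm_pairs
    if pm_idx.size < 2:
        raise IntegrityError("pm_mm_ttest needs at least 2 PM/MM pairs")
    v = array.values_for(layout)
    pm, mm = v[pm_idx], v[mm_idx]
    if log2:
        pm, mm = np.log2(1.0 + pm), np.log2(1.0 + mm)
    d = pm - mm
    n = d.size
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return 0.0
        return math.inf if mean > 0 else -math.inf
    return float(mean / (sd / math.sqrt(n)))


# ---------------------------------------------------------------------------
# background / scaling
# ---------------------------------------------------------------------------


def average_background(array: ArrayIntensities, fraction: float = 0.02) -> float:
    """Mean of the ``fraction`` lowest cell intensities (all cells,
    assigned to probe sets or not); at least one cell is used."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    v = array.values
    m = max(1, int(math.floor(fraction * v.size)))
    lowest = np.partition(v, m - 1)[:m]
    return float(lowest.mean())


def scaling_factor(
    array: ArrayIntensities, target: float = 500.0, trim: float = 0.02
) -> float:
    """``target`` divided by the trimmed mean intensity (the lowest and
    highest ``floor(trim * N)`` cells are discarded)."""
    if target <= 0:
        raise ValueError("target must be positive")
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    v = np.sort(array.values)
    m = int(math.floor(trim * v.size))
    core = v[m : v.size - m]
    tm = core.mean()
    if tm == 0.0:
        raise IntegrityError("trimmed mean intensity is 0; scaling factor undefined")
    return float(target / tm)


# ---------------------------------------------------------------------------
# RNA degradation slope
# ---------------------------------------------------------------------------


def rna_degradation_slope(
    array: ArrayIntensities, layout: ChipLayout, standardize: bool = False
) -> float:
    """OLS slope of mean PM intensity against 5'->3' probe position.

    Only probe sets whose PM probe count equals the modal PM count
    participate, so every position is an average over the same number
    of probe sets. Positions are the within-set ordinals of the probes
    sorted by ``position_index``. With ``standardize`` the position
    means are shifted so position 0 is 0 and scaled by the mean
    standard error of the position means before fitting.
    """
    df = layout.probes
    pm = layout.pm_mask
    has_pos = ~np.isnan(df["position_index"].to_numpy(float))
    codes = layout.set_codes
    use = pm & has_pos & (codes >= 0)
    if not use.any():
        raise IntegrityError("no PM probe carries a position_index")
    v = array.values_for(layout)
    sub_codes = codes[use]
    counts = np.bincount(sub_codes, minlength=len(layout.set_ids))
    sizes = counts[counts > 0]
    modal = np.bincount(sizes).argmax()
    sets = np.flatnonzero(counts == modal)
    if sets.size < 2:
        raise IntegrityError(
            f"fewer than 2 probe sets have the modal PM count ({modal})"
        )
    if modal < 3:
        raise IntegrityError("need at least 3 probe positions for a slope")
    in_modal = use & np.isin(codes, sets)
    order = np.lexsort(
        (df["position_index"].to_numpy(float)[in_modal], codes[in_modal])
    )
    mat = v[in_modal][order].reshape(sets.size, modal)
    means = mat.mean(axis=0)
    positions = np.arange(modal, dtype=float)
    if standardize:
        se = mat.std(axis=0, ddof=1) / math.sqrt(sets.size)
        means = (means - means[0]) / se.mean()
    pc = positions - positions.mean()
    return float((pc * (means - means.mean())).sum() / (pc * pc).sum())


# ---------------------------------------------------------------------------
# 3'/5' control ratios
# ---------------------------------------------------------------------------


def three_five_ratio(
    array: ArrayIntensities, layout: ChipLayout, pair_label: str
) -> float:
    """Mean PM intensity of the 3' control probe set over the 5' one."""
    pair = next(
        (cp for cp in layout.control_pairs if cp.label == pair_label), None
    )
    if pair is None:
        raise IntegrityError(f"unknown control pair label {pair_label!r}")
    v = array.values_for(layout)
    means = {}
    for ps in (pair.probe_set_3prime, pair.probe_set_5prime):
        code = np.flatnonzero(layout.set_ids == ps)
        mask = (layout.set_codes == code[0]) & layout.pm_mask
        if not mask.any():
            raise IntegrityError(f"control probe set {ps!r} has no PM probes")
        means[ps] = v[mask].mean()
    five = means[pair.probe_set_5prime]
    if five == 0.0:
        raise IntegrityError(
            f"5' control probe set {pair.probe_set_5prime!r} has mean 0"
        )
    return float(means[pair.probe_set_3prime] / five)


# ---------------------------------------------------------------------------
# MAS5-style detection (reduced form) and percent present
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _signed_rank_sf(n: int) -> np.ndarray:
    """P(W+ >= w) for w = 0..n(n+1)/2 under the signed-rank null,
    by dynamic programming over the generating function prod(1 + x^i)."""
    top = n * (n + 1) // 2
    counts = np.zeros(top + 1, dtype=float)
    counts[0] = 1.0
    for i in range(1, n + 1):
        counts[i:] += counts[: top + 1 - i]
    sf = counts[::-1].cumsum()[::-1] / 2.0**n
    return sf


def signed_rank_p_greater(d: np.ndarray) -> float:
    """One-sided p-value (alternative: median > 0) of the Wilcoxon
    signed-rank test. Zeros are dropped; the exact distribution is used
    for n <= 25 without ties, a normal approximation with continuity
    and tie corrections otherwise."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0
    absd = np.abs(d)
    ranks = rankdata(absd, method="average")
    w = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size != n
    if n <= 25 and not has_ties:
        return float(_signed_rank_sf(n)[int(round(w))])
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    if has_ties:
        _, t = np.unique(absd, return_counts=True)
        var -= (t**3 - t).sum() / 48.0
    if var <= 0:
        return 1.0 if w <= mu else 0.0
    z = (w - mu - 0.5) / math.sqrt(var)
    return float(norm.sf(z))


def detection_pvalues(
    array: ArrayIntensities, layout: ChipLayout, tau: float = 0.015
) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe-set detection p-values.

    For every probe set with at least one usable PM/MM pair (pairs with
    PM + MM = 0 are skipped), the discrimination scores
    R_i = (PM_i - MM_i) / (PM_i + MM_i) are tested one-sided against
    ``tau``. Returns (probe set codes into ``layout.set_ids``, p-values).
    """
    pm_idx, mm_idx = layout.pm_pairs
    if pm_idx.size == 0:
        raise IntegrityError("layout has no PM/MM pairs")
    v = array.values_for(layout)
    pm, mm = v[pm_idx], v[mm_idx]
    codes = layout.set_codes[pm_idx]
    keep = ((pm + mm) > 0) & (codes >= 0)
    if not keep.any():
        raise IntegrityError("no probe set has a usable PM/MM pair")
    r = (pm[keep] - mm[keep]) / (pm[keep] + mm[keep])
    d = r - tau
    codes = codes[keep]

    order = np.argsort(codes, kind="stable")
    codes, d = codes[order], d[order]
    uniq, starts = np.unique(codes, return_index=True)
    bounds = np.append(starts, codes.size)
    pvals = np.empty(uniq.size, dtype=float)

    # fast path: vectorize sets sharing a pair count, exact, no ties/zeros
    sizes = np.diff(bounds)
    done = np.zeros(uniq.size, dtype=bool)
    for n in np.unique(sizes):
        idx = np.flatnonzero(sizes == n)
        block = np.stack([d[bounds[i] : bounds[i] + n] for i in idx])
        absd = np.abs(block)
        clean = (block != 0.0).all(axis=1) & (
            np.sort(absd, axis=1)[:, 1:] != np.sort(absd, axis=1)[:, :-1]
        ).all(axis=1)
        if n <= 25 and clean.any():
            ranks = rankdata(absd[clean], method="average", axis=1)
            w = np.rint((ranks * (block[clean] > 0)).sum(axis=1)).astype(int)
            pvals[idx[clean]] = _signed_rank_sf(int(n))[w]
            done[idx[clean]] = True
    for i in np.flatnonzero(~done):
        pvals[i] = signed_rank_p_greater(d[bounds[i] : bounds[i + 1]])
    return uniq, pvals


def percent_present(
    array: ArrayIntensities,
    layout: ChipLayout,
    tau: float = 0.015,
    alpha1: float = 0.04,
) -> float:
    """Percentage of tested probe sets called Present (p < alpha1)."""
    _, pvals = detection_pvalues(array, layout, tau=tau)
    return float(100.0 * (pvals < alpha1).mean())


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


def quality_report(
    array: ArrayIntensities,
    layout: ChipLayout,
    config: Mapping[str, object] | None = None,
) -> QualityReport:
    """Run every applicable metric and assemble a :class:`QualityReport`.

    Both IQRray probe scopes are reported side by side. Metrics that
    cannot be computed on this layout (no PM/MM pairs, no position
    indices, ...) are recorded as missing with the reason.
    """
    cfg = dict(config or {})
    report = QualityReport(array_id=array.array_id)

    def attempt(name: str, direction: str, fn) -> None:
        try:
            report.add(name, fn(), direction)
        except (IntegrityError, ValueError) as exc:
            report.missing[name] = str(exc)

    attempt(
        "iqrray_all_probes",
        "ascending",
        lambda: _score.iqrray(array, layout, "all_probes"),
    )
    attempt(
        "iqrray_pm_only",
        "ascending",
        lambda: _score.iqrray(array, layout, "pm_only"),
    )
    attempt(
        "pm_mm_ttest",
        "ascending",
        lambda: pm_mm_ttest(array, layout, log2=bool(cfg.get("log2_ttest", False))),
    )
    attempt(
        "average_background",
        "descending",
        lambda: average_background(
            array, fraction=float(cfg.get("background_fraction", 0.02))
        ),
    )
    attempt(
        "scaling_factor",
        "descending",
        lambda: scaling_factor(
            array,
            target=float(cfg.get("scaling_target", 500.0)),
            trim=float(cfg.get("scaling_trim", 0.02)),
        ),
    )
    attempt(
        "rna_degradation_slope",
        "ascending",
        lambda: rna_degradation_slope(
            array, layout, standardize=bool(cfg.get("standardize_slope", False))
        ),
    )
    attempt(
        "percent_present",
        "ascending",
        lambda: percent_present(
            array,
            layout,
            tau=float(cfg.get("tau", 0.015)),
            alpha1=float(cfg.get("alpha1", 0.04)),
        ),
    )
    for cp in layout.control_pairs:
        attempt(
            f"three_five_ratio_{cp.label}",
            "descending",
            lambda cp=cp: three_five_ratio(array, layout, cp.label),
        )
    return report
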