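"""The IQRray quality statistic.

An array is scored in three steps: (1) rank every probe intensity on the
array (midranks for ties), (2) average the ranks of the probes in each
probe set, (3) take the interquartile range (IQR) of the per-set average
ranks. On a high-quality array, probes targeting the same transcript
have consistent signal, so probe sets targeting expressed genes sit at
high average ranks and probe sets targeting silent genes at low ones —
a wide spread. Noise of any origin mixes low and high ranks within probe
sets and pulls every average toward the grand mean rank, shrinking the
IQR. Larger IQRray therefore means better quality, and because the
statistic is rank-based it is directly comparable between arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .chip_model import ArrayIntensities, ChipLayout
from .errors import IntegrityError

PROBE_SCOPES = ("all_probes", "pm_only", "assigned_only")


@dataclass(frozen=True)
class RankVector:
    """Ascending midranks of the probes in scope (1 = dimmest).

    ``positions`` are row positions into the layout's probe table for
    the ranked probes, so rank k belongs to layout probe
    ``positions[k]``. The rank sum is exactly ``n (n + 1) / 2``.
    """

    positions: np.ndarray
    ranks: np.ndarray
    n_ranked: int

    def as_series(self, layout: ChipLayout) -> pd.Series:
        return pd.Series(self.ranks, index=layout.probe_ids[self.positions])


@dataclass(frozen=True)
class ProbeSetRankSummary:
    """Mean rank and member count per probe set (sets with ranked members)."""

    average_ranks: pd.Series
    set_sizes: pd.Series


def _scope_mask(layout: ChipLayout, probe_scope: str) -> np.ndarray:
    if probe_scope == "all_probes":
        return np.ones(layout.n_probes, dtype=bool)
    if probe_scope == "pm_only":
        return layout.pm_mask.copy()
    if probe_scope == "assigned_only":
        return layout.set_codes >= 0
    raise ValueError(f"unknown probe_scope {probe_scope!r}; use one of {PROBE_SCOPES}")


def rank_intensities(
    array: ArrayIntensities, layout: ChipLayout, probe_scope: str = "all_probes"
) -> RankVector:
    """Rank the intensities of the probes in scope, ascending, midranks
    for ties. Probes outside the scope are excluded entirely (they do
    not occupy rank mass)."""
    mask = _scope_mask(layout, probe_scope)
    positions = np.flatnonzero(mask)
    if positions.size == 0:
        raise IntegrityError(f"probe scope {probe_scope!r} selects no probes")
    values = array.values_for(layout)[positions]
    ranks = rankdata(values, method="average")
    return RankVector(positions=positions, ranks=ranks, n_ranked=positions.size)


def probe_set_average_ranks(
    ranks: RankVector, layout: ChipLayout
) -> ProbeSetRankSummary:
    """Average the ranks of each probe set's ranked members.

    Probes with no probe set never contribute; probe sets with zero
    ranked members are omitted.
    """
    codes = layout.set_codes[ranks.positions]
    keep = codes >= 0
    codes = codes[keep]
    if codes.size == 0:
        raise IntegrityError("no ranked probe belongs to any probe set")
    n_sets = len(layout.set_ids)
    sums = np.bincount(codes, weights=ranks.ranks[keep], minlength=n_sets)
    counts = np.bincount(codes, minlength=n_sets)
    present = counts > 0
    ids = pd.Index(layout.set_ids[present], name="probe_set_id")
    return ProbeSetRankSummary(
        average_ranks=pd.Series(sums[present] / counts[present], index=ids),
        set_sizes=pd.Series(counts[present], index=ids),
    )


def iqrray_score(summary: ProbeSetRankSummary) -> float:
    """Interquartile range (Q3 - Q1) of the probe-set average ranks,
    quantiles by linear interpolation between order statistics
    (quantile q of n sorted values sits at position 1 + (n - 1) q)."""
    values = summary.average_ranks.to_numpy(dtype=float)
    if values.size < 2:
        raise IntegrityError(
            f"IQRray needs at least 2 probe sets, got {values.size}"
        )
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return float(q3 - q1)


def iqrray(
    array: ArrayIntensities, layout: ChipLayout, probe_scope: str = "all_probes"
) -> float:
    """One-call IQRray score: rank, average per probe set, take the IQR."""
    ranks = rank_intensities(array, layout, probe_scope)
    summary = probe_set_average_ranks(ranks, layout)
    return iqrray_score(summary)


def iqrray_null_iqr_normal(n_probes: int, set_size: int) -> float:
    """Normal-approximation IQR of probe-set average ranks when probes
    are assigned to sets at random: the average rank of a set of k
    probes drawn without replacement from {1..N} has standard deviation
    sqrt((N + 1)(N - k) / (12 k)); the IQR of a normal is 1.349 sd."""
    n, k = float(n_probes), float(set_size)
    sd = np.sqrt((n + 1.0) * (n - k) / (12.0 * k))
    return float(1.3489795003921634 * sd)  # 2 * Phi^-1(0.75)
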