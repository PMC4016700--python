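"""Synthetic probe-level arrays and two-species expression collections.

The array generator emulates the features the quality metrics respond
to: probe sets with consistent versus globally shuffled rank structure
(a ``corruption`` fraction of probes has its values re-shuffled across
the whole array, the mechanism by which noise of any origin mixes ranks
between probe sets), a PM/MM intensity shift toward a nonspecific
background level, and multiplicative 5' attenuation mimicking RNA
degradation. Intensities are log-normal-shaped (exponentiated
Gaussian), so rank-based and linear-scale metrics are both exercised.

The collection generator emulates a two-species compendium: per-organ
latent gene signatures shared between species through 1:1 orthologs,
reference profiles in species B, and species-A arrays whose gene-level
noise and probe-level corruption both follow a per-array quality in
[0, 1]. Most arrays are good with a small tail of clearly degraded
ones, the situation a database screening pipeline faces.

All randomness flows from the single seed recorded in the spec; reruns
are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chip_model import ArrayIntensities, ChipLayout, ControlPair, write_cel
from .expression_summary import (
    ExpressionProfile,
    GeneMap,
    build_profile,
    summarize_probe_sets,
)


@dataclass
class ArraySimSpec:
    """Parameters of one simulated array.

    ``corruption`` is the fraction of probes whose values are shuffled
    globally (0 = perfectly consistent probe sets, 1 = random array);
    ``pm_mm_shift`` is the log-scale attenuation of MM probes toward
    background (0 disables MM partners); ``degradation_strength`` is
    the total log-scale 5' attenuation across a probe set.
    """

    n_probe_sets: int = 200
    probes_per_set: int | Sequence[int] = 11
    corruption: float = 0.0
    pm_mm_shift: float = 0.0
    degradation_strength: float = 0.0
    n_unassigned: int = 0
    seed: int = 0
    log_mean: float = 6.0
    log_sd: float = 1.2
    mm_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.corruption <= 1.0:
            raise ValueError("corruption must be in [0, 1]")
        if self.n_probe_sets < 1:
            raise ValueError("n_probe_sets must be >= 1")
        sizes = self.set_sizes()
        if (sizes < 1).any():
            raise ValueError("probes_per_set entries must be >= 1")
        if self.pm_mm_shift < 0:
            raise ValueError("pm_mm_shift must be >= 0")

    def set_sizes(self) -> np.ndarray:
        if isinstance(self.probes_per_set, (int, np.integer)):
            return np.full(self.n_probe_sets, int(self.probes_per_set))
        sizes = np.asarray(self.probes_per_set, dtype=int)
        if sizes.size != self.n_probe_sets:
            raise ValueError("probes_per_set length must equal n_probe_sets")
        return sizes


def make_layout(
    n_probe_sets: int,
    probes_per_set: int | Sequence[int] = 11,
    with_mm: bool = False,
    with_positions: bool = True,
    n_unassigned: int = 0,
    platform_id: str = "synthetic",
    control_pairs: Sequence[ControlPair] = (),
) -> ChipLayout:
    """Build a rectangular synthetic layout: probe sets ``ps00000`` ...,
    PM probes ``psXXXXX_pmJ`` (position_index J, 0 = most 5'), optional
    MM partners, optional unassigned background probes."""
    sizes = (
        np.full(n_probe_sets, int(probes_per_set))
        if isinstance(probes_per_set, (int, np.integer))
        else np.asarray(probes_per_set, dtype=int)
    )
    rows: list[tuple] = []
    for s in range(n_probe_sets):
        ps = f"ps{s:05d}"
        for j in range(sizes[s]):
            pm_id, mm_id = f"{ps}_pm{j}", f"{ps}_mm{j}"
            rows.append((pm_id, ps, True, mm_id if with_mm else None, float(j)))
            if with_mm:
                rows.append((mm_id, ps, False, pm_id, float(j)))
    for j in range(n_unassigned):
        rows.append((f"bg{j:05d}", None, True, None, math.nan))
    n = len(rows)
    n_cols = int(math.ceil(math.sqrt(n)))
    n_rows = int(math.ceil(n / n_cols))
    idx = np.arange(n)
    probes = pd.DataFrame(
        {
            "probe_id": [r[0] for r in rows],
            "x": idx % n_cols,
            "y": idx // n_cols,
            "probe_set_id": [r[1] for r in rows],
            "is_pm": [r[2] for r in rows],
            "partner_probe_id": [r[3] for r in rows],
            "position_index": [r[4] for r in rows]
            if with_positions
            else [math.nan] * n,
        }
    )
    return ChipLayout(
        platform_id=platform_id,
        probes=probes,
        control_pairs=list(control_pairs),
        n_rows=n_rows,
        n_cols=n_cols,
    )


def _corrupt(values: np.ndarray, fraction: float, rng: np.random.Generator) -> None:
    """Shuffle a ``fraction`` of the entries of ``values`` among
    themselves, in place."""
    m = int(round(fraction * values.size))
    if m < 2:
        return
    idx = rng.choice(values.size, size=m, replace=False)
    values[idx] = values[rng.permutation(idx)]


def simulate_array(
    spec: ArraySimSpec,
    layout: ChipLayout | None = None,
    array_id: str | None = None,
) -> tuple[ChipLayout, ArrayIntensities]:
    """Simulate one array (and, unless given, its layout).

    With corruption 0, probes of the same probe set occupy consecutive
    global ranks (blocks of sorted log-normal draws are dealt to probe
    sets in random order); with corruption 1 the ranks are a uniform
    random permutation. MM partners (when ``pm_mm_shift > 0``) are the
    PM value attenuated toward background by ``exp(-pm_mm_shift)`` with
    log-normal noise; 5' attenuation follows ``degradation_strength``.
    Corruption shuffles PM and MM probes alike.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = spec.set_sizes()
    with_mm = spec.pm_mm_shift > 0
    if layout is None:
        layout = make_layout(
            spec.n_probe_sets,
            sizes,
            with_mm=with_mm,
            n_unassigned=spec.n_unassigned,
        )
    n_pm_total = int(sizes.sum())

    # deal blocks of consecutive sorted values to probe sets in random order
    sorted_logs = np.sort(rng.normal(spec.log_mean, spec.log_sd, n_pm_total))
    block_of_set = rng.permutation(spec.n_probe_sets)
    starts = np.zeros(spec.n_probe_sets, dtype=int)
    order_sizes = sizes[np.argsort(block_of_set)]
    starts[np.argsort(block_of_set)] = np.concatenate(
        ([0], np.cumsum(order_sizes)[:-1])
    )
    pm_log = np.empty(n_pm_total)
    pos = 0
    for s in range(spec.n_probe_sets):
        k = sizes[s]
        block = sorted_logs[starts[s] : starts[s] + k]
        pm_log[pos : pos + k] = rng.permutation(block)
        pos += k

    if spec.degradation_strength > 0:
        chunks = []
        for s in range(spec.n_probe_sets):
            k = sizes[s]
            rel = np.arange(k) / (k - 1) if k > 1 else np.ones(1)
            chunks.append(spec.degradation_strength * (1.0 - rel))
        pm_log = pm_log - np.concatenate(chunks)

    pm_values = np.exp(pm_log)

    # assemble full probe vector in layout order
    values = np.empty(layout.n_probes)
    pm_rows = np.flatnonzero(layout.pm_mask & (layout.set_codes >= 0))
    values[pm_rows] = pm_values
    if with_mm:
        bg = math.exp(spec.log_mean - 2.0 * spec.log_sd)
        att = math.exp(-spec.pm_mm_shift)
        pm_idx, mm_idx = layout.pm_pairs
        eps = rng.normal(0.0, spec.mm_noise_sd, pm_idx.size)
        values[mm_idx] = bg + np.maximum(values[pm_idx] - bg, 0.0) * att * np.exp(eps)
    unassigned = layout.set_codes < 0
    if unassigned.any():
        values[unassigned] = np.exp(
            rng.normal(spec.log_mean, spec.log_sd, int(unassigned.sum()))
        )

    _corrupt(values, spec.corruption, rng)
    name = array_id or f"sim_seed{spec.seed}"
    return layout, ArrayIntensities(name, layout.platform_id, layout.probe_ids, values)


# ---------------------------------------------------------------------------
# two-species collections
# ---------------------------------------------------------------------------


@dataclass
class CollectionSimSpec:
    """Parameters of a synthetic two-species organ compendium.

    ``quality`` maps each array to gene-level noise (sd interpolated
    log-linearly across ``noise_sd_range``; quality 1 = low end) and to
    probe-level corruption ``1 - quality``. The default quality law is
    a mixture: ``1 - bad_fraction`` good arrays (Beta(6, 2)) and a tail
    of degraded ones (0.4 Beta(1.5, 8)) per organ.
    """

    n_species_genes: int = 2000
    n_organs: int = 3
    arrays_per_organ: int = 40
    n_references_per_organ: int = 4
    probes_per_set: int = 11
    organ_signal_sd: float = 1.0
    noise_sd_range: tuple[float, float] = (0.25, 2.5)
    reference_noise_sd: float = 0.25
    quality: Sequence[float] | None = None
    bad_fraction: float = 0.1
    ortholog_fraction: float = 0.8
    pm_mm_shift: float = 1.0
    probe_affinity_sd: float = 0.5
    probe_noise_sd: float = 0.15
    log_mean: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ortholog_fraction <= 1.0:
            raise ValueError("ortholog_fraction must be in [0, 1]")
        if self.quality is not None:
            q = np.asarray(self.quality, dtype=float)
            if q.size != self.arrays_per_organ:
                raise ValueError("quality must have one entry per array per organ")
            if ((q < 0) | (q > 1)).any():
                raise ValueError("quality values must be in [0, 1]")


@dataclass
class SimulatedCollection:
    """Everything the benchmark needs, with the latent truth attached."""

    layout: ChipLayout
    arrays: list[ArrayIntensities]
    profiles: list[ExpressionProfile]
    references: list[ExpressionProfile]
    gene_map: GeneMap
    organs: dict[str, str]
    experiments: dict[str, str]
    true_quality: dict[str, float]


def _organ_qualities(spec: CollectionSimSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.quality is not None:
        return np.asarray(spec.quality, dtype=float)
    n = spec.arrays_per_organ
    n_bad = int(round(spec.bad_fraction * n))
    good = rng.beta(6.0, 2.0, n - n_bad)
    bad = 0.4 * rng.beta(1.5, 8.0, n_bad)
    q = np.concatenate([good, bad])
    rng.shuffle(q)
    return q


def simulate_two_species_collection(spec: CollectionSimSpec) -> SimulatedCollection:
    """Generate a species-A array collection (probe level) plus
    species-B gene-level references sharing per-organ signatures
    through 1:1 orthologs. Species-A profiles are produced by the real
    summarization pipeline, so probe-level corruption propagates into
    the conservation score exactly as it would for real data."""
    rng = np.random.default_rng(spec.seed)
    G, k = spec.n_species_genes, spec.probes_per_set

    genes_a = np.array([f"gA{i:05d}" for i in range(G)], dtype=object)
    genes_b = np.array([f"gB{i:05d}" for i in range(G)], dtype=object)
    n_orth = int(round(spec.ortholog_fraction * G))
    orth_idx = np.sort(rng.choice(G, size=n_orth, replace=False))
    gene_map = GeneMap(
        probe_set_to_genes={f"ps{i:05d}": {genes_a[i]} for i in range(G)},
        ortholog_pairs=[(genes_a[i], genes_b[i]) for i in orth_idx],
    )
    if n_orth == 0 and spec.ortholog_fraction == 0.0:
        pass  # legal spec; downstream HOC computations will error

    layout = make_layout(G, k, with_mm=spec.pm_mm_shift > 0, platform_id="synthA")
    affinity = rng.normal(0.0, spec.probe_affinity_sd, G * k)
    organs = [f"organ{o}" for o in range(spec.n_organs)]
    signatures = {o: rng.normal(0.0, spec.organ_signal_sd, G) for o in organs}

    references: list[ExpressionProfile] = []
    for o in organs:
        mu = signatures[o][orth_idx]
        for r in range(spec.n_references_per_organ):
            vals = np.exp(mu + rng.normal(0.0, spec.reference_noise_sd, n_orth))
            references.append(
                ExpressionProfile(
                    array_id=f"{o}_ref{r}",
                    species="speciesB",
                    values=pd.Series(vals, index=genes_b[orth_idx]),
                )
            )

    lo, hi = spec.noise_sd_range
    pm_rows = np.flatnonzero(layout.pm_mask & (layout.set_codes >= 0))
    pm_sets = layout.set_codes[pm_rows]
    bg = math.exp(spec.log_mean - 2.5)
    att = math.exp(-spec.pm_mm_shift)

    arrays: list[ArrayIntensities] = []
    profiles: list[ExpressionProfile] = []
    organ_of: dict[str, str] = {}
    exp_of: dict[str, str] = {}
    quality_of: dict[str, float] = {}
    for o in organs:
        qualities = _organ_qualities(spec, rng)
        for j, q in enumerate(qualities):
            array_id = f"{o}_a{j:03d}"
            sd_gene = hi ** (1.0 - q) * lo**q
            c = 1.0 - q
            g = signatures[o] + rng.normal(0.0, sd_gene, G)
            pm_log = (
                spec.log_mean
                + g[pm_sets]
                + affinity
                + rng.normal(0.0, spec.probe_noise_sd, pm_rows.size)
            )
            values = np.empty(layout.n_probes)
            values[pm_rows] = np.exp(pm_log)
            if spec.pm_mm_shift > 0:
                pm_idx, mm_idx = layout.pm_pairs
                eps = rng.normal(0.0, 0.1 + 0.4 * c, pm_idx.size)
                values[mm_idx] = (
                    bg + np.maximum(values[pm_idx] - bg, 0.0) * att * np.exp(eps)
                )
            _corrupt(values, c, rng)
            array = ArrayIntensities(array_id, layout.platform_id, layout.probe_ids, values)
            arrays.append(array)
            if n_orth:
                profiles.append(
                    build_profile(
                        summarize_probe_sets(array, layout),
                        gene_map,
                        species="speciesA",
                        array_id=array_id,
                    )
                )
            organ_of[array_id] = o
            exp_of[array_id] = f"{o}_e{j // 6:02d}"
            quality_of[array_id] = float(q)

    return SimulatedCollection(
        layout=layout,
        arrays=arrays,
        profiles=profiles,
        references=references,
        gene_map=gene_map,
        organs=organ_of,
        experiments=exp_of,
        true_quality=quality_of,
    )


def write_fixture_cel(
    array: ArrayIntensities, layout: ChipLayout, path: str | Path
) -> ArrayIntensities:
    """Write a CEL v4 fixture and return the array as stored (cell
    means are float32, so values are cast before writing; reading the
    file recovers the returned array bit-exactly)."""
    stored = ArrayIntensities(
        array.array_id,
        array.platform_id,
        array.probe_ids,
        array.values_for(layout).astype(np.float32).astype(float),
    )
    write_cel(stored, layout, path)
    return stored
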