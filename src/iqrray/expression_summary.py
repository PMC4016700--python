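"""Probe-level data to gene-level expression profiles.

The pipeline is deliberately simple: average the raw PM intensities of
each probe set, drop probe sets that match more than one gene, average
probe sets matching the same gene, and keep only genes that have a 1:1
ortholog in the partner species. The downstream conservation score is
rank-based, so no normalization or log transform is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .chip_model import ArrayIntensities, ChipLayout
from .errors import FormatError, IntegrityError


@dataclass
class GeneMap:
    """Probe-set -> gene assignments plus 1:1 ortholog pairs."""

    probe_set_to_genes: dict[str, set[str]]
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for a, b in self.ortholog_pairs:
            for g in (a, b):
                if g in seen:
                    raise IntegrityError(
                        f"gene {g!r} occurs in more than one ortholog pair"
                    )
                seen.add(g)

    @property
    def ortholog_genes(self) -> set[str]:
        return {g for pair in self.ortholog_pairs for g in pair}

    def partner_of(self, gene: str) -> str | None:
        for a, b in self.ortholog_pairs:
            if gene == a:
                return b
            if gene == b:
                return a
        return None


@dataclass
class ExpressionProfile:
    """Gene-level summarized expression for one array."""

    array_id: str
    species: str
    values: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.Series):
            self.values = pd.Series(dict(self.values), dtype=float)
        self.values = self.values.astype(float)


def read_gene_map(
    probe_set_genes: str | Path, orthologs: str | Path | None = None
) -> GeneMap:
    """Read probe-set->gene rows (TSV: probe_set_id, gene_id; repeated
    rows for multi-gene probe sets) and optional ortholog pairs
    (TSV: gene_a, gene_b)."""
    ps = pd.read_csv(probe_set_genes, sep="\t", dtype=str)
    if not {"probe_set_id", "gene_id"} <= set(ps.columns):
        raise FormatError("probe-set map needs columns probe_set_id, gene_id")
    mapping: dict[str, set[str]] = {}
    for r in ps.itertuples(index=False):
        mapping.setdefault(r.probe_set_id, set()).add(r.gene_id)
    pairs: list[tuple[str, str]] = []
    if orthologs is not None:
        orth = pd.read_csv(orthologs, sep="\t", dtype=str)
        if not {"gene_a", "gene_b"} <= set(orth.columns):
            raise FormatError("ortholog table needs columns gene_a, gene_b")
        pairs = [(r.gene_a, r.gene_b) for r in orth.itertuples(index=False)]
    return GeneMap(probe_set_to_genes=mapping, ortholog_pairs=pairs)


def summarize_probe_sets(
    array: ArrayIntensities, layout: ChipLayout
) -> pd.Series:
    """Arithmetic mean of raw PM intensities per probe set (probe sets
    with no PM probe are omitted)."""
    v = array.values_for(layout)
    use = layout.pm_mask & (layout.set_codes >= 0)
    codes = layout.set_codes[use]
    n_sets = len(layout.set_ids)
    sums = np.bincount(codes, weights=v[use], minlength=n_sets)
    counts = np.bincount(codes, minlength=n_sets)
    present = counts > 0
    return pd.Series(
        sums[present] / counts[present],
        index=pd.Index(layout.set_ids[present], name="probe_set_id"),
    )


def build_profile(
    ps_values: Mapping[str, float] | pd.Series,
    gene_map: GeneMap,
    species: str,
    array_id: str = "",
    log2: bool = False,
) -> ExpressionProfile:
    """Gene-level profile: drop multi-gene probe sets, average probe
    sets per gene, keep only genes with a 1:1 ortholog partner."""
    if not isinstance(ps_values, pd.Series):
        ps_values = pd.Series(dict(ps_values), dtype=float)
    universe = gene_map.ortholog_genes
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for ps, value in ps_values.items():
        genes = gene_map.probe_set_to_genes.get(ps)
        if genes is None or len(genes) != 1:
            continue  # unmapped or multi-gene probe set
        (gene,) = genes
        if gene not in universe:
            continue
        sums[gene] = sums.get(gene, 0.0) + float(value)
        counts[gene] = counts.get(gene, 0) + 1
    if not sums:
        raise IntegrityError(
            f"profile for array {array_id!r} is empty after gene filtering"
        )
    values = pd.Series({g: sums[g] / counts[g] for g in sums}, dtype=float)
    if log2:
        values = np.log2(1.0 + values)
    return ExpressionProfile(array_id=array_id, species=species, values=values)


def align_profiles(
    a: ExpressionProfile, b: ExpressionProfile, gene_map: GeneMap
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Pair the two profiles' values by ortholog pair, restricted to
    pairs present in both; returns (values_a, values_b, pairs_used)."""
    va, vb, used = [], [], []
    for ga, gb in gene_map.ortholog_pairs:
        if ga in a.values.index and gb in b.values.index:
            pa, pb = ga, gb
        elif gb in a.values.index and ga in b.values.index:
            pa, pb = gb, ga
        else:
            continue
        va.append(a.values[pa])
        vb.append(b.values[pb])
        used.append((pa, pb))
    if not used:
        raise IntegrityError(
            f"profiles {a.array_id!r} and {b.array_id!r} share no ortholog pair"
        )
    return np.asarray(va, float), np.asarray(vb, float), used


def read_profiles(path: str | Path, species: str) -> list[ExpressionProfile]:
    """Read profiles from a long TSV (array_id, gene_id, value)."""
    df = pd.read_csv(path, sep="\t", dtype={"array_id": str, "gene_id": str})
    if not {"array_id", "gene_id", "value"} <= set(df.columns):
        raise FormatError("profile TSV needs columns array_id, gene_id, value")
    out = []
    for array_id, sub in df.groupby("array_id", sort=True):
        values = pd.Series(
            sub["value"].to_numpy(float), index=sub["gene_id"].to_numpy(object)
        )
        out.append(ExpressionProfile(str(array_id), species, values))
    return out


def write_profiles(profiles: list[ExpressionProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for gene, value in p.values.items():
            rows.append((p.array_id, gene, format(value, ".6g")))
    pd.DataFrame(rows, columns=["array_id", "gene_id", "value"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
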