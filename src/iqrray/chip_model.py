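"""Platform layouts and probe-level intensities.

A :class:`ChipLayout` captures the static geometry and semantics of an
Affymetrix-style platform: which probes exist, where they sit on the
cell grid, which probe set (if any) each belongs to, PM/MM partnering,
the 5'->3' position index of each probe within its target transcript,
and the registry of 3'/5' control probe-set pairs (actin/GAPDH style).

An :class:`ArrayIntensities` holds one array's raw probe-level signal,
keyed to a layout. Two on-disk representations are supported: a simple
tab-separated table, and the Affymetrix CEL version-4 binary (probes
addressed by ``y * n_cols + x``; the per-cell MEAN is the intensity).
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, IntegrityError

LAYOUT_COLUMNS = (
    "probe_id",
    "x",
    "y",
    "probe_set_id",
    "is_pm",
    "partner_probe_id",
    "position_index",
)

CONTROL_COLUMNS = ("label", "probe_set_3", "probe_set_5")


@dataclass(frozen=True)
class ControlPair:
    """A registered 3'/5' control probe-set pair (e.g. AFFX GAPDH)."""

    label: str
    probe_set_3prime: str
    probe_set_5prime: str


@dataclass(eq=False)
class ChipLayout:
    """Validated static description of one platform.

    ``probes`` is a DataFrame with columns ``probe_id`` (str), ``x``/``y``
    (0-based ints), ``probe_set_id`` (str or None), ``is_pm`` (bool),
    ``partner_probe_id`` (str or None) and ``position_index`` (float,
    NaN when absent).  Validation runs on construction.
    """

    platform_id: str
    probes: pd.DataFrame
    control_pairs: list[ControlPair] = field(default_factory=list)
    n_rows: int = 0
    n_cols: int = 0

    def __post_init__(self) -> None:
        df = self.probes.reset_index(drop=True)
        missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"layout is missing columns: {missing}")
        self.probes = df
        if self.n_cols <= 0:
            self.n_cols = int(df["x"].max()) + 1 if len(df) else 0
        if self.n_rows <= 0:
            self.n_rows = int(df["y"].max()) + 1 if len(df) else 0
        self._validate()

    # -- validation -------------------------------------------------

    def _validate(self) -> None:
        df = self.probes
        if df["probe_id"].duplicated().any():
            dupes = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
            raise IntegrityError(f"duplicate probe_id values: {dupes[:5]}")

        x = df["x"].to_numpy()
        y = df["y"].to_numpy()
        bad = (x < 0) | (x >= self.n_cols) | (y < 0) | (y >= self.n_rows)
        if bad.any():
            rows = np.flatnonzero(bad)[:5] + 1
            raise IntegrityError(
                f"probe coordinates outside the {self.n_rows}x{self.n_cols} "
                f"grid at rows {rows.tolist()}"
            )
        flat = y.astype(np.int64) * self.n_cols + x
        if len(np.unique(flat)) != len(flat):
            seen: dict[int, int] = {}
            for i, f in enumerate(flat):
                if f in seen:
                    raise IntegrityError(
                        f"duplicate (x, y) cell at rows {seen[f] + 1} and {i + 1}"
                    )
                seen[f] = i

        pos = {pid: i for i, pid in enumerate(df["probe_id"])}
        pset = df["probe_set_id"].to_numpy(dtype=object)
        partner = df["partner_probe_id"].to_numpy(dtype=object)
        is_pm = df["is_pm"].to_numpy(dtype=bool)
        for i, p in enumerate(partner):
            if p is None:
                continue
            j = pos.get(p)
            if j is None:
                raise IntegrityError(
                    f"probe {df['probe_id'][i]!r} (row {i + 1}) references "
                    f"missing partner {p!r}"
                )
            if partner[j] != df["probe_id"][i]:
                raise IntegrityError(
                    f"asymmetric PM/MM pairing between {df['probe_id'][i]!r} "
                    f"and {p!r}"
                )
            if is_pm[i] == is_pm[j]:
                raise IntegrityError(
                    f"probes {df['probe_id'][i]!r} and {p!r} are paired but "
                    f"have the same PM/MM flag"
                )
            if pset[i] != pset[j]:
                raise IntegrityError(
                    f"paired probes {df['probe_id'][i]!r} and {p!r} belong to "
                    f"different probe sets"
                )

        known_sets = {s for s in pset if s is not None}
        for cp in self.control_pairs:
            for ps in (cp.probe_set_3prime, cp.probe_set_5prime):
                if ps not in known_sets:
                    raise IntegrityError(
                        f"control pair {cp.label!r} references unknown probe "
                        f"set {ps!r}"
                    )

        # distinct position indices within each probe set
        pidx = df["position_index"].to_numpy(dtype=float)
        has_pos = ~np.isnan(pidx)
        if has_pos.any():
            sub = df.loc[has_pos & (pset != None)]  # noqa: E711 (object array)
            # distinctness matters separately on PM and MM sides of a set
            dup = sub.duplicated(subset=["probe_set_id", "is_pm", "position_index"])
            if dup.any():
                bad_set = sub.loc[dup, "probe_set_id"].iloc[0]
                raise IntegrityError(
                    f"probe set {bad_set!r} has duplicated position_index values"
                )

    # -- derived views ----------------------------------------------

    @cached_property
    def probe_ids(self) -> np.ndarray:
        return self.probes["probe_id"].to_numpy(dtype=object)

    @cached_property
    def probe_index(self) -> pd.Index:
        return pd.Index(self.probes["probe_id"])

    @cached_property
    def _set_factorization(self) -> tuple[np.ndarray, np.ndarray]:
        codes, uniques = pd.factorize(self.probes["probe_set_id"])
        return codes, np.asarray(uniques, dtype=object)

    @property
    def set_codes(self) -> np.ndarray:
        """Integer probe-set code per probe; -1 for unassigned probes."""
        return self._set_factorization[0]

    @property
    def set_ids(self) -> np.ndarray:
        return self._set_factorization[1]

    @cached_property
    def pm_mask(self) -> np.ndarray:
        return self.probes["is_pm"].to_numpy(dtype=bool)

    @cached_property
    def pm_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Row positions of (PM, MM) partners, one entry per pair."""
        df = self.probes
        pos = {pid: i for i, pid in enumerate(df["probe_id"])}
        pm_rows, mm_rows = [], []
        partner = df["partner_probe_id"].to_numpy(dtype=object)
        for i in np.flatnonzero(self.pm_mask):
            p = partner[i]
            if p is not None:
                pm_rows.append(i)
                mm_rows.append(pos[p])
        return (
            np.asarray(pm_rows, dtype=np.intp),
            np.asarray(mm_rows, dtype=np.intp),
        )

    @property
    def n_probes(self) -> int:
        return len(self.probes)


@dataclass(eq=False)
class ArrayIntensities:
    """One array's probe-level signal, in layout row order."""

    array_id: str
    platform_id: str
    probe_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        if self.values.shape != self.probe_ids.shape:
            raise IntegrityError("probe_ids and values differ in length")
        if not np.all(np.isfinite(self.values)):
            raise IntegrityError(f"array {self.array_id!r} has non-finite intensities")
        if (self.values < 0).any():
            raise IntegrityError(f"array {self.array_id!r} has negative intensities")

    @classmethod
    def from_mapping(
        cls, array_id: str, platform_id: str, values: Mapping[str, float]
    ) -> "ArrayIntensities":
        ids = np.asarray(list(values.keys()), dtype=object)
        return cls(array_id, platform_id, ids, np.asarray(list(values.values()), float))

    def values_for(self, layout: ChipLayout) -> np.ndarray:
        """Intensities aligned to ``layout.probes`` row order."""
        if len(self.probe_ids) == len(layout.probe_ids) and (
            self.probe_ids is layout.probe_ids
            or np.array_equal(self.probe_ids, layout.probe_ids)
        ):
            return self.values
        series = pd.Series(self.values, index=self.probe_ids)
        aligned = series.reindex(layout.probe_index)
        missing = aligned.index[aligned.isna()]
        if len(missing):
            raise IntegrityError(
                f"array {self.array_id!r} is missing intensities for layout "
                f"probes: {list(missing[:5])}"
            )
        return aligned.to_numpy(dtype=float)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.probe_ids, name=self.array_id)


# ---------------------------------------------------------------------------
# layout TSV I/O
# ---------------------------------------------------------------------------


def read_controls(path: str | Path) -> list[ControlPair]:
    """Read the companion control-pair registry (TSV or YAML)."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            entries = yaml.safe_load(fh) or []
        if not isinstance(entries, list):
            raise FormatError(f"{path}: control YAML must be a list of mappings")
        pairs = []
        for e in entries:
            missing = [c for c in CONTROL_COLUMNS if c not in e]
            if missing:
                raise FormatError(f"{path}: control entry missing keys {missing}")
            pairs.append(ControlPair(e["label"], e["probe_set_3"], e["probe_set_5"]))
        return pairs
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CONTROL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: control TSV missing columns {missing}")
    return [
        ControlPair(r.label, r.probe_set_3, r.probe_set_5)
        for r in df.itertuples(index=False)
    ]


def read_layout(
    path: str | Path,
    format: str = "tsv",
    platform_id: str | None = None,
    controls: str | Path | Sequence[ControlPair] | None = None,
    n_rows: int = 0,
    n_cols: int = 0,
) -> ChipLayout:
    """Read a layout TSV (columns ``probe_id, x, y, probe_set_id, is_pm,
    partner_probe_id, position_index``; empty string means null)."""
    if format != "tsv":
        raise FormatError(f"unsupported layout format {format!r}")
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in LAYOUT_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: layout TSV missing columns {missing}")

    def _int_col(name: str, allow_empty: bool = False) -> np.ndarray:
        col = raw[name].to_numpy(dtype=object)
        out = np.full(len(col), np.nan)
        for i, v in enumerate(col):
            if v == "":
                if allow_empty:
                    continue
                raise FormatError(f"{path}: empty {name!r} at row {i + 2}")
            try:
                out[i] = int(v)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: bad integer {v!r} in column {name!r} at row {i + 2}"
                ) from exc
        return out

    x = _int_col("x")
    y = _int_col("y")
    is_pm_raw = _int_col("is_pm")
    if not np.isin(is_pm_raw, (0, 1)).all():
        raise FormatError(f"{path}: is_pm must be 0 or 1")
    position = _int_col("position_index", allow_empty=True)

    def _opt_str(name: str) -> np.ndarray:
        return np.array(
            [v if v != "" else None for v in raw[name]], dtype=object
        )

    probes = pd.DataFrame(
        {
            "probe_id": raw["probe_id"].astype(str),
            "x": x.astype(int),
            "y": y.astype(int),
            "probe_set_id": _opt_str("probe_set_id"),
            "is_pm": is_pm_raw.astype(bool),
            "partner_probe_id": _opt_str("partner_probe_id"),
            "position_index": position,
        }
    )
    if controls is None:
        pairs: list[ControlPair] = []
    elif isinstance(controls, (str, Path)):
        pairs = read_controls(controls)
    else:
        pairs = list(controls)
    return ChipLayout(
        platform_id=platform_id or path.stem,
        probes=probes,
        control_pairs=pairs,
        n_rows=n_rows,
        n_cols=n_cols,
    )


def write_layout(layout: ChipLayout, path: str | Path) -> None:
    """Write the canonical layout TSV (inverse of :func:`read_layout`)."""
    df = layout.probes
    out = pd.DataFrame(
        {
            "probe_id": df["probe_id"],
            "x": df["x"],
            "y": df["y"],
            "probe_set_id": ["" if v is None else v for v in df["probe_set_id"]],
            "is_pm": df["is_pm"].astype(int),
            "partner_probe_id": [
                "" if v is None else v for v in df["partner_probe_id"]
            ],
            "position_index": [
                "" if np.isnan(v) else str(int(v)) for v in df["position_index"]
            ],
        }
    )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# intensity I/O
# ---------------------------------------------------------------------------


def read_intensities(
    path: str | Path,
    layout: ChipLayout,
    format: str | None = None,
    array_id: str | None = None,
    strict: bool = False,
) -> ArrayIntensities:
    """Read one array's intensities (``tsv`` or ``cel_v4``).

    Every layout probe must receive exactly one value. Probes present in
    a TSV but absent from the layout are skipped with a warning (strict
    mode turns this into an error).
    """
    path = Path(path)
    if format is None:
        format = "cel_v4" if path.suffix.lower() == ".cel" else "tsv"
    name = array_id or path.stem
    if format == "cel_v4":
        ncols, nrows, means = _read_cel_cells(path)
        if (ncols, nrows) != (layout.n_cols, layout.n_rows):
            raise IntegrityError(
                f"{path}: CEL grid {nrows}x{ncols} does not match layout "
                f"{layout.n_rows}x{layout.n_cols}"
            )
        flat = (
            layout.probes["y"].to_numpy(np.int64) * ncols
            + layout.probes["x"].to_numpy(np.int64)
        )
        values = means[flat].astype(float)
        return ArrayIntensities(name, layout.platform_id, layout.probe_ids, values)
    if format != "tsv":
        raise FormatError(f"unsupported intensity format {format!r}")

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "intensity" not in raw.columns:
        raise FormatError(f"{path}: intensity TSV missing 'intensity' column")
    try:
        inten = raw["intensity"].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric intensity value") from exc
    if "probe_id" in raw.columns:
        ids = raw["probe_id"].to_numpy(dtype=object)
    elif {"x", "y"} <= set(raw.columns):
        key = (
            raw["y"].astype(int).to_numpy(np.int64) * layout.n_cols
            + raw["x"].astype(int).to_numpy(np.int64)
        )
        flat = (
            layout.probes["y"].to_numpy(np.int64) * layout.n_cols
            + layout.probes["x"].to_numpy(np.int64)
        )
        lookup = dict(zip(flat, layout.probe_ids))
        ids = np.array([lookup.get(k) for k in key], dtype=object)
        unknown_xy = ids == None  # noqa: E711
        if unknown_xy.any():
            msg = f"{path}: {unknown_xy.sum()} rows address cells not in the layout"
            if strict:
                raise IntegrityError(msg)
            warnings.warn(msg, stacklevel=2)
            ids, inten = ids[~unknown_xy], inten[~unknown_xy]
    else:
        raise FormatError(
            f"{path}: intensity TSV needs a 'probe_id' column or 'x' and 'y'"
        )

    series = pd.Series(inten, index=ids)
    if series.index.duplicated().any():
        dupes = series.index[series.index.duplicated()][:5].tolist()
        raise IntegrityError(f"{path}: duplicate intensities for probes {dupes}")
    unknown = series.index.difference(layout.probe_index)
    if len(unknown):
        msg = f"{path}: probes not in layout: {list(unknown[:5])}"
        if strict:
            raise IntegrityError(msg)
        warnings.warn(msg, stacklevel=2)
        series = series.drop(unknown)
    aligned = series.reindex(layout.probe_index)
    missing = aligned.index[aligned.isna()]
    if len(missing):
        raise IntegrityError(
            f"{path}: no intensity for layout probes: {list(missing[:5])}"
        )
    return ArrayIntensities(
        name, layout.platform_id, layout.probe_ids, aligned.to_numpy(float)
    )


def write_intensities_tsv(array: ArrayIntensities, path: str | Path) -> None:
    df = pd.DataFrame({"probe_id": array.probe_ids, "intensity": array.values})
    df["intensity"] = df["intensity"].map(lambda v: format(v, ".6g"))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# CEL version-4 binary
# ---------------------------------------------------------------------------

_CEL_MAGIC = 64
_CEL_VERSION = 4
_CELL_DTYPE = np.dtype([("mean", "<f4"), ("stdev", "<f4"), ("npixels", "<i2")])


def _write_string(fh, text: str) -> None:
    data = text.encode("ascii")
    fh.write(struct.pack("<i", len(data)))
    fh.write(data)


def _read_string(fh) -> str:
    (n,) = struct.unpack("<i", fh.read(4))
    return fh.read(n).decode("ascii")


def write_cel(array: ArrayIntensities, layout: ChipLayout, path: str | Path) -> None:
    """Write a CEL v4 binary. Intensities are stored as little-endian
    float32 cell means; cells not covered by a layout probe are 0."""
    ncells = layout.n_rows * layout.n_cols
    cells = np.zeros(ncells, dtype=_CELL_DTYPE)
    cells["npixels"] = 9
    flat = (
        layout.probes["y"].to_numpy(np.int64) * layout.n_cols
        + layout.probes["x"].to_numpy(np.int64)
    )
    cells["mean"][flat] = array.values_for(layout).astype(np.float32)
    header = f"Cols={layout.n_cols}\nRows={layout.n_rows}\n"
    with open(path, "wb") as fh:
        fh.write(struct.pack("<2i", _CEL_MAGIC, _CEL_VERSION))
        fh.write(struct.pack("<3i", layout.n_cols, layout.n_rows, ncells))
        _write_string(fh, header)
        _write_string(fh, "Percentile")
        _write_string(fh, "")
        fh.write(struct.pack("<i", 2))  # cell margin
        fh.write(struct.pack("<II", 0, 0))  # outliers, masked
        fh.write(struct.pack("<i", 0))  # subgrids
        fh.write(cells.tobytes())


def _read_cel_cells(path: str | Path) -> tuple[int, int, np.ndarray]:
    with open(path, "rb") as fh:
        head = fh.read(8)
        if len(head) < 8:
            raise FormatError(f"{path}: truncated CEL file")
        magic, version = struct.unpack("<2i", head)
        if magic != _CEL_MAGIC:
            raise FormatError(f"{path}: bad CEL magic number {magic} (expected 64)")
        if version != _CEL_VERSION:
            raise FormatError(f"{path}: unsupported CEL version {version}")
        ncols, nrows, ncells = struct.unpack("<3i", fh.read(12))
        if ncells != ncols * nrows:
            raise FormatError(f"{path}: inconsistent CEL cell count")
        _read_string(fh)  # header text
        _read_string(fh)  # algorithm
        _read_string(fh)  # algorithm parameters
        fh.read(4)  # cell margin
        fh.read(8)  # outlier / masked counts
        fh.read(4)  # subgrids
        data = fh.read(ncells * _CELL_DTYPE.itemsize)
        if len(data) != ncells * _CELL_DTYPE.itemsize:
            raise FormatError(f"{path}: truncated CEL cell block")
        cells = np.frombuffer(data, dtype=_CELL_DTYPE)
    return ncols, nrows, cells["mean"].copy()
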