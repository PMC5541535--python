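"""Reading, validation and serialisation of movement-study artefacts.

All spatial inputs are planar coordinates in metres; timestamps are seconds.
Geographic (lon/lat) fixes must be projected before they reach the rest of
the package — :func:`project_lonlat` is a pass-through hook for that, the
core never sees unprojected coordinates.

Observation days are treated as independent follows: no displacement step or
interpolation ever crosses a day boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: seconds per calendar day, used when ``day_id`` must be derived from ``t``
DAY_SECONDS = 86_400.0

OBS_COLUMNS = ["animal_id", "t", "x", "y"]
RANK_COLUMNS = ["animal_id", "sex", "rank"]


class FormatError(ValueError):
    """The file does not have the expected columns or format."""


class ValidationError(ValueError):
    """The file parsed but violates a table invariant."""


@dataclass
class ObservationTable:
    """Asynchronous timestamped planar positions, one row per GPS fix.

    ``df`` has columns ``animal_id, t, x, y, day_id``, sorted by
    ``(animal_id, t)`` with no duplicate ``(animal_id, t)`` pair and strictly
    increasing timestamps within each animal-day.

    Parameters
    ----------
    df : pandas.DataFrame
        Validated fix table (use :func:`load_observations` or
        :func:`validate_observations` to build one).
    n_dropped : int
        Number of raw rows rejected during validation (duplicates,
        non-finite coordinates).
    """

    df: pd.DataFrame
    n_dropped: int = 0

    @property
    def animals(self) -> list[str]:
        return sorted(self.df["animal_id"].unique())

    @property
    def days(self) -> list[str]:
        return sorted(self.df["day_id"].unique())

    def track(self, animal: str, day: str | None = None) -> pd.DataFrame:
        """Time-ordered fixes of one animal, optionally within one day."""
        sub = self.df[self.df["animal_id"] == animal]
        if day is not None:
            sub = sub[sub["day_id"] == day]
        return sub

    def equals(self, other: "ObservationTable") -> bool:
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        return a[["animal_id", "day_id"]].equals(b[["animal_id", "day_id"]]) and np.allclose(
            a[["t", "x", "y"]].to_numpy(float), b[["t", "x", "y"]].to_numpy(float)
        )


@dataclass
class RankTable:
    """Ordinal dominance ranks, one entry per adult.

    ``rank`` is sex-specific with 1 = highest rank within that sex; a merged
    group-wide ordering (used for rank differences between any two animals)
    is produced by :meth:`merged_order`.
    """

    df: pd.DataFrame  # columns animal_id, sex, rank

    @property
    def animals(self) -> list[str]:
        return list(self.df["animal_id"])

    def merged_order(self, sex_order: tuple[str, ...] = ("M", "F")) -> dict[str, int]:
        """Group-wide ordinal rank (1 = highest) merging the sexes.

        The default places males above females, matching the convention of
        labelling a hierarchy from the top male downward; pass a different
        ``sex_order`` to change the merge.
        """
        out: dict[str, int] = {}
        place = 1
        for sex in sex_order:
            sub = self.df[self.df["sex"] == sex].sort_values("rank")
            for aid in sub["animal_id"]:
                out[aid] = place
                place += 1
        return out


def validate_observations(df: pd.DataFrame, source: str = "<memory>") -> ObservationTable:
    """Validate a raw fix table and return a clean :class:`ObservationTable`.

    Rows with non-finite coordinates and duplicate ``(animal_id, t)`` pairs
    are dropped (counted in ``n_dropped``); after sorting by ``(animal_id,
    t)`` the strict within-animal monotonicity invariant holds by
    construction.
    """
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing required column(s) {missing}")
    df = df.copy()
    for col in ("t", "x", "y"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(bad[bad.isna() & df[col].notna()].index[0])
            raise FormatError(f"{source}: non-numeric value in column {col!r} at row {row}") from exc
    n_raw = len(df)
    finite = np.isfinite(df[["t", "x", "y"]].to_numpy(float)).all(axis=1)
    df = df[finite]
    if "day_id" not in df.columns:
        df["day_id"] = (df["t"].to_numpy(float) // DAY_SECONDS).astype(int).astype(str)
    df["animal_id"] = df["animal_id"].astype(str)
    df["day_id"] = df["day_id"].astype(str)
    df = df.sort_values(["animal_id", "t"], kind="mergesort")
    df = df.drop_duplicates(subset=["animal_id", "t"], keep="first")
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.warning("%s: dropped %d invalid/duplicate row(s)", source, n_dropped)
    if df.empty:
        logger.warning("%s: observation table is empty", source)
    return ObservationTable(df[OBS_COLUMNS + ["day_id"]].reset_index(drop=True), n_dropped)


def load_observations(path: str | Path, max_gap: float = 1800.0) -> ObservationTable:
    """Load a GPS fix CSV (``animal_id,t,x,y[,day_id]``).

    ``max_gap`` (seconds) is not used during loading — validation is purely
    structural — but is recorded on the returned table's dataframe attrs as
    the suggested interpolation gap limit for downstream step building.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file without header") from exc
    table = validate_observations(raw, source=str(path))
    table.df.attrs["max_gap"] = float(max_gap)
    return table


def save_observations(table: ObservationTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def load_ranks(path: str | Path) -> RankTable:
    """Load a rank CSV (``animal_id,sex,rank``) and validate it."""
    df = pd.read_csv(path)
    return validate_ranks(df, source=str(path))


def validate_ranks(df: pd.DataFrame, source: str = "<memory>") -> RankTable:
    missing = [c for c in RANK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing required column(s) {missing}")
    df = df.copy()
    df["animal_id"] = df["animal_id"].astype(str)
    df["sex"] = df["sex"].astype(str)
    bad_sex = sorted(set(df["sex"]) - {"M", "F"})
    if bad_sex:
        raise ValidationError(f"{source}: unknown sex code(s) {bad_sex}")
    df["rank"] = pd.to_numeric(df["rank"], errors="raise").astype(int)
    if (df["rank"] < 1).any():
        raise ValidationError(f"{source}: ranks must be positive integers")
    for sex, sub in df.groupby("sex"):
        dup = sub[sub["rank"].duplicated()]
        if not dup.empty:
            raise ValidationError(
                f"{source}: duplicate rank {int(dup['rank'].iloc[0])} within sex {sex}"
            )
    if df["animal_id"].duplicated().any():
        raise ValidationError(f"{source}: duplicate animal_id")
    return RankTable(df[RANK_COLUMNS].reset_index(drop=True))


def check_ranks_cover(ranks: RankTable, animals: Iterable[str]) -> None:
    missing = sorted(set(animals) - set(ranks.animals))
    if missing:
        raise ValidationError(f"animals missing from rank table: {missing}")


def project_lonlat(
    df: pd.DataFrame, transform: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]
) -> pd.DataFrame:
    """Apply a user-supplied ``(lon, lat) -> (x, y)`` projection.

    The package itself is projection-agnostic; this is only a convenience
    for callers whose raw fixes are geographic.
    """
    out = df.copy()
    x, y = transform(df["lon"].to_numpy(float), df["lat"].to_numpy(float))
    out["x"], out["y"] = x, y
    return out.drop(columns=["lon", "lat"])


# ---------------------------------------------------------------------------
# network serialisation

_NODE_PREFIX = "# nodes:"


def export_network(network, path: str | Path, fmt: str = "csv") -> None:
    """Write an influence network as an edge-list CSV or GraphML.

    The CSV carries a ``# nodes:`` comment line so that isolated nodes
    survive a round trip; edges are rows ``source,target,weight,sign`` where
    ``weight`` is the signed influence coefficient.
    """
    path = Path(path)
    g = network.graph
    if fmt == "csv":
        rows = [
            {"source": u, "target": v, "weight": d["weight"], "sign": d["sign"]}
            for u, v, d in g.edges(data=True)
        ]
        with open(path, "w") as fh:
            fh.write(_NODE_PREFIX + " " + ";".join(str(n) for n in g.nodes) + "\n")
            pd.DataFrame(rows, columns=["source", "target", "weight", "sign"]).to_csv(
                fh, index=False, float_format="%.10g"
            )
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unsupported network format {fmt!r} (use 'csv' or 'graphml')")


def read_network(path: str | Path, fmt: str | None = None):
    """Read a network written by :func:`export_network`."""
    from .network import InfluenceNetwork  # local import: io has no other reason to know networks

    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix == ".graphml" else "csv"
    if fmt == "graphml":
        g = nx.read_graphml(path)
        out = nx.DiGraph()
        out.add_nodes_from(g.nodes)
        for u, v, d in g.edges(data=True):
            out.add_edge(u, v, weight=float(d["weight"]), sign=int(d["sign"]))
        return InfluenceNetwork(out)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(_NODE_PREFIX):
            raise FormatError(f"{path}: missing '{_NODE_PREFIX}' header line")
        nodes = [n for n in first[len(_NODE_PREFIX):].strip().split(";") if n]
        df = pd.read_csv(fh)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for row in df.itertuples(index=False):
        g.add_edge(str(row.source), str(row.target), weight=float(row.weight), sign=int(row.sign))
    return InfluenceNetwork(g)
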