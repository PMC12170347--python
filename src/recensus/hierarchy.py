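"""Nested areal systems and aggregation operators.

Small-area census extracts are published at every level of a nested
statistical geography (here generically L1 < L2 < L3 < L4 < STATE, mirroring
the Australian SA1..SA4 + state nesting) and along two marginal
stratifications of the fine units: socioeconomic decile and a five-category
remoteness classification.  This module holds the hierarchy container and
builds the 0/1 aggregation matrices that connect a fine-unit count vector to
each published (or externally compared) table.

All vectors and matrices share one fixed fine-unit ordering: lexicographic
by ``unit_id``, frozen when the hierarchy is built.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "LEVELS",
    "REMOTENESS_CATEGORIES",
    "AGE_GROUPS",
    "POP_COLUMNS",
    "Hierarchy",
    "AggregationMatrix",
    "build_hierarchy",
    "aggregation_matrix",
    "correspondence_map",
    "read_hierarchy_csv",
    "write_hierarchy_csv",
    "read_geojson_centroids",
]

#: Areal levels, fine to coarse.
LEVELS = ("L1", "L2", "L3", "L4", "STATE")

#: The five admissible remoteness categories (major cities .. very remote).
REMOTENESS_CATEGORIES = (
    "major_cities",
    "inner_regional",
    "outer_regional",
    "remote",
    "very_remote",
)

#: Age groups carried by every count table.
AGE_GROUPS = ("0-9", "10-14", "15-19")

#: Fine-unit population columns, one per age group.
POP_COLUMNS = {"0-9": "pop_age0_9", "10-14": "pop_age10_14", "15-19": "pop_age15_19"}

_PARENT_COLS = {"L2": "l2_id", "L3": "l3_id", "L4": "l4_id", "STATE": "state_id"}

_CSV_COLUMNS = [
    "unit_id",
    "l2_id",
    "l3_id",
    "l4_id",
    "state_id",
    "ses_decile",
    "remoteness",
    "centroid_x_km",
    "centroid_y_km",
    "pop_age0_9",
    "pop_age10_14",
    "pop_age15_19",
]


@dataclass
class Hierarchy:
    """A nested areal system over fine units.

    ``units`` is one row per fine (L1) unit, sorted lexicographically by
    ``unit_id``, with its full parent chain, covariate labels, planar
    centroid in km, and per-age-group populations.
    """

    units: pd.DataFrame

    @property
    def n_fine(self) -> int:
        return len(self.units)

    @property
    def fine_ids(self) -> list[str]:
        return self.units["unit_id"].tolist()

    @property
    def centroids(self) -> np.ndarray:
        return self.units[["centroid_x_km", "centroid_y_km"]].to_numpy(float)

    @property
    def ses_decile(self) -> np.ndarray:
        cached = self.__dict__.get("_ses_cache")
        if cached is None:
            cached = self.units["ses_decile"].to_numpy(int)
            self.__dict__["_ses_cache"] = cached
        return cached

    @property
    def remoteness_codes(self) -> np.ndarray:
        """Remoteness as integer codes 0..4 in REMOTENESS_CATEGORIES order."""
        cached = self.__dict__.get("_rem_cache")
        if cached is None:
            cat = pd.Categorical(
                self.units["remoteness"], categories=REMOTENESS_CATEGORIES
            )
            cached = np.asarray(cat.codes, dtype=int)
            self.__dict__["_rem_cache"] = cached
        return cached

    def populations(self) -> pd.DataFrame:
        """Population per fine unit (rows) and age group (columns)."""
        out = self.units[[POP_COLUMNS[a] for a in AGE_GROUPS]].copy()
        out.columns = list(AGE_GROUPS)
        out.index = pd.Index(self.fine_ids, name="unit_id")
        return out

    def distances(self) -> np.ndarray:
        """Symmetric fine-unit centroid distance matrix, km."""
        return squareform(pdist(self.centroids))

    def partition_codes(self, partition: str) -> tuple[list[str], np.ndarray]:
        """Group labels and per-fine-unit group indices for a partition.

        ``partition`` is a level name (L1..STATE) or one of the covariate
        stratifications ``"ses_decile"`` / ``"remoteness"``.
        """
        if partition == "L1":
            return self.fine_ids, np.arange(self.n_fine)
        if partition in _PARENT_COLS:
            col = self.units[_PARENT_COLS[partition]]
            labels = sorted(col.unique().tolist())
            lut = {k: i for i, k in enumerate(labels)}
            return labels, col.map(lut).to_numpy(int)
        if partition == "ses_decile":
            present = sorted(set(self.ses_decile.tolist()))
            labels = [f"ses_{d}" for d in present]
            lut = {d: i for i, d in enumerate(present)}
            return labels, np.array([lut[d] for d in self.ses_decile])
        if partition == "remoteness":
            codes = self.remoteness_codes
            present = sorted(set(codes.tolist()))
            labels = [f"rem_{REMOTENESS_CATEGORIES[c]}" for c in present]
            lut = {c: i for i, c in enumerate(present)}
            return labels, np.array([lut[c] for c in codes])
        raise ValueError(f"unknown partition {partition!r}")


@dataclass
class AggregationMatrix:
    """0/1 matrix mapping fine-unit vectors to partition totals.

    Rows are target-partition units (``row_labels``), columns fine units in
    the hierarchy's fixed ordering; each column carries exactly one 1.
    """

    matrix: sparse.csr_matrix
    row_labels: list[str]
    target_label: str
    unassigned: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def apply(self, v: np.ndarray) -> np.ndarray:
        """Aggregate a fine-unit vector (or columns of a matrix)."""
        v = np.asarray(v)
        out = self.matrix @ v
        return np.asarray(out)


def build_hierarchy(area_records: pd.DataFrame) -> Hierarchy:
    """Validate fine-unit records and freeze them into a :class:`Hierarchy`.

    Records must carry every column of the hierarchy CSV schema.  Fine units
    are ordered lexicographically by ``unit_id``; that ordering is the
    contract for every downstream vector and matrix.
    """
    if len(area_records) == 0:
        raise ValueError("area_records is empty")
    missing = [c for c in _CSV_COLUMNS if c not in area_records.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df = area_records[_CSV_COLUMNS].copy()

    dup = df["unit_id"][df["unit_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate unit_id: {dup.iloc[0]!r}")
    for level, col in _PARENT_COLS.items():
        if df[col].isna().any() or (df[col].astype(str) == "").any():
            raise ValueError(f"missing parent id in column {col!r} ({level})")

    ses = df["ses_decile"].to_numpy()
    if not np.issubdtype(np.asarray(ses).dtype, np.integer):
        if not np.all(ses == np.asarray(ses, dtype=int)):
            raise ValueError("ses_decile must be integer")
        ses = np.asarray(ses, dtype=int)
    if ses.min() < 1 or ses.max() > 10:
        raise ValueError("ses_decile out of range 1..10")
    bad = set(df["remoteness"]) - set(REMOTENESS_CATEGORIES)
    if bad:
        raise ValueError(f"unknown remoteness categories: {sorted(bad)}")
    for col in POP_COLUMNS.values():
        if (df[col].to_numpy() < 0).any():
            raise ValueError(f"negative population in {col}")

    # nesting must be a partition at every level: each child id maps to one parent
    chain = ["unit_id", "l2_id", "l3_id", "l4_id", "state_id"]
    for child, parent in zip(chain[:-1], chain[1:]):
        n_parents = df.groupby(child)[parent].nunique()
        if (n_parents > 1).any():
            bad_id = n_parents[n_parents > 1].index[0]
            raise ValueError(
                f"{child} {bad_id!r} has multiple parents at {parent}"
            )

    df = df.sort_values("unit_id", kind="stable").reset_index(drop=True)
    return Hierarchy(units=df)


def aggregation_matrix(h: Hierarchy, partition: str) -> AggregationMatrix:
    """Aggregation operator from fine units to a coarser partition.

    ``partition`` names a coarser level or a covariate stratification; the
    returned matrix times a fine count vector yields partition totals.
    """
    labels, codes = h.partition_codes(partition)
    n = h.n_fine
    m = sparse.csr_matrix(
        (np.ones(n), (codes, np.arange(n))), shape=(len(labels), n)
    )
    return AggregationMatrix(matrix=m, row_labels=labels, target_label=partition)


def correspondence_map(
    h: Hierarchy,
    external_partition: pd.DataFrame,
    allow_unmapped: bool = False,
) -> AggregationMatrix:
    """Aggregation operator to an external, non-nested partition.

    ``external_partition`` has columns ``fine_id`` and ``external_id`` (a
    correspondence table, e.g. fine statistical units to local government
    areas).  Unmapped fine units are only tolerated when ``allow_unmapped``
    and are collected into an explicit ``"unassigned"`` row.
    """
    ext = external_partition[["fine_id", "external_id"]].copy()
    if ext["fine_id"].duplicated().any():
        dup = ext["fine_id"][ext["fine_id"].duplicated()].iloc[0]
        raise ValueError(f"fine_id mapped more than once: {dup!r}")
    known = set(h.fine_ids)
    unknown = set(ext["fine_id"]) - known
    if unknown:
        raise ValueError(f"fine_id not in hierarchy: {sorted(unknown)[:5]}")

    lut = dict(zip(ext["fine_id"], ext["external_id"]))
    unmapped = np.array(
        [i for i, u in enumerate(h.fine_ids) if u not in lut], dtype=int
    )
    if unmapped.size and not allow_unmapped:
        raise ValueError(
            f"{unmapped.size} fine units unmapped; pass allow_unmapped=True"
        )
    labels = sorted({str(v) for v in ext["external_id"]})
    if unmapped.size:
        labels = labels + ["unassigned"]
    lab_ix = {k: i for i, k in enumerate(labels)}
    codes = np.array(
        [
            lab_ix[str(lut[u])] if u in lut else lab_ix["unassigned"]
            for u in h.fine_ids
        ]
    )
    m = sparse.csr_matrix(
        (np.ones(h.n_fine), (codes, np.arange(h.n_fine))),
        shape=(len(labels), h.n_fine),
    )
    return AggregationMatrix(
        matrix=m, row_labels=labels, target_label="external", unassigned=unmapped
    )


def write_hierarchy_csv(h: Hierarchy, path) -> None:
    h.units.to_csv(path, index=False)


def read_hierarchy_csv(path, geojson_path=None) -> Hierarchy:
    """Read the hierarchy CSV; centroids may come from a GeoJSON sidecar.

    When the centroid columns are absent (or empty) and ``geojson_path`` is
    given, centroids are computed from each feature's geometry.
    """
    df = pd.read_csv(path)
    need_centroids = (
        "centroid_x_km" not in df.columns or "centroid_y_km" not in df.columns
    )
    if need_centroids:
        if geojson_path is None:
            raise ValueError("no centroid columns and no GeoJSON supplied")
        cent = read_geojson_centroids(geojson_path)
        df["centroid_x_km"] = [cent[u][0] for u in df["unit_id"]]
        df["centroid_y_km"] = [cent[u][1] for u in df["unit_id"]]
    return build_hierarchy(df)


def read_geojson_centroids(path) -> dict[str, tuple[float, float]]:
    """unit_id -> geometry centroid (x, y) from a GeoJSON FeatureCollection."""
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    out = {}
    for feat in gj["features"]:
        uid = feat["properties"]["unit_id"]
        c = shape(feat["geometry"]).centroid
        out[uid] = (c.x, c.y)
    return out
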