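"""Synthetic census ground truth, publication, and register emulation.

No unit-level extract of a real census health item, hospital register or
community register is redistributable, so every downstream stage of the
pipeline is exercised against a synthetic population with the same
structure: a nested areal hierarchy with socioeconomic-decile and
remoteness labels, a latent prevalence surface drawn from the generative
mirror of the smoothing model, three published response categories
(positive / negative / not stated), noise-injected and suppressed tables at
every level and margin, and two register feeds (a near-complete
hospital-style register at the L3 level, and a censored-and-rounded
community register on an external non-nested partition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .hierarchy import (
    AGE_GROUPS,
    POP_COLUMNS,
    REMOTENESS_CATEGORIES,
    AggregationMatrix,
    Hierarchy,
    aggregation_matrix,
    build_hierarchy,
    correspondence_map,
)
from .model import gp_covariance
from .perturbation import PerturbConfig, perturb_count, ndss_censor_round, SUPPRESSED

__all__ = [
    "SimConfig",
    "RegisterConfig",
    "TrueCensus",
    "simulate_truth",
    "publish_tables",
    "emulate_registers",
    "make_lga_map",
    "PUBLISH_PARTITIONS",
    "CATEGORIES",
]

#: Partitions at which tables are published: every areal level plus the two
#: covariate margins.
PUBLISH_PARTITIONS = ("L1", "L2", "L3", "L4", "STATE", "ses_decile", "remoteness")

#: Published response categories of the binary-plus-not-stated health item.
CATEGORIES = ("positive", "negative", "not_stated")


@dataclass
class SimConfig:
    """Generative settings for the synthetic census.

    The spatial domain is a square of side ``domain_size_km`` with fine-unit
    centroids uniform on it; nesting is built by recursive spatial splits so
    coarser units are contiguous.  Intercepts are on the logit scale and the
    defaults put prevalence near 1.8 per 1000 (young) and 5.2 per 1000
    (old), the scale typical of juvenile diabetes.  ``mix_w`` is the
    logit-scale mixture weight tying the middle age group to the young
    model.
    """

    n_fine: int = 400
    n_per_l2: int = 4  # fine units per L2
    n_per_l3: int = 5  # L2 units per L3
    n_per_l4: int = 5  # L3 units per L4
    domain_size_km: float = 500.0
    pop_range: tuple[int, int] = (30, 120)  # per fine unit per age group
    beta0_young: float = -6.319  # logit(0.0018)
    beta0_old: float = -5.254  # logit(0.0052)
    beta_ses: float = -0.05  # per decile, disadvantage raises risk
    remoteness_effects: tuple[float, ...] = (-0.2, -0.1, 0.0, 0.1, 0.2)
    field_sd: float = 0.3
    field_range_km: float = 50.0
    mix_w: float = 0.9
    response_rate_range: tuple[float, float] = (0.88, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        g = np.asarray(self.remoteness_effects, dtype=float)
        if g.size != len(REMOTENESS_CATEGORIES):
            raise ValueError("remoteness_effects must have 5 entries")
        if abs(g.sum()) > 1e-9:
            raise ValueError("remoteness_effects must sum to zero")
        if self.field_sd < 0 or self.field_range_km <= 0:
            raise ValueError("field_sd must be >= 0 and field_range_km > 0")
        if not (0.0 < self.mix_w <= 1.0):
            raise ValueError("mix_w must be in (0, 1]")
        lo, hi = self.response_rate_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("response_rate_range must lie in (0, 1]")
        n_l2, r2 = divmod(self.n_fine, self.n_per_l2)
        n_l3, r3 = divmod(n_l2, self.n_per_l3)
        n_l4, r4 = divmod(n_l3, self.n_per_l4)
        if r2 or r3 or r4 or n_l4 < 1:
            raise ValueError(
                "n_fine must divide evenly through n_per_l2/n_per_l3/n_per_l4"
            )


@dataclass
class RegisterConfig:
    """Register emulation settings.

    capture_hospital emulates a near-complete clinic register (ages 0-9 and
    10-14 at L3); capture_community a voluntary register (ages 0-9 and
    10-19) reported on an external partition after censor/round disclosure
    control.
    """

    capture_hospital: float = 0.999
    capture_community: float = 0.85
    lga_map: pd.DataFrame | None = None  # columns fine_id, external_id
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.capture_hospital, self.capture_community):
            if not (0.0 < p <= 1.0):
                raise ValueError("capture probabilities must be in (0, 1]")


@dataclass
class TrueCensus:
    """Latent ground truth per fine unit and age group.

    ``counts`` is long format (unit_id, age_group, N, n_stated, y, p) in
    hierarchy fine order x AGE_GROUPS order; ``u`` the realised spatial
    field per fine unit.
    """

    counts: pd.DataFrame
    u: np.ndarray

    def _pivot(self, col: str) -> np.ndarray:
        wide = self.counts.pivot(index="unit_id", columns="age_group", values=col)
        return wide[list(AGE_GROUPS)].sort_index().to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self._pivot("y").astype(np.int64)

    @property
    def n_stated(self) -> np.ndarray:
        return self._pivot("n_stated").astype(np.int64)

    @property
    def population(self) -> np.ndarray:
        return self._pivot("N").astype(np.int64)

    @property
    def prevalence(self) -> np.ndarray:
        return self._pivot("p")

    def to_csv(self, path) -> None:
        df = self.counts.copy()
        df["u"] = np.repeat(self.u, len(AGE_GROUPS))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrueCensus":
        df = pd.read_csv(path)
        u = df.drop_duplicates("unit_id").sort_values("unit_id")["u"].to_numpy()
        return cls(counts=df.drop(columns=["u"]), u=u)


def _spatial_split(order: np.ndarray, xy: np.ndarray, n_groups: int, axis: int):
    """Split an index set into n_groups contiguous chunks along one axis."""
    srt = order[np.argsort(xy[order, axis], kind="stable")]
    return np.array_split(srt, n_groups)


def simulate_truth(cfg: SimConfig) -> tuple[Hierarchy, TrueCensus]:
    """Draw a hierarchy and a complete latent truth from the generative model.

    Centroids are uniform on the square; nesting is spatially contiguous
    (recursive axis splits); socioeconomic deciles and remoteness are
    assigned block-wise by L3 unit (deciles jittered +/-1 per fine unit);
    the field u is a draw from the exponential-covariance Gaussian process;
    counts follow the binomial layers of the model.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_fine
    n_l2 = n // cfg.n_per_l2
    n_l3 = n_l2 // cfg.n_per_l3
    n_l4 = n_l3 // cfg.n_per_l4

    xy = rng.uniform(0.0, cfg.domain_size_km, size=(n, 2))

    unit_ids = np.array([f"U{i:04d}" for i in range(n)])
    l2_of = np.empty(n, dtype=object)
    l3_of = np.empty(n, dtype=object)
    l4_of = np.empty(n, dtype=object)
    i2 = i3 = 0
    for i4, l4_members in enumerate(_spatial_split(np.arange(n), xy, n_l4, 0)):
        l4_of[l4_members] = f"L4_{i4:02d}"
        for l3_members in _spatial_split(l4_members, xy, cfg.n_per_l4, 1):
            l3_of[l3_members] = f"L3_{i3:03d}"
            i3 += 1
            for l2_members in _spatial_split(l3_members, xy, cfg.n_per_l3, 0):
                l2_of[l2_members] = f"L2_{i2:04d}"
                i2 += 1

    # block-wise covariates: one base value per L3 unit.  Remoteness grows
    # with distance from the "urban" corner of the domain, with block counts
    # allocated 40/25/20/10/5% by largest remainder so every category that
    # fits is represented (as in national data, where no remoteness class
    # is empty)
    ses = np.empty(n, dtype=int)
    rem = np.empty(n, dtype=object)
    l3_labels = pd.unique(l3_of)
    block_dist = np.array(
        [np.linalg.norm(xy[l3_of == l3].mean(axis=0)) for l3 in l3_labels]
    )
    shares = np.array([0.40, 0.25, 0.20, 0.10, 0.05])
    alloc = np.floor(shares * n_l3).astype(int)
    if n_l3 >= len(shares):
        alloc = np.maximum(alloc, 1)
    rema = shares * n_l3 - np.floor(shares * n_l3)
    for k in np.argsort(rema)[::-1]:
        if alloc.sum() >= n_l3:
            break
        alloc[k] += 1
    while alloc.sum() > n_l3:
        alloc[int(np.argmax(alloc))] -= 1
    block_cat = np.repeat(np.arange(5), alloc)[np.argsort(np.argsort(block_dist))]
    for l3, cat in zip(l3_labels, block_cat):
        members = np.flatnonzero(l3_of == l3)
        base = int(rng.integers(1, 11))
        ses[members] = np.clip(base + rng.integers(-1, 2, size=members.size), 1, 10)
        rem[members] = REMOTENESS_CATEGORIES[int(cat)]

    pops = {
        col: rng.integers(cfg.pop_range[0], cfg.pop_range[1] + 1, size=n)
        for col in POP_COLUMNS.values()
    }
    records = pd.DataFrame(
        {
            "unit_id": unit_ids,
            "l2_id": l2_of,
            "l3_id": l3_of,
            "l4_id": l4_of,
            "state_id": "STATE0",
            "ses_decile": ses,
            "remoteness": rem,
            "centroid_x_km": xy[:, 0],
            "centroid_y_km": xy[:, 1],
            **pops,
        }
    )
    h = build_hierarchy(records)

    # draws below follow hierarchy fine order (== construction order here,
    # since unit ids are zero-padded ascending)
    if cfg.field_sd > 0:
        cov = gp_covariance(h.distances(), cfg.field_sd, cfg.field_range_km)
        u = np.linalg.cholesky(cov) @ rng.standard_normal(n)
    else:
        u = np.zeros(n)

    gamma = np.asarray(cfg.remoteness_effects, dtype=float)
    base = cfg.beta_ses * (h.ses_decile - 5.5) + gamma[h.remoteness_codes] + u
    eta_young = cfg.beta0_young + base
    eta_old = cfg.beta0_old + base
    eta_mid = cfg.mix_w * eta_young + (1.0 - cfg.mix_w) * eta_old
    p = np.column_stack([expit(eta_young), expit(eta_mid), expit(eta_old)])

    pop = h.populations().to_numpy()
    rate = rng.uniform(*cfg.response_rate_range, size=n)
    n_stated = rng.binomial(pop, rate[:, None])
    y = rng.binomial(n_stated, p)

    counts = pd.DataFrame(
        {
            "unit_id": np.repeat(h.fine_ids, len(AGE_GROUPS)),
            "age_group": np.tile(AGE_GROUPS, n),
            "N": pop.ravel(),
            "n_stated": n_stated.ravel(),
            "y": y.ravel(),
            "p": p.ravel(),
        }
    )
    return h, TrueCensus(counts=counts, u=u)


def true_aggregates(
    h: Hierarchy, t: TrueCensus, partition: str
) -> tuple[AggregationMatrix, dict[str, np.ndarray]]:
    """Pre-perturbation category aggregates at one partition."""
    agg = aggregation_matrix(h, partition)
    y = t.y
    n_stated = t.n_stated
    pop = t.population
    return agg, {
        "positive": agg.apply(y),
        "negative": agg.apply(n_stated - y),
        "not_stated": agg.apply(pop - n_stated),
    }


def publish_tables(
    h: Hierarchy, t: TrueCensus, pcfg: PerturbConfig, seed: int
) -> pd.DataFrame:
    """Publish every level and margin through the privacy mechanism.

    Each (partition, unit, age group, category) cell is perturbed
    independently.  ``suppressed_flag`` marks cells published as zero whose
    true count was positive — a generator-side diagnostic that a real
    extract would not reveal.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for partition in PUBLISH_PARTITIONS:
        agg, cats = true_aggregates(h, t, partition)
        for ai, age in enumerate(AGE_GROUPS):
            for cat in CATEGORIES:
                truth = cats[cat][:, ai].astype(int)
                for label, ytrue in zip(agg.row_labels, truth):
                    o = perturb_count(int(ytrue), pcfg, rng)
                    rows.append(
                        (partition, label, age, cat, o, o == 0 and ytrue > 0)
                    )
    return pd.DataFrame(
        rows,
        columns=["level", "unit_id", "age_group", "category", "count",
                 "suppressed_flag"],
    )


def make_lga_map(h: Hierarchy, n_lga: int = 25) -> pd.DataFrame:
    """A synthetic external partition not nested in the areal hierarchy.

    Fine units are grouped into contiguous bands by centroid y-coordinate
    (the hierarchy's own splits start along x), so external-unit boundaries
    cut across L2/L3 boundaries the way local government areas cut across
    statistical areas.
    """
    order = np.argsort(h.centroids[:, 1], kind="stable")
    chunks = np.array_split(order, n_lga)
    fine = np.asarray(h.fine_ids)
    rows = []
    for k, chunk in enumerate(chunks):
        for i in chunk:
            rows.append((fine[i], f"LGA_{k:03d}"))
    return pd.DataFrame(rows, columns=["fine_id", "external_id"])


def emulate_registers(
    h: Hierarchy, t: TrueCensus, register_cfg: RegisterConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulate the two comparison registers from the latent truth.

    Returns (hospital_table, community_table).  The hospital-style table is
    binomial thinning of true case counts per L3 unit for ages 0-9 and
    10-14.  The community-style table thins, aggregates to the external
    partition for ages 0-9 and 10-19, then censors counts below 20 and
    rounds to the nearest ten.
    """
    rng = np.random.default_rng(register_cfg.seed)
    y = t.y

    agg3 = aggregation_matrix(h, "L3")
    y3 = agg3.apply(y).astype(int)
    hosp_rows = []
    for ai, age in enumerate(("0-9", "10-14")):
        thinned = rng.binomial(y3[:, ai], register_cfg.capture_hospital)
        for label, c in zip(agg3.row_labels, thinned):
            hosp_rows.append((label, age, int(c)))
    hospital = pd.DataFrame(hosp_rows, columns=["unit_id", "age_group", "count"])

    lga_map = register_cfg.lga_map
    if lga_map is None:
        lga_map = make_lga_map(h)
    cmat = correspondence_map(h, lga_map)
    thinned = rng.binomial(y, register_cfg.capture_community)
    agg_counts = cmat.apply(thinned).astype(int)
    comm_rows = []
    groups = {"0-9": [0], "10-19": [1, 2]}
    for age, cols in groups.items():
        totals = agg_counts[:, cols].sum(axis=1)
        for label, c in zip(cmat.row_labels, totals):
            rep = ndss_censor_round(int(c))
            if rep is SUPPRESSED:
                comm_rows.append((label, age, 0, True))
            else:
                comm_rows.append((label, age, int(rep), False))
    community = pd.DataFrame(
        comm_rows, columns=["unit_id", "age_group", "count", "suppressed"]
    )
    return hospital, community


def write_tables_csv(tables: pd.DataFrame, path) -> None:
    tables.to_csv(path, index=False)


def read_tables_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
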