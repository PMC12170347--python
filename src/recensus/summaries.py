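"""Posterior products: prevalence summaries, register comparisons, ratios.

Turns posterior draws of latent fine-unit counts into the reporting
artefacts of a small-area prevalence study: per-unit prevalence summaries
with a confidence classification (higher confidence when the posterior
standard deviation is under 25% of the median), a national median/IQR
across units, coarse-level posterior count intervals, credible-interval
outlier tests against register tables, and simple labelled-count ratio
statistics.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .hierarchy import AGE_GROUPS, AggregationMatrix
from .mcmc import PosteriorSamples

__all__ = [
    "AGE_PRODUCTS",
    "prevalence_summary",
    "model_prevalence_draws",
    "national_summary",
    "aggregate_posterior",
    "compare_register",
    "ratio_statistics",
    "pearson_correlation",
    "write_geojson_summary",
    "load_state_age_counts",
    "load_wa_age_counts",
]


def _data_path(name: str):
    from importlib.resources import files

    return files("recensus.data").joinpath(name)


def load_state_age_counts() -> pd.DataFrame:
    """State/territory diabetes counts: census extract vs community register.

    One row per state x age group (0-9, 10-19) with the published census
    total and the community-register map total; a missing register value is
    a censored report.
    """
    with _data_path("state_age_counts.csv").open() as fh:
        return pd.read_csv(fh)


def load_wa_age_counts() -> pd.DataFrame:
    """Western-Australia counts by source (census, hospital register,
    community register) and age group."""
    with _data_path("wa_age_counts.csv").open() as fh:
        return pd.read_csv(fh)

#: Reporting age products: the two youngest groups are mapped together.
AGE_PRODUCTS = {"0-14": ("0-9", "10-14"), "15-19": ("15-19",)}

#: Posterior sd under this fraction of the median marks higher confidence.
CONFIDENCE_SD_FRACTION = 0.25


def _age_columns(age_groups, members) -> list[int]:
    return [age_groups.index(a) for a in members]


def _quantiles(draws: np.ndarray, qs) -> np.ndarray:
    # linear interpolation of order statistics, applied over the draw axis
    return np.quantile(draws, qs, axis=0, method="linear")


def model_prevalence_draws(samples: PosteriorSamples, hierarchy) -> np.ndarray:
    """Per-draw model prevalence expit(eta), shape (draws, n_fine, 3).

    Rebuilds the linear predictor from the stored scalar and field draws
    and the hierarchy covariates; the middle age group is the logit-scale
    mixture of the young and old predictors.
    """
    from scipy.special import expit

    dec55 = hierarchy.ses_decile - 5.5
    rem = hierarchy.remoteness_codes
    c, d, n = samples.u.shape
    u = samples.u.reshape(c * d, n)
    sc = {k: samples.stacked_scalar(k)[:, None] for k in samples.scalars}
    gamma = np.stack(
        [samples.stacked_scalar(f"gamma{i}") for i in range(1, 6)], axis=1
    )  # (D, 5)
    base = sc["beta_ses"] * dec55[None, :] + gamma[:, rem] + u
    ey = sc["beta0_young"] + base
    eo = sc["beta0_old"] + base
    em = sc["w"] * ey + (1.0 - sc["w"]) * eo
    return expit(np.stack([ey, em, eo], axis=2))


def prevalence_summary(
    samples: PosteriorSamples,
    denominators: np.ndarray | None = None,
    age_grouping: dict[str, tuple[str, ...]] | None = None,
    kind: str = "count",
    hierarchy=None,
) -> pd.DataFrame:
    """Per-unit, per-age-product posterior prevalence summaries.

    With ``kind="count"`` the per-draw prevalence is (grouped case count) /
    (grouped stated denominator) — the realised proportion among the latent
    counts.  With ``kind="model"`` it is the model prevalence expit(eta)
    averaged over the grouped ages with stated-denominator weights (needs
    ``hierarchy`` for the covariates); this is the smooth surface used for
    maps and national headline figures, where realised count ratios are
    degenerate at small-area scale.  Summaries are empirical moments and
    quantiles over all pooled draws.  Units with a zero grouped denominator
    are flagged and excluded from national summaries.
    """
    if samples.n_draws == 0:
        raise ValueError("samples are empty")
    age_grouping = age_grouping or AGE_PRODUCTS
    n_stated = (
        np.asarray(denominators) if denominators is not None else samples.n_stated
    )
    if kind == "count":
        src = samples.stacked_y()  # (D, n, ages)
    elif kind == "model":
        if hierarchy is None:
            raise ValueError('kind="model" needs the hierarchy')
        p_draws = model_prevalence_draws(samples, hierarchy)
    else:
        raise ValueError("kind must be 'count' or 'model'")
    rows = []
    ages = list(samples.age_groups)
    for product, members in age_grouping.items():
        cols = _age_columns(ages, members)
        den = n_stated[:, cols].sum(axis=1)  # (n,)
        flagged = den == 0
        ok = ~flagged
        if kind == "count":
            num = src[:, :, cols].sum(axis=2)  # (D, n)
            prev = np.zeros_like(num, dtype=float)
            prev[:, ok] = num[:, ok] / den[ok]
        else:
            wts = n_stated[:, cols] / np.maximum(den, 1)[:, None]  # (n, k)
            prev = (p_draws[:, :, cols] * wts[None, :, :]).sum(axis=2)
            prev[:, ~ok] = 0.0
        med, q025, q975 = _quantiles(prev, [0.5, 0.025, 0.975])
        mean = prev.mean(axis=0)
        sd = prev.std(axis=0)
        confident = sd < CONFIDENCE_SD_FRACTION * med
        for i, uid in enumerate(samples.fine_ids):
            rows.append(
                (
                    uid,
                    product,
                    mean[i],
                    med[i],
                    sd[i],
                    q025[i],
                    q975[i],
                    "higher" if confident[i] else "lower",
                    bool(flagged[i]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "unit_id",
            "age_product",
            "mean",
            "median",
            "sd",
            "q2.5",
            "q97.5",
            "confidence_class",
            "flagged",
        ],
    )


def national_summary(ps: pd.DataFrame, age_product: str | None = None) -> dict:
    """Median and IQR of per-unit posterior median prevalence, per 1000.

    Summarises across unflagged fine units (optionally one age product);
    quantiles use linear interpolation.
    """
    sub = ps[~ps["flagged"]]
    if age_product is not None:
        sub = sub[sub["age_product"] == age_product]
    if sub.empty:
        raise ValueError("no unflagged units to summarise")
    med = sub["median"].to_numpy() * 1000.0
    return {
        "median_per_1000": float(np.median(med)),
        "iqr_per_1000": (
            float(np.quantile(med, 0.25)),
            float(np.quantile(med, 0.75)),
        ),
        "n_units": int(len(med)),
    }


def aggregate_posterior(
    samples: PosteriorSamples,
    agg: AggregationMatrix,
    ages: tuple[str, ...] = AGE_GROUPS,
) -> pd.DataFrame:
    """Posterior median and 95% CrI of coarse-level counts.

    Counts are aggregated exactly per draw; display medians are rounded to
    integers and the interval reported as [floor(q2.5), ceil(q97.5)].
    """
    if agg.shape[1] != len(samples.fine_ids):
        raise ValueError("aggregation matrix does not match sample fine units")
    y = samples.stacked_y()
    cols = _age_columns(list(samples.age_groups), ages)
    fine = y[:, :, cols].sum(axis=2)  # (D, n)
    coarse = np.stack([agg.apply(v) for v in fine])  # (D, G)
    med, lo, hi = _quantiles(coarse, [0.5, 0.025, 0.975])
    return pd.DataFrame(
        {
            "unit_id": agg.row_labels,
            "post_median": np.round(med).astype(int),
            "cri_lo": np.floor(lo).astype(int),
            "cri_hi": np.ceil(hi).astype(int),
        }
    )


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.corrcoef(a, b)[0, 1])


def compare_register(
    agg_summary: pd.DataFrame,
    register: pd.DataFrame,
    raw_counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Credible-interval outlier test of posterior counts against a register.

    ``register`` has columns unit_id, count and optionally suppressed; an
    outlier is a non-suppressed register count outside the unit's 95% CrI.
    Pearson correlation over non-suppressed units is attached as a frame
    attribute ``correlation`` (NaN when fewer than 3 usable units), plus
    ``correlation_raw`` against optional raw published counts (columns
    unit_id, count).
    """
    reg = register.copy()
    if "suppressed" not in reg.columns:
        reg["suppressed"] = False
    merged = agg_summary.merge(reg[["unit_id", "count", "suppressed"]], on="unit_id")
    merged = merged.rename(columns={"count": "register"})
    merged["outlier"] = ~merged["suppressed"] & (
        (merged["register"] < merged["cri_lo"])
        | (merged["register"] > merged["cri_hi"])
    )
    ok = ~merged["suppressed"]
    if ok.sum() >= 3:
        corr = pearson_correlation(
            merged.loc[ok, "register"], merged.loc[ok, "post_median"]
        )
    else:
        corr = float("nan")
    merged.attrs["correlation"] = corr
    if raw_counts is not None:
        raw = merged.merge(
            raw_counts.rename(columns={"count": "raw"}), on="unit_id", how="left"
        )
        ok2 = ok.to_numpy() & raw["raw"].notna().to_numpy()
        merged.attrs["correlation_raw"] = (
            pearson_correlation(raw.loc[ok2, "register"], raw.loc[ok2, "raw"])
            if ok2.sum() >= 3
            else float("nan")
        )
    return merged


def ratio_statistics(
    table_a: pd.Series,
    table_b: pd.Series,
    exclusions: set[str] | None = None,
    ndigits: int | None = None,
) -> float:
    """100 x (sum of a) / (sum of b) over shared, non-excluded labels.

    Both tables are label -> count; labels present in only one table or in
    ``exclusions`` are dropped.  Missing (NaN) counts drop the label too.
    Rounding to the reported precision is caller-specified via ndigits.
    """
    exclusions = exclusions or set()
    shared = [
        k
        for k in table_a.index
        if k in table_b.index and k not in exclusions
        and pd.notna(table_a[k]) and pd.notna(table_b[k])
    ]
    if not shared:
        raise ValueError("no shared labels after exclusions")
    denom = float(table_b[shared].sum())
    if denom == 0:
        raise ValueError("denominator table sums to zero")
    value = 100.0 * float(table_a[shared].sum()) / denom
    return round(value, ndigits) if ndigits is not None else value


def write_geojson_summary(
    geojson_path, summary: pd.DataFrame, out_path, age_product: str = "0-14"
) -> None:
    """Join per-unit summary properties onto a GeoJSON FeatureCollection."""
    with open(geojson_path) as fh:
        gj = json.load(fh)
    sub = summary[summary["age_product"] == age_product].set_index("unit_id")
    for feat in gj["features"]:
        uid = feat["properties"]["unit_id"]
        if uid in sub.index:
            row = sub.loc[uid]
            feat["properties"].update(
                {
                    "mean_prevalence": float(row["mean"]),
                    "median_prevalence": float(row["median"]),
                    "sd": float(row["sd"]),
                    "confidence_class": row["confidence_class"],
                }
            )
    with open(out_path, "w") as fh:
        json.dump(gj, fh)
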