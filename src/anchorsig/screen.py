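"""Anchor-gene correlation screening and differential expression.

The screen computes, within the tumor group, the Pearson correlation of every
probe against a fixed anchor probe, together with the tumor/control ratio of
mean log2 expression (T/C) and a one-tailed two-sample t-test, then partitions
probes into an up-correlated list (up-regulated and r >= r_up) and a
down-correlated list (down-regulated and r <= r_down).  The canonical
thresholds are r_up = 0.6 (broad list) or 0.72 (stringent list) and
r_down = -0.6.

T/C is deliberately the ratio of group means of *log2* values — the
convention of the microarray tables this reproduces — not a linear-scale fold
change; typical values are 1.05–1.7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ExpressionCohort, ProbeAnnotation

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "probe_id",
    "gene_symbol",
    "r",
    "n_pairs",
    "tc_ratio",
    "p_value",
    "direction",
    "categories",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and conventions of one screening run."""

    anchor_probe: str
    r_up: float = 0.6
    r_down: float = -0.6
    p_max: float = 0.05
    direction_rule: str = "tc_and_p"  # or "tc_only"
    gene_level: bool = False
    test_variant: str = "pooled"  # or "welch"

    def __post_init__(self) -> None:
        if not (-1 < self.r_down < self.r_up < 1):
            raise ValueError(
                f"need -1 < r_down < r_up < 1, got r_down={self.r_down}, r_up={self.r_up}"
            )
        if self.direction_rule not in ("tc_and_p", "tc_only"):
            raise ValueError(f"unknown direction_rule {self.direction_rule!r}")
        if self.test_variant not in ("pooled", "welch"):
            raise ValueError(f"unknown test_variant {self.test_variant!r}")


@dataclass
class ScreenResult:
    """Ranked screen output: full records plus the two threshold partitions."""

    records: pd.DataFrame
    up_correlated: pd.DataFrame
    down_correlated: pd.DataFrame
    config: ScreenConfig
    n_undefined: int = 0


# ---------------------------------------------------------------------------
# Correlation profile
# ---------------------------------------------------------------------------


def pearson_profile(
    cohort: ExpressionCohort, anchor_probe: str, group_samples: Sequence[str]
) -> pd.DataFrame:
    """Pearson r of every probe against the anchor within one sample group.

    Uses pairwise-complete observations.  Probes with zero variance or fewer
    than 3 complete pairs get r = NaN and are excluded downstream (count
    logged).  A zero-variance anchor is a hard error: the screen would be
    meaningless.
    """
    if len(group_samples) < 3:
        raise ValueError("need at least 3 samples to correlate")
    sub = cohort.subset_samples(list(group_samples))
    a = sub.probe_values(anchor_probe)
    V = sub.values

    finite_a = np.isfinite(a)
    a_all = a[finite_a]
    if a_all.size < 3 or np.allclose(a_all, a_all[0]):
        raise ValueError(f"anchor probe {anchor_probe!r} has zero variance in group")

    W = np.isfinite(V) & finite_a[None, :]
    n = W.sum(axis=1).astype(float)
    Vz = np.where(W, np.nan_to_num(V), 0.0)
    az = np.where(finite_a, a, 0.0)

    sx = Vz.sum(axis=1)
    sa = W @ az
    sxx = (Vz * Vz).sum(axis=1)
    saa = W @ (az * az)
    sxa = Vz @ az

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxa - sx * sa / n
        var_x = sxx - sx * sx / n
        var_a = saa - sa * sa / n
        denom = np.sqrt(var_x * var_a)
        r = np.where((denom > 0) & (n >= 3), cov / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)

    n_undefined = int(np.isnan(r).sum())
    if n_undefined:
        logger.warning(
            "pearson_profile: %d probes undefined (zero variance or <3 pairs)", n_undefined
        )
    return pd.DataFrame({"probe_id": sub.probe_ids, "r": r, "n_pairs": n.astype(int)})


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def differential_expression(
    cohort: ExpressionCohort,
    tumor_samples: Sequence[str],
    control_samples: Sequence[str],
    test_variant: str = "pooled",
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Per-probe T/C ratio, one-tailed t-test p, and regulation direction.

    ``tc_ratio`` is mean(tumor log2) / mean(control log2).  The one-tailed p
    reports significance of the *observed* direction (half the two-sided p; a
    zero t-statistic yields 0.5).  Direction is up if tc_ratio > 1 and
    p <= p_max, down if tc_ratio < 1 and p <= p_max, else flat.
    """
    if len(tumor_samples) < 2 or len(control_samples) < 2:
        raise ValueError("need at least 2 samples per group")
    t_vals = cohort.subset_samples(list(tumor_samples)).values
    c_vals = cohort.subset_samples(list(control_samples)).values

    with np.errstate(invalid="ignore"):
        t_mean = np.nanmean(t_vals, axis=1)
        c_mean = np.nanmean(c_vals, axis=1)
    bad = np.where(c_mean <= 0)[0]
    if bad.size:
        raise ValueError(
            f"control mean <= 0 for probe {cohort.probe_ids[bad[0]]!r}: "
            "log2 intensities must be positive for a meaningful T/C ratio"
        )
    tc = t_mean / c_mean

    res = stats.ttest_ind(
        t_vals,
        c_vals,
        axis=1,
        equal_var=(test_variant == "pooled"),
        nan_policy="omit",
    )
    p_two = np.asarray(res.pvalue, dtype=float)
    p_one = p_two / 2.0  # alternative follows the observed sign; t=0 -> 0.5

    direction = np.full(len(tc), "flat", dtype=object)
    ok = np.isfinite(p_one)
    direction[(tc > 1) & ok & (p_one <= p_max)] = "up"
    direction[(tc < 1) & ok & (p_one <= p_max)] = "down"

    return pd.DataFrame(
        {
            "probe_id": cohort.probe_ids,
            "tc_ratio": tc,
            "p_value": p_one,
            "direction": direction,
        }
    )


# ---------------------------------------------------------------------------
# Screen assembly and thresholding
# ---------------------------------------------------------------------------


def _sort_ranked(df: pd.DataFrame, ascending_r: bool = False) -> pd.DataFrame:
    """Deterministic ranking: r desc (or asc), ties by p asc then probe id."""
    return df.sort_values(
        ["r", "p_value", "probe_id"], ascending=[ascending_r, True, True]
    ).reset_index(drop=True)


def _collapse_gene_level(df: pd.DataFrame) -> pd.DataFrame:
    """Keep, per gene symbol, the probe of maximal |r| (ties: p asc, probe id)."""
    if df.empty:
        return df
    d = df.copy()
    d["_absr"] = d["r"].abs()
    d = d.sort_values(["_absr", "p_value", "probe_id"], ascending=[False, True, True])
    d = d.drop_duplicates(subset="gene_symbol", keep="first").drop(columns="_absr")
    return d


def apply_thresholds(
    records: pd.DataFrame, config: ScreenConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition screen records into up- and down-correlated lists.

    Up: direction == "up" (per the direction rule) and r >= r_up.
    Down: direction == "down" and r <= r_down.  Records with undefined r or
    fewer than 3 pairs never qualify.
    """
    rec = records.copy()
    valid = rec["r"].notna()
    if "n_pairs" in rec.columns:
        valid &= rec["n_pairs"] >= 3
    if config.direction_rule == "tc_and_p":
        up_dir = rec["direction"] == "up"
        down_dir = rec["direction"] == "down"
    else:  # tc_only
        up_dir = rec["tc_ratio"] > 1
        down_dir = rec["tc_ratio"] < 1
    up = rec[valid & up_dir & (rec["r"] >= config.r_up)]
    down = rec[valid & down_dir & (rec["r"] <= config.r_down)]
    if config.gene_level and "gene_symbol" in rec.columns:
        up = _collapse_gene_level(up)
        down = _collapse_gene_level(down)
    return _sort_ranked(up), _sort_ranked(down, ascending_r=True)


def run_screen(
    cohort: ExpressionCohort,
    groups: Mapping[str, Sequence[str]],
    config: ScreenConfig,
    annotation: Mapping[str, ProbeAnnotation] | None = None,
) -> ScreenResult:
    """Full anchor screen: correlation profile + differential expression + thresholds.

    Correlations are computed within the tumor group; T/C and the t-test
    contrast tumors against controls.
    """
    prof = pearson_profile(cohort, config.anchor_probe, groups["tumor"])
    de = differential_expression(
        cohort, groups["tumor"], groups["control"], config.test_variant, config.p_max
    )
    records = prof.merge(de, on="probe_id")
    if annotation:
        records["gene_symbol"] = [
            annotation[p].gene_symbol if p in annotation else p for p in records["probe_id"]
        ]
        records["categories"] = [
            ";".join(sorted(annotation[p].categories)) if p in annotation else ""
            for p in records["probe_id"]
        ]
    else:
        records["gene_symbol"] = records["probe_id"]
        records["categories"] = ""
    records = records[RECORD_COLUMNS]
    up, down = apply_thresholds(records, config)
    return ScreenResult(
        records=_sort_ranked(records),
        up_correlated=up,
        down_correlated=down,
        config=config,
        n_undefined=int(records["r"].isna().sum()),
    )


# ---------------------------------------------------------------------------
# Group contrast, ratio concordance, ranked tables
# ---------------------------------------------------------------------------


def correlation_group_contrast(
    cohort: ExpressionCohort,
    anchor_probe: str,
    tumor_samples: Sequence[str],
    control_samples: Sequence[str],
    probe_list: Sequence[str],
) -> pd.DataFrame:
    """Paired anchor correlations (r_tumor, r_control) per probe, unthresholded.

    The bar-plot-style export contrasting in-tumor against in-control
    co-expression of the anchor's partners.
    """
    if not probe_list:
        raise ValueError("probe_list must be non-empty")
    rt = pearson_profile(cohort, anchor_probe, tumor_samples).set_index("probe_id")
    rc = pearson_profile(cohort, anchor_probe, control_samples).set_index("probe_id")
    out = pd.DataFrame(
        {
            "probe_id": list(probe_list),
            "r_tumor": [rt.loc[p, "r"] for p in probe_list],
            "r_control": [rc.loc[p, "r"] for p in probe_list],
        }
    )
    return out


def ratio_concordance(
    ratios_a: Mapping[str, float] | pd.Series,
    ratios_b: Mapping[str, float] | pd.Series,
    gene_intersection: Sequence[str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of two per-gene ratio vectors over shared genes.

    Used to compare the tumor/control expression ratio of one cohort with a
    condition ratio from another (e.g. low/normal oxygen culture).  Returns
    the correlation and the scatter table (gene, ratio_a, ratio_b).
    """
    sa = pd.Series(ratios_a, dtype=float)
    sb = pd.Series(ratios_b, dtype=float)
    shared = [g for g in sa.index if g in sb.index]
    if gene_intersection is not None:
        wanted = set(gene_intersection)
        shared = [g for g in shared if g in wanted]
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared genes, got {len(shared)}")
    x = sa.loc[shared].to_numpy()
    y = sb.loc[shared].to_numpy()
    r = float(stats.pearsonr(x, y).statistic)
    scatter = pd.DataFrame({"gene": shared, "ratio_a": x, "ratio_b": y})
    return r, scatter


def build_ranked_table(
    records: pd.DataFrame,
    annotation: Mapping[str, ProbeAnnotation] | None = None,
    restrict_to: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Render screen records in the standard ranked-table layout.

    Columns: gene title, symbol, probe, r, GO definition, T/C, p.  With
    ``restrict_to`` (a gene list, e.g. a pathway), rows are filtered to those
    genes with no r-threshold applied; genes absent from the records are
    returned in the ``missing`` sidecar rather than raising.
    """
    rec = records.copy()
    if annotation:
        rec["gene_symbol"] = [
            annotation[p].gene_symbol if p in annotation else rec_sym
            for p, rec_sym in zip(rec["probe_id"], rec.get("gene_symbol", rec["probe_id"]))
        ]
        titles = {p: (a.gene_title or "") for p, a in annotation.items()}
        cats = {p: ";".join(sorted(a.categories)) for p, a in annotation.items()}
        rec["gene_title"] = [titles.get(p, "") for p in rec["probe_id"]]
        rec["go_definition"] = [cats.get(p, "") for p in rec["probe_id"]]
    else:
        if "gene_title" not in rec.columns:
            rec["gene_title"] = ""
        if "go_definition" not in rec.columns:
            rec["go_definition"] = rec.get("categories", "")

    missing: list[str] = []
    if restrict_to is not None and len(restrict_to) > 0:
        present = set(rec["gene_symbol"])
        missing = [g for g in restrict_to if g not in present]
        rec = rec[rec["gene_symbol"].isin(set(restrict_to))]

    table = _sort_ranked(rec)[
        ["gene_title", "gene_symbol", "probe_id", "r", "go_definition", "tc_ratio", "p_value"]
    ].rename(
        columns={
            "gene_symbol": "symbol",
            "probe_id": "probe",
            "tc_ratio": "tc",
            "p_value": "p",
        }
    )
    return table.reset_index(drop=True), missing
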