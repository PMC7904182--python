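"""Supplementary-workbook loader and printed-value reproduction.

The quantitative data behind the published figures is distributed as an
Excel workbook (one sheet per figure panel). This module loads it
defensively — sheet names are mapped to figure keys through a shipped,
editable pattern file, unmapped sheets are preserved raw with a warning —
normalizes each mapped sheet to a tidy long table, and recomputes the
printed summary quantities from it: the log-log Pearson correlation between
integrated Ca2+ and PS signals, windowed integral ratios between
genotypes, grouped necrotic-cell counts, normalized PS ratios, the
live-cell PS-positive percentage, and the ER-store-deficient peak cap.

Expected tidy schemas per figure key (column names are matched after
lower-casing and replacing spaces with underscores):

================  =======================================================
key               required columns
================  =======================================================
``fig2e``         ``embryo, ca_integral, ps_integral`` (one row per
                  time point; values may be cumulative-to-date or
                  per-interval increments — both readings are computed)
``s1figd``        ``genotype, cell_id, time_min, ca_r`` (per-cell traces)
``fig3c``         ``dose, count`` (per animal)
``fig5c/fig5f``   ``condition, rps`` (per necrotic cell)
``fig6c``         ``condition, rps``
``fig7c``         ``condition, rps`` (per living cell)
``fig9b``         ``condition, rps``
``s3figc``        ``genotype, cell_id, time_min, ca_r``
``s3figab``       ``cell_id, time_min, ca_r`` (capped *crt-1* traces)
================  =======================================================
"""

from __future__ import annotations

import json
import re
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as _cohort
from .events import FULL_WINDOW, PERIOD1, PERIOD2, IntensityTrace, integrate_trace

__all__ = ["load_supplementary", "reproduce_paper", "PRINTED_VALUES", "MissingWorkbookError"]


class MissingWorkbookError(FileNotFoundError):
    """Raised when the supplementary workbook is not on disk."""


#: Published summary values the reproduction report compares against.
#: ``cmp`` is "eq" (match to printed precision / relative tolerance) or
#: "le" (printed value is an upper bound, e.g. "less than 25%").
PRINTED_VALUES: dict[str, dict] = {
    "fig2e_pearson_r": {"value": 0.96, "cmp": "eq", "rel_tol": 0.05},
    "wt_ca_integral_pct_period1": {"value": 52.6, "cmp": "eq", "rel_tol": 0.05},
    "wt_ca_integral_pct_period2": {"value": 30.7, "cmp": "eq", "rel_tol": 0.05},
    "wt_ca_integral_pct_overall": {"value": 40.4, "cmp": "eq", "rel_tol": 0.05},
    "fig3c_untreated_necrotic_plm_mean": {"value": 1.7, "cmp": "eq", "decimals": 1},
    "unc8_crt1_normalized_ps_pct": {"value": 29.0, "cmp": "eq", "rel_tol": 0.05},
    "deg1_crt1_normalized_ps_pct": {"value": 10.0, "cmp": "le"},
    "anoh1_thapsigargin_ps_pct": {"value": 32.7, "cmp": "eq", "rel_tol": 0.05},
    "trp4_anoh1_ps_pct": {"value": 49.0, "cmp": "eq", "rel_tol": 0.05},
    "unc51_live_ps_pct": {"value": 27.4, "cmp": "eq", "rel_tol": 0.05},
    "crt1_peak_cap_fold": {"value": 1.2, "cmp": "le"},
    "crt1_ca_integral_pct_overall": {"value": 25.0, "cmp": "le"},
    "crt1_ca_integral_pct_period1": {"value": 35.0, "cmp": "le"},
    "crt1_ca_integral_pct_period2": {"value": 30.0, "cmp": "le"},
}


def _load_sheet_map() -> dict[str, list[str]]:
    text = resources.files("necroquant.data").joinpath("sheet_map.json").read_text()
    return json.loads(text)["patterns"]


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.columns = [re.sub(r"\s+", "_", str(c).strip().lower()) for c in df.columns]
    return df


def load_supplementary(path) -> dict[str, pd.DataFrame]:
    """Load the supplementary workbook into tidy tables keyed by figure.

    Unrecognized sheets are preserved raw under ``raw:<sheet name>`` with a
    warning; a malformed sheet warns and is skipped rather than aborting
    the whole load.
    """
    path = Path(path)
    if not path.exists():
        raise MissingWorkbookError(
            f"supplementary workbook not found at {path}; download the S1 Data "
            "workbook (pgen.1009066.s005.xlsx) from the article's supporting "
            "information and pass its path"
        )
    patterns = _load_sheet_map()
    try:
        book = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    except Exception as exc:  # malformed container is fatal; sheets are not
        raise ValueError(f"could not parse workbook {path}: {exc}") from exc
    tables: dict[str, pd.DataFrame] = {}
    for sheet_name, df in book.items():
        key = None
        for fig_key, pats in patterns.items():
            if any(re.search(p, sheet_name, flags=re.IGNORECASE) for p in pats):
                key = fig_key
                break
        try:
            tidy = _normalize_columns(df).dropna(how="all")
        except Exception as exc:
            warnings.warn(f"sheet {sheet_name!r} is malformed and was skipped: {exc}")
            continue
        if key is None:
            warnings.warn(f"sheet {sheet_name!r} matches no known figure; kept raw")
            tables[f"raw:{sheet_name}"] = tidy
        elif key in tables:
            warnings.warn(f"multiple sheets map to {key!r}; keeping the first")
        else:
            tables[key] = tidy
    return tables


def _trace_integrals(df: pd.DataFrame, window) -> pd.DataFrame:
    """Per-cell windowed integrals from a tidy trace table."""
    rows = []
    group_cols = [c for c in ("genotype", "condition") if c in df] + ["cell_id"]
    for keys, sub in df.groupby(group_cols, sort=False):
        sub = sub.sort_values("time_min")
        trace = IntensityTrace(sub["time_min"].to_numpy(), sub["ca_r"].to_numpy())
        value = integrate_trace(trace, window, require_qualified=False)
        rec = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        rec["integral"] = value
        rows.append(rec)
    return pd.DataFrame(rows)


def _integral_pct(trace_table: pd.DataFrame, test: str, reference: str, window) -> float:
    integ = _trace_integrals(trace_table, window)
    label_col = "genotype" if "genotype" in integ else "condition"
    t = integ.loc[integ[label_col] == test, "integral"].to_numpy()
    r = integ.loc[integ[label_col] == reference, "integral"].to_numpy()
    from .events import integral_ratio

    return integral_ratio(t, r).percent


def _fig2e_r(df: pd.DataFrame) -> dict[str, float]:
    """Pearson r of the log-log integral regression, under both readings of
    the stored values (cumulative-to-date vs per-interval increments)."""
    out = {}
    x = df["ca_integral"].to_numpy(float)
    y = df["ps_integral"].to_numpy(float)
    keep = (x > 0) & (y > 0)
    out["cumulative"] = _cohort.log_integral_regression(x[keep], y[keep]).r
    xs, ys = [], []
    for _, sub in df.groupby("embryo", sort=False):
        dx = np.diff(np.concatenate([[0.0], sub["ca_integral"].to_numpy(float)]))
        dy = np.diff(np.concatenate([[0.0], sub["ps_integral"].to_numpy(float)]))
        xs.append(dx)
        ys.append(dy)
    dx = np.concatenate(xs)
    dy = np.concatenate(ys)
    keep = (dx > 0) & (dy > 0)
    if keep.sum() >= 3:
        out["increments"] = _cohort.log_integral_regression(dx[keep], dy[keep]).r
    return out


def _normalized_pct(df: pd.DataFrame, test: str, reference: str) -> float:
    _, summary = _cohort.normalize_to_reference(df, reference=reference)
    row = summary.loc[summary["condition"] == test]
    if row.empty:
        raise ValueError(f"condition {test!r} missing from sheet")
    return 100.0 * float(row["mean"].iloc[0])


def reproduce_paper(workbook_path, ps_threshold: float = 1.5) -> pd.DataFrame:
    """Recompute the printed summary values from the supplementary workbook.

    Returns a report with one row per quantity: the recomputed value, the
    printed value, the comparison rule, and whether they agree (within 5%
    relative for recomputed ratios, to printed rounding for means, or as a
    bound for quantities the text states as "less than"). Quantities whose
    sheet is absent are reported with status ``missing-sheet``.
    """
    tables = load_supplementary(workbook_path)
    computed: dict[str, float] = {}
    notes: dict[str, str] = {}

    if "fig2e" in tables:
        both = _fig2e_r(tables["fig2e"])
        best = max(both, key=lambda k: both[k])
        computed["fig2e_pearson_r"] = both[best]
        notes["fig2e_pearson_r"] = (
            f"reading={best}; " + ", ".join(f"{k}: r={v:.4f}" for k, v in both.items())
        )
    if "s1figd" in tables:
        for key, window in (
            ("wt_ca_integral_pct_period1", PERIOD1),
            ("wt_ca_integral_pct_period2", PERIOD2),
            ("wt_ca_integral_pct_overall", FULL_WINDOW),
        ):
            computed[key] = _integral_pct(tables["s1figd"], "mec-4(+)", "mec-4(e1611)", window)
    if "fig3c" in tables:
        df = tables["fig3c"]
        untreated = df.loc[df["dose"] == 0, "count"].to_numpy()
        computed["fig3c_untreated_necrotic_plm_mean"] = _cohort.grouped_count_summary(
            untreated, group_size=10, max_per_animal=2
        ).mean
    if "fig5f" in tables:
        computed["unc8_crt1_normalized_ps_pct"] = _normalized_pct(
            tables["fig5f"], "unc-8(n491); crt-1(bz29)", "unc-8(n491)"
        )
    if "fig5c" in tables:
        computed["deg1_crt1_normalized_ps_pct"] = _normalized_pct(
            tables["fig5c"], "deg-1(u38); crt-1(bz29)", "deg-1(u38)"
        )
    if "fig6c" in tables:
        computed["anoh1_thapsigargin_ps_pct"] = _normalized_pct(
            tables["fig6c"], "anoh-1(tm4762)+TG6", "wild-type+TG6"
        )
    if "fig9b" in tables:
        computed["trp4_anoh1_ps_pct"] = _normalized_pct(
            tables["fig9b"], "trp-4(ot337); anoh-1(tm4762)", "trp-4(ot337)"
        )
    if "fig7c" in tables:
        df = tables["fig7c"]
        live = df.loc[
            df["condition"] == "ced-1(e1735); unc-51(e369); mec-4(e1611)", "rps"
        ].to_numpy()
        computed["unc51_live_ps_pct"] = _cohort.ps_positive_fraction(live, ps_threshold).percent
        sens = {
            thr: _cohort.ps_positive_fraction(live, thr).percent
            for thr in (1.2, 1.5, 2.0)
        }
        notes["unc51_live_ps_pct"] = "threshold sensitivity: " + ", ".join(
            f">{t:g}: {p:.1f}%" for t, p in sens.items()
        )
    if "s3figab" in tables:
        computed["crt1_peak_cap_fold"] = float(tables["s3figab"]["ca_r"].max())
    if "s3figc" in tables:
        for key, window in (
            ("crt1_ca_integral_pct_overall", FULL_WINDOW),
            ("crt1_ca_integral_pct_period1", PERIOD1),
            ("crt1_ca_integral_pct_period2", PERIOD2),
        ):
            computed[key] = _integral_pct(
                tables["s3figc"], "crt-1(bz29); mec-4(e1611)", "mec-4(e1611)", window
            )

    rows = []
    for key, spec in PRINTED_VALUES.items():
        printed = spec["value"]
        if key not in computed:
            rows.append(
                {"quantity": key, "computed": np.nan, "printed": printed,
                 "cmp": spec["cmp"], "agrees": False, "status": "missing-sheet", "note": ""}
            )
            continue
        value = computed[key]
        if spec["cmp"] == "le":
            agrees = value <= printed
        elif "decimals" in spec:
            agrees = round(value, spec["decimals"]) == printed
        else:
            agrees = abs(value - printed) <= spec["rel_tol"] * abs(printed)
        rows.append(
            {"quantity": key, "computed": value, "printed": printed, "cmp": spec["cmp"],
             "agrees": bool(agrees), "status": "computed", "note": notes.get(key, "")}
        )
    return pd.DataFrame(rows)
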