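"""Cohort statistics: improvement rates, paired tests, feature selection.

The improvement rate (IR) of any quantity is the fractional reduction from
its baseline value, ``IR = (pre − post)/pre`` for clinical scores and
``IR = (off − on)/off`` for EMG features, so that improvement is positive.
With this convention sample entropy — which *rises* when stimulation
de-regularises the pathological tremor pattern — takes negative IRs.

Paired DBS-off/on comparisons use two-sided paired t-tests without
multiple-comparison correction (a Benjamini–Hochberg option exists behind a
flag, default off). Inter-feature structure and feature–outcome association
use Spearman rank correlation at the same uncorrected alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st

from .features import FEATURE_NAMES
from .io import Condition, PatientRecord

__all__ = [
    "improvement_rate",
    "build_ir_table",
    "paired_change_table",
    "spearman_cocorrelation",
    "select_predictive_features",
    "CLINICAL_IR_COLUMNS",
]

CLINICAL_IR_COLUMNS = ["IR_UPDRS_III", "IR_UPDRS_t"]


def improvement_rate(pre: float, post: float) -> float:
    """Fractional improvement (pre − post)/pre; requires pre > 0.

    1 means complete resolution, 0 no change; negative values mean
    worsening (or, for features like sample entropy, an increase).
    """
    pre = float(pre)
    post = float(post)
    if not pre > 0:
        raise ValueError(f"improvement rate needs pre > 0, got {pre}")
    return (pre - post) / pre


def build_ir_table(
    feature_table: pd.DataFrame,
    patients: "list[PatientRecord] | pd.DataFrame | None" = None,
) -> pd.DataFrame:
    """Per-patient IR of every feature and of the clinical scales.

    ``feature_table`` is the tidy output of
    :func:`~tremormark.features.cohort_feature_table` (one row per
    patient × condition). Clinical scores come either from ``patients`` or
    from score columns already present in ``feature_table``. Feature IRs are
    ``(off − on)/off``; NaN where the off value is not positive or either
    side is missing.
    """
    off = feature_table[feature_table["condition"] == Condition.DBS_OFF.value]
    on = feature_table[feature_table["condition"] == Condition.DBS_ON.value]
    off = off.set_index("patient_id")
    on = on.set_index("patient_id")
    common = off.index.intersection(on.index).sort_values()

    rows = {}
    for name in FEATURE_NAMES:
        o = off.loc[common, name].astype(float)
        n = on.loc[common, name].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ir = (o - n) / o
        ir[o <= 0] = np.nan
        rows[f"IR_{name}"] = ir
    out = pd.DataFrame(rows, index=common)

    scores = _collect_scores(feature_table, patients)
    if scores is not None:
        scores = scores.loc[scores.index.intersection(common)]
        out["IR_UPDRS_III"] = [
            improvement_rate(r.UPDRS_III_pre, r.UPDRS_III_post)
            for r in scores.loc[common].itertuples()
        ]
        out["IR_UPDRS_t"] = [
            improvement_rate(r.UPDRS_t_pre, r.UPDRS_t_post)
            for r in scores.loc[common].itertuples()
        ]
    out.index.name = "patient_id"
    return out


def paired_change_table(
    feature_table: pd.DataFrame,
    patients: "list[PatientRecord] | pd.DataFrame | None" = None,
    correction: "str | None" = None,
) -> pd.DataFrame:
    """Off/on means, SDs, IRs and paired-t p per feature (plus clinical rows).

    One row per feature, plus ``UPDRS_III`` and ``UPDRS_t`` rows when scores
    are available. Pairs with a missing value on either side are dropped per
    feature. Zero-variance differences give ``p = 1`` with a ``degenerate``
    flag. ``correction="bh"`` adds a Benjamini–Hochberg adjusted column
    (default: none, mirroring an uncorrected alpha).
    """
    off = feature_table[
        feature_table["condition"] == Condition.DBS_OFF.value
    ].set_index("patient_id")
    on = feature_table[
        feature_table["condition"] == Condition.DBS_ON.value
    ].set_index("patient_id")
    common = off.index.intersection(on.index).sort_values()
    if len(common) < 2:
        raise ValueError("paired comparison needs >= 2 patients with both conditions")

    rows = []
    for name in FEATURE_NAMES:
        o = off.loc[common, name].astype(float).to_numpy()
        n = on.loc[common, name].astype(float).to_numpy()
        rows.append(_paired_row(name, o, n, ir=_feature_ir(o, n)))

    scores = _collect_scores(feature_table, patients)
    if scores is not None:
        scores = scores.loc[common]
        for label, pre_col, post_col in (
            ("UPDRS_III", "UPDRS_III_pre", "UPDRS_III_post"),
            ("UPDRS_t", "UPDRS_t_pre", "UPDRS_t_post"),
        ):
            pre = scores[pre_col].to_numpy(float)
            post = scores[post_col].to_numpy(float)
            rows.append(_paired_row(label, pre, post, ir=(pre - post) / pre))

    table = pd.DataFrame(rows).set_index("name")
    if correction == "bh":
        table["p_bh"] = _benjamini_hochberg(table["p"].to_numpy())
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return table


def _paired_row(name: str, off: np.ndarray, on: np.ndarray, ir: np.ndarray) -> dict:
    ok = np.isfinite(off) & np.isfinite(on)
    o, n = off[ok], on[ok]
    degenerate = False
    if o.size < 2:
        t_stat, p = np.nan, np.nan
        degenerate = True
    elif np.allclose(o - n, (o - n)[0]):
        # zero-variance differences: the t statistic is undefined
        t_stat, p = (0.0, 1.0) if np.allclose(o, n) else (np.nan, 1.0)
        degenerate = True
    else:
        t_stat, p = st.ttest_rel(o, n)
    ir = np.asarray(ir, dtype=float)[ok]
    ir_ok = ir[np.isfinite(ir)]
    return {
        "name": name,
        "off_mean": float(np.mean(o)) if o.size else np.nan,
        "off_sd": float(np.std(o, ddof=1)) if o.size > 1 else np.nan,
        "on_mean": float(np.mean(n)) if n.size else np.nan,
        "on_sd": float(np.std(n, ddof=1)) if n.size > 1 else np.nan,
        "ir_mean": float(np.mean(ir_ok)) if ir_ok.size else np.nan,
        "ir_sd": float(np.std(ir_ok, ddof=1)) if ir_ok.size > 1 else np.nan,
        "n_pairs": int(o.size),
        "t": float(t_stat),
        "p": float(p),
        "degenerate": degenerate,
    }


def _feature_ir(off: np.ndarray, on: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ir = (off - on) / off
    ir = np.where(off > 0, ir, np.nan)
    return ir


def spearman_cocorrelation(
    ir_table: pd.DataFrame,
    columns: "list[str] | None" = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Feature-to-feature Spearman co-correlation of per-patient IRs.

    Returns ``(R, P, R_thresholded)`` DataFrames; the thresholded map zeroes
    entries with ``p >= alpha`` (diagonal kept at 1). Zero-variance columns
    are excluded with a warning.
    """
    import warnings

    cols = columns or [c for c in ir_table.columns if c.startswith("IR_") and c not in CLINICAL_IR_COLUMNS]
    data = ir_table[cols].dropna()
    if len(data) < 3:
        raise ValueError("co-correlation needs >= 3 complete patients")
    keep = [c for c in cols if data[c].nunique() > 1]
    dropped = sorted(set(cols) - set(keep))
    if dropped:
        warnings.warn(f"excluding zero-variance columns {dropped}", stacklevel=2)
    rho, p = st.spearmanr(data[keep].to_numpy())
    if np.ndim(rho) == 0:  # scipy collapses the two-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    np.fill_diagonal(p, 0.0)
    r_df = pd.DataFrame(rho, index=keep, columns=keep)
    p_df = pd.DataFrame(p, index=keep, columns=keep)
    thresholded = r_df.where(p_df < alpha, 0.0)
    return r_df, p_df, thresholded


def select_predictive_features(
    ir_table: pd.DataFrame,
    alpha: float = 0.05,
    min_complete_fraction: float = 0.8,
) -> pd.DataFrame:
    """Features whose IR tracks the clinical tremor-scale IR.

    Spearman-correlates each feature's per-patient IR against
    ``IR_UPDRS_t`` and returns the features with ``p < alpha`` sorted by
    |R| descending (columns: feature, R, p, n). Features observed in fewer
    than ``min_complete_fraction`` of the cohort (e.g. a tremor peak
    undetectable in most DBS-on recordings) are not selectable, so the
    downstream complete-case prediction model keeps its sample size.
    """
    if "IR_UPDRS_t" not in ir_table.columns:
        raise ValueError("ir_table lacks IR_UPDRS_t")
    y = ir_table["IR_UPDRS_t"]
    if y.dropna().nunique() <= 1:
        raise ValueError("IR_UPDRS_t is constant; selection impossible")
    n_total = int(y.notna().sum())
    min_n = max(3, int(np.ceil(min_complete_fraction * n_total)))
    rows = []
    for name in FEATURE_NAMES:
        col = f"IR_{name}"
        if col not in ir_table.columns:
            continue
        pair = ir_table[[col, "IR_UPDRS_t"]].dropna()
        if len(pair) < min_n or pair[col].nunique() <= 1:
            continue
        r, p = st.spearmanr(pair[col], pair["IR_UPDRS_t"])
        rows.append({"feature": name, "R": float(r), "p": float(p), "n": len(pair)})
    result = pd.DataFrame(rows, columns=["feature", "R", "p", "n"])
    selected = result[result["p"] < alpha]
    return selected.reindex(
        selected["R"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)


def _collect_scores(
    feature_table: pd.DataFrame,
    patients: "list[PatientRecord] | pd.DataFrame | None",
) -> "pd.DataFrame | None":
    score_cols = ["UPDRS_III_pre", "UPDRS_III_post", "UPDRS_t_pre", "UPDRS_t_post"]
    if patients is None:
        if set(score_cols) <= set(feature_table.columns):
            return (
                feature_table.drop_duplicates("patient_id")
                .set_index("patient_id")[score_cols]
            )
        return None
    if isinstance(patients, pd.DataFrame):
        return patients.set_index("patient_id")[score_cols] if "patient_id" in patients.columns else patients[score_cols]
    rows = {
        p.patient_id: {
            "UPDRS_III_pre": p.updrs_iii_pre,
            "UPDRS_III_post": p.updrs_iii_post,
            "UPDRS_t_pre": p.updrs_t_pre,
            "UPDRS_t_post": p.updrs_t_post,
        }
        for p in patients
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
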