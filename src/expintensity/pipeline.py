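"""End-to-end evaluation of the scoring algorithm on monitoring data.

Strings together the downstream analyses run against a monitoring data
set: stratified concentration summaries, the two-way log-scale ANOVA, the
score/concentration/model-prediction correlation matrix, the
multiplicative regression fit, and the score-category summary with its
trend test.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .eq1 import fit_eq1, predict_eq1
from .io import write_table
from .records import MonitoringRecord
from .stats import (
    monitoring_frame,
    spearman_rho,
    summarize_groups,
    trend_test,
    two_way_anova_log,
)
from .weights import (
    UnassignedWeightError,
    category_labels,
    categorize_score,
    intensity_score,
    load_weight_table,
)


def _summary_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stratum": " / ".join(str(s) for s in row.stratum),
                "N": row.n,
                "AM": round(row.am, 2),
                "GM": round(row.gm, 2),
                "GSD": round(row.gsd, 2),
            }
            for row in summaries
        ]
    )


def evaluate_monitoring(
    records: Iterable[MonitoringRecord],
    versions: Sequence[str] = ("v1", "v2"),
    cutpoints: Sequence[float] = (50.0, 100.0),
    outdir: Optional[Path] = None,
    metadata: Optional[dict] = None,
    method_coded_one=frozenset({"hand_spray"}),
) -> dict:
    """Run the full evaluation; optionally write result tables to ``outdir``.

    Returns a dict with keys ``summary`` (method x glove GroupSummary
    frame), ``anova`` (AnovaResult), ``correlations`` (Spearman matrix
    over scores, concentration and model predictions), ``fit``
    (ModelFit), ``fit_table``, ``category_summary`` and ``trend`` (z, p).
    """
    records = list(records)
    if not records:
        raise ValueError("no monitoring records to evaluate")
    tables = {v: load_weight_table(v) for v in versions}
    df = monitoring_frame(records, method_coded_one)

    # scores per version; a version that cannot score a method (unassigned
    # weight) reports NaN for that record rather than aborting the run
    score_cols = {}
    for v, table in tables.items():
        scores = []
        for r in records:
            try:
                scores.append(intensity_score(r, table))
            except UnassignedWeightError:
                scores.append(float("nan"))
        score_cols[f"score_{v}"] = np.array(scores)

    summary = summarize_groups(df, ("method", "gloves"))
    anova = two_way_anova_log(df)

    fit = fit_eq1(records, method_coded_one)
    preds = np.array(
        [
            predict_eq1(fit, r, method_coded_one, allow_negative=True)
            for r in records
        ]
    )

    corr_cols = dict(score_cols)
    corr_cols["concentration"] = df["concentration"].to_numpy()
    corr_cols["predicted"] = preds
    names = list(corr_cols)
    corr = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            va, vb = corr_cols[a], corr_cols[b]
            ok = ~(np.isnan(va) | np.isnan(vb))
            corr.loc[a, b] = (
                spearman_rho(va[ok], vb[ok]) if ok.sum() >= 3 else float("nan")
            )

    # category summary on the last requested version (v2 by convention)
    cat_version = versions[-1]
    cat_scores = score_cols[f"score_{cat_version}"]
    labels = category_labels(cutpoints)
    cats = [categorize_score(s, cutpoints) for s in cat_scores]
    cat_df = df.assign(category=[labels[c] for c in cats], _cat=cats)
    cat_summary = summarize_groups(cat_df, ("category",))
    order = {labels[i]: i for i in range(len(labels))}
    cat_summary.sort(key=lambda row: order[row.stratum[0]])
    z, p_trend = trend_test(df["concentration"].to_numpy(), cats)

    fit_table = pd.DataFrame(
        [
            {
                "variable": name,
                "coefficient": (
                    "na" if fit.coefficient(name) is None
                    else round(fit.coefficient(name), 3)
                ),
                "p_value": (
                    "na" if name not in fit.p_values
                    else round(fit.p_values[name], 4)
                ),
            }
            for name in (
                "alpha0", "alpha1", "alpha2", "alpha3", "beta1", "beta2"
            )
        ]
    )

    results = {
        "summary": _summary_frame(summary),
        "anova": anova,
        "correlations": corr,
        "fit": fit,
        "fit_table": fit_table,
        "category_summary": _summary_frame(cat_summary),
        "trend": (z, p_trend),
        "scores": pd.DataFrame(
            {"id": df["id"], **score_cols, "concentration": df["concentration"]}
        ),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = dict(metadata or {})
        write_table(results["summary"], outdir / "summary_method_glove.csv", meta)
        write_table(
            results["category_summary"], outdir / "summary_category.csv", meta
        )
        write_table(
            results["correlations"].reset_index(names="variable"),
            outdir / "correlations.csv",
            meta,
        )
        write_table(
            pd.concat(
                [
                    fit_table,
                    pd.DataFrame(
                        [
                            {
                                "variable": "r_squared",
                                "coefficient": round(fit.r_squared, 4),
                                "p_value": "",
                            },
                            {
                                "variable": "converged",
                                "coefficient": fit.converged,
                                "p_value": "",
                            },
                        ]
                    ),
                ],
                ignore_index=True,
            ),
            outdir / "model_fit.csv",
            meta,
        )
        report = outdir / "report.txt"
        with open(report, "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            fh.write(
                "Two-way ANOVA on log concentration (main effects):\n"
                f"  CR glove use: F = {anova.f_glove:.3f}, "
                f"p = {anova.p_glove:.4g}\n"
                f"  Application method: F = {anova.f_method:.3f}, "
                f"p = {anova.p_method:.4g}\n"
                f"Trend across score categories ({cat_version}): "
                f"z = {z:.3f}, p = {p_trend:.4g}\n"
                f"Model fit R-squared = {fit.r_squared:.3f}, "
                f"n = {fit.n_used}\n"
            )
    return results
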