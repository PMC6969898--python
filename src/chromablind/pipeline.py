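"""End-to-end analysis of a study log against the three-feature model.

Glues the stages together the way the full experiment is analysed: per-pair
detection-time distributions and dominant modes, the critical time and the
easy/hard partition, observer screening and consistency, the regression fit
with repeated-split validation, and the two difficulty classifiers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import regression, study
from .config import RunConfig

__all__ = ["analyse_study", "report_to_json"]


def analyse_study(
    features: pd.DataFrame,
    records: pd.DataFrame,
    config: RunConfig | None = None,
    n_splits: int = 100,
) -> dict:
    """Run the full analysis pipeline.

    Parameters
    ----------
    features : DataFrame with ``pair_id, f_cm, f_si, f_ue``.
    records : study log DataFrame (one row per trial).
    config : pipeline settings; defaults to :class:`RunConfig` defaults.
    n_splits : number of random 70/30 splits for validation.

    Returns a dict holding the distribution summaries, screening tables,
    critical time, fitted results and evaluation/classification outputs.
    """
    config = config or RunConfig()
    dists = study.pair_distributions(
        records, grid_step=config.kde_grid_step, max_time=config.max_time
    )
    modes = {d.pair_id: d.mode_time for d in dists}
    t_crit, fallback = critical = study.critical_time(
        list(modes.values()), default=config.t_crit_default,
        grid_step=config.kde_grid_step, max_time=config.max_time,
    )
    labels = study.partition_by_time(modes, t_crit)

    screening = study.screen_observers(records)
    consistency = study.consistency_sign_test(records, modes)

    df = features.merge(
        pd.DataFrame({"pair_id": list(modes), "mode_time": list(modes.values())}),
        on="pair_id",
    )
    model = regression.DetectionTimeModel.from_dataframe(
        df, intercept=config.intercept
    )
    results = model.fit()
    X = df[regression.FEATURE_NAMES].to_numpy()
    y = df["mode_time"].to_numpy()
    cv = regression.cross_validate(
        X, y, n_splits=n_splits, train_frac=0.7, seed=config.seed,
        intercept=config.intercept,
    )
    label_arr = np.array([labels[p] for p in df["pair_id"]])
    classification = {}
    uniq, counts = np.unique(label_arr, return_counts=True)
    # QDA needs each training fold to hold more class members than features,
    # so skip classification when the minority class is very small
    if uniq.size == 2 and counts.min() >= 8:
        folds = int(min(10, counts.min()))
        for method in ("qda", "tree"):
            classification[method] = regression.classify_difficulty(
                X, label_arr, method=method, folds=folds, seed=config.seed
            )

    return {
        "config": config,
        "distributions": dists,
        "mode_times": modes,
        "t_crit": t_crit,
        "t_crit_fallback": fallback,
        "labels": labels,
        "screening": screening,
        "consistency": consistency,
        "fit": results,
        "cv": cv,
        "classification": classification,
        "pair_table": df,
    }


def report_to_json(report: dict) -> dict:
    """JSON-serialisable summary of :func:`analyse_study` output."""
    res = report["fit"]
    cfg: RunConfig = report["config"]
    out = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_pairs": int(len(report["pair_table"])),
        "coefficients": {
            "b1": res.params.b1, "b2": res.params.b2, "b3": res.params.b3,
        },
        "bse": [float(v) for v in res.bse],
        "t_crit_s": report["t_crit"],
        "t_crit_fallback": bool(report["t_crit_fallback"]),
        "n_outlier_observers": int(report["screening"]["outlier"].sum()),
        "cv": {
            "plcc": report["cv"].plcc,
            "srocc": report["cv"].srocc,
            "rmse_s": report["cv"].rmse_s,
            "n_splits": report["cv"].n_splits,
        },
    }
    if res.params.intercept is not None:
        out["coefficients"]["intercept"] = res.params.intercept
    for method, c in report["classification"].items():
        out[f"{method}_accuracy"] = c["accuracy"]
    return out
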