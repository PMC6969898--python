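"""Detection-time distribution analysis and observer screening.

A flicker trial ends when the observer clicks on the change or when the 60 s
limit is reached (a *censored* trial).  Per-pair detection times are
typically heavy-tailed — a minority of observers take far longer than most —
so the *dominant mode* of a kernel density estimate, not the mean, is used
as the pair's representative time.  Modes over the whole stimulus set fall
into two clusters (easy and hard pairs) separated by a density minimum, the
*critical time*.

Observers are screened on false-positive rate (clicks far from the changed
region) and non-detection rate; anyone above the population mean plus two
standard deviations on either rate is flagged as an outlier.  A per-observer
sign test against the per-pair modes identifies systematically fast or slow
observers.

Study logs are plain CSV with columns
``observer_id,pair_id,seq_index,time_s,click_x,click_y,detected,correct``.
Censored trials have ``detected = False`` and ``time_s = 60``; they are
excluded from the time distributions but counted in the screening rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import binomtest, norm

from .exceptions import InsufficientDataError

__all__ = [
    "DetectionDistribution",
    "silverman_bandwidth",
    "detection_density",
    "dominant_mode",
    "pair_distributions",
    "critical_time",
    "partition_by_time",
    "mark_correct",
    "screen_observers",
    "consistency_sign_test",
    "load_study_log",
    "save_study_log",
]

LOG_COLUMNS = [
    "observer_id", "pair_id", "seq_index", "time_s",
    "click_x", "click_y", "detected", "correct",
]

#: Minimum relative height for a local maximum to count as a significant peak.
SIGNIFICANT_PEAK_FRACTION = 0.05


@dataclass
class DetectionDistribution:
    """Summary of one pair's valid (non-censored) detection times."""

    pair_id: object
    valid_times: np.ndarray
    mean_time: float
    mode_time: float
    dominance_ratio: float
    bandwidth: float
    grid: np.ndarray = field(repr=False)
    density: np.ndarray = field(repr=False)


def silverman_bandwidth(times: np.ndarray) -> float:
    """Silverman's rule of thumb, robust variant.

    ``h = 0.9 * min(sd, IQR/1.34) * n^(-1/5)``; when the sample is (nearly)
    degenerate the non-zero branch of the two spreads is used, falling back
    to a fixed 0.5 s kernel if both vanish.
    """
    t = np.asarray(times, dtype=float)
    sd = t.std(ddof=1)
    iqr = np.subtract(*np.percentile(t, [75, 25])) / 1.34
    spreads = [s for s in (sd, iqr) if s > 0]
    if not spreads:
        return 0.5
    return 0.9 * min(spreads) * t.size ** (-0.2)


def _time_grid(grid_step: float = 0.1, max_time: float = 60.0) -> np.ndarray:
    return np.arange(0.0, max_time + grid_step / 2, grid_step)


def detection_density(
    times,
    grid_step: float = 0.1,
    max_time: float = 60.0,
    bandwidth: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian kernel density of detection times on a fixed grid.

    Returns ``(grid, density, bandwidth)``; the density integrates to ≈ 1
    over the grid (mass outside [0, max_time] is not re-normalised, matching
    an unbounded Gaussian KDE).
    """
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise InsufficientDataError(
            f"need at least 2 valid times for a density, got {t.size}"
        )
    h = silverman_bandwidth(t) if bandwidth is None else float(bandwidth)
    grid = _time_grid(grid_step, max_time)
    dens = norm.pdf((grid[:, None] - t[None, :]) / h).mean(axis=1) / h
    return grid, dens, h


def _significant_peaks(grid: np.ndarray, dens: np.ndarray) -> np.ndarray:
    """Indices of local maxima at least 5% as high as the global maximum."""
    peaks, _ = find_peaks(dens)
    # grid endpoints can carry the global maximum; include them if they are
    # one-sided maxima
    if dens.size >= 2 and dens[0] > dens[1]:
        peaks = np.concatenate([[0], peaks])
    if dens.size >= 2 and dens[-1] > dens[-2]:
        peaks = np.concatenate([peaks, [dens.size - 1]])
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dens))])
    return peaks[dens[peaks] >= SIGNIFICANT_PEAK_FRACTION * dens.max()]


def dominant_mode(
    times,
    grid_step: float = 0.1,
    max_time: float = 60.0,
) -> tuple[float, float]:
    """Location of the highest density peak and its dominance ratio.

    The ratio compares the global peak height with the next significant
    local maximum (``inf`` when the estimate is unimodal); ties in peak
    height are broken toward the smaller time.
    """
    grid, dens, _ = detection_density(times, grid_step, max_time)
    peaks = _significant_peaks(grid, dens)
    order = np.lexsort((grid[peaks], -dens[peaks]))  # height desc, time asc
    best = peaks[order[0]]
    mode_time = float(grid[best])
    if order.size == 1:
        return mode_time, float("inf")
    second = peaks[order[1]]
    return mode_time, float(dens[best] / dens[second])


def pair_distributions(
    records: pd.DataFrame,
    grid_step: float = 0.1,
    max_time: float = 60.0,
    min_valid: int = 2,
) -> list[DetectionDistribution]:
    """Per-pair distribution summaries from a study log.

    Only valid (detected) trials enter the distributions; pairs with fewer
    than ``min_valid`` of them are skipped with a warning.
    """
    out = []
    for pair_id, grp in records.groupby("pair_id", sort=True):
        t = grp.loc[grp["detected"].astype(bool), "time_s"].to_numpy(float)
        if t.size < min_valid:
            warnings.warn(f"pair {pair_id}: only {t.size} valid times, skipped")
            continue
        grid, dens, h = detection_density(t, grid_step, max_time)
        mode_time, ratio = dominant_mode(t, grid_step, max_time)
        out.append(
            DetectionDistribution(
                pair_id=pair_id, valid_times=t, mean_time=float(t.mean()),
                mode_time=mode_time, dominance_ratio=ratio, bandwidth=h,
                grid=grid, density=dens,
            )
        )
    return out


def critical_time(
    modes,
    default: float = 36.0,
    grid_step: float = 0.1,
    max_time: float = 60.0,
) -> tuple[float, bool]:
    """Easy/hard boundary: the density minimum between the two main clusters.

    A KDE of the per-pair mode times is scanned for its two highest
    significant peaks; the critical time is the grid location of the density
    minimum between them.  If the mode distribution is unimodal (or
    degenerate) the configured ``default`` is returned with the fallback
    flag set.

    Returns ``(t_crit, used_fallback)``.
    """
    m = np.asarray(modes, dtype=float)
    if m.size < 4:
        raise InsufficientDataError(
            f"need at least 4 pair modes for a critical time, got {m.size}"
        )
    if np.ptp(m) == 0:
        warnings.warn("all modes identical; falling back to default critical time")
        return float(default), True
    grid, dens, _ = detection_density(m, grid_step, max_time)
    peaks = _significant_peaks(grid, dens)
    if peaks.size < 2:
        warnings.warn("unimodal mode distribution; falling back to default")
        return float(default), True
    top = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = int(top.min()), int(top.max())
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(grid[valley]), False


def partition_by_time(modes: dict, t_crit: float) -> dict:
    """Label each pair C1 (mode below the critical time) or C2 (at/above)."""
    return {pid: ("C1" if t < t_crit else "C2") for pid, t in modes.items()}


def mark_correct(
    records: pd.DataFrame,
    change_masks: dict,
    dilation_radius: int = 20,
) -> pd.DataFrame:
    """Set the ``correct`` flag from click coordinates and change masks.

    A detected trial is correct when the click lands inside the change
    region dilated by ``dilation_radius`` pixels (clicks far from the region
    are false positives).  Censored trials are never correct.
    """
    from skimage.morphology import dilation, disk

    dilated = {
        pid: dilation(np.asarray(mask, bool), disk(dilation_radius))
        for pid, mask in change_masks.items()
    }
    rec = records.copy()
    correct = np.zeros(len(rec), dtype=bool)
    for i, row in enumerate(rec.itertuples(index=False)):
        if not row.detected or row.pair_id not in dilated:
            continue
        m = dilated[row.pair_id]
        x, y = row.click_x, row.click_y
        if np.isfinite(x) and np.isfinite(y):
            c, r = int(round(x)), int(round(y))
            if 0 <= r < m.shape[0] and 0 <= c < m.shape[1]:
                correct[i] = bool(m[r, c])
    rec["correct"] = correct
    return rec


def screen_observers(records: pd.DataFrame) -> pd.DataFrame:
    """Per-observer screening rates and outlier flags.

    False-positive rate = detected-but-incorrect trials / trials; the
    non-detection rate counts censored trials.  An observer is an outlier
    when either rate exceeds the population mean plus two standard
    deviations of that rate.  Observers with zero trials are excluded with
    a warning.
    """
    obs_ids = records["observer_id"].unique()
    if obs_ids.size < 3:
        raise InsufficientDataError("need at least 3 observers for screening")
    rows = []
    for oid, grp in records.groupby("observer_id", sort=True):
        n = len(grp)
        if n == 0:
            warnings.warn(f"observer {oid}: no trials, excluded")
            continue
        detected = grp["detected"].astype(bool)
        correct = grp["correct"].astype(bool)
        rows.append({
            "observer_id": oid,
            "n_trials": n,
            "false_positive_rate": float((detected & ~correct).sum() / n),
            "non_detection_rate": float((~detected).sum() / n),
        })
    stats = pd.DataFrame(rows)
    for col in ("false_positive_rate", "non_detection_rate"):
        thresh = stats[col].mean() + 2 * stats[col].std(ddof=1)
        stats[f"{col}_outlier"] = stats[col] > thresh
    stats["outlier"] = (
        stats["false_positive_rate_outlier"] | stats["non_detection_rate_outlier"]
    )
    return stats


def consistency_sign_test(
    records: pd.DataFrame,
    mode_times: dict,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Sign test of each observer's times against the per-pair modes.

    For every observer, valid trials on pairs with a defined mode contribute
    the sign of ``time - mode``; ties are dropped.  The two-sided binomial
    test p-value tells whether the observer is systematically on one side,
    and ``speed_group`` is "fast" when the observer beats the mode on more
    than half of the pairs, else "slow".
    """
    rows = []
    for oid, grp in records.groupby("observer_id", sort=True):
        valid = grp[grp["detected"].astype(bool)]
        diffs = np.array([
            row.time_s - mode_times[row.pair_id]
            for row in valid.itertuples(index=False)
            if row.pair_id in mode_times
        ])
        diffs = diffs[diffs != 0]  # drop ties
        if diffs.size < min_pairs:
            warnings.warn(f"observer {oid}: fewer than {min_pairs} usable pairs")
            continue
        below = int((diffs < 0).sum())
        p = binomtest(below, diffs.size, 0.5, alternative="two-sided").pvalue
        rows.append({
            "observer_id": oid,
            "n_pairs": int(diffs.size),
            "frac_below_mode": below / diffs.size,
            "sign_test_p": float(p),
            "speed_group": "fast" if below / diffs.size > 0.5 else "slow",
        })
    return pd.DataFrame(rows)


def load_study_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"study log missing columns: {sorted(missing)}")
    df["detected"] = df["detected"].astype(bool)
    df["correct"] = df["correct"].astype(bool)
    return df


def save_study_log(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False, columns=LOG_COLUMNS)
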