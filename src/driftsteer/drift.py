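"""Drift, convergence and null statistics across imaging sessions.

Definitions (all angles degrees, orientation convention period 180°):

drift magnitude |ΔPO|
    absolute circular PO change of a neuron between two sessions, [0, 90].
rPO
    PO expressed as absolute circular distance from an *experienced*
    orientation, [0, 90].
convergence Δ|rPO|
    ``rPO_pre - rPO_post``; positive when the neuron moved toward the
    experienced orientation.

A neuron contributes to a session pair only when *concurrently tuned* —
responsive and orientation-tuned on both days.  A PO change is
*significant* when each day's PO falls outside the other day's bootstrap
CI (both tested circularly).

Two permutation nulls probe what drives population convergence: the
magnitude shuffle permutes |ΔPO| across neurons while keeping each
neuron's drift direction (toward/away), and the direction shuffle
assigns each neuron a random direction while keeping its magnitude.
Only the direction shuffle should abolish convergence if drift is
direction-biased but magnitude-blind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .angles import orientation_distance, signed_orientation_diff
from .errors import ParameterError
from .tuning import ResponseMatrix

__all__ = [
    "make_drift_records",
    "convergence_summary",
    "shuffle_test",
    "ShuffleResult",
    "psc_matrix",
    "psc_similarity_decay",
    "fit_exponential_decay",
    "behavioral_modulation",
    "ModulationRecord",
    "filter_by_modulation",
    "DriftAnalysis",
]

RECORD_COLUMNS = [
    "neuron", "day_pre", "day_post", "interval", "po_pre", "po_post",
    "delta_po", "drift_magnitude", "significant", "rpo_pre", "rpo_post",
    "convergence",
]


def _in_circular_interval(angle, lo, width, tol=1e-9):
    """Membership of ``angle`` in the arc starting at ``lo`` spanning ``width``
    degrees (orientation circle)."""
    return (np.asarray(angle) - np.asarray(lo)) % 180.0 <= np.asarray(width) + tol


def make_drift_records(tuning_by_day: pd.DataFrame, experienced: float | None = None) -> pd.DataFrame:
    """Per-neuron drift records for every session pair.

    Parameters
    ----------
    tuning_by_day : DataFrame
        Concatenated tuning tables with columns ``neuron, day, po, ci_low,
        ci_high, ci_width, responsive, tuned`` (``*_deg`` aliases are
        accepted).
    experienced : float, optional
        Experienced orientation in degrees.  When given, rPO and
        convergence columns are filled; otherwise they are NaN.

    Returns
    -------
    DataFrame
        One row per concurrently tuned neuron per ordered session pair
        (columns in :data:`RECORD_COLUMNS`).  Empty (with a warning) if
        no neuron is concurrently tuned on any pair.
    """
    t = tuning_by_day.rename(columns={
        "po_deg": "po", "ci_low_deg": "ci_low", "ci_high_deg": "ci_high",
        "ci_width_deg": "ci_width"})
    days = np.sort(t["day"].unique())
    if len(days) < 2:
        raise ParameterError("need at least two sessions to compute drift")
    rows = []
    for i in range(len(days)):
        for j in range(i + 1, len(days)):
            a = t[t.day == days[i]].set_index("neuron")
            b = t[t.day == days[j]].set_index("neuron")
            common = a.index.intersection(b.index)
            a, b = a.loc[common], b.loc[common]
            ok = (a.tuned & a.responsive & b.tuned & b.responsive).to_numpy(bool)
            if not ok.any():
                continue
            a, b = a[ok], b[ok]
            delta = signed_orientation_diff(b.po.to_numpy(), a.po.to_numpy())
            sig = (~_in_circular_interval(b.po.to_numpy(), a.ci_low.to_numpy(),
                                          a.ci_width.to_numpy())
                   & ~_in_circular_interval(a.po.to_numpy(), b.ci_low.to_numpy(),
                                            b.ci_width.to_numpy()))
            rec = pd.DataFrame({
                "neuron": a.index.to_numpy(),
                "day_pre": days[i], "day_post": days[j],
                "interval": days[j] - days[i],
                "po_pre": a.po.to_numpy(), "po_post": b.po.to_numpy(),
                "delta_po": delta, "drift_magnitude": np.abs(delta),
                "significant": sig,
            })
            if experienced is not None:
                rec["rpo_pre"] = orientation_distance(rec.po_pre, experienced)
                rec["rpo_post"] = orientation_distance(rec.po_post, experienced)
                rec["convergence"] = rec.rpo_pre - rec.rpo_post
            else:
                rec["rpo_pre"] = rec["rpo_post"] = rec["convergence"] = np.nan
            rows.append(rec)
    if not rows:
        warnings.warn("no concurrently tuned neurons on any session pair")
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(rows, ignore_index=True)[RECORD_COLUMNS]


def convergence_summary(records: pd.DataFrame, n_boot: int = 10_000, rng=None):
    """Median convergence with a percentile-bootstrap 95% CI.

    ``records`` may be a drift-record DataFrame (its ``convergence``
    column is used) or a bare array of convergence values.
    """
    conv = np.asarray(records["convergence"] if isinstance(records, pd.DataFrame)
                      else records, dtype=float)
    if conv.size == 0:
        raise ParameterError("convergence_summary needs at least one record")
    rng = np.random.default_rng(rng)
    med = float(np.median(conv))
    idx = rng.integers(0, conv.size, size=(n_boot, conv.size))
    boots = np.median(conv[idx], axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return med, (float(lo), float(hi))


@dataclass
class ShuffleResult:
    """Null distribution of median convergence under a shuffle."""

    mode: str
    medians: np.ndarray

    def ci(self, level: float = 95.0):
        lo, hi = np.percentile(self.medians, [(100 - level) / 2, 100 - (100 - level) / 2])
        return float(lo), float(hi)


def shuffle_test(records: pd.DataFrame, mode: str, n_shuffle: int = 1000, rng=None) -> ShuffleResult:
    """Permutation null for population convergence.

    mode='magnitude'
        permute drift magnitudes across neurons, keep each neuron's drift
        direction (sign of its motion relative to the experienced
        orientation);
    mode='direction'
        assign each neuron a random toward/away direction (p=1/2), keep
        its magnitude.

    For every shuffle, ``rpo_post`` is re-derived as
    ``clip(rpo_pre - direction·magnitude, 0, 90)`` and the median of the
    resulting convergence values is recorded.
    """
    if mode not in ("magnitude", "direction"):
        raise ParameterError(f"unknown shuffle mode {mode!r}")
    if len(records) < 1:
        raise ParameterError("shuffle_test needs records")
    rng = np.random.default_rng(rng)
    rpo_pre = records["rpo_pre"].to_numpy(float)
    mag = records["drift_magnitude"].to_numpy(float)
    # toward (+1) if the neuron moved closer to the experienced orientation
    direction = np.where(records["convergence"].to_numpy(float) >= 0, 1.0, -1.0)
    n = mag.size
    medians = np.empty(n_shuffle)
    for s in range(n_shuffle):
        if mode == "magnitude":
            m = mag[rng.permutation(n)]
            d = direction
        else:
            m = mag
            d = rng.choice([-1.0, 1.0], size=n)
        rpo_post = np.clip(rpo_pre - d * m, 0.0, 90.0)
        medians[s] = np.median(rpo_pre - rpo_post)
    return ShuffleResult(mode=mode, medians=medians)


# ---------------------------------------------------------------------------
# pairwise signal correlations


def psc_matrix(rm: ResponseMatrix) -> np.ndarray:
    """Pairwise signal correlation (PSC) matrix.

    Pearson correlation between the trial-averaged tuning curves of every
    neuron pair.  Neurons with a zero-variance tuning curve get NaN rows
    and columns; downstream day-to-day comparisons drop those entries.
    """
    curves = rm.tuning_curves()
    if curves.shape[0] < 2:
        raise ParameterError("psc_matrix needs at least two neurons")
    sd = curves.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(curves)
    bad = sd == 0
    c[bad, :] = np.nan
    c[:, bad] = np.nan
    np.fill_diagonal(c, 1.0)
    return c


def _exp_decay(x, a, b, c):
    return a + b * np.exp(-c * x)


def fit_exponential_decay(intervals, similarities):
    """Least-squares fit of ``y = a + b·exp(-c·x)`` with c >= 0.

    Initialized at ``(min(y), max(y) - min(y), 0.1)``; tolerances are
    tight enough that noise-free data are recovered to ~1e-8.  Returns
    ``(a, b, c)``; optimizer failures propagate as RuntimeError.
    """
    x = np.asarray(intervals, dtype=float)
    y = np.asarray(similarities, dtype=float)
    p0 = (float(y.min()), float(y.max() - y.min()), 0.1)
    params, _ = optimize.curve_fit(
        _exp_decay, x, y, p0=p0,
        bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20_000)
    return tuple(float(p) for p in params)


def psc_similarity_decay(psc_by_day, day_labels):
    """Across-day similarity of the PSC matrix and its exponential-decay fit.

    Each day's PSC matrix is vectorized (strict upper triangle), matrices
    are correlated across all day pairs, and ``y = a + b·exp(-c·x)`` is
    fitted by least squares to similarity ``y`` versus interval ``x``.

    Returns
    -------
    day_corr : ndarray, (n_days, n_days)
    params : (a, b, c)
    fit : dict
        Diagnostics: intervals, similarities, residual norm, success flag.

    Raises
    ------
    ParameterError
        Fewer than three distinct intervals (fit under-determined).
    RuntimeError
        Propagated from the optimizer on non-convergence, with the data
        attached — never a silent fallback.
    """
    mats = [np.asarray(m, dtype=float) for m in psc_by_day]
    days = np.asarray(day_labels, dtype=float)
    iu = np.triu_indices(mats[0].shape[0], k=1)
    vecs = [m[iu] for m in mats]
    nd = len(vecs)
    day_corr = np.eye(nd)
    for i in range(nd):
        for j in range(i + 1, nd):
            ok = np.isfinite(vecs[i]) & np.isfinite(vecs[j])
            day_corr[i, j] = day_corr[j, i] = stats.pearsonr(vecs[i][ok], vecs[j][ok])[0]
    x = np.array([days[j] - days[i] for i in range(nd) for j in range(i + 1, nd)])
    y = np.array([day_corr[i, j] for i in range(nd) for j in range(i + 1, nd)])
    if len(np.unique(x)) < 3:
        raise ParameterError("need >= 3 distinct intervals for the exponential fit")
    params = fit_exponential_decay(x, y)
    resid = float(np.linalg.norm(_exp_decay(x, *params) - y))
    return day_corr, params, {"intervals": x, "similarity": y, "residual_norm": resid}


# ---------------------------------------------------------------------------
# behavioral-state modulation


@dataclass
class ModulationRecord:
    """Effective behavioral modulation of one neuron across a session pair.

    ``modulation`` is the Pearson correlation between single-trial
    stimulus-response amplitudes and the behavior covariate, multiplied
    by the mean across-session change of that covariate; zero (flagged)
    when the behavior has no variance.
    """

    neuron: int
    modulation: float
    correlation: float
    behavior_change: float
    degenerate: bool = False


def behavioral_modulation(response_amplitudes, behavior, behavior_session_change,
                          neuron: int = 0) -> ModulationRecord:
    """Running/arousal modulation index for one neuron (see class docs)."""
    amps = np.asarray(response_amplitudes, dtype=float)
    beh = np.asarray(behavior, dtype=float)
    if amps.size != beh.size or amps.size < 3:
        raise ParameterError("need >= 3 paired trials with behavior")
    change = float(behavior_session_change)
    if beh.std() == 0 or amps.std() == 0:
        return ModulationRecord(neuron, 0.0, 0.0, change, degenerate=True)
    corr = float(stats.pearsonr(beh, amps)[0])
    return ModulationRecord(neuron, corr * change, corr, change)


def filter_by_modulation(records: pd.DataFrame, modulation, drop_fraction: float) -> pd.DataFrame:
    """Drop the records most affected by behavioral-state changes.

    Removes the ``drop_fraction`` of records with the largest absolute
    modulation.  Ties at the cut are broken deterministically: among
    equal |modulation|, higher neuron ids are dropped first.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ParameterError("drop_fraction must lie in [0, 1)")
    if drop_fraction == 0.0 or len(records) == 0:
        return records.copy()
    mod = np.asarray([m.modulation if isinstance(m, ModulationRecord) else m
                      for m in modulation], dtype=float)
    if mod.size != len(records):
        raise ParameterError("modulation length must match records")
    n_drop = int(np.floor(drop_fraction * len(records)))
    neuron = records["neuron"].to_numpy()
    order = np.lexsort((neuron, np.abs(mod)))  # ascending |mod|; ties: small ids first
    keep = np.sort(order[: len(records) - n_drop])
    return records.iloc[keep].reset_index(drop=True)


class DriftAnalysis:
    """Convenience wrapper bundling drift records with their summaries.

    Thin object layer over the module functions, mirroring the
    Model/Results idiom used elsewhere in the package.
    """

    def __init__(self, tuning_by_day: pd.DataFrame, experienced: float | None = None):
        self.experienced = experienced
        self.records = make_drift_records(tuning_by_day, experienced=experienced)

    def convergence(self, n_boot: int = 10_000, rng=None):
        return convergence_summary(self.records, n_boot=n_boot, rng=rng)

    def shuffle(self, mode: str, n_shuffle: int = 1000, rng=None) -> ShuffleResult:
        return shuffle_test(self.records, mode, n_shuffle=n_shuffle, rng=rng)

    def summary(self) -> str:
        r = self.records
        med, (lo, hi) = self.convergence(n_boot=2000, rng=0) if len(r) else (np.nan, (np.nan, np.nan))
        return "\n".join([
            "Drift analysis",
            "==============",
            f"records:             {len(r)}",
            f"session pairs:       {r.groupby(['day_pre', 'day_post']).ngroups if len(r) else 0}",
            f"median |dPO|:        {r['drift_magnitude'].median():.2f} deg" if len(r) else "median |dPO|:        n/a",
            f"significant changes: {100 * r['significant'].mean():.1f}%" if len(r) else "significant changes: n/a",
            f"median convergence:  {med:.2f} deg  [95% CI {lo:.2f}, {hi:.2f}]",
        ])
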