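"""Step 2: delineation of emigration-timing windows (life-history pathways).

The cross-year average daily-emigrant series, pooled over streams and brood
years on the brood-cycle day axis, is multimodal: spring, summer and fall
subyearling emigration plus spring yearling emigration.  A four-component
normal mixture is fit to the day values weighted by rounded abundance
(equivalent to expanding each emigrant into one observation of its day), and
the three interior local minima of the fitted mixture density — taken over
integer days between successive component means — become the cutoffs that
delineate the four emigration windows.  Windows are common across streams
and years; daily abundances are then summed within windows.

The EM here is a small weighted 1-D implementation (scikit-learn's mixture
EM does not accept observation weights); its log-likelihood is monotone
non-decreasing over iterations and degenerate components trigger jittered
restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lhprod.errors import ConvergenceError, ValidationError

__all__ = [
    "MixtureFit",
    "LhpWindows",
    "LHP_LABELS",
    "fit_day_mixture",
    "find_cutoffs",
    "make_windows",
    "sum_windows",
    "pooled_daily_series",
]

LHP_LABELS = ("spring0", "summer0", "fall0", "spring1")


@dataclass
class MixtureFit:
    """Four-component normal mixture over brood-cycle days.

    Components are sorted by mean; ``loglik_path`` records the weighted
    log-likelihood after each EM iteration (non-decreasing).
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    loglik: float
    n_iter: int
    loglik_path: np.ndarray

    def density(self, x):
        x = np.asarray(x, dtype=float)
        z = (x[..., None] - self.means) / self.sds
        comp = self.weights * np.exp(-0.5 * z ** 2) / (
            self.sds * np.sqrt(2 * np.pi))
        return comp.sum(axis=-1)


@dataclass
class LhpWindows:
    """First/last brood-cycle day of the four emigration windows."""

    labels: tuple
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=int)
        self.ends = np.asarray(self.ends, dtype=int)
        if np.any(self.ends < self.starts):
            raise ValidationError("window end before start")
        if np.any(self.starts[1:] <= self.ends[:-1]):
            raise ValidationError("windows must be ordered and non-overlapping")

    def for_age(self, age_class):
        """Windows belonging to one trap season (spring1 is the yearling
        window; the first three are subyearling)."""
        sel = [i for i, lab in enumerate(self.labels)
               if (lab == "spring1") == (age_class == "yearling")]
        return LhpWindows(tuple(self.labels[i] for i in sel),
                          self.starts[sel], self.ends[sel])

    def to_frame(self):
        return pd.DataFrame({"lhp": list(self.labels), "t0": self.starts,
                             "tf": self.ends})


def _weighted_em(x, w, means, sds, weights, max_iter, tol):
    """One weighted EM run; returns (means, sds, weights, loglik_path) or
    None when a component degenerates."""
    x = x[:, None]
    path = []
    ll_old = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        z = (x - means) / sds
        log_comp = (np.log(weights) - np.log(sds)
                    - 0.5 * np.log(2 * np.pi) - 0.5 * z ** 2)
        m = log_comp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
        ll = float(np.sum(w * lse))
        path.append(ll)
        resp = np.exp(log_comp - lse[:, None])
        wk = (w[:, None] * resp).sum(axis=0)
        if np.any(wk <= 0):
            return None
        means = ((w[:, None] * resp * x).sum(axis=0)) / wk
        var = ((w[:, None] * resp * (x - means) ** 2).sum(axis=0)) / wk
        sds = np.sqrt(var)
        weights = wk / wk.sum()
        if np.any(sds < 0.5):  # sub-day component: degenerate spike
            return None
        if ll - ll_old < tol * max(1.0, abs(ll)):
            break
        ll_old = ll
    order = np.argsort(means)
    return (means[order], sds[order], weights[order], np.asarray(path),
            n_iter)


def fit_day_mixture(days, abundance, seed=0, n_components=4, n_restarts=10,
                    max_iter=500, tol=1e-10) -> MixtureFit:
    """Fit the timing mixture to per-day abundance weights.

    ``abundance`` is rounded to the nearest integer and used as observation
    weights on the day values; days with zero rounded abundance drop out.
    Initialization is quantile-based with common SD = span/8 and equal
    weights; ``n_restarts`` jittered starts are tried and the best
    log-likelihood kept.  Deterministic given ``seed``.
    """
    days = np.asarray(days, dtype=float)
    w = np.round(np.asarray(abundance, dtype=float))
    if np.any(w < 0):
        raise ValidationError("abundance weights must be nonnegative")
    keep = w > 0
    x, w = days[keep], w[keep]
    if w.sum() < n_components:
        raise ValidationError(
            f"total rounded abundance must be >= {n_components}")
    span = x.max() - x.min()
    if span <= 0:
        raise ConvergenceError(
            "all abundance on a single day: mixture is degenerate")
    rng = np.random.default_rng(seed)
    # weighted quantile initial means
    order = np.argsort(x)
    cw = np.cumsum(w[order]) / w.sum()
    qs = (np.arange(n_components) + 0.5) / n_components
    mean0 = np.interp(qs, cw, x[order])
    sd0 = np.full(n_components, max(span / 8.0, 1.0))
    wt0 = np.full(n_components, 1.0 / n_components)

    best = None
    attempts = 0
    for restart in range(n_restarts):
        m0 = mean0 if restart == 0 else mean0 + rng.normal(
            0.0, span / 20.0, n_components)
        res = _weighted_em(x, w, np.sort(m0), sd0.copy(), wt0.copy(),
                           max_iter, tol)
        attempts += 1
        if res is None:
            continue
        if best is None or res[3][-1] > best[3][-1]:
            best = res
    if best is None:
        raise ConvergenceError(
            f"mixture EM degenerated in all {attempts} restarts "
            "(component SD collapsed); inspect the daily series")
    means, sds, weights, path, n_iter = best
    return MixtureFit(means=means, sds=sds, weights=weights,
                      loglik=float(path[-1]), n_iter=n_iter,
                      loglik_path=path)


def find_cutoffs(mix: MixtureFit) -> np.ndarray:
    """Integer-day local minima of the mixture density between successive
    component means (ties broken toward the smallest day)."""
    means = np.asarray(mix.means, dtype=float)
    if np.unique(np.round(means)).size < means.size:
        raise ValidationError("component means are not distinct")
    cuts = []
    for k in range(means.size - 1):
        lo = int(np.ceil(means[k]))
        hi = int(np.floor(means[k + 1]))
        grid = np.arange(lo, hi + 1)
        if grid.size < 3:
            raise ValidationError(
                f"no interior days between modes {k} and {k + 1}; "
                "modes may have merged — inspect the mixture fit")
        dens = mix.density(grid.astype(float))
        j = int(np.argmin(dens))  # argmin returns the first (smallest day)
        if j == 0 or j == grid.size - 1:
            raise ValidationError(
                f"no interior density minimum between modes {k} and "
                f"{k + 1}; modes may have merged — inspect the mixture fit")
        cuts.append(int(grid[j]))
    return np.asarray(cuts, dtype=int)


def make_windows(mix: MixtureFit, subyearling_season, yearling_season
                 ) -> LhpWindows:
    """Turn mixture cutoffs into the four emigration windows, clipped to
    trap-season coverage (no winter-gap days)."""
    c1, c2, c3 = find_cutoffs(mix)
    s0, s1 = subyearling_season
    y0, y1 = yearling_season
    starts = [s0, c1 + 1, c2 + 1, max(y0, c3 + 1)]
    ends = [c1, c2, min(s1, c3), y1]
    ends[2] = min(s1, ends[2]) if ends[2] >= starts[2] else s1
    return LhpWindows(LHP_LABELS, np.array(starts), np.array(ends))


def sum_windows(days, abundance, windows: LhpWindows) -> pd.Series:
    """Sum daily abundances within each window (the window totals M_h).

    The total across LHPs equals the total over all in-window days.
    """
    days = np.asarray(days)
    abundance = np.asarray(abundance, dtype=float)
    out = {}
    for lab, t0, tf in zip(windows.labels, windows.starts, windows.ends):
        msk = (days >= t0) & (days <= tf)
        out[lab] = float(abundance[msk].sum())
    return pd.Series(out)


def pooled_daily_series(migration_fits, mode="mean"):
    """Pool estimated daily abundances across streams and years onto the
    brood-cycle day axis.

    ``mode="mean"`` (default) averages across (year, stream) series so
    high-abundance years do not dominate the timing signal; ``mode="sum"``
    totals them.  Returns (days, abundance) arrays.
    """
    if mode not in ("mean", "sum"):
        raise ValidationError(f"unknown pooling mode {mode!r}")
    acc = {}
    for fit in migration_fits:
        d = fit.dataset
        for ti, day in enumerate(d.days):
            acc.setdefault(int(day), []).extend(fit.m_hat[:, ti].tolist())
    days = np.array(sorted(acc))
    agg = np.array([np.mean(acc[d]) if mode == "mean" else np.sum(acc[d])
                    for d in days])
    return days, agg
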