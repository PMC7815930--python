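"""Channel activation t-maps and feature-space visualization.

A channel is called active when the robust-regression t-value of its dHbO
series against the expected hemodynamic response (video boxcar convolved with
the canonical HRF) exceeds the critical Student-t quantile at df = N - 1.
Robust fitting uses iteratively reweighted least squares with Tukey bisquare
weights (tuning constant 4.685) and an intercept, matching the conventional
robust-fit defaults.

Decoder features (flattened post-pooling activations) are projected onto
their first two principal components for inspection of class separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .hemodynamics import ConfigError, DataError, HemoSeries
from .paradigm import Event
from .synthetic_data import HRFParams, canonical_hrf

__all__ = [
    "DesignRegressor",
    "RobustFit",
    "TMap",
    "PCAProjection",
    "CHANNEL_LAYOUT",
    "expected_response",
    "robust_t",
    "tmap",
    "feature_pca",
    "tmap_grid",
]

#: Nominal prefrontal montage positions (x: left -1 .. right +1, y: low/high row);
#: channels 1-6 left hemisphere, 7-12 right.  Presentation only.
CHANNEL_LAYOUT = {
    1: (-0.9, 0.0), 2: (-0.75, 0.35), 3: (-0.55, 0.0), 4: (-0.4, 0.35),
    5: (-0.2, 0.0), 6: (-0.05, 0.35), 7: (0.05, 0.35), 8: (0.2, 0.0),
    9: (0.4, 0.35), 10: (0.55, 0.0), 11: (0.75, 0.35), 12: (0.9, 0.0),
}


@dataclass(frozen=True)
class DesignRegressor:
    """Expected hemodynamic response per sample, unit peak."""

    values: np.ndarray
    fs: float


@dataclass(frozen=True)
class RobustFit:
    beta: float
    t_value: float
    df: int
    converged: bool
    exact_fit: bool = False


@dataclass
class TMap:
    t_values: np.ndarray            # per channel
    df: int
    t_crit: float
    active: np.ndarray              # bool per channel
    channel_ids: tuple[int, ...]
    alpha: float = 0.05


@dataclass
class PCAProjection:
    scores: np.ndarray              # samples x 2
    explained_variance_ratio: np.ndarray
    components: np.ndarray          # 2 x d loadings


def expected_response(schedule: list[Event], hrf: HRFParams = HRFParams(),
                      fs: float = 15.625, n_samples: int | None = None) -> DesignRegressor:
    """Video-phase boxcar convolved with the canonical HRF, rescaled to unit peak."""
    videos = [ev for ev in schedule if ev.kind == "video"]
    if not videos:
        raise ConfigError("schedule has no video events to regress on")
    total_s = max(ev.onset_s + ev.duration_s for ev in schedule)
    n = n_samples if n_samples is not None else int(np.floor(total_s * fs))
    box = np.zeros(n)
    for ev in videos:
        start = int(np.floor(ev.onset_s * fs))
        stop = min(start + int(np.floor(ev.duration_s * fs)), n)
        box[start:stop] = 1.0
    kernel = canonical_hrf(np.arange(0, hrf.duration_s, 1 / fs), hrf)
    resp = np.convolve(box, kernel)[:n]
    peak = resp.max()
    if peak <= 0:
        raise ConfigError("design regressor is identically zero")
    return DesignRegressor(resp / peak, fs)


def robust_t(y: np.ndarray, x: "DesignRegressor | np.ndarray",
             tune: float = 4.685, maxiter: int = 50, tol: float = 1e-8) -> RobustFit:
    """IRLS bisquare regression of y on x (with intercept); t = beta / se(beta).

    An exact (zero-residual) fit is reported with t = +/-inf and the
    ``exact_fit`` flag instead of a spurious finite statistic.
    """
    import statsmodels.api as sm

    xv = x.values if isinstance(x, DesignRegressor) else np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape != xv.shape or y.ndim != 1:
        raise DataError("y and the regressor must be equal-length 1-D series")
    n = y.size
    if n < 3:
        raise DataError("robust fit needs at least 3 samples")
    if np.ptp(xv) == 0:
        raise ConfigError("constant regressor")
    design = sm.add_constant(xv)
    # exact-fit guard: OLS residuals at machine-precision zero
    beta_ls, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta_ls
    scale_y = max(np.std(y), 1.0)
    if np.max(np.abs(resid)) < 1e-10 * scale_y:
        t = np.inf if beta_ls[1] > 0 else (-np.inf if beta_ls[1] < 0 else 0.0)
        return RobustFit(float(beta_ls[1]), float(t), n - 1, True, exact_fit=True)
    model = sm.RLM(y, design, M=sm.robust.norms.TukeyBiweight(c=tune))
    res = model.fit(maxiter=maxiter, tol=tol)
    converged = bool(getattr(res, "fit_history", {}).get("iteration", maxiter) < maxiter) \
        if hasattr(res, "fit_history") else True
    beta = float(res.params[1])
    t = beta / float(res.bse[1])
    return RobustFit(beta, t, n - 1, converged)


def tmap(hemo: HemoSeries, regressor: DesignRegressor, alpha: float = 0.05) -> TMap:
    """Per-channel robust t-values of dHbO against the expected response.

    One-tailed test: a channel is active when t > t_crit at the given alpha,
    df = N - 1 (N samples per channel).
    """
    if not 0 < alpha < 1:
        raise ConfigError("alpha must be in (0, 1)")
    n = hemo.n_samples
    if regressor.values.size != n:
        raise DataError("regressor length does not match the series")
    t_values = np.array([robust_t(hemo.dhbo[:, c], regressor).t_value
                         for c in range(hemo.dhbo.shape[1])])
    df = n - 1
    t_crit = float(scipy.stats.t.ppf(1 - alpha, df))
    return TMap(t_values, df, t_crit, t_values > t_crit, hemo.channel_ids, alpha)


def feature_pca(features: np.ndarray) -> PCAProjection:
    """Project samples onto the top-2 principal components of their covariance."""
    from sklearn.decomposition import PCA

    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise DataError("need a (>=2 samples, >=2 features) matrix")
    if np.allclose(x.var(axis=0), 0):
        raise DataError("zero-variance features: PCA is degenerate")
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(x)
    return PCAProjection(scores, pca.explained_variance_ratio_, pca.components_)


def tmap_grid(tm: TMap, resolution: int = 64) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly interpolated topographic grid of t-values for rendering.

    Returns (grid_x, grid_y, values); NaN outside the channel hull.  Purely
    presentational — the TMap values are the contract.
    """
    from scipy.interpolate import griddata

    pts = np.array([CHANNEL_LAYOUT[ch] for ch in tm.channel_ids])
    gx, gy = np.meshgrid(np.linspace(-1, 1, resolution), np.linspace(-0.2, 0.55, resolution))
    vals = griddata(pts, tm.t_values, (gx, gy), method="linear")
    return gx, gy, vals
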