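"""Bout-level 3-D swim kinematics and the associated statistics.

Summarizes a swim bout (time series of poses) by the yaw, inclination and
roll of the head and the mean lateral and dorsal bending angles; reports
the maximum change (signed extremum of the deviation from the first
frame) and the total change (final minus initial) of each. Statistical
helpers implement the pooled-bootstrap difference-of-means test, the exact
binomial asymmetry test, and SVD eigenshapes of the bending-angle series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthesis import SwimBout

__all__ = [
    "BoutKinematics",
    "bout_kinematics",
    "quartile_summary",
    "bootstrap_mean_difference_test",
    "binomial_asymmetry_test",
    "eigenshapes",
]


@dataclass
class BoutKinematics:
    times: np.ndarray
    theta0: np.ndarray
    phi0: np.ndarray
    gamma0: np.ndarray
    mean_dtheta: np.ndarray
    mean_dphi: np.ndarray
    z: np.ndarray
    max_change: dict
    total_change: dict
    z_range: tuple[float, float]


def _signed_extremum(dev: np.ndarray) -> float:
    """Largest-|.| deviation, sign kept (ties break to the earlier frame)."""
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


def bout_kinematics(bout: SwimBout, max_mode: str = "signed_extremum",
                    interpolate_gaps: bool = True) -> BoutKinematics:
    """Kinematic summary of one swim bout.

    Angle series are unwrapped before differencing and all changes are
    measured relative to the first frame. ``max_mode`` selects the signed
    extremum of the deviation (default) or the max-minus-min range.
    """
    if len(bout.poses) < 2:
        raise ValueError("a bout needs at least 2 frames")
    theta0 = np.unwrap([p.theta0 for p in bout.poses])
    phi0 = np.unwrap([p.phi0 for p in bout.poses])
    gamma0 = np.unwrap([p.gamma0 for p in bout.poses])
    mean_dtheta = np.array([np.mean(p.dtheta) for p in bout.poses])
    mean_dphi = np.array([np.mean(p.dphi) for p in bout.poses])
    z = np.array([p.z0 for p in bout.poses])
    series = {"theta0": theta0, "phi0": phi0, "gamma0": gamma0,
              "mean_dtheta": mean_dtheta, "mean_dphi": mean_dphi}
    for name, s in series.items():
        if interpolate_gaps and np.any(~np.isfinite(s)):
            good = np.isfinite(s)
            series[name] = np.interp(np.arange(len(s)),
                                     np.flatnonzero(good), s[good])
    max_change, total_change = {}, {}
    for name, s in series.items():
        dev = s - s[0]
        if max_mode == "signed_extremum":
            max_change[name] = _signed_extremum(dev)
        elif max_mode == "range":
            max_change[name] = float(dev.max() - dev.min())
        else:
            raise ValueError(f"unknown max_mode {max_mode!r}")
        total_change[name] = float(s[-1] - s[0])
    return BoutKinematics(
        times=np.asarray(bout.times), theta0=theta0, phi0=phi0, gamma0=gamma0,
        mean_dtheta=mean_dtheta, mean_dphi=mean_dphi, z=z,
        max_change=max_change, total_change=total_change,
        z_range=(float((z - z[0]).min()), float((z - z[0]).max())))


def quartile_summary(values: np.ndarray) -> tuple[float, float, float]:
    """(Q1, Q3, IQR) with numpy's linear-interpolation quartiles."""
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 values for quartiles")
    q1, q3 = np.percentile(values, [25, 75])
    return float(q1), float(q3), float(q3 - q1)


def bootstrap_mean_difference_test(
    a: np.ndarray,
    b: np.ndarray,
    n_resamples: int = 10000,
    seed: int = 0,
    statistic=np.mean,
    orient: str = "larger-mean",
) -> float:
    """One-sided pooled-bootstrap test that mean(a) > mean(b).

    Samples are pooled under the null; pairs of same-size resamples are
    drawn with replacement and the difference of their statistics forms
    the null distribution D. Returns p = Pr(D >= observed difference).
    With ``orient='larger-mean'`` the observed difference is taken as
    mu1 - mu2 with mu1 > mu2 (so under a true null p concentrates on
    (0, 0.5]); ``orient='fixed'`` tests the pre-specified direction
    statistic(a) - statistic(b), whose null p-values are uniform on
    (0, 1). ``statistic`` may be any reducer (e.g. a quartile).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        import warnings
        warnings.warn("unequal sample sizes; resampling preserves each size")
    observed = statistic(a) - statistic(b)
    if orient == "larger-mean":
        observed = abs(observed)
    elif orient != "fixed":
        raise ValueError("orient must be 'larger-mean' or 'fixed'")
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    # chunked vectorized resampling
    chunk = max(1, min(n_resamples, int(2e6 // max(len(a) + len(b), 1))))
    done = 0
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        x = pooled[rng.integers(0, len(pooled), size=(m, len(a)))]
        y = pooled[rng.integers(0, len(pooled), size=(m, len(b)))]
        d = np.apply_along_axis(statistic, 1, x) - np.apply_along_axis(statistic, 1, y) \
            if statistic is not np.mean else x.mean(axis=1) - y.mean(axis=1)
        count += int(np.sum(d >= observed))
        done += m
    return count / n_resamples


def binomial_asymmetry_test(k: int, n: int, p0: float = 0.5) -> float:
    """Exact upper-tail binomial probability P(X >= k) under Binomial(n, p0)."""
    from scipy import stats

    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(stats.binom.sf(k - 1, n, p0))


def eigenshapes(theta_matrix: np.ndarray, center: bool = True):
    """SVD bending modes of a (frames x 16) bending-angle series.

    Columns 0..7 are the lateral angles (dtheta) and 8..15 the dorsal
    angles (dphi). Returns (modes, variance_fractions, labels) with modes
    ordered by decreasing singular value and each labelled
    'lateral' or 'dorsal' by where most of its energy lies.
    """
    X = np.asarray(theta_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (frames >= 2) x angles matrix")
    if center:
        X = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    total = var.sum()
    fractions = var / total if total > 0 else var
    half = X.shape[1] // 2
    labels = ["lateral" if np.sum(v[:half]**2) >= np.sum(v[half:]**2)
              else "dorsal" for v in vt]
    return vt, fractions, labels
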