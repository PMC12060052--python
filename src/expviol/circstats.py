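"""Axial circular statistics for orientation data.

Gratings are axial stimuli: an orientation of theta degrees is physically
identical to theta + 180 degrees.  All statistics here therefore operate on
the doubled circle — angles are multiplied by two, mapped onto the full
360-degree circle, summarised with ordinary circular statistics, and the
result is halved back onto the axial range.

Conventions
-----------
* Orientations live on [0, 180) degrees; 0 = vertical, positive = clockwise.
* Signed axial differences (reproduction errors, expectation violations)
  live on (-90, 90].
* ``angular_sd`` follows the circular-standard-deviation convention
  sqrt(-2 ln R); the angular-deviation alternative sqrt(2 (1 - R)) is
  available through ``convention="angular_deviation"``.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "axial_wrap",
    "wrap_orientation",
    "axial_mean",
    "angular_sd",
    "UndefinedMeanError",
]

#: Resultant lengths below this are treated as a degenerate (undefined) mean.
_RESULTANT_TOL = 1e-9


class UndefinedMeanError(ValueError):
    """Raised when the axial mean is undefined (near-zero resultant length)."""


def axial_wrap(delta):
    """Wrap an angular difference onto the signed axial range (-90, 90].

    Parameters
    ----------
    delta : float or array_like
        Angular difference(s) in degrees.

    Returns
    -------
    float or ndarray
        ``delta`` reduced modulo 180 into (-90, 90].

    Raises
    ------
    ValueError
        If any input is non-finite.
    """
    arr = np.asarray(delta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("axial_wrap requires finite input")
    wrapped = np.mod(arr, 180.0)
    wrapped = np.where(wrapped > 90.0, wrapped - 180.0, wrapped)
    if np.isscalar(delta) or arr.ndim == 0:
        return float(wrapped)
    return wrapped


def wrap_orientation(theta):
    """Wrap orientation(s) onto the axial domain [0, 180)."""
    arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("wrap_orientation requires finite input")
    out = np.mod(arr, 180.0)
    if np.isscalar(theta) or arr.ndim == 0:
        return float(out)
    return out


def _doubled_resultant(angles_deg, weights=None):
    """Mean resultant vector of the doubled angles; returns (R, mean_dir_rad)."""
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle sample")
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    rad = np.deg2rad(2.0 * a)
    if weights is None:
        w = np.ones_like(rad)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != rad.shape:
            raise ValueError("weights must match angles in shape")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
    c = np.sum(w * np.cos(rad)) / w.sum()
    s = np.sum(w * np.sin(rad)) / w.sum()
    return float(np.hypot(c, s)), float(np.arctan2(s, c))


def axial_mean(angles_deg, weights=None):
    """Axial mean direction, as a signed angle in (-90, 90].

    Angles are doubled onto the full circle, the mean resultant direction is
    computed, and the direction is halved back.  For samples of signed errors
    this is the circular analogue of the arithmetic mean ("bias").

    Raises
    ------
    UndefinedMeanError
        If the resultant length is (numerically) zero, e.g. for the antipodal
        pair {80, -80} whose doubled angles cancel.
    """
    r, mean_dir = _doubled_resultant(angles_deg, weights)
    if r < _RESULTANT_TOL:
        raise UndefinedMeanError(
            f"axial mean undefined: resultant length {r:.2e} is ~0"
        )
    return axial_wrap(np.rad2deg(mean_dir) / 2.0)


def angular_sd(angles_deg, weights=None, convention="circular_sd"):
    """Angular standard deviation of an axial sample, in degrees.

    With ``R`` the mean resultant length of the doubled angles:

    * ``convention="circular_sd"`` (default): ``0.5 * sqrt(-2 ln R)``,
      the CircStat ``circ_std`` convention.  Equals the linear SD in the
      small-dispersion limit.
    * ``convention="angular_deviation"``: ``0.5 * sqrt(2 (1 - R))``,
      CircStat's second output.

    The leading 1/2 undoes the angle doubling.  Returns ``inf`` with a
    warning when ``R == 0`` (uniform dispersion).
    """
    if convention not in ("circular_sd", "angular_deviation"):
        raise ValueError(f"unknown convention {convention!r}")
    r, _ = _doubled_resultant(angles_deg, weights)
    if convention == "angular_deviation":
        return float(np.rad2deg(0.5 * np.sqrt(2.0 * (1.0 - r))))
    if r < _RESULTANT_TOL:
        warnings.warn("zero resultant length: angular SD is infinite")
        return float("inf")
    return float(np.rad2deg(0.5 * np.sqrt(-2.0 * np.log(r))))
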