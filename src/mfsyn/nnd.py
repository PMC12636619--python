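"""Cross-channel nearest-neighbor distances and two-Gaussian decomposition.

For every molecule (trace centroid) of one color channel, the nearest-neighbor
distance (NND) is the 3D Euclidean distance to the closest molecule of the
other channel.  Pooled over fields of view, the NND histogram separates into
a short-distance component (specifically associated molecule pairs) and a
broad component at ~150 nm that arises for any two unrelated molecule
populations at these densities; both are summarized by a two-Gaussian
least-squares fit to the binned counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

from .errors import FitError, ValidationError


@dataclass(frozen=True)
class NndResult:
    """Sorted nearest-neighbor distances from one channel to the other."""

    source_channel: str
    target_channel: str
    distances: np.ndarray  # sorted ascending, nm
    n_source: int


@dataclass(frozen=True)
class NndMixtureFit:
    """Two-Gaussian fit of an NND histogram: A*exp(-(d-m)^2 / 2 s^2) per mode.

    ``fallback`` marks fits where only one mode was detectable and a single
    Gaussian was used (the second component is then NaN).
    """

    bin_width_nm: float
    a1: float
    m1: float
    s1: float
    a2: float
    m2: float
    s2: float
    rss: float
    fallback: bool = False


def nearest_neighbor_distances(
    source_xyz, target_xyz, source_channel: str = "A", target_channel: str = "B",
    dims: int = 3,
) -> NndResult:
    """Distance from each source molecule to its closest target molecule.

    ``dims=2`` restricts the metric to the XY plane (sensitivity analysis);
    the default is the full 3D Euclidean distance on Z-corrected coordinates.
    """
    src = np.atleast_2d(np.asarray(source_xyz, dtype=float))[:, :dims]
    tgt = np.atleast_2d(np.asarray(target_xyz, dtype=float))
    if tgt.size == 0:
        raise ValidationError(f"target channel {target_channel!r} is empty")
    tgt = tgt[:, :dims]
    d, _ = cKDTree(tgt).query(src, k=1)
    return NndResult(source_channel, target_channel, np.sort(np.asarray(d, float)),
                     len(src))


def _two_gauss(d, a1, m1, s1, a2, m2, s2):
    return (a1 * np.exp(-0.5 * ((d - m1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((d - m2) / s2) ** 2))


def _one_gauss(d, a, m, s):
    return a * np.exp(-0.5 * ((d - m) / s) ** 2)


def fit_nnd_histogram(result: NndResult, bin_width_nm: float = 10.0) -> NndMixtureFit:
    """Least-squares two-Gaussian fit to the binned NND counts.

    Bins of ``bin_width_nm`` start at zero; the fit is initialized from the
    two most prominent local maxima of a lightly smoothed histogram.  If only
    one mode is detectable, a single-Gaussian fit is returned with
    ``fallback=True``.
    """
    d = np.asarray(result.distances, dtype=float)
    if d.size < 100:
        raise ValidationError(f"need >= 100 distances, got {d.size}")
    n_bins = max(int(np.ceil((d.max() + 0.5 * bin_width_nm) / bin_width_nm)), 1)
    edges = np.arange(n_bins + 1) * bin_width_nm
    counts, _ = np.histogram(d, bins=edges)
    if int((counts > 0).sum()) < 8:
        raise ValidationError("need at least 8 non-empty histogram bins")
    centers = 0.5 * (edges[:-1] + edges[1:])

    smoothed = gaussian_filter1d(counts.astype(float), sigma=1.0)
    peaks, _ = find_peaks(smoothed, prominence=0.0)
    # edge bins can hold a mode that find_peaks misses; consider them too
    cand = list(peaks)
    for edge in (0, len(smoothed) - 1):
        if edge not in cand and smoothed[edge] >= smoothed.max() * 0.1:
            cand.append(edge)
    cand = sorted(set(cand), key=lambda i: -smoothed[i])

    # primary mode = most prominent; second mode = strongest local max at
    # least 3 bins away (the two components of interest are well separated)
    pair = None
    if cand:
        first = cand[0]
        far = [i for i in cand[1:] if abs(i - first) >= 3]
        if far:
            pair = (first, far[0])
    if pair is not None:
        i1, i2 = sorted(pair)
        p0 = [smoothed[i1], centers[i1], max(bin_width_nm, 1.0),
              smoothed[i2], centers[i2], max(3 * bin_width_nm, 1.0)]
        try:
            popt, _ = curve_fit(
                _two_gauss, centers, counts, p0=p0,
                bounds=([0, 0, 1e-3, 0, 0, 1e-3],
                        [np.inf, edges[-1], edges[-1], np.inf, edges[-1], edges[-1]]),
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise FitError(f"two-Gaussian NND fit did not converge: {exc}")
        a1, m1, s1, a2, m2, s2 = popt
        if m1 > m2:
            a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1
        rss = float(np.sum((_two_gauss(centers, a1, m1, s1, a2, m2, s2) - counts) ** 2))
        return NndMixtureFit(bin_width_nm, float(a1), float(m1), float(s1),
                             float(a2), float(m2), float(s2), rss)

    # single detectable mode: flagged fallback
    i1 = cand[0] if cand else int(np.argmax(smoothed))
    p0 = [smoothed[i1], centers[i1], max(bin_width_nm, 1.0)]
    try:
        popt, _ = curve_fit(_one_gauss, centers, counts, p0=p0,
                            bounds=([0, 0, 1e-3], [np.inf, edges[-1], edges[-1]]),
                            maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"single-Gaussian NND fallback did not converge: {exc}")
    a, m, s = popt
    rss = float(np.sum((_one_gauss(centers, a, m, s) - counts) ** 2))
    return NndMixtureFit(bin_width_nm, float(a), float(m), float(s),
                         np.nan, np.nan, np.nan, rss, fallback=True)


def peak_amplitude_ratio(
    fit_ab: NndMixtureFit, fit_ba: NndMixtureFit, mode: str = "amplitude"
) -> float:
    """Ratio of the short-distance component between the two directed fits.

    ``amplitude`` compares peak heights A1; ``area`` compares A1*s1*sqrt(2*pi).
    """
    if fit_ab.fallback or fit_ba.fallback:
        raise FitError("peak ratio undefined for single-mode fallback fits")
    if mode == "amplitude":
        return fit_ab.a1 / fit_ba.a1
    if mode == "area":
        return (fit_ab.a1 * fit_ab.s1) / (fit_ba.a1 * fit_ba.s1)
    raise ValidationError(f"unknown mode {mode!r}; use 'amplitude' or 'area'")
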