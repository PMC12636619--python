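"""Quality control, spectral unmixing, Z correction, and trace aggregation.

The raw MINFLUX export carries per-localization quality metrics: EFO (the
effective emission frequency at the probing-pattern offsets, in Hz), CFR (the
center-to-offset frequency ratio; low values mean well-centered localizations)
and DCR (the gate-channel-1 count fraction that separates the two spectrally
distinct fluorophores).  The stages here reproduce the standard processing
chain: interval filters on EFO and CFR, a strict minimum trace length, a
two-Gaussian DCR decomposition for channel unmixing, the refractive-index
Z correction, and aggregation of each trace into one molecule position whose
per-axis scatter is the working localization-precision surrogate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln

from .errors import FitError, ValidationError

#: Canonical channel labels, by DCR component.
CH_LOW = "ch_low_dcr"
CH_HIGH = "ch_high_dcr"


@dataclass(frozen=True)
class QCThresholds:
    """Closed-interval bounds on EFO (Hz) and CFR, plus the strict minimum
    number of localizations per trace.

    Defaults are the conventional acquisition bounds: EFO in 100-300 kHz,
    CFR in 0-0.9, and traces must have more than ``len_min`` (3) records,
    i.e. at least 4 localizations.
    """

    efo_min: float = 100_000.0
    efo_max: float = 300_000.0
    cfr_min: float = 0.0
    cfr_max: float = 0.9
    len_min: int = 3

    def __post_init__(self):
        if not self.efo_min < self.efo_max:
            raise ValidationError("efo_min must be < efo_max")
        if not self.cfr_min < self.cfr_max:
            raise ValidationError("cfr_min must be < cfr_max")
        if self.len_min < 0:
            raise ValidationError("len_min must be >= 0")


@dataclass(frozen=True)
class DcrMixture:
    """Two-component Gaussian decomposition of the DCR distribution.

    ``boundary`` is the equal-density crossing between the component means;
    ``channel_map`` names which fluorophore each DCR component corresponds to
    (instrument gate ordering is configuration, not a constant).
    """

    w1: float
    w2: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    boundary: float
    channel_map: dict = field(default_factory=lambda: {CH_LOW: "FX640", CH_HIGH: "FX680"})

    def __post_init__(self):
        if not np.isclose(self.w1 + self.w2, 1.0):
            raise ValidationError("mixture weights must sum to 1")
        if not (0 <= self.mu1 < self.mu2 <= 1):
            raise ValidationError("need 0 <= mu1 < mu2 <= 1")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValidationError("sigmas must be positive")
        if not (self.mu1 < self.boundary < self.mu2):
            raise ValidationError("boundary must lie strictly between the means")


@dataclass(frozen=True)
class ResolutionEstimate:
    """Per-axis mean trace spread (nm) with its standard error."""

    mean_nm: tuple  # (x, y, z)
    sem_nm: tuple
    n_traces: int


@dataclass(frozen=True)
class FilterResult:
    table: pd.DataFrame
    n_input: int
    n_retained: int
    rejected: dict  # criterion -> count; one criterion per rejected record


def filter_records(table: pd.DataFrame, thr: QCThresholds = QCThresholds()) -> FilterResult:
    """Keep records with EFO and CFR inside the closed threshold intervals.

    Rejection counts are per-criterion (EFO checked first), so
    ``n_retained + sum(rejected.values()) == n_input``.  Order is preserved.
    """
    efo_ok = (table["efo_hz"] >= thr.efo_min) & (table["efo_hz"] <= thr.efo_max)
    cfr_ok = (table["cfr"] >= thr.cfr_min) & (table["cfr"] <= thr.cfr_max)
    keep = efo_ok & cfr_ok
    n_efo = int((~efo_ok).sum())
    n_cfr = int((efo_ok & ~cfr_ok).sum())
    out = table[keep].reset_index(drop=True)
    return FilterResult(out, len(table), len(out), {"efo": n_efo, "cfr": n_cfr})


def filter_trace_length(table: pd.DataFrame, len_min: int = 3) -> pd.DataFrame:
    """Keep only traces with strictly more than ``len_min`` localizations."""
    if len(table) == 0:
        return table.reset_index(drop=True)
    counts = table.groupby(["fov_id", "tid"])["tid"].transform("size")
    return table[counts > len_min].reset_index(drop=True)


def _norm_pdf(x, mu, sigma):
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def fit_dcr_mixture(
    dcr_values,
    init: tuple | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    channel_map: dict | None = None,
) -> DcrMixture:
    """Fit a two-component Gaussian mixture to DCR values by EM.

    Initialization splits the data at the midpoint of the two means supplied
    in ``init``, or at a 2-means-style split of the sorted values otherwise.
    The decision boundary is the equal weighted-density crossing between the
    two component means.

    Raises
    ------
    FitError
        on non-convergence or if a component degenerates (weight < 0.02);
        the message advises supplying a manual boundary.
    """
    x = np.asarray(dcr_values, dtype=float)
    if x.size < 50:
        raise ValidationError(f"need >= 50 DCR values, got {x.size}")
    if np.any((x < 0) | (x > 1)):
        raise ValidationError("DCR values must lie in [0, 1]")

    if init is not None:
        mu = np.array(init, dtype=float)
    else:
        # 1D 2-means on the sorted values: start from the 25/75 percentiles
        # and iterate the midpoint split to a fixed point.
        mu = np.percentile(x, [25, 75]).astype(float)
        for _ in range(100):
            assign = x > (mu[0] + mu[1]) / 2
            new = np.array([x[~assign].mean(), x[assign].mean()])
            if np.allclose(new, mu):
                break
            mu = new
    assign = x > (mu[0] + mu[1]) / 2
    w = np.array([max((~assign).mean(), 0.05), max(assign.mean(), 0.05)])
    w = w / w.sum()
    sigma = np.array(
        [max(x[~assign].std(), 1e-3) if (~assign).any() else 0.05,
         max(x[assign].std(), 1e-3) if assign.any() else 0.05]
    )

    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        dens = np.stack([w[k] * _norm_pdf(x, mu[k], sigma[k]) for k in range(2)])
        total = dens.sum(axis=0)
        total = np.where(total > 0, total, np.finfo(float).tiny)
        resp = dens / total
        ll = np.log(total).sum()
        nk = resp.sum(axis=1)
        if np.any(nk < 1e-6):
            raise FitError(
                "degenerate mixture component; supply a manual DCR boundary"
            )
        w = nk / x.size
        mu = (resp * x).sum(axis=1) / nk
        sigma = np.sqrt((resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk)
        sigma = np.maximum(sigma, 1e-4)
        if abs(ll - ll_prev) < tol * (1 + abs(ll)):
            converged = True
            break
        ll_prev = ll
    if not converged:
        raise FitError("EM did not converge; supply a manual DCR boundary")
    if np.min(w) < 0.02:
        raise FitError(
            "degenerate mixture component (weight < 0.02); supply a manual DCR boundary"
        )

    order = np.argsort(mu)
    w, mu, sigma = w[order], mu[order], sigma[order]

    def diff(v):
        return w[0] * _norm_pdf(v, mu[0], sigma[0]) - w[1] * _norm_pdf(v, mu[1], sigma[1])

    lo, hi = mu[0], mu[1]
    if diff(lo) > 0 and diff(hi) < 0:
        boundary = brentq(diff, lo, hi)
    else:  # no sign change (extreme weight imbalance): fall back to midpoint
        boundary = 0.5 * (lo + hi)
    boundary = float(np.clip(boundary, np.nextafter(lo, hi), np.nextafter(hi, lo)))

    kwargs = {} if channel_map is None else {"channel_map": dict(channel_map)}
    return DcrMixture(
        w1=float(w[0]), w2=float(w[1]), mu1=float(mu[0]), mu2=float(mu[1]),
        sigma1=float(sigma[0]), sigma2=float(sigma[1]), boundary=boundary, **kwargs
    )


def assign_channels(
    table: pd.DataFrame, mix: DcrMixture, ambiguity_odds: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each record, then each trace, to a DCR component.

    A record goes to the component with the higher posterior density; records
    whose posterior odds (larger/smaller) fall below ``ambiguity_odds`` are
    discarded (with the default of 1 only exact ties are dropped).  Each
    surviving trace is labeled by majority vote of its records; tied traces
    are discarded whole.  The returned ``(labeled, discarded)`` pair is an
    exact partition of the input.
    """
    if len(table) == 0:
        empty = table.copy()
        labeled = empty.copy()
        labeled["channel"] = pd.Series(dtype=str)
        return labeled, empty

    d = table["dcr"].to_numpy()
    p1 = mix.w1 * _norm_pdf(d, mix.mu1, mix.sigma1)
    p2 = mix.w2 * _norm_pdf(d, mix.mu2, mix.sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.where(p1 >= p2, p1 / np.maximum(p2, np.finfo(float).tiny),
                        p2 / np.maximum(p1, np.finfo(float).tiny))
    record_ch = np.where(p1 > p2, CH_LOW, np.where(p2 > p1, CH_HIGH, "tie"))
    # records at the decision boundary are ties by policy, whatever the
    # (manually supplied) boundary's exact densities are
    ambiguous = (odds < ambiguity_odds) | (record_ch == "tie") | (d == mix.boundary)

    work = table.copy()
    work["_ch"] = record_ch
    work["_amb"] = ambiguous

    keep_mask = np.zeros(len(work), dtype=bool)
    channel_of = {}
    for key, grp in work.groupby(["fov_id", "tid"], sort=False):
        votes = grp.loc[~grp["_amb"], "_ch"]
        n_low = int((votes == CH_LOW).sum())
        n_high = int((votes == CH_HIGH).sum())
        if n_low == n_high:  # tie (or all-ambiguous): discard the trace
            continue
        channel_of[key] = CH_LOW if n_low > n_high else CH_HIGH
        keep_mask[work.index.isin(grp.index[~grp["_amb"]])] = True

    labeled = work[keep_mask].drop(columns=["_ch", "_amb"]).copy()
    labeled["channel"] = [
        channel_of[k] for k in zip(labeled["fov_id"], labeled["tid"])
    ]
    discarded = work[~keep_mask].drop(columns=["_ch", "_amb"]).reset_index(drop=True)
    return labeled.reset_index(drop=True), discarded


def correct_z(table: pd.DataFrame, factor: float = 0.7) -> pd.DataFrame:
    """Scale the measured z by ``factor`` (default 0.7).

    The coverglass/buffer refractive-index mismatch makes the focal point
    appear shallower than it is; multiplying the measured z by 0.7 restores
    the physical axial position.  x and y are untouched.
    """
    if factor <= 0:
        raise ValidationError("z correction factor must be positive")
    out = table.copy()
    out["z_nm"] = out["z_nm"] * factor
    return out


def aggregate_traces(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse each (fov_id, tid) trace to one molecule position.

    Returns a trace table with columns ``fov_id, tid, channel, n_locs,
    x_nm, y_nm, z_nm`` (per-axis mean) and ``sd_x_nm, sd_y_nm, sd_z_nm``
    (per-axis sample standard deviation, n-1 denominator).  Traces with a
    single localization cannot yield a spread and are excluded with a
    warning (impossible after the default length filter).
    """
    has_channel = "channel" in table.columns
    rows = []
    n_skipped = 0
    for (fov, tid), grp in table.groupby(["fov_id", "tid"], sort=False):
        if len(grp) < 2:
            n_skipped += 1
            continue
        xyz = grp[["x_nm", "y_nm", "z_nm"]].to_numpy()
        rows.append({
            "fov_id": fov,
            "tid": tid,
            "channel": grp["channel"].iloc[0] if has_channel else "",
            "n_locs": len(grp),
            "x_nm": xyz[:, 0].mean(),
            "y_nm": xyz[:, 1].mean(),
            "z_nm": xyz[:, 2].mean(),
            "sd_x_nm": xyz[:, 0].std(ddof=1),
            "sd_y_nm": xyz[:, 1].std(ddof=1),
            "sd_z_nm": xyz[:, 2].std(ddof=1),
        })
    if n_skipped:
        warnings.warn(f"excluded {n_skipped} trace(s) with fewer than 2 localizations")
    cols = ["fov_id", "tid", "channel", "n_locs", "x_nm", "y_nm", "z_nm",
            "sd_x_nm", "sd_y_nm", "sd_z_nm"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


def _c4(n):
    """Bias factor of the sample SD: E[s] = c4(n) * sigma for Gaussian data."""
    n = np.asarray(n, dtype=float)
    return np.exp(0.5 * np.log(2.0 / (n - 1)) + gammaln(n / 2) - gammaln((n - 1) / 2))


def estimate_resolution(
    traces: pd.DataFrame, group_by_fov: bool = False, bias_correct: bool = False
) -> ResolutionEstimate:
    """Average per-trace spread as the per-axis localization precision.

    With ``group_by_fov`` the standard error is computed across FOV means
    (matching mean +/- SEM reporting over fields of view), otherwise across
    traces.  ``bias_correct`` divides each trace's sample SD by the c4(n)
    factor so short traces do not systematically underestimate sigma.
    """
    if len(traces) < 2:
        raise ValidationError("need at least 2 traces")
    spreads = traces[["sd_x_nm", "sd_y_nm", "sd_z_nm"]].to_numpy(dtype=float)
    if bias_correct:
        spreads = spreads / _c4(traces["n_locs"].to_numpy())[:, None]
    if group_by_fov:
        fmeans = (
            pd.DataFrame(spreads, columns=["x", "y", "z"])
            .assign(fov=traces["fov_id"].to_numpy())
            .groupby("fov")
            .mean()
            .to_numpy()
        )
        mean = fmeans.mean(axis=0)
        sem = (fmeans.std(axis=0, ddof=1) / np.sqrt(len(fmeans))
               if len(fmeans) > 1 else np.zeros(3))
    else:
        mean = spreads.mean(axis=0)
        sem = spreads.std(axis=0, ddof=1) / np.sqrt(len(spreads))
    return ResolutionEstimate(tuple(mean), tuple(sem), len(traces))
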