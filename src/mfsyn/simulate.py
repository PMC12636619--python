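"""Seeded generators for every input the pipeline consumes, with ground truth.

The MINFLUX generator emulates the statistical structure of a two-color
localization experiment at synaptic boutons: molecules placed as Gaussian
clusters in a bouton-relative frame (cluster centers inside or at the
periphery of the active-zone ellipse), optional companion molecules of the
other color at a fixed mean distance, multi-localization traces with per-axis
Gaussian localization noise, a two-Gaussian DCR channel mixture, configurable
fractions of EFO/CFR contaminants outside the QC bounds, the axial
refractive-index distortion (raw z = true z / 0.7), and a matching confocal
bassoon image with one Gaussian punctum per bouton.

All generators are deterministic: the same configuration and seed produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import LOC_COLUMNS, ConfocalImage
from .optophys import FrapTrace, GluTrace
from .qc import CH_HIGH, CH_LOW

__all__ = [
    "MinfluxSimConfig", "GroundTruth", "simulate_minflux_fov",
    "simulate_frap", "GluSimParams", "simulate_iglusnfr",
]


@dataclass(frozen=True)
class MinfluxSimConfig:
    """Study-condition parameters of the MINFLUX generator.

    Defaults mirror the acquisition and analysis conditions the pipeline is
    built around: QC windows of 100-300 kHz EFO and 0-0.9 CFR, traces longer
    than 3 localizations, per-axis localization noise of (5.39, 5.14, 3.01) nm,
    DCR components near 0.25 and 0.60, a 500 x 200 nm active-zone ellipse,
    companion molecules at 22 nm, and the 1/0.7 axial distortion.
    """

    seed: int
    fov_id: str = "fov0"
    n_boutons: int = 4
    bouton_spacing_nm: float = 2000.0
    clusters_per_bouton: int = 3
    periphery_clusters_per_bouton: int = 0
    periphery_scale: float = 1.3       # elliptical radius of periphery centers
    periphery_max_radius_nm: float = 280.0  # periphery centers stay registrable
    inside_max_radius: float = 0.8     # max elliptical radius of inside centers
    min_center_separation_nm: float = 0.0   # 3D rejection-sampling distance
    molecules_per_cluster: int = 8
    cluster_sd_nm: float = 8.0
    cluster_center_z_sd_nm: float = 25.0
    cluster_channel: str = CH_HIGH
    companions_per_cluster: int = 2
    companion_distance_nm: float = 22.0
    background_molecules_per_bouton: int = 20  # split evenly between channels
    background_radius_nm: float = 280.0
    az_semi_major_nm: float = 250.0
    az_semi_minor_nm: float = 100.0
    trace_len_min: int = 3             # emitted lengths are > this bound
    trace_len_mean_extra: float = 4.0  # length = len_min + 1 + Poisson(extra)
    short_trace_fraction: float = 0.0  # stress mode: sub-threshold traces
    loc_sd_nm: tuple = (5.39, 5.14, 3.01)
    dcr_low: tuple = (0.25, 0.05)      # (mu, sigma) of the low-DCR fluorophore
    dcr_high: tuple = (0.60, 0.07)
    efo_log_mean: float = float(np.log(170_000.0))
    efo_log_sd: float = 0.15
    efo_bounds_hz: tuple = (100_000.0, 300_000.0)
    efo_contaminant_fraction: float = 0.05
    cfr_max: float = 0.9
    cfr_contaminant_fraction: float = 0.05
    z_distortion_factor: float = 1.0 / 0.7
    pixel_size_nm: float = 80.0
    punctum_sd_px: float = 3.0
    punctum_amplitude: float = 1000.0
    image_background: float = 10.0
    image_noise_sd: float = 1.0

    def __post_init__(self):
        fracs = (self.efo_contaminant_fraction, self.cfr_contaminant_fraction,
                 self.short_trace_fraction)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValidationError("fractions must lie in [0, 1]")
        if min(self.n_boutons, self.molecules_per_cluster) < 0:
            raise ValidationError("counts must be non-negative")
        if self.z_distortion_factor <= 0 or self.pixel_size_nm <= 0:
            raise ValidationError("factors and pixel size must be positive")
        if self.cluster_channel not in (CH_LOW, CH_HIGH):
            raise ValidationError(f"unknown cluster_channel {self.cluster_channel!r}")


@dataclass(frozen=True)
class GroundTruth:
    """True molecule/cluster/bouton geometry behind a simulated FOV.

    ``molecules`` has one row per emitted trace (tid equals mol_id):
    channel, true absolute and bouton-relative positions, owning bouton,
    cluster id (-1 for background) and companion flag.  ``clusters`` holds
    the planted cluster centers (bouton-relative) and their AZ-inside flag.
    """

    molecules: pd.DataFrame
    clusters: pd.DataFrame
    boutons: pd.DataFrame


def _sample_cluster_centers(rng, config):
    """Sample cluster centers for one bouton: inside centers uniform in the
    shrunk AZ ellipse, periphery centers on the scaled ellipse but kept
    within ``periphery_max_radius_nm`` of the bouton center (they represent
    clusters just outside the AZ boundary, still inside the analysis ball).
    A minimum pairwise 3D separation is enforced by rejection sampling so
    planted clusters are individually resolvable."""
    a, b = config.az_semi_major_nm, config.az_semi_minor_nm
    centers = []

    def admissible(candidate):
        if not config.min_center_separation_nm:
            return True
        return all(np.linalg.norm(candidate - c) >= config.min_center_separation_nm
                   for c in centers)

    def draw(kind):
        for _ in range(5000):
            if kind == "inside":
                theta = rng.uniform(0, 2 * np.pi)
                r = config.inside_max_radius * np.sqrt(rng.uniform())
                xy = np.array([a * r * np.cos(theta), b * r * np.sin(theta)])
            else:
                theta = rng.uniform(0, 2 * np.pi)
                xy = config.periphery_scale * np.array([a * np.cos(theta),
                                                        b * np.sin(theta)])
                if np.linalg.norm(xy) > config.periphery_max_radius_nm:
                    continue
            z = rng.normal(0, config.cluster_center_z_sd_nm)
            cand = np.array([xy[0], xy[1], z])
            if admissible(cand):
                return cand
        raise ValidationError(
            "could not place cluster centers with the requested separation")

    inside, periphery = [], []
    for _ in range(config.clusters_per_bouton):
        c = draw("inside")
        centers.append(c)
        inside.append(c)
    for _ in range(config.periphery_clusters_per_bouton):
        c = draw("periphery")
        centers.append(c)
        periphery.append(c)
    return inside, periphery


def simulate_minflux_fov(config: MinfluxSimConfig):
    """Generate one field of view: (localization table, confocal image, truth)."""
    rng = np.random.default_rng(config.seed)
    a, b = config.az_semi_major_nm, config.az_semi_minor_nm

    # bouton centers on a jittered grid, comfortably inside the image
    side = int(np.ceil(np.sqrt(config.n_boutons)))
    bx, by = [], []
    for i in range(config.n_boutons):
        gx, gy = i % side, i // side
        bx.append((gx + 1) * config.bouton_spacing_nm + rng.uniform(-100, 100))
        by.append((gy + 1) * config.bouton_spacing_nm + rng.uniform(-100, 100))
    boutons = pd.DataFrame({"bouton_id": np.arange(config.n_boutons),
                            "x_nm": bx, "y_nm": by})

    mol_rows, clu_rows = [], []
    other = CH_LOW if config.cluster_channel == CH_HIGH else CH_HIGH
    cluster_id = 0
    for bid in range(config.n_boutons):
        inside_centers, periphery_centers = _sample_cluster_centers(rng, config)
        all_centers = inside_centers + periphery_centers
        inside_flags = [True] * len(inside_centers) + [False] * len(periphery_centers)
        for (cx, cy, cz), is_in in zip(all_centers, inside_flags):
            members = np.column_stack([
                rng.normal(cx, config.cluster_sd_nm, config.molecules_per_cluster),
                rng.normal(cy, config.cluster_sd_nm, config.molecules_per_cluster),
                rng.normal(cz, config.cluster_sd_nm, config.molecules_per_cluster),
            ])
            for m in members:
                mol_rows.append((bid, cluster_id, config.cluster_channel, False, *m))
            n_comp = min(config.companions_per_cluster, len(members))
            if n_comp:
                picks = rng.choice(len(members), size=n_comp, replace=False)
                for p in picks:
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    comp = members[p] + config.companion_distance_nm * u
                    mol_rows.append((bid, cluster_id, other, True, *comp))
            clu_rows.append({"cluster_id": cluster_id, "bouton_id": bid,
                             "x_nm": cx, "y_nm": cy, "z_nm": cz,
                             "az_inside": is_in,
                             "channel": config.cluster_channel})
            cluster_id += 1
        # diffuse background molecules, both channels
        n_bg = config.background_molecules_per_bouton
        for k in range(n_bg):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = config.background_radius_nm * rng.uniform(0, 1) ** (1 / 3)
            ch = config.cluster_channel if k % 2 == 0 else other
            mol_rows.append((bid, -1, ch, False, *(r * u)))

    molecules = pd.DataFrame(
        mol_rows, columns=["bouton_id", "cluster_id", "channel", "is_companion",
                           "rel_x_nm", "rel_y_nm", "rel_z_nm"])
    molecules.insert(0, "mol_id", np.arange(len(molecules)))
    bc = boutons.set_index("bouton_id")
    molecules["x_nm"] = molecules["rel_x_nm"] + bc.loc[molecules["bouton_id"], "x_nm"].to_numpy()
    molecules["y_nm"] = molecules["rel_y_nm"] + bc.loc[molecules["bouton_id"], "y_nm"].to_numpy()
    molecules["z_nm"] = molecules["rel_z_nm"]

    # emit one trace per molecule
    recs = []
    sx, sy, sz = config.loc_sd_nm
    lo, hi = config.efo_bounds_hz
    for mol in molecules.itertuples(index=False):
        if config.short_trace_fraction and rng.uniform() < config.short_trace_fraction:
            length = int(rng.integers(1, config.trace_len_min + 1))
        else:
            length = config.trace_len_min + 1 + int(rng.poisson(config.trace_len_mean_extra))
        mu, sig = config.dcr_low if mol.channel == CH_LOW else config.dcr_high
        for j in range(length):
            x = mol.x_nm + rng.normal(0, sx)
            y = mol.y_nm + rng.normal(0, sy)
            z = (mol.z_nm + rng.normal(0, sz)) * config.z_distortion_factor
            if rng.uniform() < config.efo_contaminant_fraction:
                efo = (rng.uniform(0.3 * lo, 0.99 * lo) if rng.uniform() < 0.5
                       else rng.uniform(1.01 * hi, 2.0 * hi))
            else:
                efo = float(np.clip(rng.lognormal(config.efo_log_mean, config.efo_log_sd),
                                    lo, hi))
            if rng.uniform() < config.cfr_contaminant_fraction:
                cfr = rng.uniform(1.001 * config.cfr_max, 1.5)
            else:
                cfr = config.cfr_max * rng.beta(2.0, 5.0)
            dcr = float(np.clip(rng.normal(mu, sig), 0.0, 1.0))
            recs.append((config.fov_id, mol.mol_id, 0.001 * len(recs),
                         x, y, z, efo, cfr, dcr))
    table = pd.DataFrame(recs, columns=LOC_COLUMNS)
    table["tid"] = table["tid"].astype(np.int64)

    # confocal bassoon image: one Gaussian punctum per bouton
    px = config.pixel_size_nm
    extent = (np.array(bx + by).max() if config.n_boutons else 0) + config.bouton_spacing_nm
    n_px = int(np.ceil(extent / px))
    rr, cc = np.mgrid[0:n_px, 0:n_px]
    img = np.full((n_px, n_px), config.image_background, dtype=float)
    for x0, y0 in zip(bx, by):
        c0, r0 = x0 / px - 0.5, y0 / px - 0.5
        img += config.punctum_amplitude * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * config.punctum_sd_px ** 2))
    img += rng.normal(0, config.image_noise_sd, img.shape)
    img = np.clip(img, 0, None)
    image = ConfocalImage(img, px, config.fov_id)

    clusters = pd.DataFrame(clu_rows, columns=["cluster_id", "bouton_id", "x_nm",
                                               "y_nm", "z_nm", "az_inside", "channel"])
    return table, image, GroundTruth(molecules, clusters, boutons)


def simulate_frap(r_percent: float, t_half_s: float, noise_sd: float = 0.0,
                  n_frames: int = 100, seed: int = 0, f0: float = 0.0,
                  frame_interval_s: float = 4.0, pre_bleach_s: float = 20.0,
                  readout_delay_s: float = 1e-3) -> FrapTrace:
    """Raw FRAP channels whose normalization is the hyperbolic model + noise.

    The first post-bleach frame is read out ``readout_delay_s`` after the
    bleach (essentially at the recovery floor); later frames follow at
    ``frame_interval_s`` (15 frames per minute by default).
    """
    if t_half_s <= 0:
        raise ValidationError("t_half must be positive")
    rng = np.random.default_rng(seed)
    n_pre = int(pre_bleach_s / frame_interval_s)
    t_pre = np.arange(n_pre) * frame_interval_s
    t_post = pre_bleach_s + readout_delay_s + np.arange(n_frames) * frame_interval_s
    times = np.concatenate([t_pre, t_post])

    tp = t_post - pre_bleach_s
    model = f0 + (r_percent / 100.0 - f0) * tp / (t_half_s + tp)
    normalized = np.concatenate([np.ones(n_pre), model])
    if noise_sd > 0:
        normalized = normalized + rng.normal(0, noise_sd, len(normalized))

    background = np.full(len(times), 100.0)
    nonbleached = np.full(len(times), 1100.0)
    bleach = background + normalized * (nonbleached - background)
    return FrapTrace(times, bleach, nonbleached, background, pre_bleach_s)


@dataclass(frozen=True)
class GluSimParams:
    """Release-train parameters for the iGluSnFR generator.

    ``amplitudes`` is the per-AP dF/F0 transient amplitude (before noise) and
    ``release_p`` the per-AP release probability.  The sensor transient decays
    exponentially with ``tau_s`` (10 ms, a fast-variant decay, so 50 ms
    inter-stimulus intervals carry negligible residual).
    """

    amplitudes: tuple
    release_p: tuple
    stim_freq_hz: float = 20.0
    first_stim_s: float = 0.5
    tau_s: float = 0.010
    noise_sd: float = 0.01
    rate_hz: float = 100.0
    n_frames: int = 350

    def __post_init__(self):
        if len(self.amplitudes) != len(self.release_p):
            raise ValidationError("amplitudes and release_p must have equal length")
        if any(not 0 <= p <= 1 for p in self.release_p):
            raise ValidationError("release probabilities must lie in [0, 1]")


def _preset_params(preset: str) -> GluSimParams:
    if preset == "facilitating":
        # paired-pulse protocol; facilitation ratio 1.24 before noise
        return GluSimParams(amplitudes=(1.0, 1.24), release_p=(1.0, 1.0))
    if preset == "depressing":
        # 50-AP 20 Hz train decaying to a steady per-AP amplitude
        k = np.arange(50)
        amps = tuple(0.2 + 0.8 * np.exp(-k / 5.0))
        return GluSimParams(amplitudes=amps, release_p=(1.0,) * 50)
    raise ValidationError(f"unknown preset {preset!r}")


def simulate_iglusnfr(preset: str = "facilitating", params: GluSimParams | None = None,
                      n_rois: int = 1, seed: int = 0):
    """Simulate per-ROI dF/F0 traces for a stimulus train.

    Returns ``(traces, truth)`` where truth is a DataFrame with one row per
    (roi, ap): release indicator and the amplitude actually deposited.
    """
    p = params if params is not None else _preset_params(preset)
    rng = np.random.default_rng(seed)
    dt = 1.0 / p.rate_hz
    times = np.arange(p.n_frames) * dt
    stim_times = p.first_stim_s + np.arange(len(p.amplitudes)) / p.stim_freq_hz

    traces, truth_rows = [], []
    for roi in range(n_rois):
        y = np.zeros(p.n_frames)
        for ap, (amp, prob, ts) in enumerate(zip(p.amplitudes, p.release_p, stim_times)):
            released = bool(rng.uniform() < prob)
            if released:
                mask = times >= ts
                y[mask] += amp * np.exp(-(times[mask] - ts) / p.tau_s)
            truth_rows.append({"roi": roi, "ap": ap, "released": released,
                               "amplitude": amp if released else 0.0})
        if p.noise_sd > 0:
            y = y + rng.normal(0, p.noise_sd, p.n_frames)
        traces.append(GluTrace(y, times, stim_times, baseline_window_s=p.first_stim_s))
    return traces, pd.DataFrame(truth_rows)


def nnd_recovery_config(seed: int) -> MinfluxSimConfig:
    """Configuration for the planted-companion NND study: isolated molecule
    pairs 22 nm apart (single-molecule "clusters", each with one companion of
    the other color), plus diffuse background molecules of both channels so
    the NND histogram carries both the short pair component and the long
    random-proximity component."""
    # ~6 other-channel molecules in the 280 nm analysis ball put the
    # random-proximity NND component near 150 nm
    return MinfluxSimConfig(
        seed=seed, n_boutons=20, clusters_per_bouton=4,
        molecules_per_cluster=1, companions_per_cluster=1,
        az_semi_major_nm=250.0, az_semi_minor_nm=250.0, inside_max_radius=1.0,
        cluster_center_z_sd_nm=50.0, min_center_separation_nm=100.0,
        background_molecules_per_bouton=4,
        loc_sd_nm=(5.0, 5.0, 3.0),
    )


def az_geometry_config(seed: int) -> MinfluxSimConfig:
    """Configuration planting 12 clusters per FOV (11 inside the active-zone
    ellipse, 1 at 1.3x the elliptical radius) for the end-to-end
    classification study."""
    return MinfluxSimConfig(
        seed=seed, n_boutons=1, clusters_per_bouton=11,
        periphery_clusters_per_bouton=1, periphery_scale=1.3,
        molecules_per_cluster=8, companions_per_cluster=0,
        background_molecules_per_bouton=10,
        cluster_sd_nm=6.0, cluster_center_z_sd_nm=40.0,
        min_center_separation_nm=70.0,
    )
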