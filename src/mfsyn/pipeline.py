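"""Orchestration of the canonical MINFLUX analysis stage order.

``run_minflux_pipeline`` executes, with bookkeeping at every stage:
QC filter -> trace-length filter -> DCR unmix -> Z correction -> trace
aggregation -> resolution estimate -> bassoon centroid detection ->
registration -> FOV merge -> cross-channel NND + two-Gaussian fits ->
DBSCAN -> active-zone classification.  The report is a plain dict that
serializes to JSON deterministically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import clustering, nnd, qc, registration
from .errors import MfsynError, StageError, ValidationError
from .io import ConfocalImage, read_confocal, read_localizations


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters in one validated bundle (defaults are the
    standard analysis values; see each module for their meaning)."""

    thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    ambiguity_odds: float = 1.0
    dcr_init: tuple | None = None
    channel_map: dict | None = None
    z_factor: float = 0.7
    nnd_bin_nm: float = 10.0
    pixel_size_nm: float = 80.0
    puncta_radius_px: tuple = (3.0, 20.0)
    puncta_overlap_thr: float = 0.75
    puncta_ecc_max: float = 0.9375
    centroid_z_nm: float = 0.0
    max_radius_nm: float = 300.0
    registration_cut: str = "trace"  # or "cluster"
    cluster_params: clustering.ClusterParams = field(default_factory=clustering.ClusterParams)
    az_ellipse: clustering.AZEllipse = field(default_factory=clustering.AZEllipse)

    def __post_init__(self):
        if self.z_factor <= 0:
            raise ValidationError("z_factor must be positive")
        if self.nnd_bin_nm <= 0:
            raise ValidationError("nnd_bin_nm must be positive")
        if self.registration_cut not in ("trace", "cluster"):
            raise ValidationError("registration_cut must be 'trace' or 'cluster'")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "thresholds" in d:
            d["thresholds"] = qc.QCThresholds(**d["thresholds"])
        if "cluster_params" in d:
            d["cluster_params"] = clustering.ClusterParams(**d["cluster_params"])
        if "az_ellipse" in d:
            d["az_ellipse"] = clustering.AZEllipse(**d["az_ellipse"])
        for key in ("dcr_init", "puncta_radius_px"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _stage(name):
    """Wrap stage exceptions with the stage name for a clean abort."""
    class _Ctx:
        def __enter__(self):
            return None

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, MfsynError) and not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            return False
    return _Ctx()


def run_minflux_pipeline(tables, images, config: PipelineConfig = PipelineConfig()):
    """Run the full chain over per-FOV localization tables and confocal images.

    Parameters
    ----------
    tables
        list of localization DataFrames (or CSV paths), one per FOV.
    images
        list of :class:`ConfocalImage` (or TIFF paths), matched to ``tables``.

    Returns
    -------
    (report, artifacts)
        ``report`` is a JSON-serializable dict of per-stage counts, fits and
        the cluster table; ``artifacts`` holds the intermediate DataFrames
        (merged registered traces, cluster summaries, NND results).
    """
    tables = [read_localizations(t) if not isinstance(t, pd.DataFrame) else t
              for t in tables]
    images = [img if isinstance(img, ConfocalImage)
              else read_confocal(img, config.pixel_size_nm) for img in images]
    if len(tables) != len(images):
        raise ValidationError("need one confocal image per localization table")

    report = {"stages": {}, "parameters": _param_dict(config)}
    registered_fovs = []
    all_traces = []
    dropped_total = 0

    for table, image in zip(tables, images):
        fov = str(table["fov_id"].iloc[0]) if len(table) else image.fov_id
        stages = {}

        with _stage("qc_filter"):
            res = qc.filter_records(table, config.thresholds)
        stages["qc_filter"] = {"input": res.n_input, "retained": res.n_retained,
                               "rejected": res.rejected}

        with _stage("trace_length"):
            kept = qc.filter_trace_length(res.table, config.thresholds.len_min)
        stages["trace_length"] = {"input": res.n_retained, "retained": len(kept)}

        with _stage("unmix"):
            mix = qc.fit_dcr_mixture(kept["dcr"].to_numpy(), init=config.dcr_init,
                                     channel_map=config.channel_map)
            labeled, discarded = qc.assign_channels(kept, mix, config.ambiguity_odds)
        stages["unmix"] = {
            "mixture": {"w1": mix.w1, "w2": mix.w2, "mu1": mix.mu1, "mu2": mix.mu2,
                        "sigma1": mix.sigma1, "sigma2": mix.sigma2,
                        "boundary": mix.boundary},
            "labeled": len(labeled), "discarded": len(discarded),
        }

        with _stage("z_correction"):
            corrected = qc.correct_z(labeled, config.z_factor)

        with _stage("aggregate"):
            if len(corrected) == 0:
                raise StageError("aggregate", "no records left to aggregate")
            traces = qc.aggregate_traces(corrected)
        stages["aggregate"] = {"n_traces": len(traces)}
        all_traces.append(traces)

        with _stage("centroids"):
            puncta = registration.detect_puncta(
                image, config.puncta_radius_px, config.puncta_overlap_thr,
                config.puncta_ecc_max)
        stages["centroids"] = {"n_puncta": len(puncta)}

        with _stage("register"):
            max_r = np.inf if config.registration_cut == "cluster" else config.max_radius_nm
            reg = registration.register_to_centroids(
                traces, puncta, config.centroid_z_nm, max_r)
        stages["register"] = {"input": reg.n_input, "retained": len(reg.retained),
                              "dropped": len(reg.dropped)}
        registered_fovs.append(reg.retained)
        dropped_total += len(reg.dropped)

        report["stages"][fov] = stages

    with _stage("merge"):
        merged = registration.merge_fovs(registered_fovs)
    report["merge"] = {"n_traces": len(merged), "n_dropped": dropped_total}

    with _stage("resolution"):
        pooled = pd.concat(all_traces, ignore_index=True)
        est = qc.estimate_resolution(pooled, group_by_fov=len(tables) > 1)
    report["resolution_nm"] = {"mean": list(est.mean_nm), "sem": list(est.sem_nm),
                               "n_traces": est.n_traces}

    # cross-channel NND, both directions, on the merged bouton-relative cloud
    report["nnd"] = {}
    nnd_results = {}
    channels = sorted(merged["channel"].unique()) if len(merged) else []
    if len(channels) == 2:
        pos = {ch: merged.loc[merged["channel"] == ch,
                              ["rel_x_nm", "rel_y_nm", "rel_z_nm"]].to_numpy()
               for ch in channels}
        for src, tgt in ((channels[0], channels[1]), (channels[1], channels[0])):
            key = f"{src}->{tgt}"
            res = nnd.nearest_neighbor_distances(pos[src], pos[tgt], src, tgt)
            nnd_results[key] = res
            entry = {"n_source": res.n_source,
                     "median_nm": float(np.median(res.distances))}
            try:
                fit = nnd.fit_nnd_histogram(res, config.nnd_bin_nm)
                entry["fit"] = {"a1": fit.a1, "m1": fit.m1, "s1": fit.s1,
                                "a2": fit.a2, "m2": fit.m2, "s2": fit.s2,
                                "fallback": fit.fallback}
            except MfsynError as exc:
                entry["fit"] = None
                entry["fit_skipped"] = str(exc)
            report["nnd"][key] = entry

    # DBSCAN per channel + AZ classification
    cluster_tables = {}
    report["clusters"] = {}
    for ch in channels:
        sub = merged[merged["channel"] == ch].reset_index(drop=True)
        pts = sub[["rel_x_nm", "rel_y_nm", "rel_z_nm"]].to_numpy()
        labels = clustering.dbscan(pts, config.cluster_params)
        summary = clustering.summarize_clusters(labels, sub)
        if config.registration_cut == "cluster" and len(summary):
            r = np.sqrt(summary["x_nm"] ** 2 + summary["y_nm"] ** 2 + summary["z_nm"] ** 2)
            summary = summary[r <= config.max_radius_nm].reset_index(drop=True)
        az_labels, counts = clustering.classify_az(summary, config.az_ellipse)
        summary = summary.assign(az=az_labels)
        cluster_tables[ch] = summary
        report["clusters"][ch] = {
            "n_clusters": len(summary),
            "n_noise": int((labels == clustering.NOISE).sum()),
            "az_counts": counts,
            "table": summary.to_dict(orient="records"),
        }

    artifacts = {"merged": merged, "traces": pooled, "nnd": nnd_results,
                 "clusters": cluster_tables}
    return report, artifacts


def _param_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    for k, v in list(d.items()):
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialization of a pipeline report."""
    return json.dumps(report, sort_keys=True, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
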