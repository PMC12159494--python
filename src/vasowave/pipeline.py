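"""End-to-end resting-state and stimulation analyses.

``run_resting`` drives every resting-state stage over one or more
groups of scans: fALFF maps and ROI tables, static FC with group Δ
matrices, group-covariance PCA, wave-event detection with
dynamic/static summaries, trajectory-pattern proportions, and dynamic
seed connectivity.  ``run_stim`` block-averages stimulation sessions.
Both write CSV/JSON artefacts plus a manifest recording the
configuration and seed; reruns with the same manifest are
deterministic.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import AcquisitionSpec, BandSpec, Movie, WIDE_BAND, WAVE_BAND
from .atlas import RoiAtlas, build_atlas
from .preproc import bandpass_movie, percent_change, roi_timecourses
from .spectral import SpectralConfig, falff_map
from .connectivity import static_fc, fc_difference, dynamic_seed_fc
from .pca import PcaConfig, preprocess_for_pca, group_mean_covariance, eigenmodes, project_and_spectra
from .events import DetectorConfig, robust_zscore, smooth_z, detect_events, event_features, classify_dynamic, summarize_scan
from .patterns import ClusterConfig, build_delay_features, cluster_patterns, label_patterns, pattern_frequencies
from .synth import StimulusProtocol, simulate_cohort

log = logging.getLogger("vasowave")

__all__ = ["PipelineConfig", "run_resting", "run_stim", "analyse_scan_events"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    seed: int
    wide_band: BandSpec = WIDE_BAND
    wave_band: BandSpec = WAVE_BAND
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    pca: PcaConfig = field(default_factory=PcaConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    protocol: StimulusProtocol | None = None
    seed_roi: str = "PrimVisCtx"
    target_roi: str = "PrimVisCtx"

    def manifest(self) -> dict:
        return {
            "version": __version__,
            "seed": self.seed,
            "wide_band": [self.wide_band.low, self.wide_band.high],
            "wave_band": [self.wave_band.low, self.wave_band.high],
            "detector": {
                "z_threshold": self.detector.z_threshold,
                "min_size_px": self.detector.min_size_px,
                "smoothing_sigma_px": self.detector.smoothing_sigma_px,
                "dynamic_threshold_px": self.detector.dynamic_threshold_px,
            },
            "pca": {
                "eigenvalue_min": self.pca.eigenvalue_min,
                "n_display": self.pca.n_display,
            },
            "spectral": {
                "falff_map_threshold": self.spectral.falff_map_threshold,
            },
            "cluster": {
                "k_spatial": self.cluster.k_spatial,
                "svd_components": self.cluster.svd_components,
                "seed": self.cluster.seed,
            },
        }


def _stage(name: str):
    """Log one pipeline stage with timing; re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s: FAILED after %.1fs: %s", name, dt, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, dt)
            return False

    return _Ctx()


def analyse_scan_events(
    movie: Movie,
    atlas: RoiAtlas,
    detector: DetectorConfig = DetectorConfig(),
):
    """Wave-band event analysis of one scan: detect, feature, classify.

    Returns ``(events, summary)``; the raw movie is used as the noise
    source for the z-scoring and for the ΔCBV% amplitudes.
    """
    band = bandpass_movie(movie, detector.band)
    z, _sd = robust_zscore(band, noise_source=movie)
    del band
    z_s = smooth_z(z, detector)
    events = detect_events(z, detector, z_smoothed=z_s)
    del z
    pct = percent_change(movie)
    for ev in events:
        event_features(ev, pct, z_s, movie.spec)
        classify_dynamic(ev, detector)
    return events, summarize_scan(events, detector)


def events_table(events, labels=None) -> pd.DataFrame:
    rows = []
    for i, ev in enumerate(events):
        rows.append(
            {
                "event_id": ev.event_id,
                "t_start": ev.t_start,
                "t_end": ev.t_end,
                "duration_s": ev.duration_s,
                "peak_z": ev.peak_z,
                "peak_amplitude_pct": ev.peak_amplitude_pct,
                "propagation_px": ev.propagation_px,
                "propagation_mm": ev.propagation_mm,
                "speed_mm_s": ev.speed_mm_s,
                "dynamic": ev.dynamic,
                "area_px": ev.n_px_union,
                "pattern": labels[i].value if labels is not None else None,
            }
        )
    return pd.DataFrame(rows)


def run_resting(
    groups: dict[str, list[Movie]],
    atlas: RoiAtlas,
    config: PipelineConfig,
) -> dict:
    """Full resting-state analysis over named groups of scans.

    Writes per-scan fALFF tables, group FC and Δ matrices, PCA
    eigenvalue/explained tables, event feature CSVs, per-scan
    summaries, pattern proportions, dynamic seed-FC traces, and a run
    manifest.  Returns the collected results in memory as well.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not groups or any(len(v) < 1 for v in groups.values()):
        raise ValueError("need at least one scan per declared group")
    results: dict = {"groups": {}}

    falff_rows = []
    fc_by_group: dict[str, list] = {}
    summaries = []
    labels_per_scan: dict[str, list] = {}
    dyn_traces = {}

    for gname, movies in groups.items():
        gres: dict = {}
        fc_by_group[gname] = []
        all_events_g = []
        with _stage(f"{gname}:falff"):
            for i, m in enumerate(movies):
                _fmap, roi_f, _mask = falff_map(m, atlas, config.spectral)
                for rid, v in roi_f.items():
                    falff_rows.append(
                        {
                            "group": gname,
                            "scan": f"{gname}_{i}",
                            "roi": atlas.names[rid],
                            "hemisphere": atlas.hemisphere[rid],
                            "falff": v,
                        }
                    )
        with _stage(f"{gname}:static_fc"):
            for m in movies:
                wide = bandpass_movie(m, config.pca.band)
                fc_by_group[gname].append(static_fc(roi_timecourses(wide, atlas)))
                del wide
        with _stage(f"{gname}:pca"):
            pre = preprocess_for_pca(movies, config.pca.band)
            cov = group_mean_covariance(pre)
            modes = eigenmodes(cov, config.pca, image_shape=atlas.shape)
            modes = project_and_spectra(pre, modes, movies[0].spec.dt)
            del pre, cov
            gres["pca_explained"] = modes.explained
            gres["pca_cum10"] = modes.explained_at(10)
            gres["pca_n_retained"] = modes.n_retained
        with _stage(f"{gname}:events"):
            for i, m in enumerate(movies):
                events, summary = analyse_scan_events(m, atlas, config.detector)
                summary.update({"group": gname, "scan": f"{gname}_{i}"})
                summaries.append(summary)
                labs = label_patterns(events, atlas, m.spec.dt)
                labels_per_scan[f"{gname}_{i}"] = labs
                all_events_g.append((f"{gname}_{i}", events, labs))
        with _stage(f"{gname}:dynamic_fc"):
            m = movies[0]
            band = bandpass_movie(m, config.wave_band)
            seed_id = atlas.id_of(config.seed_roi, "right")
            target_id = atlas.id_of(config.target_roi, "left")
            trace = dynamic_seed_fc(band, atlas, seed_id, target_id)
            dyn_traces[gname] = trace
            trace.to_frame().to_csv(out / f"dynamic_fc_{gname}.csv", index=False)
            del band
        ev_tables = [
            events_table(evs, labs).assign(scan=sname)
            for sname, evs, labs in all_events_g
        ]
        if ev_tables:
            pd.concat(ev_tables, ignore_index=True).to_csv(
                out / f"events_{gname}.csv", index=False
            )
        results["groups"][gname] = gres

    pd.DataFrame(falff_rows).to_csv(out / "falff_roi.csv", index=False)
    pd.DataFrame(summaries).to_csv(out / "event_summaries.csv", index=False)
    freq = pattern_frequencies(labels_per_scan)
    freq.to_csv(out / "pattern_proportions.csv", index=False)

    gnames = list(groups)
    for g in gnames:
        pd.concat([fc.to_frame().assign(scan=i) for i, fc in enumerate(fc_by_group[g])]).to_csv(
            out / f"fc_{g}.csv", index=False
        )
    if len(gnames) >= 2:
        ref = gnames[0]
        for g in gnames[1:]:
            dz, dr = fc_difference(fc_by_group[g], fc_by_group[ref])
            labels = fc_by_group[ref][0].labels
            rows = []
            for a in range(len(labels)):
                for b in range(a + 1, len(labels)):
                    rows.append(
                        {"roi_a": labels[a], "roi_b": labels[b],
                         "dz": dz[a, b], "dr": dr[a, b]}
                    )
            pd.DataFrame(rows).to_csv(out / f"fc_diff_{g}_vs_{ref}.csv", index=False)
            results[f"fc_diff_{g}_vs_{ref}"] = dz

    results["falff"] = pd.DataFrame(falff_rows)
    results["summaries"] = pd.DataFrame(summaries)
    results["pattern_frequencies"] = freq
    results["fc_by_group"] = fc_by_group
    results["dynamic_traces"] = dyn_traces
    (out / "manifest.json").write_text(json.dumps(config.manifest(), indent=1))
    return results


def run_stim(
    movies: list[Movie],
    atlas: RoiAtlas,
    protocol: StimulusProtocol,
    config: PipelineConfig,
    rois: list[str] | None = None,
) -> dict:
    """Stimulation analysis: block-averaged ΔCBV% responses per ROI.

    ΔCBV% is computed against the initial pre-stimulus rest period;
    the four block time courses are aligned on block onset and
    averaged.  The scalar response per scan/ROI is the mean ΔCBV%
    during the stimulation epochs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rois = rois or ["PrimVisCtx", "SuperiorColl"]
    n_needed = int(round(protocol.total_duration_s / movies[0].spec.dt))
    if n_needed > movies[0].n_frames:
        raise ValueError("stimulation protocol exceeds the record")

    epochs = protocol.stim_epochs(movies[0].spec.dt)
    block_len = epochs[0][1] - epochs[0][0]
    rows = []
    block_curves: dict[str, list[np.ndarray]] = {}
    for i, m in enumerate(movies):
        pct = percent_change(m, baseline=protocol.baseline_frames(m.spec.dt))
        tcs = roi_timecourses(pct, atlas)
        for rid in tcs.ids():
            name = atlas.names[rid]
            if name not in rois:
                continue
            series = tcs.series[rid]
            blocks = np.stack([series[s : s + block_len] for s, _ in epochs])
            mean_block = blocks.mean(axis=0)
            scalar = float(np.mean([series[s:e].mean() for s, e in epochs]))
            rows.append(
                {"scan": i, "roi": name, "hemisphere": atlas.hemisphere[rid],
                 "response_pct": scalar}
            )
            block_curves.setdefault(f"{name}_{atlas.hemisphere[rid]}", []).append(mean_block)

    table = pd.DataFrame(rows)
    table.to_csv(out / "stim_responses.csv", index=False)
    curves = {
        k: np.mean(v, axis=0) for k, v in block_curves.items()
    }
    curve_df = pd.DataFrame(
        {"time_s": np.arange(block_len) * movies[0].spec.dt, **curves}
    )
    curve_df.to_csv(out / "stim_block_curves.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(config.manifest(), indent=1))
    return {"responses": table, "block_curves": curve_df}


def demo(
    out_dir: Path,
    seed: int = 0,
    n_scans: int = 3,
    height: int = 64,
    width: int = 64,
    n_frames: int = 1500,
) -> dict:
    """Simulate a two-arm cohort and run the full resting analysis."""
    spec = AcquisitionSpec(height, width, n_frames)
    atlas = build_atlas(spec)
    groups = {}
    for arm_i, arm in enumerate(("VEH", "LPS")):
        scans = simulate_cohort(arm, n_scans, spec, seed=seed + 1000 * arm_i, atlas=atlas)
        groups[arm] = [m for m, _gt in scans]
    config = PipelineConfig(out_dir=Path(out_dir), seed=seed)
    return run_resting(groups, atlas, config)
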