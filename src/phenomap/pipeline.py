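"""End-to-end orchestration of the synthetic and analysis stages.

``run_pipeline`` executes the enabled stages in dependency order
(synth -> sleep -> photometry; synth -> histology -> brain map), writes every
artifact under the output directory, and returns a :class:`dict` run report
whose numeric content is a pure function of the configuration and seeds.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import __version__, io
from .brainmap import normalize_and_downsample, render_map, roi_group_stats
from .histoquant import cluster_density, measure_filter_bin, segment_clusters
from .photometry import align_to_epochs, compare_states, preprocess_trace
from .sleepsig import build_signal_grid, detect_rbd_events, score_stages, summarize_sleep
from .synthdata import (
    SynthGroupSeriesConfig,
    SynthImageConfig,
    SynthPhotometryConfig,
    SynthSleepConfig,
    generate_group_sections,
    generate_photometry,
    generate_polysomnogram,
    generate_section_image,
    random_disk_specs,
)


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Missing or inconsistent input data (CLI exit code 3)."""


def demo_config(seed: int = 0) -> dict:
    """Small all-synthetic configuration exercising every stage."""
    return {
        "seed": seed,
        "sleep": {
            "duration_s": 7200.0,
            "rate_hz": 500.0,
            "epoch_s": 20.0,
            "rbd_fraction": 0.2,
            "baseline_mode": "mean2sd",
        },
        "photometry": {"zwin_s": 60.0, "target_hz": 500.0},
        "histology": {"shape": [256, 256], "percentile": 95.0,
                      "pixel_area_um2": 6.25},
        "brainmap": {
            "group_sizes": {"control": 4, "early": 4, "late": 4},
            "grid_shape": [12, 12],
            "effect_blocks": [[3, 7, 3, 7]],
            "effect_d": 2.0,
            "alpha": 0.05,
            "fdr": False,
            "render": False,
        },
    }


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the configured stages on synthetic inputs and write all artifacts.

    Returns the run report (also written to ``report.json``); reports from
    identical configs and seeds are numerically identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "seed" not in config:
        raise ConfigError("config must carry a top-level seed")
    seed = int(config["seed"])
    report: dict = {"version": __version__, "seed": seed, "config": config,
                    "warnings": [], "outputs": {}}

    # --- sleep + RBD --------------------------------------------------------
    if "sleep" in config:
        c = config["sleep"]
        scfg = SynthSleepConfig(
            duration_s=float(c.get("duration_s", 7200.0)),
            rate_hz=float(c.get("rate_hz", 500.0)),
            epoch_s=float(c.get("epoch_s", 20.0)),
            rbd_fraction=float(c.get("rbd_fraction", 0.05)),
            seed=seed,
        )
        rec, truth = generate_polysomnogram(scfg)
        grid = build_signal_grid(rec, epoch_s=scfg.epoch_s)
        grid = score_stages(grid)
        grid, events = detect_rbd_events(grid, mode=c.get("baseline_mode", "mean2sd"))
        summary = summarize_sleep(grid, events)
        accuracy = float(np.mean(grid.stage == truth.stages))
        io.write_epoch_grid_csv(grid, out / "epoch_grid.csv")
        io.write_json(summary.to_dict(), out / "sleep_summary.json")
        report["sleep"] = {
            "n_epochs": len(grid),
            "stage_accuracy_vs_truth": accuracy,
            "n_rbd_events": summary.n_rbd_events,
            "rbd_per_rem_pct": summary.rbd_per_rem_pct,
            "pct_time": summary.pct_time,
            "excluded": summary.excluded,
        }
        if summary.excluded:
            report["warnings"].append(f"sleep: {summary.exclusion_reason}")
        report["outputs"]["epoch_grid"] = "epoch_grid.csv"
        report["outputs"]["sleep_summary"] = "sleep_summary.json"

        # --- photometry (needs the stage truth) ----------------------------
        if "photometry" in config:
            pc = config["photometry"]
            pcfg = SynthPhotometryConfig(seed=seed + 1)
            session = generate_photometry(pcfg, truth)
            session = preprocess_trace(
                session,
                target_hz=float(pc.get("target_hz", 500.0)),
                zwin_s=float(pc.get("zwin_s", 60.0)),
            )
            aligned = align_to_epochs(session, grid)
            if pc.get("write_traces", False):  # full z-trace is large
                io.write_photometry_csv(session, out / "photometry_z.csv")
                report["outputs"]["photometry_z"] = "photometry_z.csv"
            aligned.per_epoch.to_csv(out / "photometry_epochs.csv", index=False)
            comparisons = {}
            if aligned.state_n.get("RBD", 0) >= 2 and aligned.state_n.get("REM", 0) >= 2:
                # single-animal demo: report state aggregates only
                comparisons = {
                    ch: {st: m for st, m in means.items()}
                    for ch, means in aligned.state_means.items()
                }
            report["photometry"] = {
                "state_n": aligned.state_n,
                "state_means": comparisons or aligned.state_means,
                "degenerate_windows": len(session.degenerate_windows),
            }
            report["outputs"]["photometry_epochs"] = "photometry_epochs.csv"

    # --- histology ----------------------------------------------------------
    if "histology" in config:
        hc = config["histology"]
        rng = np.random.default_rng(seed + 2)
        shape = tuple(hc.get("shape", [256, 256]))
        icfg = SynthImageConfig(
            shape=shape,
            pixel_area_um2=float(hc.get("pixel_area_um2", 6.25)),
            clusters=random_disk_specs(rng, shape),
            seed=seed + 2,
        )
        img, truth_clusters = generate_section_image(icfg)
        labels = segment_clusters(img, percentile=float(hc.get("percentile", 95.0)))
        table = measure_filter_bin(labels, img)
        summary = cluster_density(table, img)
        io.write_section_tiff(img, out / "section.tif")
        table.to_csv(out / "clusters.csv", index=False)
        io.write_json(summary.to_dict(), out / "cluster_summary.json")
        report["histology"] = {
            "n_truth_clusters": len(truth_clusters),
            "counts": summary.counts,
            "total_density_per_mm2": summary.total_density_per_mm2,
        }
        report["outputs"]["clusters"] = "clusters.csv"
        report["outputs"]["cluster_summary"] = "cluster_summary.json"

    # --- brain map ----------------------------------------------------------
    if "brainmap" in config:
        bc = config["brainmap"]
        gcfg = SynthGroupSeriesConfig(
            group_sizes=dict(bc.get("group_sizes", {"control": 4, "pff": 4})),
            grid_shape=tuple(bc.get("grid_shape", [12, 12])),
            effect_blocks=[tuple(b) for b in bc.get("effect_blocks", [[3, 7, 3, 7]])],
            effect_d=float(bc.get("effect_d", 2.0)),
            seed=seed + 3,
        )
        images, effect_truth, _ = generate_group_sections(gcfg)
        control = gcfg.control_label or next(iter(gcfg.group_sizes))
        grids = {
            g: [normalize_and_downsample(im, block=gcfg.block) for im in lst]
            for g, lst in images.items()
        }
        stat_map = roi_group_stats(
            grids, control, alpha=float(bc.get("alpha", 0.05)),
            fdr=bool(bc.get("fdr", False)))
        stat_map.table.to_csv(out / "roi_stats.csv", index=False)
        sig = stat_map.significant
        sens = (float(np.mean(sig[effect_truth])) if effect_truth.any() else None)
        fp = float(np.mean(sig[~effect_truth])) if (~effect_truth).any() else None
        report["brainmap"] = {
            "grid_shape": list(stat_map.grid_shape),
            "n_significant": int(sig.sum()),
            "true_effect_sensitivity": sens,
            "null_roi_positive_rate": fp,
        }
        report["outputs"]["roi_stats"] = "roi_stats.csv"
        if stat_map.extras.get("divergence"):
            report["warnings"].append(f"brainmap: {stat_map.extras['divergence']}")
        if bc.get("render", False):
            fgrid = stat_map.grid("F")
            render_map(fgrid, out / "roi_F.png", vmin=0.0,
                       vmax=float(np.nanmax(fgrid)) or 1.0, title="per-ROI F")
            report["outputs"]["roi_F_png"] = "roi_F.png"

    io.write_json(report, out / "report.json")
    return report
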