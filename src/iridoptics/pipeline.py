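"""End-to-end seeded pipeline: sample -> simulate -> summarize -> NE report.

A single global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence`` with fixed stage keys, so any stage can
be re-run independently yet reproducibly.
"""
from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import cell_dynamics, colorimetry, io, physiology, stack_synth, tmm
from .config import AppConfig

_STAGES = {
    "ordered_spectrum": 0,
    "disordered_spectrum": 1,
    "ne": 2,
    "morphometry_stripe": 3,
    "morphometry_interstripe": 4,
    "tracks": 5,
}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic child seed (< 2**31) for a named pipeline stage."""
    key = _STAGES[stage]
    return int(np.random.SeedSequence([int(seed), key]).generate_state(1)[0] % 2**31)


def pipeline_run(config: AppConfig, outdir: str | Path) -> io.RunManifest:
    """Run the full analysis bundle under one seeded manifest.

    Produces, under ``outdir``: both crystallotype mean spectra (CSV +
    metadata sidecars), a colorimetry summary JSON, the NE-response
    report JSON, synthetic morphometry CSVs with the group comparison,
    and (optionally) a synthetic track dataset with its behaviour
    report.  Returns the manifest, also written to ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = io.RunManifest(
        command="pipeline_run", seed=config.seed, config=config.model_dump()
    ).start()

    ordered = config.ordered_preset()
    disordered = config.disordered_preset()

    # --- spectra + colorimetry -------------------------------------------
    summaries = {}
    for name, preset in (("ordered", ordered), ("disordered", disordered)):
        cfg = config.simulation.to_mc(stage_seed(config.seed, f"{name}_spectrum"))
        spec = tmm.monte_carlo_spectrum(preset, cfg)
        path = io.write_spectrum_csv(spec, outdir / f"spectrum_{name}.csv")
        manifest.record_output(path)
        summaries[name] = colorimetry.spectral_summary(spec)
    summary_path = outdir / "colorimetry_summary.json"
    summary_path.write_text(json.dumps(summaries, indent=2))
    manifest.record_output(summary_path)

    # --- NE response ------------------------------------------------------
    ne_cfg = config.simulation.to_mc(stage_seed(config.seed, "ne"))
    report = physiology.ne_response(ordered, disordered, config.ne.to_model(), ne_cfg)
    for side in ("ordered", "disordered"):
        resp = getattr(report, side)
        for phase in ("pre", "post"):
            spec = getattr(resp, f"spectrum_{phase}")
            path = io.write_spectrum_csv(spec, outdir / f"ne_{side}_{phase}.csv")
            manifest.record_output(path)
    ne_path = outdir / "ne_report.json"
    ne_path.write_text(json.dumps(report.to_dict(), indent=2))
    manifest.record_output(ne_path)

    # --- morphometry ------------------------------------------------------
    stripe = stack_synth.sample_morphometry(
        **stack_synth.STRIPE_MORPHOMETRY,
        rng_seed=stage_seed(config.seed, "morphometry_stripe"),
        crystallotype="ordered",
    )
    interstripe = stack_synth.sample_morphometry(
        **stack_synth.INTERSTRIPE_MORPHOMETRY,
        rng_seed=stage_seed(config.seed, "morphometry_interstripe"),
        crystallotype="disordered",
    )
    for name, sample in (("stripe", stripe), ("interstripe", interstripe)):
        path = io.write_morphometry_csv(sample, outdir / f"morphometry_{name}.csv")
        manifest.record_output(path)
    cmp_path = outdir / "morphometry_comparison.json"
    cmp_path.write_text(
        json.dumps(stack_synth.summarize_morphometry(stripe, interstripe), indent=2)
    )
    manifest.record_output(cmp_path)

    # --- cell tracks ------------------------------------------------------
    if config.include_tracks:
        tr_cfg = config.tracks
        dataset = cell_dynamics.generate_tracks(
            tr_cfg.n_dense, tr_cfg.n_loose, tr_cfg.to_params(),
            rng_seed=stage_seed(config.seed, "tracks"),
        )
        t_path, d_path = io.write_tracks_csv(
            dataset, outdir / "tracks.csv", outdir / "divisions.csv"
        )
        manifest.record_output(t_path)
        manifest.record_output(d_path)
        track_report = analyze_tracks(dataset, min_displacement_um=tr_cfg.min_displacement_um,
                                      rng_seed=stage_seed(config.seed, "tracks"))
        tr_path = outdir / "track_report.json"
        tr_path.write_text(json.dumps(track_report, indent=2))
        manifest.record_output(tr_path)

    manifest.finish(outdir / "manifest.json")
    return manifest


def analyze_tracks(
    dataset: cell_dynamics.TrackDataset,
    min_displacement_um: float = 20.0,
    rng_seed: int = 0,
) -> dict:
    """Division-angle, migration and proliferation report for a dataset."""
    out: dict = {}
    div = dataset.divisions.merge(
        dataset.tracks[["cell_id", "class"]].drop_duplicates(), on="cell_id", how="left"
    )
    angles: dict = {}
    for cls, g in div.groupby("class"):
        if len(g) == 0:
            continue
        s = cell_dynamics.division_angle_stats(g["angle_deg"].to_numpy(float))
        angles[str(cls)] = {
            "n": s.n,
            "mean_axis_deg": s.mean_axis_deg,
            "resultant_length": s.resultant_length,
            "p_uniform": s.p_uniform,
        }
    out["division_angles"] = angles
    migration = {}
    for cls in ("dense", "loose"):
        if (dataset.tracks["class"] == cls).any():
            rep = cell_dynamics.migration_bias(
                dataset, cls, min_displacement_um, rng_seed=rng_seed
            )
            migration[cls] = {
                "n_qualifying": rep.n_qualifying,
                "mean_dv_um": None if rep.empty else rep.mean_dv_um,
                "ci_um": None if rep.empty else [rep.ci_low_um, rep.ci_high_um],
                "fraction_away": None if rep.empty else rep.fraction_away_from_interstripe,
            }
    out["migration"] = migration
    rates = cell_dynamics.proliferation_rates(dataset)
    out["proliferation"] = {
        cls: {
            "n_cells": r.n_cells,
            "n_divisions": r.n_divisions,
            "cell_hours": r.cell_hours,
            "rate_per_cell_hour": r.rate_per_cell_hour,
            "ci": [r.ci_low, r.ci_high],
        }
        for cls, r in rates["classes"].items()
    }
    if "loose_vs_dense" in rates:
        out["proliferation"]["loose_vs_dense"] = rates["loose_vs_dense"]
    return out
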