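"""End-to-end orchestration: config, stages, manifest.

A :class:`PipelineConfig` (usually loaded from YAML) selects stages and
their parameters.  ``simulate`` writes a full set of synthetic inputs with
truth sidecars; the analysis stages (``morph``, ``turnover``, ``qpcr``,
``screen``, ``enrich``) each read their inputs from the output directory
and write plain-text results.  Every run ends with a ``manifest.json``
listing the files produced, the parameters and seeds used, and the package
version, so a fixed seed and config reproduce the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as stio
from . import __version__
from .enrichment import AnnotationSet, build_network, enrichment_table, export_graph
from .geotaxis import (
    classify_severity,
    day_of_loss,
    line_trajectory,
    normalize_trajectory,
    percent_decline,
    summarize_screen,
    ScreenGene,
)
from .morphometry import (
    detect_z_discs,
    measure_sarcomere_lengths,
    measure_thin_filament_length,
    summarize_group,
)
from .qpcr import normalize_to_day0, relative_expression_table
from .synthetic import (
    ClimbingDesign,
    QpcrDesign,
    StriationTruth,
    TurnoverKinetics,
    gen_ct_table,
    gen_geotaxis,
    gen_pulse_chase,
    gen_screen_fixture,
    gen_striation_profile,
)
from .turnover import summarize_turnover

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "STAGES"]

STAGES = ("simulate", "morph", "turnover", "qpcr", "screen", "enrich")

_DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    "simulate": {
        "sarcomere_length": 3.36,
        "h_zone_width": 0.16,
        "pixel_size": 0.05,
        "psf_sigma": 0.05,
        "n_profiles": 10,
        "n_sarcomeres": 8,
        "noise_sd": 0.05,
        "pulse_timepoints": list(range(0, 170, 15)),
        "n_sarcomeres_per_tp": 40,
        "pulse_noise_sd": 5.0,
        "knockdown_expression": 0.02,
        "n_replicates": 3,
        "p_start": 0.8,
        "p_end_fraction": 0.18,
        "n_vials": 10,
        "flies_per_vial": 10,
        "tech_reps": 5,
        "class_counts": [5, 13, 28, 86],
    },
    "morph": {"smooth_sigma": None, "min_prominence": 0.2},
    "turnover": {"alpha": 0.05},
    "qpcr": {"reference": "GAPDH", "calibrator_day": 0},
    "screen": {"loss_tol": 0.0},
    "enrich": {"terms": None},
}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration.

    Unknown top-level or per-stage keys are rejected so that typos in a
    YAML file fail loudly instead of silently falling back to defaults.
    """

    seed: int = 0
    output_dir: str = "sarcotrack_out"
    stages: tuple[str, ...] = STAGES
    params: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage, kv in self.params.items():
            if stage not in STAGES:
                raise ValueError(f"parameters for unknown stage {stage!r}")
            bad = set(kv) - set(_DEFAULT_PARAMS[stage])
            if bad:
                raise ValueError(f"unknown keys for stage {stage!r}: {sorted(bad)}")

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        known = {"seed", "output_dir", "stages", "params"}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        kw = dict(raw)
        if "stages" in kw:
            kw["stages"] = tuple(kw["stages"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def stage_params(self, stage: str) -> dict[str, Any]:
        merged = dict(_DEFAULT_PARAMS[stage])
        merged.update(self.params.get(stage, {}))
        return merged


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages and return (and write) the manifest."""
    out = Path(config.output_dir)
    inputs = out / "inputs"
    files: list[str] = []

    def _record(path: Path) -> Path:
        files.append(str(path.relative_to(out)))
        return path

    for stage in STAGES:  # canonical order regardless of listing order
        if stage not in config.stages:
            continue
        p = config.stage_params(stage)
        try:
            if stage == "simulate":
                _stage_simulate(p, config.seed, inputs, _record)
            elif stage == "morph":
                _stage_morph(p, inputs, out, _record)
            elif stage == "turnover":
                _stage_turnover(p, inputs, out, _record)
            elif stage == "qpcr":
                _stage_qpcr(p, inputs, out, _record)
            elif stage == "screen":
                _stage_screen(p, inputs, out, _record)
            elif stage == "enrich":
                _stage_enrich(p, inputs, out, _record)
        except FileNotFoundError as exc:
            raise RuntimeError(f"stage {stage!r}: missing input {exc.filename}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(s for s in STAGES if s in config.stages),
        "parameters": {s: config.stage_params(s) for s in config.stages},
        "files": sorted(files),
    }
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(p: dict, seed: int, inputs: Path, record) -> None:
    (inputs / "profiles").mkdir(parents=True, exist_ok=True)
    truth = StriationTruth.from_period(
        p["sarcomere_length"],
        p["h_zone_width"],
        pixel_size=p["pixel_size"],
        psf_sigma=p["psf_sigma"],
    )
    for i in range(p["n_profiles"]):
        prof = gen_striation_profile(
            truth, p["n_sarcomeres"], noise_sd=p["noise_sd"], seed=seed * 1000 + i
        )
        stio.write_profile_csv(prof, record(inputs / "profiles" / f"profile_{i:02d}.csv"))
    stio.write_truth_json(truth, record(inputs / "profiles" / "truth.json"))

    tp = p["pulse_timepoints"]
    for k, (label, kin) in enumerate(
        (
            ("Act88F_GFP", TurnoverKinetics(lag=20.0, rise_end=95.0, decay_halflife=72.0)),
            ("eGFP", TurnoverKinetics(lag=15.0, rise_end=95.0, body_fraction=0.95, decays=False)),
        )
    ):
        series = gen_pulse_chase(
            kin, tp, p["n_sarcomeres_per_tp"], noise_sd=p["pulse_noise_sd"],
            seed=seed * 1000 + 500 + k, label=label,
        )
        stio.write_pulse_chase_csv(series, record(inputs / f"pulse_chase_{label}.csv"))
        stio.write_truth_json(kin, record(inputs / f"pulse_chase_{label}.truth.json"))

    design = QpcrDesign(
        targets=("Act88F",),
        reference="GAPDH",
        conditions=(("RNAi", 0), ("RNAi", 6), ("control", 0), ("control", 6)),
        expression={
            ("Act88F", "RNAi", 0): 1.0,
            ("Act88F", "RNAi", 6): p["knockdown_expression"],
            ("Act88F", "control", 0): 1.0,
            ("Act88F", "control", 6): 0.75,
        },
        base_ct={"Act88F": 18.0, "GAPDH": 16.0},
    )
    stio.write_ct_csv(gen_ct_table(design, p["n_replicates"], seed=seed), record(inputs / "ct_table.csv"))

    climb = ClimbingDesign.linear_decline(
        p["p_start"], p["p_start"] * p["p_end_fraction"],
        n_vials=p["n_vials"], flies_per_vial=p["flies_per_vial"], tech_reps=p["tech_reps"],
    )
    stio.write_geotaxis_csv(gen_geotaxis(climb, seed=seed), record(inputs / "geotaxis.csv"))

    fixture = gen_screen_fixture(tuple(p["class_counts"]), seed=seed)
    rows = [
        {"gene": g.gene, "day": d, "score": s}
        for g in fixture.genes
        for d, s in sorted(g.trajectory.items())
    ]
    pd.DataFrame(rows).to_csv(record(inputs / "screen_trajectories.csv"), index=False)
    stio.write_annotations_tsv(fixture.go_annotations, record(inputs / "annotations.tsv"))
    stio.write_edges_tsv(fixture.edges, record(inputs / "edges.tsv"))


def _stage_morph(p: dict, inputs: Path, out: Path, record) -> None:
    profiles = sorted((inputs / "profiles").glob("profile_*.csv"))
    if not profiles:
        raise RuntimeError("stage 'morph': no profile CSVs found under inputs/profiles")
    rows = []
    for path in profiles:
        prof = stio.read_profile_csv(path)
        z = detect_z_discs(prof, smooth_sigma=p["smooth_sigma"], min_prominence=p["min_prominence"])
        if z is None:
            continue
        lengths = measure_sarcomere_lengths(z)
        for (z1, z2), sl in zip(zip(z[:-1], z[1:]), lengths):
            tfl, hz, degenerate = measure_thin_filament_length(prof, (z1, z2))
            rows.append(
                {"id": path.stem, "genotype": "control", "day": 0,
                 "SL_um": sl, "TFL_um": tfl, "HZ_um": hz, "degenerate": degenerate}
            )
    per = pd.DataFrame(rows)
    per.to_csv(record(out / "morphometry_per_sarcomere.csv"), index=False)
    summary = []
    for col in ("SL_um", "TFL_um", "HZ_um"):
        g = summarize_group(per[col].to_numpy())
        summary.append({"parameter": col, "n": g.n, "mean": g.mean, "sd": g.sd, "sem": g.sem})
    pd.DataFrame(summary).to_csv(record(out / "morphometry_summary.csv"), index=False)


def _stage_turnover(p: dict, inputs: Path, out: Path, record) -> None:
    rows, ratio_rows = [], []
    for path in sorted(inputs.glob("pulse_chase_*.csv")):
        series = stio.read_pulse_chase_csv(path)
        s = summarize_turnover(series, alpha=p["alpha"])
        rows.append(
            {"label": series.label, "onset_h": s.onset, "peak_h": s.peak_time,
             "halflife_h": s.halflife}
        )
        for t, m, e in zip(series.timepoints, s.ratio_mean, s.ratio_sem):
            ratio_rows.append({"label": series.label, "timepoint_h": t, "ratio_mean": m, "ratio_sem": e})
    if not rows:
        raise RuntimeError("stage 'turnover': no pulse-chase CSVs found")
    pd.DataFrame(rows).to_csv(record(out / "turnover_summary.csv"), index=False)
    pd.DataFrame(ratio_rows).to_csv(record(out / "turnover_ratio_series.csv"), index=False)


def _stage_qpcr(p: dict, inputs: Path, out: Path, record) -> None:
    ct = stio.read_ct_csv(inputs / "ct_table.csv")
    folds = relative_expression_table(
        ct, reference=p["reference"], calibrator_day=p["calibrator_day"]
    )
    folds = normalize_to_day0(folds)
    folds["percent_vs_calibrator"] = 100.0 * (1.0 - folds["fold_change"])
    folds.to_csv(record(out / "relative_expression.csv"), index=False)


def _stage_screen(p: dict, inputs: Path, out: Path, record) -> None:
    geo = stio.read_geotaxis_csv(inputs / "geotaxis.csv")
    traj = normalize_trajectory(line_trajectory(geo))
    traj.rename("normalized_score").to_csv(record(out / "climbing_trajectory.csv"))
    decline = percent_decline(traj)

    genes = []
    trajs = pd.read_csv(inputs / "screen_trajectories.csv")
    for gene, grp in trajs.groupby("gene"):
        series = grp.set_index("day")["score"].sort_index()
        loss = day_of_loss(series, tol=p["loss_tol"])
        cls = classify_severity(loss, grid=tuple(series.index))
        genes.append(
            ScreenGene(gene=str(gene), trajectory=dict(series), day_of_loss=loss, severity=cls)
        )
    with open(record(out / "classification.tsv"), "w") as fh:
        fh.write("gene\tday_of_loss\tseverity\n")
        for g in sorted(genes, key=lambda g: g.gene):
            fh.write(f"{g.gene}\t{'' if g.day_of_loss is None else g.day_of_loss}\t{g.severity}\n")
    summary = summarize_screen(genes)
    summary["percent_decline_reference_line"] = decline
    with open(record(out / "screen_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def _stage_enrich(p: dict, inputs: Path, out: Path, record) -> None:
    annotations = stio.read_annotations_tsv(inputs / "annotations.tsv")
    cls_path = out / "classification.tsv"
    if not cls_path.exists():
        raise RuntimeError("stage 'enrich': run the 'screen' stage first (needs classification.tsv)")
    cls_df = pd.read_csv(cls_path, sep="\t")
    universe = tuple(cls_df["gene"])
    ann = AnnotationSet(annotations=annotations, universe=universe)
    classes = {
        str(cls): list(grp["gene"]) for cls, grp in cls_df.groupby("severity")
    }
    terms = p["terms"] or sorted({t for ts in annotations.values() for t in ts})
    table = enrichment_table(terms, classes, ann)
    table.to_csv(record(out / "enrichment_ratios.csv"))

    severities = dict(zip(cls_df["gene"], cls_df["severity"]))
    edges = stio.read_edges_tsv(inputs / "edges.tsv")
    graph = build_network(severities, edges)
    export_graph(graph, str(record(out / "network.graphml")), format="graphml")


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(specs: Sequence[tuple[str | Path, str]]) -> list[str]:
    """Schema-check input files; returns a list of human-readable issues.

    ``specs`` pairs each path with a format name: ``profile``, ``ct``,
    ``geotaxis``, ``pulse_chase``, ``annotations`` or ``edges``.  An empty
    report means every file passed.
    """
    issues: list[str] = []
    for path, fmt in specs:
        path = Path(path)
        if not path.exists():
            issues.append(f"{path}: file not found")
            continue
        try:
            if fmt == "profile":
                df = pd.read_csv(path)
                if not {"position_um", "intensity"} <= set(df.columns):
                    issues.append(f"{path}: expected columns position_um,intensity")
                else:
                    spacing = np.diff(df["position_um"].to_numpy(dtype=float))
                    if spacing.size and (spacing.max() - spacing.min() > 1e-9):
                        issues.append(f"{path}: non-uniform position spacing")
                    if spacing.size and spacing.min() <= 0:
                        issues.append(f"{path}: positions not strictly increasing")
            elif fmt == "ct":
                df = stio.read_ct_csv(path)
                bad = df.index[df["ct"] <= 0].tolist()
                if bad:
                    issues.append(f"{path}: non-positive Ct in rows {bad}")
            elif fmt == "geotaxis":
                df = stio.read_geotaxis_csv(path)
                bad = df.index[
                    (df["successes"] < 0) | (df["successes"] > df["n_flies"])
                ].tolist()
                if bad:
                    issues.append(f"{path}: successes outside [0, n_flies] in rows {bad}")
            elif fmt == "pulse_chase":
                stio.read_pulse_chase_csv(path)
            elif fmt == "annotations":
                stio.read_annotations_tsv(path)
            elif fmt == "edges":
                stio.read_edges_tsv(path)
            else:
                issues.append(f"{path}: unknown format {fmt!r}")
        except Exception as exc:  # malformed rows are findings, not crashes
            issues.append(f"{path}: {exc}")
    return issues
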