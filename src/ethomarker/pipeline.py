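"""End-to-end orchestration, file formats and run reporting.

All artifacts are delimited text (CSV with ``#``-prefixed header comments
naming the producing stage, configuration hash and seed) or structured text
(YAML manifests and reports), so every intermediate of a run can be audited
with a pager.

Stage order follows the analysis flowchart: descriptors -> SOM ethogram ->
class characterization -> contingency / correspondence analysis -> the three
discriminant searches (biomarkers, behaviour, combined) -> perfect-model
collection -> Mahalanobis index -> final-model selection. A stage failure is
recorded with context and its dependents are skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contingency as ct
from . import descriptors as dd
from . import discriminant as da
from . import ethogram as eg
from . import index as ix
from . import synthetic as syn
from .core import BIOMARKER_NAMES, ArenaSpec, Trajectory

__all__ = [
    "RunConfig",
    "RunReport",
    "run_all",
    "write_study",
    "read_study",
    "write_csv",
]

CLASS_NAMES = tuple(f"N{i}" for i in range(1, 10))


# ---------------------------------------------------------------------------
# study I/O


def write_csv(df: pd.DataFrame, path: Path, stage: str, config_hash: str, seed) -> None:
    """Write a CSV with a comment header declaring provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# stage: {stage}\n# config_hash: {config_hash}\n# seed: {seed}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_study(study: syn.SimulatedStudy, out_dir) -> None:
    """Write a study: one trajectory CSV per fish + manifest + biomarkers."""
    out = Path(out_dir)
    traj_dir = out / "trajectories"
    traj_dir.mkdir(parents=True, exist_ok=True)
    h = "simulated"
    for traj in study.trajectories:
        df = pd.DataFrame({"time": traj.t, "x": traj.x, "y": traj.y})
        write_csv(df, traj_dir / f"{traj.fish_id}.csv", "simulate", h, study.seed)
    write_csv(study.biomarkers, out / "biomarkers.csv", "simulate", h, study.seed)
    manifest = {
        "arena": {
            "centre_x": study.arena.centre_x,
            "centre_y": study.arena.centre_y,
            "radius": study.arena.radius,
            "frame_rate": study.arena.frame_rate,
        },
        "seed": study.seed,
        "concentrations": [float(c) for c in study.design.concentrations],
        "fish": [
            {
                "fish_id": r.fish_id,
                "condition": float(r.condition),
                "replicate": int(r.replicate),
            }
            for r in study.condition_map.itertuples()
        ],
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)


def read_study(study_dir) -> tuple[list[Trajectory], pd.DataFrame | None, pd.DataFrame, ArenaSpec]:
    """Load trajectories, biomarker table (None if absent), condition map, arena."""
    study_dir = Path(study_dir)
    with open(study_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    arena = ArenaSpec(**manifest["arena"])
    condition_map = pd.DataFrame(manifest["fish"])
    trajectories = []
    for row in condition_map.itertuples():
        path = study_dir / "trajectories" / f"{row.fish_id}.csv"
        df = read_csv(path)
        for col in ("time", "x", "y"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        trajectories.append(
            Trajectory(
                fish_id=row.fish_id,
                condition=float(row.condition),
                arena=arena,
                t=df["time"].to_numpy(),
                x=df["x"].to_numpy(),
                y=df["y"].to_numpy(),
            )
        )
    bio_path = study_dir / "biomarkers.csv"
    biomarkers = read_csv(bio_path) if bio_path.exists() else None
    return trajectories, biomarkers, condition_map, arena


# ---------------------------------------------------------------------------
# configuration and report


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    If ``study_dir`` is None a synthetic study is generated under the
    reference conditions with ``seed``. ``combined_k_range`` bounds the
    fixed-size searches over the 21-regressor combined pool.
    """

    output_dir: Path | str = "ethomarker_run"
    study_dir: Path | str | None = None
    seed: int = 0
    duration: float = 41.0
    descriptor_window_s: float = 1.0
    som: eg.SOMConfig = field(default_factory=eg.SOMConfig)
    combined_k_range: tuple[int, int] = (1, 5)
    alpha: float = 0.05
    mc_draws: int = 200_000
    max_candidates: int = 25

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.study_dir is not None and not Path(self.study_dir).exists():
            raise ValueError(f"study_dir {self.study_dir} does not exist")

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc["output_dir"] = str(doc["output_dir"])
        doc["study_dir"] = None if doc["study_dir"] is None else str(doc["study_dir"])
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    """Per-stage summaries of a run; every stage reports or is marked skipped."""

    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, name: str, status: str, t0: float, **summary) -> None:
        self.stages[name] = {
            "status": status,
            "wall_time_s": round(time.perf_counter() - t0, 3),
            **summary,
        }

    def skip(self, name: str, reason: str) -> None:
        self.stages[name] = {"status": "skipped", "reason": reason}

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": self.stages,
            "warnings": self.warnings,
        }


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# the run


def run_all(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all artifacts under output_dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    report = RunReport(config_hash=h, seed=config.seed)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        _run_stages(config, out, h, report)
    report.warnings = sorted(set(report.warnings) | {str(w.message) for w in caught})

    with open(out / "report.yaml", "w") as fh:
        yaml.safe_dump(_json_safe(report.to_dict()), fh, sort_keys=False)
    with open(out / "report.json", "w") as fh:
        json.dump(_json_safe(report.to_dict()), fh, indent=2)
    return report


def _run_stages(config: RunConfig, out: Path, h: str, report: RunReport) -> None:
    seed = config.seed

    # --- input: load or simulate -----------------------------------------
    t0 = time.perf_counter()
    try:
        if config.study_dir is not None:
            trajectories, biomarkers, condition_map, arena = read_study(config.study_dir)
        else:
            design = syn.StudyDesign()
            arena = ArenaSpec()
            tparams = syn.default_trajectory_params(seed=seed, duration=config.duration)
            bparams = syn.default_biomarker_params(seed=seed)
            study = syn.simulate_study(design, arena, tparams, bparams)
            write_study(study, out / "study")
            trajectories = study.trajectories
            biomarkers = study.biomarkers
            condition_map = study.condition_map
        report.record(
            "input", "ok", t0,
            n_fish=len(trajectories),
            biomarkers_present=biomarkers is not None,
        )
    except Exception as exc:  # noqa: BLE001 - stage contract: record and stop
        report.record("input", "failed", t0, error=repr(exc))
        for name in ("descriptors", "ethogram", "characterization", "contingency",
                     "discriminant", "index_selection"):
            report.skip(name, "input failed")
        return

    # --- descriptors ------------------------------------------------------
    t0 = time.perf_counter()
    desc_by_fish: dict[str, pd.DataFrame] = {}
    for traj in trajectories:
        desc_by_fish[traj.fish_id] = dd.assemble_descriptors(
            traj, window=config.descriptor_window_s
        )
    pooled = pd.concat(
        [d[d["valid"]].assign(fish_id=fid) for fid, d in desc_by_fish.items()],
        ignore_index=True,
    )
    desc_dir = out / "descriptors"
    for fid, d in desc_by_fish.items():
        write_csv(d, desc_dir / f"{fid}.csv", "descriptors", h, seed)
    report.record(
        "descriptors", "ok", t0,
        n_valid_frames=int(len(pooled)),
        window_s=config.descriptor_window_s,
    )

    # --- SOM ethogram -----------------------------------------------------
    t0 = time.perf_counter()
    som_cfg = dataclasses.replace(config.som, seed=seed)
    model = eg.train_som(pooled, som_cfg)
    labels = eg.assign_classes(model, pooled)
    pooled = pooled.assign(behaviour_class=labels)
    eg.save_model(model, out / "ethogram_model.yaml")
    report.record(
        "ethogram", "ok", t0,
        n_classes=som_cfg.n_nodes,
        quantization_error_first=float(model.quantization_history[0]),
        quantization_error_final=float(model.quantization_history[-1]),
    )

    # --- class characterization -------------------------------------------
    t0 = time.perf_counter()
    charac = eg.characterize_classes(pooled, labels, alpha=config.alpha)
    write_csv(
        charac.means.reset_index(names="class"),
        out / "class_means.csv", "characterization", h, seed,
    )
    write_csv(
        charac.letters.reset_index(names="class"),
        out / "class_letters.csv", "characterization", h, seed,
    )
    write_csv(
        charac.anova.reset_index(),
        out / "class_anova.csv", "characterization", h, seed,
    )
    report.record(
        "characterization", "ok", t0,
        anova_df=[int(charac.anova["df1"].iloc[0]), int(charac.anova["df2"].iloc[0])],
    )

    # --- contingency / correspondence analysis ----------------------------
    t0 = time.perf_counter()
    labels_by_fish = {
        fid: g["behaviour_class"].to_numpy() for fid, g in pooled.groupby("fish_id")
    }
    class_names = tuple(sorted(set(labels)))
    table = ct.build_profile(labels_by_fish, condition_map, "condition", class_names)
    chi = ct.chi_square_independence(table, alpha=config.alpha)
    ca = ct.correspondence_analysis(table)
    write_csv(ct.residual_report(chi), out / "residuals.csv", "contingency", h, seed)
    write_csv(
        ca.row_coordinates.reset_index(), out / "ca_row_coordinates.csv",
        "contingency", h, seed,
    )
    write_csv(
        ca.col_coordinates.reset_index(), out / "ca_col_coordinates.csv",
        "contingency", h, seed,
    )
    report.record(
        "contingency", "ok", t0,
        chi_square=float(chi.statistic), df=int(chi.df), p=float(chi.p),
        total_inertia=float(ca.total_inertia),
        inertia_proportions=[float(v) for v in ca.inertia_proportions],
        n_significant_cells=int(chi.significant.to_numpy().sum()),
    )

    # --- discriminant searches --------------------------------------------
    t0 = time.perf_counter()
    props = ct.build_profile(labels_by_fish, condition_map, "fish", class_names)
    behaviour = props.drop(columns="condition")
    behaviour_groups = props["condition"]

    searches: dict[str, list[da.SubsetModelResult]] = {}
    if biomarkers is not None:
        # pair fish i <-> biomarker replicate i within condition
        cmap = condition_map.copy()
        bio = biomarkers.merge(cmap, on=["condition", "replicate"])
        bio = bio.set_index("fish_id").loc[behaviour.index]
        X_bio = bio[list(BIOMARKER_NAMES)]
        prov = {c: "biomarker" for c in BIOMARKER_NAMES}
        prov.update({c: "behaviour" for c in behaviour.columns})
        t_bio = da.FeatureTable(
            X=X_bio.reset_index(drop=True),
            groups=behaviour_groups.reset_index(drop=True),
            provenance=prov,
        )
        searches["biomarkers"] = da.best_subsets_exhaustive(t_bio, tuple(BIOMARKER_NAMES))
        X_comb = pd.concat(
            [X_bio.reset_index(drop=True), behaviour.reset_index(drop=True)], axis=1
        )
        t_comb = da.FeatureTable(
            X=X_comb, groups=behaviour_groups.reset_index(drop=True), provenance=prov
        )
        klo, khi = config.combined_k_range
        khi = min(khi, t_comb.rank_bound, len(X_comb.columns))
        combined = []
        for k in range(max(1, klo), khi + 1):
            combined.extend(da.best_subsets_fixed_size(t_comb, tuple(X_comb.columns), k))
        searches["combined"] = sorted(combined, key=da._rank_key)
    else:
        report.warnings.append("biomarker table absent: biomarker and combined searches skipped")
        t_comb = None

    t_beh = da.FeatureTable(
        X=behaviour.reset_index(drop=True),
        groups=behaviour_groups.reset_index(drop=True),
        provenance={c: "behaviour" for c in behaviour.columns},
    )
    searches["behaviour"] = da.best_subsets_exhaustive(t_beh, tuple(behaviour.columns))

    summary = {}
    for name, results in searches.items():
        ok = [r for r in results if r.status == "ok"]
        best = ok[0] if ok else None
        summary[name] = {
            "n_evaluated": len(results),
            "best_loocv_accuracy": None if best is None else best.loocv_accuracy,
            "best_subset": None if best is None else list(best.subset),
        }
        top = pd.DataFrame(
            {
                "subset": [";".join(r.subset) for r in results[:100]],
                "n_effects": [r.n_effects for r in results[:100]],
                "loocv_accuracy": [r.loocv_accuracy for r in results[:100]],
                "status": [r.status for r in results[:100]],
            }
        )
        write_csv(top, out / f"search_{name}.csv", "discriminant", h, seed)
    report.record("discriminant", "ok", t0, **summary)

    # --- perfect models + integrative index --------------------------------
    t0 = time.perf_counter()
    all_results = [r for rs in searches.values() for r in rs]
    perfect = da.collect_perfect_models(all_results)
    sel_table = t_comb if biomarkers is not None else t_beh
    if not perfect:
        report.warnings.append("no zero-LOOCV-error model; proceeding with best available")
        ok = sorted((r for r in all_results if r.status == "ok"), key=da._rank_key)
        candidates = ok[:1]
    else:
        candidates = perfect[: config.max_candidates]
    if not candidates:
        report.skip("index_selection", "no fittable model")
        return
    selection = ix.select_final_model(
        candidates, sel_table,
        alpha=config.alpha, mc_draws=config.mc_draws, seed=seed,
    )
    write_csv(selection.audit, out / "model_selection.csv", "index_selection", h, seed)
    chosen = selection.chosen
    cv = selection.chosen_verdict
    if chosen is not None:
        model = chosen.fitted or da.fit_lda(sel_table, chosen.subset)
        idx = ix.mahalanobis_index(model, sel_table)
        write_csv(idx, out / "chosen_model_index.csv", "index_selection", h, seed)
    report.record(
        "index_selection", "ok", t0,
        n_perfect_models=len(perfect),
        n_candidates_scored=len(candidates),
        chosen_subset=None if chosen is None else list(chosen.subset),
        chosen_pattern=None if cv is None else cv.pattern,
        chosen_monotonicity_score=None if cv is None else cv.monotonicity_score,
        chosen_anova_F=None if cv is None else cv.anova.F,
        chosen_anova_df=None if cv is None else list(cv.anova.df),
        chosen_anova_p=None if cv is None else cv.anova.p,
    )
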