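"""End-to-end study pipeline: simulate -> preprocess -> score -> train ->
evaluate -> report.

Every stage is seeded from the master seed by a fixed counter scheme
(``stage_seed = (master_seed * 1009 + stage_index) mod 2^31``), so single
stages can be rerun reproducibly, and a manifest of per-stage seeds and
output hashes makes any silent change detectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from sichml import cohort as coh
from sichml import evaluation as ev
from sichml import preprocess as prep
from sichml import scores as sc
from sichml import svm as svmm
from sichml.phantom import GridSpec, SignalParams, brain_mask, render_ct, render_template_sections


@dataclass
class RunConfig:
    """One structured configuration for the whole pipeline."""

    n_sich: int = 16
    n_control: int = 100
    # grid
    grid_shape: tuple[int, int, int] = (64, 64, 40)
    grid_spacing: tuple[float, float, float] = (3.0, 3.0, 4.0)
    upper_start: int = 12
    lower_stop: int = 16
    # rendering
    noise_sd: float = 2.0
    signal_amplitude: float = 1.0
    jitter: bool = True
    register: bool = False      # run rigid re-alignment before joining
    # cleaning
    hu_low: float = 0.0
    hu_high: float = 200.0
    subject_threshold: int = 5
    # svm
    kernel_kind: str = "linear"
    kernel_scale: float = 1.0
    kernel_offset: float = -1.0
    kernel_gamma: float | None = None
    base_c: float = 1.0
    # evaluation
    foil_sets_per_case: int = 110
    n_boot: int = 500
    models: tuple[str, ...] = ("automated", "manual", "sedan", "hat",
                               "adapted_sedan", "adapted_hat")
    # bookkeeping
    master_seed: int = 0
    write_volumes: bool = False

    def grid(self) -> GridSpec:
        return GridSpec(shape=tuple(self.grid_shape),
                        spacing=tuple(self.grid_spacing),
                        upper_start=self.upper_start,
                        lower_stop=self.lower_stop)

    def kernel(self) -> svmm.KernelSpec:
        return svmm.KernelSpec(kind=svmm.KernelKind(self.kernel_kind),
                               scale=self.kernel_scale,
                               offset=self.kernel_offset,
                               gamma=self.kernel_gamma)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        d["grid_spacing"] = list(d["grid_spacing"])
        d["models"] = list(d["models"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["grid_shape"] = tuple(d["grid_shape"])
        d["grid_spacing"] = tuple(d["grid_spacing"])
        d["models"] = tuple(d["models"])
        return cls(**d)


def stage_seed(master_seed: int, stage_index: int) -> int:
    return (master_seed * 1009 + stage_index) % (2 ** 31)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def build_cohort_matrix(truths: Sequence[coh.LatentTruth],
                        grid: GridSpec,
                        noise_sd: float,
                        signal: SignalParams,
                        seed: int,
                        jitter: bool = True,
                        register: bool = False,
                        hu_low: float = 0.0,
                        hu_high: float = 200.0,
                        subject_threshold: int = 5,
                        volume_dir: Path | None = None,
                        subject_ids: Sequence[str] | None = None,
                        ) -> tuple[prep.CohortVoxelMatrix, np.ndarray]:
    """Render, (optionally re-align,) join, mask, clean and intensity-correct
    a whole cohort.  Returns the corrected matrix and the brain mask."""
    mask = brain_mask(grid)
    voxel_index = prep.mask_voxel_index(mask)
    if register:
        template_upper, template_lower = render_template_sections(grid)
    vectors = np.empty((len(truths), int(mask.sum())))
    for i, truth in enumerate(truths):
        upper, lower = render_ct(truth, grid, noise_sd=noise_sd,
                                 seed=int(np.random.default_rng([seed, i])
                                          .integers(2 ** 31)),
                                 signal=signal, jitter=jitter)
        if register:
            upper = prep.normalize_section(upper, template_upper)
            lower = prep.normalize_section(lower, template_lower)
        if volume_dir is not None:
            sid = subject_ids[i] if subject_ids else f"s{i:04d}"
            prep.section_to_nifti(upper, volume_dir / f"{sid}_upper.nii.gz")
            prep.section_to_nifti(lower, volume_dir / f"{sid}_lower.nii.gz")
        joined = prep.join_sections(upper, lower)
        vectors[i] = prep.apply_brain_mask(joined, mask)
    matrix = prep.clean_cohort(vectors, hu_low=hu_low, hu_high=hu_high,
                               subject_threshold=subject_threshold,
                               voxel_index=voxel_index)
    matrix = prep.global_intensity_correct(matrix)
    return matrix, mask


def automated_distance_fn(matrix_values: np.ndarray, labels_pm: np.ndarray,
                          nihss: np.ndarray, kernel: svmm.KernelSpec,
                          base_c: float = 1.0, uniform_caps: bool = False):
    """Per-split train/predict closure for the whole-image SVM.

    The cohort kernel matrix is computed once; each split's training solve
    and test distances then reduce to slicing it, which is what makes 1760
    splits tractable.
    """
    K = svmm.kernel_matrix(kernel, matrix_values, matrix_values)

    def fn(train: tuple[int, ...], test: tuple[int, ...]) -> np.ndarray:
        tr = np.asarray(train)
        te = np.asarray(test)
        caps = (np.full(len(tr), base_c) if uniform_caps
                else svmm.nihss_to_caps(nihss[tr], base_c))
        model = svmm.train_svm(matrix_values[tr], labels_pm[tr], caps=caps,
                               kernel=kernel, gram=K[np.ix_(tr, tr)])
        alpha = model.diagnostics["alpha"]
        return K[np.ix_(te, tr)] @ (alpha * labels_pm[tr]) + model.bias

    return fn


def manual_distance_fn(records: Sequence[coh.ClinicalRecord],
                       consensuses: Sequence[coh.ConsensusReading],
                       kernel: svmm.KernelSpec, base_c: float = 1.0):
    records = list(records)
    consensuses = list(consensuses)

    def fn(train: tuple[int, ...], test: tuple[int, ...]) -> np.ndarray:
        tr_records = [records[i] for i in train]
        tr_cons = [consensuses[i] for i in train]
        caps = svmm.nihss_to_caps([r.nihss for r in tr_records], base_c)
        model = svmm.train_manual_svm(tr_records, tr_cons, caps=caps, kernel=kernel)
        X_test = svmm.manual_features([records[i] for i in test],
                                      [consensuses[i] for i in test])
        return svmm.decision_distance(model, X_test)

    return fn


def score_distance_fn(score_values: np.ndarray):
    """Prognostic scores need no training; higher score = more SICH-like,
    so the signed distance is the negated score."""
    values = np.asarray(score_values, dtype=float)

    def fn(train: tuple[int, ...], test: tuple[int, ...]) -> np.ndarray:
        return -values[list(test)]

    return fn


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full study pipeline into ``out_dir``; returns the directory.

    Outputs: clinical.csv, truths.csv, readings.csv, scores.csv,
    or_table.csv, matrix/ (values + sidecar), report.csv, report.md,
    manifest.json, and per-subject NIfTI volumes when configured.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(json.dumps(dataclasses.asdict(config))),
                      "stages": {}}

    def record_stage(name: str, idx: int) -> int:
        s = stage_seed(config.master_seed, idx)
        manifest["stages"][name] = {"seed": s}
        return s

    try:
        stage = "simulate"
        s = record_stage(stage, 0)
        records, truths = coh.generate_cohort(config.n_sich, config.n_control, seed=s)
        coh.records_to_frame(records).to_csv(out / "clinical.csv", index=False)
        coh.truths_to_frame(truths).to_csv(out / "truths.csv", index=False)

        stage = "raters"
        s = record_stage(stage, 1)
        panels = coh.simulate_raters(truths, seed=s)
        consensuses = [coh.consensus_reading(p) for p in panels]
        coh.readings_to_frame(panels, [r.subject_id for r in records]
                              ).to_csv(out / "readings.csv", index=False)

        stage = "preprocess"
        s = record_stage(stage, 2)
        vol_dir = None
        if config.write_volumes:
            vol_dir = out / "volumes"
            vol_dir.mkdir(exist_ok=True)
        matrix, mask = build_cohort_matrix(
            truths, config.grid(), config.noise_sd,
            SignalParams(amplitude=config.signal_amplitude), seed=s,
            jitter=config.jitter, register=config.register,
            hu_low=config.hu_low, hu_high=config.hu_high,
            subject_threshold=config.subject_threshold,
            volume_dir=vol_dir, subject_ids=[r.subject_id for r in records])
        prep.save_matrix(matrix, out / "matrix")

        stage = "scores"
        record_stage(stage, 3)
        panels_df = []
        for r, c in zip(records, consensuses):
            p = sc.score_panel(r, c)
            panels_df.append({"subject_id": r.subject_id, "sedan": p.sedan,
                              "hat": p.hat, "adapted_sedan": p.adapted_sedan,
                              "adapted_hat": p.adapted_hat})
        scores_df = pd.DataFrame(panels_df)
        scores_df.to_csv(out / "scores.csv", index=False)
        sc.cohort_or_table(records, consensuses).to_csv(out / "or_table.csv", index=False)

        stage = "evaluate"
        s = record_stage(stage, 4)
        labels = np.array([r.outcome == coh.Outcome.SICH for r in records])
        labels_pm = svmm.outcome_labels(records)
        nihss = np.array([r.nihss for r in records], dtype=float)
        plan = ev.make_split_plan(labels, config.foil_sets_per_case, seed=s)
        (out / "split_plan.json").write_text(json.dumps(
            {"seed": s, "splits": [[list(tr), list(te)] for tr, te in plan.splits]}))

        fns = {}
        for name in config.models:
            if name == "automated":
                fns[name] = automated_distance_fn(matrix.values, labels_pm,
                                                  nihss, config.kernel(),
                                                  config.base_c)
            elif name == "manual":
                fns[name] = manual_distance_fn(records, consensuses,
                                               config.kernel(), config.base_c)
            else:
                fns[name] = score_distance_fn(scores_df[name].to_numpy())
        results = {name: ev.evaluate(plan, labels, fn) for name, fn in fns.items()}

        stage = "report"
        s = record_stage(stage, 5)
        report = ev.compare_models(results, n_boot=config.n_boot, seed=s)
        report.to_csv(out / "report.csv", index=False)
        (out / "report.md").write_text(_report_markdown(report))
    except Exception as exc:                         # noqa: BLE001
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(stage, exc) from exc

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest.setdefault("outputs", {})[str(f.relative_to(out))] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _report_markdown(report: pd.DataFrame) -> str:
    case_cols = [c for c in report.columns if c.startswith("modal_rank_case_")]
    lines = ["| model | AUC (95% CI) | identified | p vs reference | modal ranks |",
             "|---|---|---|---|---|"]
    for _, row in report.iterrows():
        ranks = " ".join(str(int(row[c])) for c in case_cols)
        lines.append(
            f"| {row['model']} | {row['auc']:.3f} "
            f"({row['auc_ci_low']:.3f}-{row['auc_ci_high']:.3f}) | "
            f"{int(row['identified'])} | {row['p_vs_reference']:.3f} | {ranks} |")
    lines.append("")
    lines.append("p-values are a paired case-bootstrap surrogate for the "
                 "unspecified original comparison test.")
    return "\n".join(lines) + "\n"
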