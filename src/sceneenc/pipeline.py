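"""Configuration and end-to-end pipeline orchestration.

``run_pipeline`` executes: synth -> features -> (optional stimulus
selection) -> encode -> partition -> infer -> report, writing each
stage's artifacts (PNG stimuli, NPZ arrays, CSV tables, JSON manifests)
under the configured output directory.  Every manifest carries the
config hash and the per-stage seeds, and all randomness flows through
seeds derived deterministically from the single top-level seed, so a
rerun with the same config is bit-identical for deterministic stages.

Stages later in the chain recompute missing upstream results in memory
(deterministically), so each CLI subcommand can be invoked on its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import encoding as enc
from . import inference as inf
from . import rdm as rdm_mod
from .features import FeatureMatrix
from .gabor import GaborBankSpec, build_gabor_bank, gabor_feature_matrix
from .surface import fit_distance_bins, surface_feature_matrix
from .synth import (
    DesignSpec,
    VoxelPopulationSpec,
    generate_stimulus_set,
    simulate_localizer_stats,
    simulate_voxel_responses,
)

logger = logging.getLogger("sceneenc")

STAGES = ("synth", "features", "select", "encode", "partition", "infer", "report")

MODEL_PAIRS = (("gabor", "3d-global"), ("gabor", "3d-quadrant"))


class _Cfg(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GaborConfig(_Cfg):
    spatial_frequencies: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 16.0)
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    grid_sizes: tuple[int, ...] = (2, 2, 3, 5, 6)
    envelope_ratio: float = 0.25
    nonlinearity: str = "log"

    def to_spec(self) -> GaborBankSpec:
        return GaborBankSpec(
            spatial_frequencies=self.spatial_frequencies,
            orientations=self.orientations,
            grid_sizes=self.grid_sizes,
            envelope_ratio=self.envelope_ratio,
            nonlinearity=self.nonlinearity,
        )


class SurfaceConfig(_Cfg):
    n_distance_bins: int = 3
    max_pixels_sampled: int = 1_000_000


class DesignConfig(_Cfg):
    n_runs: int = 36
    repeats_per_stimulus: int = 3
    tr: float = 0.8
    epoch_len_trs: int = 12

    def to_spec(self) -> DesignSpec:
        return DesignSpec(
            n_runs=self.n_runs,
            repeats_per_stimulus=self.repeats_per_stimulus,
            tr=self.tr,
            epoch_len_trs=self.epoch_len_trs,
        )


class PopulationConfig(_Cfg):
    n_voxels: int
    label: str
    weight_scale: float = 1.0
    noise_sd: float = 1.0


class RidgeSettings(_Cfg):
    n_outer_folds: int = 9
    n_inner_folds: int = 10
    inner_metric: str = "r2_corr"

    def to_config(self) -> enc.RidgeConfig:
        return enc.RidgeConfig(
            n_outer_folds=self.n_outer_folds,
            n_inner_folds=self.n_inner_folds,
            inner_metric=self.inner_metric,
        )


class SelectionConfig(_Cfg):
    enabled: bool = False
    n_target: int = 20
    n_initial_iters: int = 50
    candidates_per_image: int = 1000
    keep_fraction: float = 0.5
    metric: str = "pearson"


class InferenceConfig(_Cfg):
    n_subjects: int = 2
    n_perm: int = 1000
    roi_cap: int = 200
    roi_min: int = 1
    nc_n_perm: int = 500
    localizer_effect: float = 3.0


class PipelineConfig(_Cfg):
    out_dir: str = "sceneenc_out"
    seed: int = 0
    n_images: int = 20
    resolution: tuple[int, int] = (64, 64)
    window: tuple[float, float] = (2.4, 4.8)
    gabor: GaborConfig = Field(default_factory=GaborConfig)
    surface: SurfaceConfig = Field(default_factory=SurfaceConfig)
    design: DesignConfig = Field(default_factory=DesignConfig)
    populations: list[PopulationConfig] = Field(
        default_factory=lambda: [
            PopulationConfig(n_voxels=30, label="gabor-coded", noise_sd=1.0),
            PopulationConfig(n_voxels=30, label="3d-global-coded", noise_sd=1.0),
        ]
    )
    ridge: RidgeSettings = Field(default_factory=RidgeSettings)
    selection: SelectionConfig = Field(default_factory=SelectionConfig)
    inference: InferenceConfig = Field(default_factory=InferenceConfig)

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31 - 1))
        for stage, child in zip(STAGES, children)
    }


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


class Pipeline:
    """Stateful pipeline runner; stages populate ``self.ctx`` lazily."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.seeds = _stage_seeds(config.seed)
        self.ctx: dict = {}

    # -- helpers ----------------------------------------------------------
    def _manifest(self, stage: str, extra: dict | None = None):
        payload = {
            "stage": stage,
            "config_hash": self.config.config_hash(),
            "stage_seed": self.seeds[stage],
            "config": json.loads(self.config.model_dump_json()),
        }
        if extra:
            payload.update(extra)
        path = self.out / f"manifest_{stage}.json"
        path.write_text(json.dumps(payload, indent=2, default=str))

    def _require(self, key: str, producer: str):
        if key not in self.ctx:
            self.run_stage(producer)
        if key not in self.ctx:
            raise PipelineError(producer, f"did not produce required artifact {key!r}")
        return self.ctx[key]

    # -- stages -----------------------------------------------------------
    def stage_synth(self):
        cfg = self.config
        stimset = generate_stimulus_set(
            cfg.n_images, seed=self.seeds["synth"], resolution=tuple(cfg.resolution)
        )
        self.ctx["stimulus_set"] = stimset
        stim_dir = self.out / "stimuli"
        stim_dir.mkdir(exist_ok=True)
        from PIL import Image

        for sid, sample in zip(stimset.stimulus_ids, stimset.samples):
            img = (np.clip(sample.image, 0, 1) * 255).astype(np.uint8)
            Image.fromarray(img, mode="L").save(stim_dir / f"{sid}.png")
        np.savez(
            stim_dir / "maps.npz",
            depth=np.stack([s.depth for s in stimset.samples]).astype(np.float32),
            normals=np.stack([s.normals for s in stimset.samples]).astype(np.float32),
            valid=np.stack([s.valid_mask for s in stimset.samples]),
            stimulus_ids=np.asarray(stimset.stimulus_ids),
        )
        self._manifest("synth", {"n_images": len(stimset)})

    def stage_features(self):
        cfg = self.config
        stimset = self._require("stimulus_set", "synth")
        bank = build_gabor_bank(cfg.gabor.to_spec(), resolution=tuple(cfg.resolution))
        bins = fit_distance_bins(
            stimset,
            n_bins=cfg.surface.n_distance_bins,
            max_pixels_sampled=cfg.surface.max_pixels_sampled,
            seed=self.seeds["features"],
        )
        feats = {
            "gabor": gabor_feature_matrix(stimset, bank),
            "3d-global": surface_feature_matrix(stimset, bins, "global"),
            "3d-quadrant": surface_feature_matrix(stimset, bins, "quadrant"),
        }
        self.ctx["features"] = feats
        self.ctx["distance_bins"] = bins
        fdir = self.out / "features"
        fdir.mkdir(exist_ok=True)
        for name, fm in feats.items():
            np.savez(fdir / f"{name}.npz", values=fm.values, zscored=fm.zscored)
            pd.DataFrame({"feature_label": fm.feature_labels}).to_csv(
                fdir / f"{name}_labels.csv", index=False
            )
        self._manifest(
            "features",
            {
                "distance_bin_edges": list(bins.edges),
                "n_features": {k: v.n_features for k, v in feats.items()},
            },
        )

    def stage_select(self):
        cfg = self.config
        if not cfg.selection.enabled:
            logger.info("selection stage disabled; skipping")
            return
        stimset = self._require("stimulus_set", "synth")
        feats = self._require("features", "features")
        sel = cfg.selection
        kept = rdm_mod.prefilter_pool(stimset, keep_fraction=sel.keep_fraction)
        rdm_a = rdm_mod.compute_rdm(feats["3d-global"])
        rdm_b = rdm_mod.compute_rdm(feats["3d-quadrant"])
        state = rdm_mod.initial_random_search(
            rdm_a, rdm_b, sel.n_target, sel.n_initial_iters,
            seed=self.seeds["select"], pool_indices=kept, method=sel.metric,
        )
        state = rdm_mod.greedy_replacement(
            state, rdm_a, rdm_b, candidates_per_image=sel.candidates_per_image,
            seed=self.seeds["select"] + 1, method=sel.metric,
        )
        # Monitored (not optimized) decorrelation against the Gabor model.
        rdm_g = rdm_mod.compute_rdm(feats["gabor"])
        monitored = {
            "gabor_vs_3d-global": rdm_mod.rdm_correlation(
                rdm_g.subset(state.selected), rdm_a.subset(state.selected), sel.metric
            ),
            "gabor_vs_3d-quadrant": rdm_mod.rdm_correlation(
                rdm_g.subset(state.selected), rdm_b.subset(state.selected), sel.metric
            ),
        }
        self.ctx["selection"] = state
        selected_ids = [stimset.stimulus_ids[i] for i in state.selected]
        (self.out / "selection.json").write_text(
            json.dumps(
                {
                    "selected_indices": [int(i) for i in state.selected],
                    "objective": state.objective,
                    "trace": state.trace,
                    "monitored_rdm_correlations": monitored,
                },
                indent=2,
            )
        )
        pd.DataFrame({"stimulus_id": selected_ids}).to_csv(
            self.out / "selected_stimuli.csv", index=False
        )
        self._manifest("select", {"objective": state.objective})

    def stage_encode(self):
        cfg = self.config
        feats = self._require("features", "features")
        design = cfg.design.to_spec()
        ridge_cfg = cfg.ridge.to_config()
        pops = [
            VoxelPopulationSpec(
                n_voxels=p.n_voxels,
                label=p.label,
                weight_scale=p.weight_scale,
                noise_sd=p.noise_sd,
                weight_seed=self.seeds["encode"] + 7919 * s + i,
            )
            for s in range(cfg.inference.n_subjects)
            for i, p in enumerate(cfg.populations)
        ]
        n_per_subj = len(cfg.populations)
        subjects = []
        for s in range(cfg.inference.n_subjects):
            subj_pops = pops[s * n_per_subj : (s + 1) * n_per_subj]
            trials = simulate_voxel_responses(
                feats, subj_pops, design, seed=self.seeds["encode"] + 104729 * s
            )
            ds = enc.preprocess_trials(trials, window=tuple(cfg.window))
            plan = enc.make_folds(
                ds.run_id, ds.task_label, n_folds=ridge_cfg.n_outer_folds
            )
            # Trial-aligned design matrices (one row per trial).
            model_sets: dict[str, np.ndarray] = {
                name: fm.zscored[trials.stimulus_idx] for name, fm in feats.items()
            }
            for a, b in MODEL_PAIRS:
                model_sets[f"{a}+{b}"] = np.hstack([model_sets[a], model_sets[b]])
            results = {}
            for name, X in model_sets.items():
                results[name] = enc.nested_cv_predict(
                    X, ds.y, plan, ridge_cfg, run_labels=ds.run_id, model_name=name
                )
            subjects.append(
                {"trials": trials, "dataset": ds, "plan": plan, "results": results}
            )
        self.ctx["subjects"] = subjects
        edir = self.out / "encoding"
        edir.mkdir(exist_ok=True)
        rows = []
        for s, subj in enumerate(subjects):
            for name, res in subj["results"].items():
                np.savez(
                    edir / f"subj{s:02d}_{name}.npz",
                    voxel_r=res.voxel_r,
                    fold_r=res.fold_r,
                    lambdas=res.lambdas,
                )
                rows.append(
                    {
                        "subject": s,
                        "model": name,
                        "mean_r": float(res.voxel_r.mean()),
                    }
                )
        pd.DataFrame(rows).to_csv(edir / "summary.csv", index=False)
        self._manifest("encode", {"n_subjects": cfg.inference.n_subjects})

    def stage_partition(self):
        subjects = self._require("subjects", "encode")
        rows = []
        for s, subj in enumerate(subjects):
            res = subj["results"]
            parts = {}
            for a, b in MODEL_PAIRS:
                part = inf.variance_partition(
                    res[a].voxel_r, res[b].voxel_r, res[f"{a}+{b}"].voxel_r,
                    model_a=a, model_b=b,
                )
                parts[(a, b)] = part
                for comp, vals in (
                    (f"unique_{a}", part.unique_a),
                    (f"unique_{b}", part.unique_b),
                    ("shared", part.shared),
                ):
                    rows.append(
                        {
                            "subject": s,
                            "pair": f"{a}_vs_{b}",
                            "component": comp,
                            "mean_value": float(vals.mean()),
                        }
                    )
            subj["partitions"] = parts
        df = pd.DataFrame(rows)
        df.to_csv(self.out / "partition.csv", index=False)
        self.ctx["partition_table"] = df
        self._manifest("partition")

    def stage_infer(self):
        cfg = self.config
        subjects = self._require("subjects", "encode")
        if "partitions" not in subjects[0]:
            self.run_stage("partition")
        n_perm = cfg.inference.n_perm
        model_names = list(subjects[0]["results"])
        rois = {}
        for s, subj in enumerate(subjects):
            stats = simulate_localizer_stats(
                [
                    VoxelPopulationSpec(
                        n_voxels=p.n_voxels, label=p.label,
                        weight_scale=p.weight_scale, noise_sd=p.noise_sd,
                    )
                    for p in cfg.populations
                ],
                seed=self.seeds["infer"] + s,
                effect_size=cfg.inference.localizer_effect,
            )
            labels = subj["trials"].voxel_labels
            for roi_label in sorted(set(labels)):
                roi = inf.select_roi_voxels(
                    stats,
                    candidate_mask=labels == roi_label,
                    cap=cfg.inference.roi_cap,
                    minimum=cfg.inference.roi_min,
                    name=roi_label,
                )
                if roi is not None:
                    rois.setdefault(roi_label, []).append(roi)
        group_p = {}
        for roi_label, roi_per_subj in rois.items():
            if len(roi_per_subj) != len(subjects):
                continue
            obs = {m: [] for m in model_names}
            nulls = {m: [] for m in model_names}
            for subj, roi in zip(subjects, roi_per_subj):
                null_r = inf.permutation_null_r(
                    subj["results"], roi.voxel_idx,
                    n_perm=n_perm, seed=self.seeds["infer"],
                )
                for m in model_names:
                    obs[m].append(
                        float(subj["results"][m].voxel_r[roi.voxel_idx].mean())
                    )
                    nulls[m].append(null_r[m].mean(axis=1))
            for m in model_names:
                group_p[f"{roi_label}:{m}"] = inf.group_permutation_test(
                    np.asarray(obs[m]), np.vstack(nulls[m])
                )
        (self.out / "group_pvalues.json").write_text(json.dumps(group_p, indent=2))
        self.ctx["group_p"] = group_p
        self._manifest("infer", {"n_perm": n_perm})

    def stage_report(self):
        subjects = self._require("subjects", "encode")
        rows = []
        for s, subj in enumerate(subjects):
            labels = subj["trials"].voxel_labels
            for name, res in subj["results"].items():
                for roi_label in sorted(set(labels)):
                    sel = labels == roi_label
                    rows.append(
                        {
                            "subject": s,
                            "roi": roi_label,
                            "model": name,
                            "mean_r": float(res.voxel_r[sel].mean()),
                        }
                    )
        df = pd.DataFrame(rows)
        df.to_csv(self.out / "report.csv", index=False)
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            piv = df.groupby(["roi", "model"])["mean_r"].mean().unstack()
            ax = piv.plot.bar(rot=0, figsize=(7, 4))
            ax.set_ylabel("mean cross-validated r")
            ax.figure.tight_layout()
            ax.figure.savefig(self.out / "report_performance.png", dpi=120)
            plt.close(ax.figure)
        except Exception as exc:  # plotting must never fail the pipeline
            logger.warning("report plot failed: %s", exc)
        self._manifest("report")

    # -- driver -----------------------------------------------------------
    def run_stage(self, stage: str):
        if stage not in STAGES:
            raise PipelineError(stage, "unknown stage")
        fn = getattr(self, f"stage_{stage}")
        t0 = time.monotonic()
        logger.info("stage %s: starting", stage)
        try:
            fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        logger.info("stage %s: done in %.1fs", stage, time.monotonic() - t0)

    def run(self, stages=None) -> Path:
        for stage in stages or STAGES:
            self.run_stage(stage)
        return self.out


def run_pipeline(config: PipelineConfig, stages=None) -> Path:
    """Run the configured stages and return the artifact directory."""
    return Pipeline(config).run(stages)
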