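"""End-to-end reproducible runs: configuration, orchestration, reporting.

A run is described by a YAML/`RunConfig` document with per-stage parameter
blocks.  Stages execute in dependency order (corpus -> train -> receptive
fields -> tuning -> connectivity -> perturbation -> neural fit -> report),
each writing its outputs under the run directory and recording checksums and
wall-clock in a JSON manifest.  One global seed fans out deterministically
to per-stage seeds, so any stage re-run with the same config reproduces its
outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import netmodel as nm
from . import perturbation as pert
from . import receptive_fields as rfmod
from . import synthetic_data as sd
from . import tuning as tn

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "report", "stage_seed"]

STAGES = ("corpus", "train", "receptive_fields", "tuning", "connectivity",
          "perturbation", "report")

_KNOWN_KEYS = {
    "seed", "outdir", "scale_profile", "stages",
    "corpus", "train", "receptive_fields", "tuning", "connectivity",
    "perturbation", "neural_fit", "report",
}


@dataclass
class RunConfig:
    """Validated run configuration; unknown top-level keys are rejected."""

    seed: int = 0
    outdir: str = "run_output"
    scale_profile: str = "desk"
    stages: tuple[str, ...] = STAGES
    corpus: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    receptive_fields: dict = field(default_factory=dict)
    tuning: dict = field(default_factory=dict)
    connectivity: dict = field(default_factory=dict)
    perturbation: dict = field(default_factory=dict)
    neural_fit: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw = {**raw, "stages": tuple(raw["stages"])}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    stages: dict = field(default_factory=dict)  # name -> {outputs, checksums, seconds, seed}

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"config_hash": self.config_hash,
             "package_version": self.package_version,
             "stages": self.stages}, indent=2))


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, verbose: bool = False) -> RunManifest:
    """Execute the configured stages in order; returns the manifest.

    Stage outputs land under ``config.outdir``.  A stage whose upstream
    artifact is missing raises an error naming the stage to run first.
    """
    from . import __version__

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
    manifest = RunManifest(cfg_hash, __version__)
    ctx: dict = {}

    def record(stage: str, t0: float, paths: list[Path], seed: int) -> None:
        manifest.stages[stage] = {
            "seconds": round(time.time() - t0, 3),
            "seed": seed,
            "outputs": {p.name: _checksum(p) for p in paths},
        }

    def need(key: str, producer: str):
        if key not in ctx:
            raise RuntimeError(
                f"missing upstream artifact {key!r}: run the {producer!r} stage first")
        return ctx[key]

    for stage in config.stages:
        seed = stage_seed(config.seed, stage)
        t0 = time.time()
        if verbose:
            print(f"[{stage}] seed={seed}")
        if stage == "corpus":
            params = sd.MovieGenParams(seed=seed, **config.corpus)
            train_clips, val_clips = sd.generate_movie_corpus(params)
            ctx["train_clips"], ctx["val_clips"] = train_clips, val_clips
            manifest_path = out / "corpus_manifest.json"
            manifest_path.write_text(json.dumps({
                "n_train": len(train_clips), "n_val": len(val_clips),
                "params": dataclasses.asdict(params)}))
            record(stage, t0, [manifest_path], seed)
        elif stage == "train":
            overrides = dict(config.train)
            net_cfg = nm.NetworkConfig.desk_profile(seed=seed, **overrides) \
                if config.scale_profile == "desk" \
                else nm.NetworkConfig(seed=seed, **overrides)
            model = nm.init_network(net_cfg)
            model, history = nm.train(model, need("train_clips", "corpus"),
                                      net_cfg, validation=ctx.get("val_clips"),
                                      verbose=verbose)
            ckpt = out / "checkpoint.h5"
            nm.save_checkpoint(ckpt, model, net_cfg, epoch=net_cfg.n_epochs)
            log = out / "training_log.csv"
            history.to_csv(log, index=False)
            ctx["model"], ctx["net_cfg"] = model, net_cfg
            record(stage, t0, [ckpt, log], seed)
        elif stage == "receptive_fields":
            model = need("model", "train")
            kw = dict(config.receptive_fields)
            n_frames = kw.pop("n_noise_frames", 25000)
            inclusion_kw = {k: kw.pop(k) for k in ("min_size", "min_r")
                            if k in kw}
            rfs = rfmod.response_weighted_average(model, n_frames, seed=seed)
            fits = rfmod.fit_gabors(rfs, seed=seed, **kw)
            mask, summary = rfmod.apply_inclusion_criteria(fits, **inclusion_kw)
            table = rfmod.fits_to_frame(fits)
            path = out / "gabor_fits.csv"
            table.to_csv(path, index=False)
            (out / "inclusion_summary.json").write_text(json.dumps(summary))
            ctx["rfs"], ctx["fits"], ctx["included"] = rfs, fits, mask
            record(stage, t0, [path], seed)
        elif stage == "tuning":
            model = need("model", "train")
            resp, grid = tn.grating_battery(model, **config.tuning)
            profiles = [tn.unit_tuning(resp[i], grid)
                        for i in range(model.n_hidden)]
            for p in profiles:
                tn.classify_selectivity(p, "ko")
            table = tn.tuning_table(profiles)
            path = out / "tuning.csv"
            table.to_csv(path, index=False)
            ctx["profiles"], ctx["grating_resp"] = profiles, resp
            record(stage, t0, [path], seed)
        elif stage == "connectivity":
            model = need("model", "train")
            fits = need("fits", "receptive_fields")
            profiles = need("profiles", "tuning")
            graph = conn.threshold_connections(
                model.w_rec_effective, model.excitatory_mask,
                included=ctx["included"], fits=fits,
                **config.connectivity)
            edge_path = out / "edges.csv"
            graph.edge_table().to_csv(edge_path, index=False)
            osi = np.array([p.OSI for p in profiles])
            sel = np.nan_to_num(osi) > 0.4
            prof = conn.probability_by_tuning_difference(
                graph, profiles, "orientation", "EE", selective=sel)
            prof_path = out / "ee_orientation_profile.csv"
            pd.DataFrame({"bin_low": prof.bin_edges[:-1],
                          "bin_high": prof.bin_edges[1:],
                          "connected": prof.connected_counts,
                          "candidates": prof.candidate_counts,
                          "probability": prof.probability}).to_csv(
                prof_path, index=False)
            ctx["graph"], ctx["ee_profile"] = graph, prof
            record(stage, t0, [edge_path, prof_path], seed)
        elif stage == "perturbation":
            model = need("model", "train")
            graph = need("graph", "connectivity")
            profiles = need("profiles", "tuning")
            kw = {"n_grid": [0, 50], "n_repeats": 5}
            kw.update(config.perturbation)
            curve = pert.ablation_error_curve(
                model, graph, profiles, ctx.get("val_clips", [])[:10],
                ctx["net_cfg"], seed=seed, **kw)
            path = out / "ablation_curve.csv"
            curve.to_csv(path, index=False)
            ctx["ablation_curve"] = curve
            record(stage, t0, [path], seed)
        elif stage == "report":
            paths = report(ctx, out)
            record(stage, t0, paths, seed)
        else:
            raise ValueError(f"unknown stage {stage!r}")
    manifest.save(out / "manifest.json")
    return manifest


def report(ctx: dict, outdir: Path) -> list[Path]:
    """Summary CSV + figures from whatever stages have run; side-effect-free
    on the stage outputs themselves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    paths: list[Path] = []
    summary: dict = {}
    if "profiles" in ctx:
        classes = pd.Series([p.selectivity_class for p in ctx["profiles"]])
        summary["selectivity_fractions"] = classes.value_counts(normalize=True).to_dict()
    if "included" in ctx:
        summary["n_included_units"] = int(np.sum(ctx["included"]))
    if "ee_profile" in ctx:
        summary["ee_orientation_probability"] = [
            None if not np.isfinite(v) else float(v)
            for v in ctx["ee_profile"].probability]
    spath = outdir / "summary.json"
    spath.write_text(json.dumps(summary, indent=2))
    paths.append(spath)

    if "ee_profile" in ctx:
        prof = ctx["ee_profile"]
        fig, ax = plt.subplots(figsize=(4, 3))
        centers = 0.5 * (prof.bin_edges[:-1] + prof.bin_edges[1:])
        ax.plot(centers, prof.probability, "o-")
        ax.set_xlabel("Δ orientation preference (deg)")
        ax.set_ylabel("connection probability")
        fig.tight_layout()
        fpath = outdir / "ee_orientation_profile.png"
        fig.savefig(fpath, dpi=120)
        plt.close(fig)
        paths.append(fpath)
    if "ablation_curve" in ctx:
        curve = ctx["ablation_curve"]
        fig, ax = plt.subplots(figsize=(4, 3))
        for cls_name, sub in curve.groupby("class"):
            ax.errorbar(sub.n_ablate, sub.mse_mean, yerr=sub.mse_sem,
                        label=cls_name, marker="o")
        ax.set_xlabel("ablated connections")
        ax.set_ylabel("next-frame MSE")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fpath = outdir / "ablation_curve.png"
        fig.savefig(fpath, dpi=120)
        plt.close(fig)
        paths.append(fpath)
    return paths
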