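"""End-to-end orchestration: generation -> decoding -> ROI -> fusion -> stats.

A single declarative :class:`RunConfig` (optionally loaded from YAML)
drives the whole synthetic pipeline.  Every stochastic stage derives its
seed deterministically from the master seed, the stage name and the
subject index, so reruns with the same config are byte-identical.  Stages
exchange long-form TSV files inside the output directory; every output
carries a provenance header (config hash + master seed) and a
``manifest.json`` records what was produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import bayes, decoding, fusion, roi as roi_mod
from .synth import (
    BlockGeometry,
    GroundTruth,
    RoiSpec,
    derive_seed,
    generate_eeg,
    generate_roi_betas,
    make_design,
)

__all__ = ["RunConfig", "run_all", "summarize", "config_from_yaml", "config_to_yaml"]

ALL_STAGES = ("decoding", "timegen", "roi", "fusion", "stats")


@dataclass
class RunConfig:
    """Declarative description of one synthetic end-to-end run."""

    truth: GroundTruth = field(default_factory=GroundTruth)
    outdir: str = "imfusion_out"
    master_seed: int = 0
    eeg_runs: int = 4
    eeg_reps: int = 10
    fmri_runs: int = 6
    window: int = 3
    chunk_size: int = 5
    decode_iterations: int = 50
    decode_time_step: int = 1
    timegen_iterations: int = 10
    timegen_time_step: int = 8
    prior_width: float = 0.707
    null_range: float = 0.5
    null_mode: str = "point"
    q: float = 0.05
    min_cluster_ms: float = 12.0
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    def stage_seed(self, stage: str, subject: int = 0) -> int:
        return derive_seed(self.master_seed, stage, subject)

    def config_hash(self) -> str:
        return hashlib.sha256(config_to_yaml(self).encode()).hexdigest()[:16]


def _config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["stages"] = list(cfg.stages)
    t = d["truth"]
    t["epoch_ms"] = list(t["epoch_ms"])
    t["category_latency_ms"] = list(t["category_latency_ms"])
    for spec in t["rois"].values():
        spec["latency_ms"] = list(spec["latency_ms"])
    return d


def _config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    t = dict(d.pop("truth", {}))
    rois = {}
    for name, spec in dict(t.pop("rois", {})).items():
        spec = dict(spec)
        geom = BlockGeometry(**spec.pop("geometry", {}))
        spec["latency_ms"] = tuple(spec.pop("latency_ms", (600.0, 2500.0)))
        rois[name] = RoiSpec(geometry=geom, **spec)
    if "epoch_ms" in t:
        t["epoch_ms"] = tuple(t["epoch_ms"])
    if "category_latency_ms" in t:
        t["category_latency_ms"] = tuple(t["category_latency_ms"])
    truth = GroundTruth(rois=rois, **t) if rois else GroundTruth(**t)
    if "stages" in d:
        d["stages"] = tuple(d["stages"])
    return RunConfig(truth=truth, **d)


def config_to_yaml(cfg: RunConfig) -> str:
    return yaml.safe_dump(_config_to_dict(cfg), sort_keys=True)


def config_from_yaml(text_or_path: str) -> RunConfig:
    p = Path(text_or_path)
    text = p.read_text() if p.exists() else text_or_path
    return _config_from_dict(yaml.safe_load(text))


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> str:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()}\tmaster_seed={cfg.master_seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return path.name


def _write_matrix_tsv(mat: np.ndarray, path: Path, cfg: RunConfig, header: str) -> str:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()}\tmaster_seed={cfg.master_seed}\t{header}\n")
        pd.DataFrame(mat).to_csv(fh, sep="\t", index=False, header=False, float_format="%.10g")
    return path.name


def run_all(config: RunConfig) -> dict:
    """Run the configured stages for every synthetic subject.

    Returns the manifest (also written to ``outdir/manifest.json``).
    Reruns with the same config overwrite the same files with identical
    bytes.
    """
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    n_sub = cfg.truth.n_subjects
    roi_names = list(cfg.truth.rois)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.master_seed,
        "stages": list(cfg.stages),
        "n_subjects": n_sub,
        "subjects": {},
        "group": [],
        "stage_seeds": {},
        "errors": {},
    }
    (out / "config.yaml").write_text(config_to_yaml(cfg))

    cat_curves, people_curves, places_curves = [], [], []
    fusion_avg: dict[str, list[np.ndarray]] = {r: [] for r in roi_names}
    diff_waves: dict[str, list[np.ndarray]] = {}
    contrast_rows, decode_rows = [], []
    fusion_time = None
    decode_time = None

    for s in range(n_sub):
        files: list[str] = []
        truth_s = cfg.truth.for_subject(s)
        sub = f"s{s:02d}"
        try:
            needs_eeg = {"decoding", "timegen", "fusion"} & set(cfg.stages)
            epochs = None
            if needs_eeg:
                design = make_design(
                    cfg.eeg_runs,
                    cfg.eeg_reps,
                    cfg.truth.n_conditions,
                    seed=cfg.stage_seed("design", s),
                )
                manifest["stage_seeds"][f"eeg/{sub}"] = cfg.stage_seed("eeg", s)
                epochs = generate_eeg(design, truth_s, seed=cfg.stage_seed("eeg", s))

            if "decoding" in cfg.stages:
                per_pair = decoding.decode_timecourse(
                    epochs,
                    window=cfg.window,
                    chunk_size=cfg.chunk_size,
                    n_iter=cfg.decode_iterations,
                    seed=cfg.stage_seed("decoding", s),
                    time_step=cfg.decode_time_step,
                )
                rows = []
                for level in ("category", "within_people", "within_places"):
                    agg = decoding.aggregate_pairs(per_pair, level)
                    rows.append(
                        pd.DataFrame(
                            {
                                "time_ms": agg.time_ms,
                                "time_imagery_ms": agg.time_ms - fusion.IMAGERY_ONSET_MS,
                                "accuracy": agg.accuracy,
                                "level": level,
                            }
                        )
                    )
                    if level == "category":
                        cat_curves.append(agg.accuracy)
                        decode_time = agg.time_ms
                    elif level == "within_people":
                        people_curves.append(agg.accuracy)
                    else:
                        places_curves.append(agg.accuracy)
                files.append(_write_tsv(pd.concat(rows), out / f"decoding_{sub}.tsv", cfg))

            if "timegen" in cfg.stages:
                tg = decoding.time_generalize(
                    epochs,
                    n_iter=cfg.timegen_iterations,
                    window=cfg.window,
                    seed=cfg.stage_seed("timegen", s),
                    time_step=cfg.timegen_time_step,
                )
                files.append(
                    _write_matrix_tsv(
                        tg.accuracy, out / f"timegen_{sub}.tsv", cfg, "train x test accuracy (%)"
                    )
                )

            betas = {}
            if {"roi", "fusion"} & set(cfg.stages):
                for rname in roi_names:
                    for hemi in ("lh", "rh"):
                        betas[(rname, hemi)] = generate_roi_betas(
                            truth_s,
                            rname,
                            hemisphere=hemi,
                            n_runs=cfg.fmri_runs,
                            seed=cfg.stage_seed("betas", s),
                        )

            if "roi" in cfg.stages:
                for rname in roi_names:
                    per_hemi_c = [
                        roi_mod.roi_contrast(betas[(rname, h)]) for h in ("lh", "rh")
                    ]
                    avg_c = roi_mod.average_hemispheres(*per_hemi_c)
                    contrast_rows.append((s, rname, "avg", avg_c.contrast))
                    for level in ("category", "within_people", "within_places"):
                        per_hemi_d = [
                            roi_mod.roi_decode(betas[(rname, h)], level)
                            for h in ("lh", "rh")
                        ]
                        avg_d = roi_mod.average_hemispheres(*per_hemi_d)
                        decode_rows.append((s, rname, "avg", level, avg_d.accuracy))

            if "fusion" in cfg.stages:
                eeg_rdms = fusion.eeg_rdm_timeseries(epochs)
                fusion_time = eeg_rdms.time_ms
                fused_avg = {}
                long_rows = []
                for rname in roi_names:
                    per_hemi = []
                    for hemi in ("lh", "rh"):
                        rdm = fusion.fmri_rdm(betas[(rname, hemi)])
                        files.append(
                            _write_matrix_tsv(
                                rdm.values,
                                out / f"rdm_{sub}_{rname}_{hemi}.tsv",
                                cfg,
                                f"metric={rdm.metric}\tcondition_order=people_then_places",
                            )
                        )
                        per_hemi.append(
                            fusion.fuse(eeg_rdms, rdm, subject=s, roi=rname, hemisphere=hemi)
                        )
                    avg = fusion.hemisphere_average(*per_hemi)
                    fused_avg[rname] = avg
                    fusion_avg[rname].append(avg.rho)
                    for series in (*per_hemi, avg):
                        long_rows.append(
                            pd.DataFrame(
                                {
                                    "subject": s,
                                    "roi": rname,
                                    "hemisphere": series.hemisphere,
                                    "time_ms": series.time_ms,
                                    "time_imagery_ms": series.time_ms - fusion.IMAGERY_ONSET_MS,
                                    "rho": series.rho,
                                }
                            )
                        )
                files.append(_write_tsv(pd.concat(long_rows), out / f"fusion_{sub}.tsv", cfg))
                if "V1" in fused_avg:
                    for rname in roi_names:
                        if rname == "V1":
                            continue
                        d = fusion.difference_wave(fused_avg[rname], fused_avg["V1"])
                        diff_waves.setdefault(d.pair, []).append(d.values)
            manifest["subjects"][sub] = files
        except Exception as exc:  # partial failures reported per stage/subject
            manifest["errors"][sub] = f"{type(exc).__name__}: {exc}"
            manifest["subjects"][sub] = files

    # ------------------------------------------------------------------ group
    group_files: list[str] = []
    if "stats" in cfg.stages:
        bf_kwargs = dict(
            prior_width=cfg.prior_width, null_range=cfg.null_range, null_mode=cfg.null_mode,
            on_degenerate="saturate",
        )
        if cat_curves and len(cat_curves) >= 3:
            ev = bayes.evidence_timeseries(
                np.vstack(cat_curves), decode_time, null_value=50.0,
                direction="greater", **bf_kwargs,
            )
            group_files.append(
                _write_tsv(
                    pd.DataFrame(
                        {
                            "time_ms": ev.time_ms,
                            "bf10": ev.bf10,
                            "label": ev.labels,
                        }
                    ),
                    out / "evidence_decoding_category.tsv",
                    cfg,
                )
            )
        onset_rows = []
        if fusion_avg and len(next(iter(fusion_avg.values()), [])) >= 3:
            for rname, curves in fusion_avg.items():
                ev = bayes.evidence_timeseries(
                    np.vstack(curves), fusion_time, null_value=0.0,
                    direction="greater", **bf_kwargs,
                )
                group_files.append(
                    _write_tsv(
                        pd.DataFrame(
                            {"time_ms": ev.time_ms, "bf10": ev.bf10, "label": ev.labels}
                        ),
                        out / f"evidence_fusion_{rname}.tsv",
                        cfg,
                    )
                )
                res = fusion.onset_latency(ev, min_duration_ms=cfg.min_cluster_ms)
                onset_rows.append(
                    (
                        rname,
                        np.nan if res.onset_ms is None else res.onset_ms,
                        np.nan if res.onset_imagery_ms is None else res.onset_imagery_ms,
                        len(res.clusters),
                    )
                )
            for pair, waves in diff_waves.items():
                ev = bayes.evidence_timeseries(
                    np.vstack(waves), fusion_time, null_value=0.0,
                    direction="two-sided", **bf_kwargs,
                )
                group_files.append(
                    _write_tsv(
                        pd.DataFrame(
                            {"time_ms": ev.time_ms, "bf10": ev.bf10, "label": ev.labels}
                        ),
                        out / f"evidence_diff_{pair}.tsv",
                        cfg,
                    )
                )
        if onset_rows:
            group_files.append(
                _write_tsv(
                    pd.DataFrame(
                        onset_rows,
                        columns=["roi", "onset_ms", "onset_imagery_ms", "n_clusters"],
                    ),
                    out / "onsets.tsv",
                    cfg,
                )
            )
        if contrast_rows:
            cdf = pd.DataFrame(contrast_rows, columns=["subject", "roi", "hemisphere", "contrast"])
            group_files.append(_write_tsv(cdf, out / "roi_contrast.tsv", cfg))
            if cdf["subject"].nunique() >= 3:
                rows = []
                for rname, sub_df in cdf.groupby("roi"):
                    tt = sps.ttest_1samp(sub_df["contrast"], 0.0)
                    rows.append((rname, sub_df["contrast"].mean(), tt.statistic, tt.pvalue))
                fdf = pd.DataFrame(rows, columns=["roi", "mean_contrast", "t", "p"])
                fdr = bayes.bh_fdr(fdf["p"].to_numpy(), q=cfg.q)
                fdf["significant"] = fdr.mask
                fdf["fdr_threshold"] = fdr.threshold
                group_files.append(_write_tsv(fdf, out / "roi_contrast_fdr.tsv", cfg))
        if decode_rows:
            ddf = pd.DataFrame(
                decode_rows, columns=["subject", "roi", "hemisphere", "level", "accuracy"]
            )
            group_files.append(_write_tsv(ddf, out / "roi_decoding.tsv", cfg))
            if ddf["subject"].nunique() >= 3:
                rows = []
                for (rname, level), sub_df in ddf.groupby(["roi", "level"]):
                    tt = sps.ttest_1samp(sub_df["accuracy"], 50.0, alternative="greater")
                    rows.append((rname, level, sub_df["accuracy"].mean(), tt.statistic, tt.pvalue))
                fdf = pd.DataFrame(rows, columns=["roi", "level", "mean_accuracy", "t", "p"])
                fdr = bayes.bh_fdr(fdf["p"].to_numpy(), q=cfg.q)
                fdf["significant"] = fdr.mask
                fdf["fdr_threshold"] = fdr.threshold
                group_files.append(_write_tsv(fdf, out / "roi_decoding_fdr.tsv", cfg))

    manifest["group"] = group_files
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def summarize(outdir: str, plot: bool = False) -> dict:
    """Group-level tables (means +- SE) from a completed result bundle.

    With a single subject the SE columns are NaN and flagged in the
    returned ``notes``.  Raises ``FileNotFoundError`` for an empty or
    missing bundle.  ``plot=True`` additionally writes ``summary.png``
    with the group fusion curves.
    """
    out = Path(outdir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {outdir!r}; run run_all first")
    manifest = json.loads(manifest_path.read_text())
    tables: dict = {"notes": [], "manifest": manifest}
    if manifest.get("errors"):
        tables["notes"].append(f"stages with errors: {sorted(manifest['errors'])}")

    def _read(name: str) -> pd.DataFrame | None:
        p = out / name
        return pd.read_csv(p, sep="\t", comment="#") if p.exists() else None

    cdf = _read("roi_contrast.tsv")
    if cdf is not None:
        g = cdf.groupby("roi")["contrast"].agg(["mean", "sem", "count"]).reset_index()
        if (g["count"] < 2).any():
            g.loc[g["count"] < 2, "sem"] = np.nan
            tables["notes"].append("SE undefined with a single subject")
        tables["contrast"] = g
    ddf = _read("roi_decoding.tsv")
    if ddf is not None:
        g = ddf.groupby(["roi", "level"])["accuracy"].agg(["mean", "sem", "count"]).reset_index()
        if (g["count"] < 2).any():
            g.loc[g["count"] < 2, "sem"] = np.nan
            if "SE undefined with a single subject" not in tables["notes"]:
                tables["notes"].append("SE undefined with a single subject")
        tables["decoding"] = g
    onsets = _read("onsets.tsv")
    if onsets is not None:
        tables["onsets"] = onsets

    fusion_curves = {}
    for sub_files in manifest.get("subjects", {}).values():
        for name in sub_files:
            if name.startswith("fusion_"):
                df = _read(name)
                for rname, sub_df in df[df["hemisphere"] == "avg"].groupby("roi"):
                    fusion_curves.setdefault(rname, []).append(
                        sub_df.sort_values("time_ms")[["time_ms", "rho"]].to_numpy()
                    )
    if fusion_curves:
        rows = []
        for rname, curves in fusion_curves.items():
            t = curves[0][:, 0]
            r = np.stack([c[:, 1] for c in curves])
            se = r.std(axis=0, ddof=1) / np.sqrt(len(curves)) if len(curves) > 1 else np.full_like(t, np.nan)
            rows.append(pd.DataFrame({"roi": rname, "time_ms": t, "mean_rho": r.mean(axis=0), "sem_rho": se}))
        tables["fusion"] = pd.concat(rows, ignore_index=True)
        if plot:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(7, 4))
            for rname, sub_df in tables["fusion"].groupby("roi"):
                ax.plot(sub_df["time_ms"], sub_df["mean_rho"], label=rname, lw=1)
            ax.axhline(0, color="k", lw=0.5)
            ax.set_xlabel("time from cue onset (ms)")
            ax.set_ylabel("fusion rho")
            ax.legend(fontsize=6, ncol=3)
            fig.tight_layout()
            fig.savefig(out / "summary.png", dpi=120)
            plt.close(fig)
    if len(tables) <= 2 and not tables["notes"]:
        raise FileNotFoundError(f"bundle {outdir!r} contains no stage outputs")
    return tables
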