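"""End-to-end orchestration: simulate -> score -> fit -> standardize ->
test -> cluster -> report.

Every stage writes plain CSV/JSON files into the output directory and
the run manifest records the package version, the master seed, and a
SHA-256 hash of every emitted file, so a rerun with an identical config
is bit-identical and verifiably so.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, abnormality, glmm, groupstats, sdt, subtyping
from .calibration import FULL_SPEC, MAIN_SPEC, NULL_SPEC, attach_covariates
from .synthetic import (
    GenerativeConfig,
    StudyDesign,
    generate_external_scores,
    generate_participants,
    shoes_config,
    simulate_bfft,
    simulate_experiment,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("cpdeficits")

BFFT_NULL_SPEC = glmm.ModelSpec(
    response="recalled", fixed=("age_c", "gender", "tv_band", "print_band"), random_intercept=True
)
BFFT_MAIN_SPEC = glmm.ModelSpec(
    response="recalled",
    fixed=("age_c", "gender", "tv_band", "print_band", "group"),
    random_intercept=True,
)
BFFT_FULL_SPEC = glmm.ModelSpec(
    response="recalled",
    fixed=("age_c", "gender", "tv_band", "print_band", "group", "group:tv_band", "group:print_band"),
    random_intercept=True,
)


@dataclass
class PipelineConfig:
    """Serializable description of one pipeline run."""

    faces: GenerativeConfig = field(default_factory=GenerativeConfig)
    shoes: GenerativeConfig | None = None  # derived from faces when omitted
    design: StudyDesign = field(default_factory=StudyDesign)
    seed: int = 0
    dprime_correction: str = "half"
    residual_scale: str = "logit"
    distance_policy: str = "pairwise_complete"
    cluster_columns: tuple[str, ...] = (
        "perceptual",
        "associative",
        "mnestic",
        "faces_total",
        "shoes_total",
        "overall",
    )
    bayesian: bool = False  # posterior summaries for interaction effects
    heatmap: bool = False
    external_missing_rate: float = 0.05

    def resolved_shoes(self) -> GenerativeConfig:
        return self.shoes if self.shoes is not None else shoes_config(self.faces)

    def to_dict(self) -> dict:
        d = {
            "faces": self.faces.to_dict(),
            "shoes": self.resolved_shoes().to_dict(),
            "design": dataclasses.asdict(self.design),
            "seed": self.seed,
            "dprime_correction": self.dprime_correction,
            "residual_scale": self.residual_scale,
            "distance_policy": self.distance_policy,
            "cluster_columns": list(self.cluster_columns),
            "bayesian": self.bayesian,
            "heatmap": self.heatmap,
            "external_missing_rate": self.external_missing_rate,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "faces" in d:
            d["faces"] = GenerativeConfig.from_dict(d["faces"])
        if d.get("shoes") is not None:
            d["shoes"] = GenerativeConfig.from_dict(d["shoes"])
        if "design" in d:
            des = dict(d["design"])
            for k in ("parts", "illumination_levels"):
                if k in des:
                    des[k] = tuple(des[k])
            d["design"] = StudyDesign(**des)
        if "cluster_columns" in d:
            d["cluster_columns"] = tuple(d["cluster_columns"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text) or {}
        return cls.from_dict(d)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.10g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("simulate")
def stage_simulate(config: PipelineConfig, outdir: Path) -> dict[str, pd.DataFrame]:
    faces_cfg = config.faces
    participants = generate_participants(faces_cfg, seed=config.seed)
    faces = simulate_experiment(participants, config.design, faces_cfg, "faces_longterm", seed=config.seed)
    shoes = simulate_experiment(
        participants, config.design, config.resolved_shoes(), "shoes_longterm", seed=config.seed + 1
    )
    trials = pd.concat([faces, shoes], ignore_index=True)
    bfft = simulate_bfft(participants, config=faces_cfg, seed=config.seed)
    external = generate_external_scores(
        participants, seed=config.seed, missing_rate=config.external_missing_rate
    )
    pub_cols = ["participant_id", "group", "age", "gender", "tv_band", "print_band", "questionnaire_total"]
    _write_csv(participants[pub_cols], outdir / "participants.csv")
    _write_csv(trials, outdir / "trials.csv")
    _write_csv(bfft, outdir / "bfft.csv")
    _write_csv(external.drop(columns=["archetype"]), outdir / "external_scores.csv")
    # latent columns are simulation-internal; keep them out of the interchange files
    return {"participants": participants, "trials": trials, "bfft": bfft, "external": external}


@_stage("sdt")
def stage_sdt(config: PipelineConfig, trials: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    table = sdt.sdt_table(trials, correction=config.dprime_correction)
    _write_csv(table, outdir / "sdt.csv")
    return table


@_stage("fit")
def stage_fit(
    config: PipelineConfig, data: dict[str, pd.DataFrame], outdir: Path
) -> dict[str, dict]:
    trials = attach_covariates(data["trials"], data["participants"])
    bfft = attach_covariates(data["bfft"], data["participants"])
    results: dict[str, dict] = {}
    for exp, frame, specs in (
        ("faces_longterm", trials[trials["experiment"] == "faces_longterm"], (NULL_SPEC, MAIN_SPEC, FULL_SPEC)),
        ("shoes_longterm", trials[trials["experiment"] == "shoes_longterm"], (NULL_SPEC, MAIN_SPEC, FULL_SPEC)),
        ("bfft", bfft, (BFFT_NULL_SPEC, BFFT_MAIN_SPEC, BFFT_FULL_SPEC)),
    ):
        if frame[ _group_key(specs[0]) ].nunique() < 2 or (frame["group"] == "CP").sum() == 0:
            log.warning("experiment %s: no CP observations; skipping group models", exp)
            fits = {"null": glmm.fit_glmm(specs[0], frame)}
            results[exp] = {"fits": {k: f.to_dict() for k, f in fits.items()}, "lr_tests": {}}
            continue
        null_fit = glmm.fit_glmm(specs[0], frame)
        main_fit = glmm.fit_glmm(specs[1], frame)
        full_fit = glmm.fit_glmm(specs[2], frame)
        tests = {
            "main_vs_null": dataclasses.asdict(glmm.lr_test(null_fit, main_fit)),
            "full_vs_main": dataclasses.asdict(glmm.lr_test(main_fit, full_fit)),
        }
        entry = {
            "fits": {"null": null_fit.to_dict(), "main": main_fit.to_dict(), "full": full_fit.to_dict()},
            "lr_tests": tests,
        }
        if config.bayesian:
            inter = [c for c in full_fit.coef.index if c.startswith("group[")]
            post = glmm.posterior_summary(
                specs[2], frame, coefficients=inter, seed=config.seed, check_convergence=False
            )
            entry["posterior"] = {k: dataclasses.asdict(v) for k, v in post.items()}
        results[exp] = entry
    (outdir / "fits.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    return results


def _group_key(spec: glmm.ModelSpec) -> str:
    return spec.group_col


@_stage("scores")
def stage_scores(
    config: PipelineConfig, data: dict[str, pd.DataFrame], outdir: Path
) -> dict[str, pd.DataFrame]:
    participants = data["participants"]
    ctl_ids = participants.loc[participants["group"] == "control", "participant_id"]
    cp_ids = participants.loc[participants["group"] == "CP", "participant_id"]
    trials = attach_covariates(data["trials"], participants)
    bfft = attach_covariates(data["bfft"], participants)

    columns: dict[str, pd.Series] = {}
    for test_id, frame, spec in (
        ("faces_longterm", trials[trials["experiment"] == "faces_longterm"], NULL_SPEC),
        ("shoes_longterm", trials[trials["experiment"] == "shoes_longterm"], NULL_SPEC),
        ("bfft", bfft, BFFT_NULL_SPEC),
    ):
        ctl = frame[frame["participant_id"].isin(ctl_ids)]
        loo, full = abnormality.loo_control_residuals(spec, ctl, scale=config.residual_scale)
        residuals = loo["residual"].copy()
        cases = frame[frame["participant_id"].isin(cp_ids)]
        if len(cases):
            case_res = abnormality.case_residuals(full, cases, scale=config.residual_scale)
            residuals = pd.concat([residuals, case_res["residual"]])
        columns[test_id] = abnormality.standardize(loo["residual"], residuals)

    ztable = abnormality.build_ztable(columns, participants.set_index("participant_id").index)
    external = abnormality.ingest_external_z(
        data["external"].drop(columns=["archetype"]), pd.Index(ctl_ids)
    )
    ztable = ztable.join(external)
    cmap = abnormality.default_category_map()
    ztable = abnormality.aggregate_scores(ztable, cmap, pd.Index(ctl_ids))
    deficits = abnormality.deficit_table(ztable, pd.Index(ctl_ids))

    zlong = ztable.reset_index().melt(id_vars="participant_id", var_name="column", value_name="z")
    zlong["is_missing"] = zlong["z"].isna()
    _write_csv(zlong, outdir / "zscores.csv")
    _write_csv(deficits, outdir / "deficits.csv")
    (outdir / "category_map.json").write_text(json.dumps(cmap.to_dict(), indent=2, sort_keys=True))
    return {"ztable": ztable, "deficits": deficits}


@_stage("group")
def stage_group(
    config: PipelineConfig,
    data: dict[str, pd.DataFrame],
    sdt_table_: pd.DataFrame,
    ztable: pd.DataFrame,
    outdir: Path,
) -> pd.DataFrame:
    participants = data["participants"]
    ctl_ids = set(participants.loc[participants["group"] == "control", "participant_id"])
    cp_ids = set(participants.loc[participants["group"] == "CP", "participant_id"])
    rows = []
    if cp_ids:
        for exp in sdt_table_["experiment"].unique():
            sub = sdt_table_[sdt_table_["experiment"] == exp].set_index("participant_id")
            for metric, direction in (("error_rate", "less"), ("dprime", "greater")):
                x = sub.loc[sub.index.isin(ctl_ids), metric]
                y = sub.loc[sub.index.isin(cp_ids), metric]
                # controls first; direction encodes "CPs perform worse"
                res = groupstats.wilcoxon_rank_sum(x, y, alternative=direction)
                rows.append(
                    {"test_name": f"{exp}:{metric}", "comparison": "control_vs_CP",
                     "W": res.W, "n0": res.n_x, "nCP": res.n_y, "p": res.p,
                     "alternative": res.alternative}
                )
        for col in ("faces_longterm", "shoes_longterm", "bfft", "overall"):
            if col not in ztable.columns:
                continue
            x = ztable.loc[ztable.index.isin(ctl_ids), col].dropna()
            y = ztable.loc[ztable.index.isin(cp_ids), col].dropna()
            if len(x) and len(y):
                res = groupstats.wilcoxon_rank_sum(x, y, alternative="greater")
                rows.append(
                    {"test_name": f"zscore:{col}", "comparison": "control_vs_CP",
                     "W": res.W, "n0": res.n_x, "nCP": res.n_y, "p": res.p,
                     "alternative": res.alternative}
                )
        # self-assessment vs overall deficit among CPs
        cp = participants[participants["group"] == "CP"].set_index("participant_id")
        if "overall" in ztable.columns and len(cp) >= 3:
            overall = ztable.loc[cp.index, "overall"]
            keep = overall.notna()
            if keep.sum() >= 3:
                corr = groupstats.rank_correlation(
                    cp.loc[keep, "questionnaire_total"], overall[keep]
                )
                rows.append(
                    {"test_name": "questionnaire_vs_overall", "comparison": "within_CP",
                     "W": corr.rho, "n0": corr.n, "nCP": corr.n, "p": corr.p,
                     "alternative": "two-sided"}
                )
    else:
        log.warning("no CP participants; group comparisons skipped")
    out = pd.DataFrame(rows, columns=["test_name", "comparison", "W", "n0", "nCP", "p", "alternative"])
    _write_csv(out, outdir / "group_tests.csv")
    return out


@_stage("cluster")
def stage_cluster(
    config: PipelineConfig, ztable: pd.DataFrame, deficits: pd.DataFrame, outdir: Path
) -> dict:
    cols = [c for c in config.cluster_columns if c in ztable.columns]
    usable = ztable[ztable[cols].notna().any(axis=1)]
    dropped = set(ztable.index) - set(usable.index)
    if dropped:
        log.warning("excluding participants with no usable summary scores: %s", sorted(dropped))
    dist = subtyping.pairwise_distance(usable, columns=cols, policy=config.distance_policy)
    dend = subtyping.complete_linkage(dist)
    report = subtyping.profile_report(ztable.loc[usable.index], deficits, dend, aggregate_columns=cols)
    (outdir / "dendrogram.json").write_text(
        json.dumps(
            {
                "merges": dend.merges.tolist(),
                "labels": list(dend.labels),
                "leaf_order": list(dend.leaf_order),
                "linkage": "complete",
                "distance_policy": config.distance_policy,
            },
            indent=2,
        )
    )
    _write_csv(report, outdir / "profile.csv", index=True)
    if config.heatmap:
        _heatmap(report, outdir / "profile_heatmap.png")
    return {"dendrogram": dend, "profile": report}


def _heatmap(report: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    zcols = [c for c in report.columns if not c.endswith("_deficit")]
    Z = report[zcols].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(0.5 * len(zcols) + 2, 0.25 * len(report) + 2))
    im = ax.imshow(np.ma.masked_invalid(Z), cmap="RdBu", vmin=-5, vmax=5, aspect="auto")
    ax.set_xticks(range(len(zcols)), zcols, rotation=90, fontsize=7)
    ax.set_yticks(range(len(report)), report.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and return the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    data = stage_simulate(config, outdir)
    sdt_table_ = stage_sdt(config, data["trials"], outdir)
    fits = stage_fit(config, data, outdir)
    scores = stage_scores(config, data, outdir)
    stage_group(config, data, sdt_table_, scores["ztable"], outdir)
    stage_cluster(config, scores["ztable"], scores["deficits"], outdir)

    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    files = sorted(p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package": "cpdeficits",
        "version": __version__,
        "seed": config.seed,
        "elapsed_s": round(time.perf_counter() - t0, 3),
        "files": {name: _sha256(outdir / name) for name in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
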