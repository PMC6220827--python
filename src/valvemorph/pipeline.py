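"""End-to-end orchestration: feature extraction -> consensus -> group
statistics -> classification, plus a synthetic-cohort simulation study with
parameter-recovery diagnostics. Every stage logs row counts; outputs are
plain CSV/JSON so reruns under a fixed seed are byte-identical."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import consensus as cons
from . import outline as out
from . import stats as gstats
from . import synthetic as syn
from . import texture as tex
from .io import (
    DEFAULT_PIXEL_SCALE,
    MaskedValveImage,
    ValveOutline,
    VoteTable,
    read_masked_image,
    read_outlines,
    read_vote_table,
    write_feature_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "run_simulation_study", "extract_features"]


@dataclass
class RunConfig:
    """Configuration of a pipeline run; round-trips losslessly through YAML."""

    outlines_path: str | None = None
    outlines_layout: str = "wide_table"
    images_dir: str | None = None
    votes_path: str | None = None
    out_dir: str = "results"
    pixel_scale: float = DEFAULT_PIXEL_SCALE
    n_harmonics: int = 14
    n_samples: int = 512
    cv_replicates: int = 100
    cv_folds: int = 10
    seed: int = 0
    algorithms: tuple = tuple(cls.ALGORITHMS)
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls_, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "algorithms" in data and data["algorithms"] is not None:
            data["algorithms"] = tuple(data["algorithms"])
        return cls_(**data)


def extract_features(
    outlines: list[ValveOutline],
    images: list[MaskedValveImage] | None = None,
    n_harmonics: int = 14,
    n_samples: int = 512,
) -> pd.DataFrame:
    """Outline features merged with stria density/orientation per specimen."""
    feats = out.extract_outline_features(outlines, n_harmonics, n_samples)
    logger.info("outline features: %d specimens", len(feats))
    density = {}
    orientation = {}
    for img in images or []:
        try:
            est, ori = tex.estimate_stria_features(img)
            density[img.specimen_id] = est.density if est.accepted else np.nan
            orientation[img.specimen_id] = (
                ori.theta if ori is not None and ori.converged else np.nan
            )
        except ValueError as exc:
            logger.warning("texture failed for %s: %s", img.specimen_id, exc)
            density[img.specimen_id] = np.nan
            orientation[img.specimen_id] = np.nan
    feats["stria_density"] = feats["specimen_id"].map(density).astype(float)
    feats["stria_orientation"] = feats["specimen_id"].map(orientation).astype(float)
    return feats


class StageError(RuntimeError):
    pass


def run_pipeline(
    config: RunConfig,
    outlines: list[ValveOutline] | None = None,
    images: list[MaskedValveImage] | None = None,
    votes: VoteTable | None = None,
    features: pd.DataFrame | None = None,
) -> dict:
    """Execute features -> consensus -> stats -> classify; write all outputs
    under ``config.out_dir`` and return them in memory as well.

    Inputs may be passed directly (synthetic cohorts) or read from the paths
    in the config. A stage failure aborts with a stage-named error; outputs
    of completed stages are retained on disk.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    try:
        if outlines is None and config.outlines_path:
            outlines = read_outlines(
                config.outlines_path, config.outlines_layout,
                pixel_scale=config.pixel_scale,
            )
        if images is None and config.images_dir:
            img_dir = Path(config.images_dir)
            if img_dir.is_dir():
                images = [
                    read_masked_image(p, config.pixel_scale)
                    for p in sorted(img_dir.glob("*.png")) + sorted(img_dir.glob("*.tif*"))
                ]
            else:
                logger.warning("image directory %s missing; texture features skipped", img_dir)
        if votes is None and config.votes_path:
            votes = read_vote_table(config.votes_path)
    except Exception as exc:
        raise StageError(f"input stage failed: {exc}") from exc

    try:
        if features is None:
            if outlines is None:
                raise ValueError("no outlines available")
            features = extract_features(
                outlines, images, config.n_harmonics, config.n_samples
            )
        write_feature_table(features, out_dir / "features.csv")
        report["features"] = features
        logger.info("features stage: %d rows", len(features))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"features stage failed: {exc}") from exc

    if votes is None:
        logger.warning("no vote table; consensus/stats/classification skipped")
        return report

    try:
        consensus_df = cons.consensus_table(votes)
        consensus_df.to_csv(out_dir / "consensus.csv", index=False)
        report["consensus"] = consensus_df
        summary = cons.agreement_summary(votes)
        report["agreement"] = summary
        (out_dir / "agreement.json").write_text(
            json.dumps(
                {
                    "n_specimens": summary.n_specimens,
                    "full_agreement_count": summary.full_agreement_count,
                    "full_agreement_fraction": summary.full_agreement_fraction,
                    "allow_k_counts": summary.allow_k_counts,
                    "per_group": summary.per_group,
                },
                indent=2,
            )
        )
        sim = cons.pairwise_similarity(votes)
        sim.to_csv(out_dir / "similarity.csv")
        report["similarity"] = sim
        coords = []
        for sid in votes.specimen_ids:
            res = cons.majority_vote(votes.votes.loc[sid], sid)
            if sum(res.counts[s] for s in gstats.SPECIES) > 0:
                x, y = cons.ternary_coordinates(res)
                coords.append({"specimen_id": sid, "x": x, "y": y})
        pd.DataFrame(coords).to_csv(out_dir / "ternary.csv", index=False)
        logger.info(
            "consensus stage: %d specimens, %.1f%% full agreement",
            summary.n_specimens, 100 * summary.full_agreement_fraction,
        )
    except Exception as exc:
        raise StageError(f"consensus stage failed: {exc}") from exc

    try:
        summaries = pd.concat(
            [
                gstats.summarize_groups(
                    features, consensus_df, s,
                    feature_names=[c for c in out.NON_EFD_FEATURES if c in features.columns],
                )
                for s in gstats.STRINGENCIES
            ]
        )
        summaries.to_csv(out_dir / "group_summaries.csv", index=False)
        report["group_summaries"] = summaries
        labels = cls.classification_labels(consensus_df)
        merged = features.set_index("specimen_id")
        anova_rows = []
        for feat_name in out.NON_EFD_FEATURES:
            if feat_name not in merged.columns:
                continue
            ids = merged.index.intersection(labels.index)
            try:
                res = gstats.feature_anova(
                    merged.loc[ids, feat_name], labels.loc[ids], feat_name
                )
                anova_rows.append(
                    {"feature": feat_name, "F": res.F, "df1": res.df1,
                     "df2": res.df2, "p": res.p}
                )
            except ValueError as exc:
                logger.warning("ANOVA skipped for %s: %s", feat_name, exc)
        anova_df = pd.DataFrame(anova_rows)
        anova_df.to_csv(out_dir / "anova.csv", index=False)
        report["anova"] = anova_df
        ids = merged.index.intersection(labels.index)
        anc = gstats.feature_ancova(
            merged.loc[ids, "heteropolarity_index"],
            merged.loc[ids, "length"],
            labels.loc[ids],
            "heteropolarity_index",
        )
        anc.group_lines.to_csv(out_dir / "heteropolarity_regressions.csv", index=False)
        report["ancova_heteropolarity"] = anc
        logger.info("stats stage: %d ANOVA features", len(anova_df))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stats stage failed: {exc}") from exc

    try:
        labels = cls.classification_labels(consensus_df)
        sets = cls.build_feature_sets(features, config.n_harmonics)
        rows = []
        cv_rows = []
        rng = np.random.default_rng(config.seed)
        for set_name, (spec_, matrix) in sets.items():
            for algo in config.algorithms:
                seed_ = int(rng.integers(2**31))
                try:
                    rep = cls.fit_predict_resubstitution(
                        matrix, labels, algo, set_name, seed=seed_
                    )
                except ValueError as exc:
                    logger.warning("%s/%s not applicable: %s", algo, set_name, exc)
                    rep = cls.ClassifierReport(
                        algo, set_name, len(matrix), None, None, True, str(exc)
                    )
                rows.append(dataclasses.asdict(rep))
            for algo in ("svm", "random_forest"):
                if algo not in config.algorithms:
                    continue
                seed_ = int(rng.integers(2**31))
                try:
                    cv = cls.cross_validate(
                        matrix, labels, algo,
                        folds=config.cv_folds, replicates=config.cv_replicates,
                        seed=seed_, feature_set=set_name,
                    )
                except ValueError as exc:
                    logger.warning("CV %s/%s skipped: %s", algo, set_name, exc)
                    continue
                cv_rows.append(
                    {"algorithm": algo, "feature_set": set_name,
                     "replicates": cv.replicates, "mean_pct": cv.mean_pct,
                     "min_pct": cv.min_pct, "max_pct": cv.max_pct}
                )
        resub_df = pd.DataFrame(rows)
        resub_df.to_csv(out_dir / "classification_resubstitution.csv", index=False)
        cv_df = pd.DataFrame(cv_rows)
        cv_df.to_csv(out_dir / "classification_cv.csv", index=False)
        report["resubstitution"] = resub_df
        report["cross_validation"] = cv_df
        logger.info("classification stage: %d resubstitution rows", len(resub_df))
    except Exception as exc:
        raise StageError(f"classification stage failed: {exc}") from exc

    return report


@dataclass
class StudyConfig:
    """Synthetic simulation study configuration."""

    n_per_species: tuple = (60, 40, 30)
    n_texture_images: int = 30
    texture_noise_sd: float = 5.0
    cv_replicates: int = 10
    seed: int = 0
    out_dir: str = "results/study"
    algorithms: tuple = tuple(cls.ALGORITHMS)


def run_simulation_study(config: StudyConfig) -> dict:
    """Generate a cohort, run the full pipeline, and report parameter
    recovery (feature bias/RMSE against generator ground truth)."""
    spec = syn.default_cohort_spec(
        n_per_species=tuple(config.n_per_species), noise_sd=config.texture_noise_sd
    )
    cohort = syn.generate_cohort(spec, seed=config.seed, render_images=False)
    truth = cohort["truth"].set_index("specimen_id")

    # texture on a deterministic subset (image rendering dominates runtime)
    rng = np.random.default_rng(config.seed + 1)
    n_img = min(config.n_texture_images, len(truth))
    # stratify the texture subset across species so every group keeps
    # complete cases for the feature sets that include stria descriptors
    img_ids: list[str] = []
    for sp_name, grp in truth.groupby("species"):
        k = max(2, int(round(n_img * len(grp) / len(truth))))
        img_ids.extend(rng.choice(grp.index, size=min(k, len(grp)), replace=False))
    img_ids = sorted(img_ids)
    images = []
    for sid in img_ids:
        row = truth.loc[sid]
        vp = syn.SyntheticValveParams(
            length=float(row["length"]), width=float(row["width_param"]),
            h=float(row["h"]), bulge=float(row["bulge"]),
        )
        tp = syn.StriaTextureParams(
            density=float(row["stria_density"]),
            theta_deg=float(row["stria_orientation"]),
            noise_sd=config.texture_noise_sd,
        )
        img, _ = syn.generate_striated_image(vp, tp, seed=int(rng.integers(2**31)), specimen_id=sid)
        images.append(img)

    run_cfg = RunConfig(
        out_dir=config.out_dir, seed=config.seed,
        cv_replicates=config.cv_replicates, algorithms=tuple(config.algorithms),
    )
    report = run_pipeline(
        run_cfg, outlines=cohort["outlines"], images=images, votes=cohort["votes"]
    )

    feats = report["features"].set_index("specimen_id")
    joined = feats.join(truth, rsuffix="_true")
    hi_err = joined["heteropolarity_index"] - joined["heteropolarity_index_true"]
    dens = joined.dropna(subset=["stria_density"])
    dens_rel = (dens["stria_density"] - dens["stria_density_true"]) / dens["stria_density_true"]
    ori = joined.dropna(subset=["stria_orientation"])
    ori_err = ori["stria_orientation"] - ori["stria_orientation_true"]
    recovery = {
        "heteropolarity_bias": float(hi_err.mean()),
        "heteropolarity_rmse": float(np.sqrt((hi_err**2).mean())),
        "length_rel_rmse": float(
            np.sqrt((((joined["length"] - joined["length_true"]) / joined["length_true"]) ** 2).mean())
        ),
        "density_rel_rmse": float(np.sqrt((dens_rel**2).mean())) if len(dens) else np.nan,
        "density_n": int(len(dens)),
        "orientation_rmse": float(np.sqrt((ori_err**2).mean())) if len(ori) else np.nan,
        "orientation_n": int(len(ori)),
    }
    report["recovery"] = recovery
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    (Path(config.out_dir) / "recovery.json").write_text(json.dumps(recovery, indent=2))
    return report
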