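"""End-to-end orchestration: synthesise stimuli and ratings, extract
descriptors, prune, fit both models, and assemble comparison reports.

Every stage is a pure function over in-memory objects; the CLI wraps these
with file I/O (WAV/CSV/JSON) and a run manifest.  Seeds for synthesis,
ratings, fold assignment and network initialisation are carried in the
config and recorded in every report, so a run is reproducible
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import descriptors as desc
from . import evaluate, mlp, plsr, reduction, synth

log = logging.getLogger(__name__)

#: Emotion dimensions carried through modelling.
EMOTION_DIMS = ("valence", "tension", "energy")

#: Training epochs per dimension: tension converges more slowly.
DEFAULT_EPOCHS = {"valence": 700, "tension": 1000, "energy": 700}


@dataclass
class PipelineConfig:
    out_dir: str = "runs/default"
    seed: int = 0
    n_participants: int = 40
    stimulus_config: dict | None = None
    effect: synth.PlantedEffectSpec = field(default_factory=lambda: synth.DEFAULT_EFFECTS)
    prune_threshold: float = reduction.PRUNE_THRESHOLD
    n_hidden: int = 3
    learning_rate: float = 0.2
    epochs: dict = field(default_factory=lambda: dict(DEFAULT_EPOCHS))
    write_wav: bool = False

    def seeds(self) -> dict[str, int]:
        """Stage seeds derived deterministically from the master seed."""
        ss = np.random.SeedSequence(self.seed).spawn(4)
        names = ("synthesis", "ratings", "folds", "init")
        return {n: int(s.generate_state(1)[0] % (2**31 - 1))
                for n, s in zip(names, ss)}


@dataclass
class PipelineResult:
    metadata: pd.DataFrame
    ratings: pd.DataFrame
    mean_ratings: pd.DataFrame
    descriptor_matrix: pd.DataFrame
    reduction_report: reduction.ReductionReport
    plsr_reports: dict[str, plsr.PLSRFitReport]
    nn_reports: dict[str, mlp.MLPCVReport]
    contributions: dict[str, pd.Series]
    comparison: pd.DataFrame
    rank_table: pd.DataFrame
    reliability: dict
    seeds: dict[str, int]


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage on synthetic data and return all artefacts."""
    config = config or PipelineConfig()
    seeds = config.seeds()

    log.info("synthesising stimuli")
    clips, meta = synth.generate_stimulus_set(config.stimulus_config,
                                              seed=seeds["synthesis"])
    ratings = synth.generate_ratings(meta, config.effect, config.n_participants,
                                     seed=seeds["ratings"])
    mean_ratings = evaluate.aggregate_ratings(ratings)
    reliability = evaluate.reliability_report(ratings)

    log.info("extracting descriptors for %d clips", len(clips))
    X23 = desc.extract_matrix(clips)

    log.info("pruning collinear descriptors")
    red = reduction.reduce_descriptors(X23, threshold=config.prune_threshold)
    X = X23[red.retained]
    Xn, _ = reduction.range_normalize(X)

    plsr_reports = {}
    nn_reports = {}
    contributions = {}
    fold_plan = mlp.make_fold_plan(list(X.index), seed=seeds["folds"])
    for dim in EMOTION_DIMS:
        y = mean_ratings[f"{dim}_norm"]
        log.info("fitting PLSR for %s", dim)
        plsr_reports[dim] = plsr.crossvalidate_plsr(X, y.loc[X.index],
                                                    seed=seeds["folds"])
        log.info("training networks for %s", dim)
        cfg = mlp.MLPConfig(n_inputs=X.shape[1], n_hidden=config.n_hidden,
                            learning_rate=config.learning_rate,
                            epochs=config.epochs.get(dim, 700),
                            seed=seeds["init"])
        nn_reports[dim] = mlp.crossvalidate_mlp(Xn, y.loc[Xn.index], fold_plan, cfg)
        contributions[dim] = mlp.average_contributions(nn_reports[dim].fold_models)

    comparison = _comparison(mean_ratings, Xn, plsr_reports, nn_reports)
    ranks = evaluate.rank_table(
        {d: plsr_reports[d].loading_table for d in EMOTION_DIMS},
        contributions)
    return PipelineResult(metadata=meta, ratings=ratings, mean_ratings=mean_ratings,
                          descriptor_matrix=X23, reduction_report=red,
                          plsr_reports=plsr_reports, nn_reports=nn_reports,
                          contributions=contributions, comparison=comparison,
                          rank_table=ranks, reliability=reliability, seeds=seeds)


def _comparison(mean_ratings, Xn, plsr_reports, nn_reports) -> pd.DataFrame:
    """Table of R2/Q2/RMSE per model per dimension with percent improvement.

    For the network, fitness (R2) and RMSE are computed between the mean
    ratings and the fold-model predictions pooled over the test sets, and
    Q2 from the pooled held-out squared errors.
    """
    p_tab = pd.DataFrame({d: [r.r2, r.q2, r.rmse]
                          for d, r in plsr_reports.items()},
                         index=["r2", "q2", "rmse"])
    nn = {}
    for dim, rep in nn_reports.items():
        y = mean_ratings[f"{dim}_norm"]
        press = 0.0
        tss = 0.0
        train_sse = []
        train_tss = []
        for k, model in enumerate(rep.fold_models):
            te = rep.plan.test_ids(k)
            tr = rep.plan.train_ids(k)
            resid = y.loc[te].to_numpy() - mlp.predict(model, Xn.loc[te])
            press += float(np.sum(resid**2))
            tss += float(np.sum((y.loc[te] - y.mean()) ** 2))
            fit_resid = y.loc[tr].to_numpy() - mlp.predict(model, Xn.loc[tr])
            train_sse.append(float(np.sum(fit_resid**2)))
            train_tss.append(float(np.sum((y.loc[tr] - y.loc[tr].mean()) ** 2)))
        r2 = float(np.mean([1.0 - s / t for s, t in zip(train_sse, train_tss)]))
        q2 = 1.0 - press / tss
        nn[dim] = [r2, q2, rep.mean_rmse]
    n_tab = pd.DataFrame(nn, index=["r2", "q2", "rmse"])
    return evaluate.comparison_table(p_tab, n_tab)


# ---------------------------------------------------------------------------
# File-based stage running (used by the CLI)
# ---------------------------------------------------------------------------

STAGES = ("synth", "extract", "reduce", "fit-plsr", "fit-nn",
          "contributions", "compare", "report")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Run manifest: config snapshot, per-file checksums, timestamps.

    Written atomically (tmp file + rename) at the end of a run.
    """

    def __init__(self, config: PipelineConfig):
        cfg = dataclasses.asdict(config)
        cfg["effect"] = dataclasses.asdict(config.effect)
        self.data = {"config": cfg, "seeds": config.seeds(),
                     "started": time.time(), "outputs": {}}

    def record(self, stage: str, path: str) -> None:
        self.data["outputs"][os.path.relpath(path)] = {
            "stage": stage, "sha256": _sha256(path), "time": time.time()}

    def write(self, path: str) -> None:
        self.data["finished"] = time.time()
        tmp = path + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(self.data, fh, indent=2, default=str)
        os.replace(tmp, path)


def run_to_files(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline and persist every stage output under
    ``config.out_dir`` with a manifest."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest = Manifest(config)
    result = run_pipeline(config)

    def save_csv(stage, name, df):
        path = os.path.join(out, name)
        df.to_csv(path)
        manifest.record(stage, path)

    def save_json(stage, name, obj):
        path = os.path.join(out, name)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, default=str)
        manifest.record(stage, path)

    if config.write_wav:
        wav_dir = os.path.join(out, "wav")
        os.makedirs(wav_dir, exist_ok=True)
        clips, _ = synth.generate_stimulus_set(config.stimulus_config,
                                               seed=result.seeds["synthesis"])
        for clip in clips:
            clip.write_wav(os.path.join(wav_dir, clip.stimulus_id + ".wav"))

    save_csv("synth", "metadata.csv", result.metadata)
    save_csv("synth", "ratings.csv", result.ratings.set_index("participant_id"))
    save_csv("synth", "mean_ratings.csv", result.mean_ratings)
    save_csv("extract", "descriptors.csv", result.descriptor_matrix)
    save_json("reduce", "reduction_report.json", result.reduction_report.to_dict())
    save_csv("reduce", "descriptors_retained.csv",
             result.descriptor_matrix[result.reduction_report.retained])
    for dim in EMOTION_DIMS:
        save_json("fit-plsr", f"plsr_{dim}.json", result.plsr_reports[dim].to_dict())
        save_csv("fit-plsr", f"plsr_loadings_{dim}.csv",
                 result.plsr_reports[dim].loading_table)
        save_json("fit-nn", f"nn_{dim}.json", result.nn_reports[dim].to_dict())
        save_json("fit-nn", f"nn_weights_{dim}.json",
                  [m.to_dict() for m in result.nn_reports[dim].fold_models])
        save_csv("contributions", f"contributions_{dim}.csv",
                 result.contributions[dim].to_frame())
    save_csv("compare", "comparison.csv", result.comparison.set_index("metric"))
    save_csv("report", "rank_table.csv", result.rank_table)
    with open(os.path.join(out, "report.txt"), "w") as fh:
        fh.write(evaluate.render_table(result.comparison, "Model comparison"))
        fh.write("\n\n")
        fh.write(evaluate.render_table(result.rank_table, "Top-descriptor ranks"))
        fh.write("\n")
    manifest.record("report", os.path.join(out, "report.txt"))
    manifest.write(os.path.join(out, "manifest.json"))
    return result
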