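"""End-to-end orchestration: simulate -> preprocess -> features -> map ->
classify -> predict -> changes, with a reproducibility manifest.

``run_all`` executes every stage in order on a synthetic cohort (or a
fixture directory) and writes flat CSV/JSON/HDF5/PNG outputs plus
``manifest.json`` recording the config hash, package version, seed and
per-stage row counts.  Outputs contain no timestamps, so re-running with an
identical config reproduces byte-identical CSV/JSON files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
import warnings
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .behavior import cell_scores, consistency_report, rm_anova_2x3, score_and_group
from .channels import SCOPES, fingerprint, topomap
from .errors import PairingError, PipelineError
from .model_eval import (
    SVMConfig,
    SVRConfig,
    cross_session_classify,
    loocv_classify,
    loocv_svr,
)
from .preprocess import PreprocessConfig, preprocess_pipeline
from .spectral import WelchConfig, cohort_entropy
from .synth import SynthConfig, generate_cohort, read_fixture, write_fixture

log = logging.getLogger("wmentropy")


@dataclass
class RunConfig:
    """Everything a full run needs; serializable to/from YAML."""

    out_dir: str = "wmentropy_run"
    fixture_dir: str = None  # if set, load this cohort instead of simulating
    seed: int = 0
    log_level: str = "INFO"
    write_fixture_files: bool = False
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    welch: WelchConfig = field(default_factory=WelchConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    svr: SVRConfig = field(default_factory=SVRConfig)

    def __post_init__(self):
        self.synth.seed = self.seed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("synth", SynthConfig),
            ("preprocess", PreprocessConfig),
            ("welch", WelchConfig),
            ("svm", SVMConfig),
            ("svr", SVRConfig),
        ):
            if key in d and isinstance(d[key], dict):
                kw = dict(d[key])
                for tup in ("loads", "band", "baseline_window", "retention_window"):
                    if tup in kw and isinstance(kw[tup], list):
                        kw[tup] = tuple(kw[tup])
                d[key] = sub(**kw)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(_jsonable(self.to_dict()), f, sort_keys=True)

    def config_hash(self) -> str:
        d = _jsonable(self.to_dict())
        d.pop("out_dir", None)  # where results land does not change them
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def _dump_json(obj, path: str) -> None:
    with open(path, "w") as f:
        json.dump(_jsonable(obj), f, indent=2, sort_keys=True, allow_nan=True)
        f.write("\n")


def _setup_logging(out_dir: str, level: str):
    log.setLevel(getattr(logging, level.upper(), logging.INFO))
    log.handlers.clear()
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    for h in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(os.path.join(out_dir, "run.log"), mode="w"),
    ):
        h.setFormatter(fmt)
        log.addHandler(h)


def run_all(cfg: RunConfig) -> str:
    """Run the whole analysis; returns the output directory path.

    On a stage failure, partial outputs are kept, a ``FAILED`` marker file
    names the stage, and :class:`~wmentropy.errors.PipelineError` is raised.
    """
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    _setup_logging(out, cfg.log_level)
    manifest = {
        "package": "wmentropy",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": _jsonable(cfg.to_dict()),
        "stages": {},
    }
    stage = "simulate"
    try:
        if cfg.fixture_dir:
            log.info("loading fixture cohort from %s", cfg.fixture_dir)
            epochs, behavior, truth = read_fixture(cfg.fixture_dir)
            target = truth.target_channel
        else:
            log.info("simulating cohort (seed=%d)", cfg.seed)
            epochs, behavior, truth = generate_cohort(cfg.synth)
            target = cfg.synth.target_channel
            if cfg.write_fixture_files:
                write_fixture(
                    (epochs, behavior, truth), os.path.join(out, "fixture")
                )
        manifest["stages"][stage] = {
            "blocks": len(epochs),
            "trials": int(sum(e.n_trials for e in epochs)),
            "behavior_rows": len(behavior),
        }

        stage = "preprocess"
        clean, n_rejected = [], 0
        for e in epochs:
            c, rejected = preprocess_pipeline(e, cfg.preprocess)
            clean.append(c)
            n_rejected += len(rejected)
        manifest["stages"][stage] = {
            "trials_kept": int(sum(e.n_trials for e in clean)),
            "trials_rejected": n_rejected,
        }

        stage = "features"
        features = cohort_entropy(clean, cfg.welch)
        features.to_csv(os.path.join(out, "features.csv"), index=False)
        manifest["stages"][stage] = {"rows": len(features)}

        stage = "scores"
        scores = score_and_group(behavior)
        scores.to_csv(os.path.join(out, "scores.csv"), index=False)
        for s in sorted(behavior["session"].unique()):
            try:
                rm_anova_2x3(cell_scores(behavior[behavior["session"] == s])).to_csv(
                    os.path.join(out, f"anova_session{s}.csv"), index=False
                )
            except PairingError as exc:
                # hand x load ANOVA needs every subject in all six cells;
                # sparse designs skip it rather than fail the run
                log.warning("session %s ANOVA skipped: %s", s, exc)
        manifest["stages"][stage] = {"rows": len(scores)}

        stage = "map"
        maps = {}
        for scope in SCOPES:
            cmap = fingerprint(features, scores, scope=scope)
            cmap.table.assign(scope=scope).to_csv(
                os.path.join(out, f"correlation_{scope}.csv"), index=False
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                topomap(cmap, os.path.join(out, f"topomap_{scope}.png"))
            maps[scope] = cmap
        best = maps["merged"].best_channel
        _dump_json(
            {s: m.best_channel for s, m in maps.items()},
            os.path.join(out, "best_channel.json"),
        )
        manifest["stages"][stage] = {"channels": len(maps["merged"].table),
                                     "best_channel": best}
        log.info("best channel (merged): %s (target was %s)", best, target)

        stage = "classify"
        feat = features[features["channel"] == best]
        by_session = {
            s: feat[feat["session"] == s]
            .merge(scores[scores["session"] == s], on=["subject", "session"])
            .sort_values("subject")
            for s in (1, 2)
        }
        reports = {}
        for s in (1, 2):
            d = by_session[s]
            reports[f"intra_s{s}"] = loocv_classify(
                d["sen"], d["group"], cfg.svm, subjects=d["subject"],
                scheme=f"intra_s{s}",
            )
        for train_s, test_s in ((2, 1), (1, 2)):
            tr, te = by_session[train_s], by_session[test_s]
            reports[f"inter_train{train_s}_test{test_s}"] = cross_session_classify(
                tr["sen"], tr["group"], te["sen"], te["group"], cfg.svm,
                subjects=te["subject"],
                scheme=f"inter_train{train_s}_test{test_s}",
            )
        _dump_json(
            {k: r.to_dict() for k, r in reports.items()},
            os.path.join(out, "classification.json"),
        )
        manifest["stages"][stage] = {
            k: {"ca": r.ca, "auc": r.auc} for k, r in reports.items()
        }

        stage = "predict"
        from .channels import fdr_bh

        regs = {}
        for scope in SCOPES:
            if scope == "merged":
                d = feat.merge(scores, on=["subject", "session"]).sort_values(
                    ["subject", "session"]
                )
            else:
                d = by_session[int(scope[-1])]
            regs[scope] = loocv_svr(
                d["sen"], d["srt"], cfg.svr, subjects=d["subject"],
                sessions=d["session"], scope=scope,
            )
        qs, _ = fdr_bh([r.p for r in regs.values()])
        for q, r in zip(qs, regs.values()):
            r.q = float(q)
        _dump_json(
            {k: r.to_dict() for k, r in regs.items()},
            os.path.join(out, "regression.json"),
        )
        manifest["stages"][stage] = {
            k: {"rmsep": r.rmsep, "r": r.r} for k, r in regs.items()
        }

        stage = "changes"
        report = consistency_report(scores, features, best)
        report.table.to_csv(os.path.join(out, "changes.csv"), index=False)
        _dump_json(
            {"channel": report.channel, "counts": report.counts,
             "zero_flagged": report.zero_flagged},
            os.path.join(out, "changes.json"),
        )
        manifest["stages"][stage] = report.counts
    except Exception as exc:
        with open(os.path.join(out, "FAILED"), "w") as f:
            f.write(f"{stage}: {exc}\n")
        _dump_json(manifest, os.path.join(out, "manifest.json"))
        raise PipelineError(stage, str(exc)) from exc

    _dump_json(manifest, os.path.join(out, "manifest.json"))
    log.info("run complete: %s", out)
    return out
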