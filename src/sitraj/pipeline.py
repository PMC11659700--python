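"""Seeded end-to-end orchestration: simulate -> score -> associate ->
trajectory -> forecast -> respond-score -> enrich.

A run is driven by a YAML/JSON config validated against a small schema;
every stochastic stage receives a seed derived from the root seed and
the stage name, so reruns are byte-identical.  Each stage logs how many
records its filters dropped (minimum-posts, 72-hour window,
insufficient history), since attrition is filter-driven and should be
auditable, and the run manifest records per-stage outputs with row
counts and SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import association, enrichment, forecast, io, positivity, synthetic, trajectory
from .errors import ConfigurationError, InsufficientHistoryError
from .scoring import LexiconRiskScorer, aggregate_daily

__all__ = ["load_config", "validate_config", "run_pipeline", "STAGES"]

log = logging.getLogger("sitraj")

STAGES = ("simulate", "score", "associate", "trajectory", "forecast", "respond-score", "enrich")

_SCHEMA: dict[str, type | tuple[type, ...]] = {"seed": int, "stages": list}

_STAGE_KEYS = {
    "simulate": {
        "n_users", "n_days", "latent_persistence", "latent_noise_sd", "post_rate",
        "score_link_slope", "score_noise_sd", "interaction_effect", "mention_threshold",
        "mention_min_day", "response_prob", "response_drift", "favorable_drift",
        "favorable_prob", "survey_every",
    },
    "score": {"min_posts"},
    "associate": {"windows", "min_posts", "threshold_si", "auc_window", "n_perm"},
    "trajectory": {"mode", "thresholds"},
    "forecast": {"eval_days"},
    "respond-score": {"window_hours", "horizon", "threshold", "min_history", "pct"},
    "enrich": {"unit", "min_count"},
}


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: Any) -> None:
    """Validate a run config; errors carry a JSON-pointer-style path."""
    if not isinstance(cfg, dict):
        raise ConfigurationError("/: config must be a mapping")
    for key, typ in _SCHEMA.items():
        if key not in cfg:
            raise ConfigurationError(f"/{key}: required key missing")
        if not isinstance(cfg[key], typ):
            raise ConfigurationError(f"/{key}: expected {typ}")
    for i, stage in enumerate(cfg["stages"]):
        if stage not in STAGES:
            raise ConfigurationError(f"/stages/{i}: unknown stage {stage!r}")
    for stage, block in cfg.get("params", {}).items():
        if stage not in STAGES:
            raise ConfigurationError(f"/params/{stage}: unknown stage")
        extra = set(block) - _STAGE_KEYS[stage]
        if extra:
            raise ConfigurationError(f"/params/{stage}/{sorted(extra)[0]}: unknown parameter")
    known = {"seed", "stages", "params"}
    extra = set(cfg) - known
    if extra:
        raise ConfigurationError(f"/{sorted(extra)[0]}: unknown top-level key")


def _stage_seed(root_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([root_seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise ConfigurationError(f"stage {stage!r}: required input {path} does not exist")
    return path


def run_pipeline(cfg: Mapping, outdir: str | Path) -> dict:
    """Run the configured stages in order; return the manifest dict.

    The manifest (also written to ``manifest.json``) lists per stage:
    seed, parameters, output files with row counts and SHA-256
    checksums, and drop counts for every filter, which together suffice
    to reproduce the run byte-for-byte.
    """
    validate_config(dict(cfg))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_seed = int(cfg["seed"])
    params = cfg.get("params", {})
    manifest: dict = {"seed": root_seed, "stages": {}}

    for stage in cfg["stages"]:
        p = dict(params.get(stage, {}))
        seed = _stage_seed(root_seed, stage)
        log.info("stage %s (seed %d)", stage, seed)
        entry: dict = {"seed": seed, "params": p, "outputs": {}, "dropped": {}}
        try:
            _run_stage(stage, p, seed, outdir, entry)
        except Exception:
            manifest["stages"][stage] = entry
            manifest["failed_stage"] = stage
            _write_manifest(outdir, manifest)
            raise
        for name in entry["outputs"]:
            entry["outputs"][name]["sha256"] = _sha256(outdir / name)
        manifest["stages"][stage] = entry
    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _out(entry: dict, name: str, rows: int) -> None:
    entry["outputs"][name] = {"rows": rows}


def _lexicon_scorer(outdir: Path) -> LexiconRiskScorer:
    truth = io.read_truth(outdir / "truth.json")
    cfg = truth["config"]
    return LexiconRiskScorer(risk_words=cfg["vocab_neg"], protective_words=cfg["vocab_pos"])


def _run_stage(stage: str, p: dict, seed: int, outdir: Path, entry: dict) -> None:
    if stage == "simulate":
        survey_every = int(p.pop("survey_every", 28))
        n_days = int(p.get("n_days", 120))
        cfg = synthetic.CohortConfig(
            seed=seed,
            survey_days=tuple(range(survey_every, n_days, survey_every)),
            **{k: v for k, v in p.items()},
        )
        cohort = synthetic.generate_mention_corpus(cfg)
        posts = [post for u in cohort.users for post in u.posts]
        _out(entry, "posts.jsonl", io.write_posts(outdir / "posts.jsonl", posts))
        _out(entry, "surveys.csv", io.write_surveys(outdir / "surveys.csv", cohort.all_surveys()))
        _out(entry, "mentions.jsonl", io.write_mentions(outdir / "mentions.jsonl", cohort.mention_events()))
        io.write_truth(outdir / "truth.json", cohort.truth)
        _out(entry, "truth.json", len(cohort.users))

    elif stage == "score":
        posts = io.read_posts(_require(outdir / "posts.jsonl", stage))
        scorer = _lexicon_scorer(outdir)
        by_user: dict[str, list] = {}
        for post in posts:
            by_user.setdefault(post.user_id, []).append(post)
        series = {uid: aggregate_daily(ps, scorer) for uid, ps in sorted(by_user.items())}
        _out(entry, "daily_scores.csv", io.write_daily_scores(outdir / "daily_scores.csv", series))

    elif stage == "associate":
        series = io.read_daily_scores(_require(outdir / "daily_scores.csv", stage))
        surveys = io.read_surveys(_require(outdir / "surveys.csv", stage))
        windows = p.get("windows", list(range(1, 22)))
        if isinstance(windows, str):
            a, b = windows.split(":")
            windows = list(range(int(a), int(b) + 1))
        scan = association.sliding_window_scan(
            series, surveys, windows, min_posts_per_day=int(p.get("min_posts", 0))
        )
        frame = scan.to_frame()
        frame.to_csv(outdir / "scan.csv", index=False)
        _out(entry, "scan.csv", len(frame))
        entry["dropped"]["surveys_without_window"] = {
            str(w): len(surveys) - scan.n_rows[w] for w in windows
        }
        w = int(p.get("auc_window", 14))
        thr = int(p.get("threshold_si", 1))
        rows = association.build_scan_rows(series, surveys, w, int(p.get("min_posts", 0)))
        rows = rows.dropna(subset=["mean_score"])
        labels = (rows["si"] >= thr).astype(int)
        auc_rows = []
        if labels.nunique() == 2:
            res = association.permutation_auc_pvalue(
                rows["mean_score"].to_numpy(), labels.to_numpy(),
                n_perm=int(p.get("n_perm", 10_000)), seed=seed,
            )
            auc_rows.append(
                {"window": w, "threshold_si": thr, "auc": res.auc, "n_case": res.n_case,
                 "n_control": res.n_control, "perm_p": res.perm_p, "n_perm": res.n_perm}
            )
        pd.DataFrame(auc_rows).to_csv(outdir / "auc.csv", index=False)
        _out(entry, "auc.csv", len(auc_rows))

    elif stage == "trajectory":
        series = io.read_daily_scores(_require(outdir / "daily_scores.csv", stage))
        surveys = io.read_surveys(_require(outdir / "surveys.csv", stage))
        mode = p.get("mode", "all_days_between")
        pairs = trajectory.build_slope_pairs(series, surveys, mode=mode)
        frame = trajectory.pairs_frame(pairs)
        frame.to_csv(outdir / "slopes.csv", index=False)
        _out(entry, "slopes.csv", len(frame))
        thresholds = p.get("thresholds", list(range(10, 101)))
        if isinstance(thresholds, str):
            parts = [int(x) for x in thresholds.split(":")]
            start, stop = parts[0], parts[1]
            step = parts[2] if len(parts) > 2 else 1
            thresholds = list(range(start, stop + 1, step))
        scan = trajectory.gap_threshold_scan(pairs, thresholds)
        scan.to_csv(outdir / "gap_scan.csv", index=False)
        _out(entry, "gap_scan.csv", len(scan))

    elif stage == "forecast":
        series = io.read_daily_scores(_require(outdir / "daily_scores.csv", stage))
        eval_days = int(p.get("eval_days", 7))
        rows = []
        skipped = 0
        for uid in sorted(series):
            s = series[uid]
            try:
                ens = forecast.train_ensemble(s, seed=seed)
            except InsufficientHistoryError:
                skipped += 1
                continue
            days = s.days[-eval_days:]
            for day in days:
                actual = s.get(day)
                try:
                    pred = forecast.predict_next(ens, s, day)
                    base = forecast.last_value_baseline(s, day)
                except Exception:
                    continue
                rows.append(
                    {"user_id": uid, "date": day.isoformat(), "actual": actual,
                     "predicted": pred, "baseline": base}
                )
        pd.DataFrame(rows).to_csv(outdir / "forecast.csv", index=False)
        _out(entry, "forecast.csv", len(rows))
        entry["dropped"]["users_insufficient_history"] = skipped

    elif stage == "respond-score":
        events = io.read_mentions(_require(outdir / "mentions.jsonl", stage))
        posts = io.read_posts(_require(outdir / "posts.jsonl", stage))
        series = io.read_daily_scores(_require(outdir / "daily_scores.csv", stage))
        scorer = _lexicon_scorer(outdir)
        window_hours = float(p.get("window_hours", 72.0))
        horizon = int(p.get("horizon", 21))
        min_history = int(p.get("min_history", 200))
        pct = float(p.get("pct", 1.0))
        by_user: dict[str, list] = {}
        for post in posts:
            by_user.setdefault(post.user_id, []).append(post)
        filtered = [positivity.filter_responses(ev, window_hours) for ev in events]
        n_resp_before = sum(len(ev.responses) for ev in events)
        n_resp_after = sum(len(ev.responses) for ev in filtered)
        responded = [ev for ev in filtered if ev.responses]
        unresponded = [ev for ev in filtered if not ev.responses]
        models = {}
        usable = []
        short_history = 0
        for ev in responded:
            history = [
                post for post in by_user.get(ev.user_id, []) if post.timestamp < ev.mention_ts
            ]
            try:
                low, high, cuts = positivity.select_extremes(
                    history, scorer, pct=pct, min_history=min_history
                )
            except InsufficientHistoryError:
                short_history += 1
                continue
            models[ev.user_id] = positivity.train_positivity_model(
                low, high, seed=seed, cutpoints=cuts
            )
            usable.append(ev)
        entry["dropped"]["responses_outside_window"] = n_resp_before - n_resp_after
        entry["dropped"]["events_without_response"] = len(unresponded)
        entry["dropped"]["events_short_history"] = short_history
        scored, groups, thr = positivity.score_and_split(
            usable, models, threshold=p.get("threshold", "corpus_mean")
        )
        pd.DataFrame(scored).to_csv(outdir / "response_scores.csv", index=False)
        _out(entry, "response_scores.csv", len(scored))
        entry["positivity_threshold"] = thr
        grouped = {
            "responded": usable,
            "no_response": unresponded,
            "positive": [ev for ev in usable if groups[ev.key] == "positive"],
            "negative": [ev for ev in usable if groups[ev.key] == "negative"],
        }
        traj = positivity.post_mention_trajectory(grouped, series, horizon_days=horizon)
        rows = []
        for g, (curve, res) in traj.items():
            for _, r in curve.iterrows():
                rows.append(
                    {"group": g, "day": int(r["day"]), "mean_score": r["mean_score"],
                     "n": int(r["n"]), "rho": res.rho, "p": res.p}
                )
        pd.DataFrame(rows).to_csv(outdir / "trajectory.csv", index=False)
        _out(entry, "trajectory.csv", len(rows))
        if grouped["responded"] and grouped["no_response"]:
            comp = positivity.last_window_comparison(
                {"responded": grouped["responded"], "no_response": grouped["no_response"]},
                series, horizon_days=horizon,
            )
            entry["last_window_comparison"] = comp._asdict()

    elif stage == "enrich":
        scores = pd.read_csv(_require(outdir / "response_scores.csv", stage))
        events = {ev.key: ev for ev in io.read_mentions(outdir / "mentions.jsonl")}
        texts: dict[str, list[str]] = {"positive": [], "negative": []}
        for _, r in scores.iterrows():
            ev = events.get(str(r["event_key"]))
            if ev is None:
                continue
            for resp in ev.responses:
                if resp.responder_id == r["responder_id"]:
                    texts[str(r["group"])].append(resp.text)
        frames = []
        for unit in ("word", "bigram"):
            if texts["positive"] and texts["negative"]:
                ca = enrichment.corpus_counts(texts["negative"], unit=unit)
                cb = enrichment.corpus_counts(texts["positive"], unit=unit)
                frames.append(
                    enrichment.enrichment_test(ca, cb, unit=unit, min_count=int(p.get("min_count", 5)))
                )
        table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        table.to_csv(outdir / "enrichment.csv", index=False)
        _out(entry, "enrichment.csv", len(table))

    else:  # pragma: no cover - guarded by validate_config
        raise ConfigurationError(f"unknown stage {stage!r}")
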