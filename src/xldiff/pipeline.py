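"""End-to-end orchestration: synth → ingest → influence → keywords → rbo →
stance → cross-lingual, with a validated config and a run manifest.

Each stage reads its predecessor's files from the artifact directory and
writes CSV/JSON outputs, so any stage can be re-run in isolation.  All
randomness flows from one top-level seed, and a rerun with the same config
and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .diffusion import (
    build_url_language_table,
    build_url_records,
    fit_timing_distribution,
    negative_mass,
    nonnative_share_ranking,
    timing_observations,
)
from .events import LANGUAGES, assign_native_language, partition_by_month, read_events, write_events
from .influence import build_degree_table, influence_ranking
from .keywords import count_keywords, load_stoplist
from .rbo import monthly_rbo_series
from .stance import StanceLabel, coverage_stats, propagate_stance, stance_timeseries
from .synth import GroundTruth, SyntheticConfig, generate_corpus, monthly_topk_seed_labels, write_fixture

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "mode": "synthetic",
    "seed": 0,
    "synthetic": {},
    "events": None,
    "seeds_file": None,
    "stoplist_file": None,
    "top_k": 10,
    "rbo": {"p": 0.9, "variant": "extrapolated"},
    "max_hops": {"en": 6, "ja": 5},
    "youtube_excluded": True,
    "nonnative_top_n": 200,
}


class ConfigError(ValueError):
    """The run configuration violates the documented schema."""


def load_config(source: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    """Load and validate a YAML/JSON config file or an in-memory mapping."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text(encoding="utf-8")) or {}
    else:
        raw = dict(source)
    return validate_config(raw)


def validate_config(raw: Mapping[str, Any]) -> dict[str, Any]:
    """Normalize against the schema; raises ConfigError before any computation."""
    unknown = set(raw) - set(DEFAULT_CONFIG) - {"out"}
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in raw.items():
        if key in ("rbo", "max_hops") and isinstance(value, Mapping):
            cfg[key].update(value)
        else:
            cfg[key] = value
    if cfg["mode"] not in ("synthetic", "files"):
        raise ConfigError(f"mode must be 'synthetic' or 'files', got {cfg['mode']!r}")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    if cfg["mode"] == "files":
        if not cfg["events"]:
            raise ConfigError("files mode requires an 'events' path")
        if not cfg["seeds_file"]:
            raise ConfigError("files mode requires a 'seeds_file' path")
    if not 0.0 < float(cfg["rbo"]["p"]) < 1.0:
        raise ConfigError("rbo.p must lie strictly inside (0, 1)")
    if cfg["rbo"]["variant"] not in ("truncated", "extrapolated"):
        raise ConfigError(f"unknown rbo variant {cfg['rbo']['variant']!r}")
    for lang in LANGUAGES:
        hops = cfg["max_hops"].get(lang)
        if not isinstance(hops, int) or hops < 1:
            raise ConfigError(f"max_hops.{lang} must be an integer >= 1")
    if int(cfg["top_k"]) < 1:
        raise ConfigError("top_k must be >= 1")
    try:
        SyntheticConfig(**cfg["synthetic"]).validate()
    except TypeError as exc:
        raise ConfigError(f"invalid synthetic config: {exc}") from exc
    return cfg


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def _read_labels(out_dir: Path) -> dict[str, dict[str, StanceLabel]]:
    df = pd.read_csv(out_dir / "stance_labels.csv", dtype=str)
    labels: dict[str, dict[str, StanceLabel]] = {lang: {} for lang in LANGUAGES}
    for row in df.itertuples(index=False):
        labels[row.language][row.user] = StanceLabel(
            row.user, row.stance, hop=int(row.hop), is_seed=row.is_seed == "True"
        )
    return labels


def _read_language_map(out_dir: Path) -> dict[str, str]:
    df = pd.read_csv(out_dir / "user_languages.csv", dtype=str)
    return dict(zip(df["user"], df["language"]))


def stage_synth(cfg: Mapping[str, Any], out_dir: Path) -> None:
    synth_cfg = SyntheticConfig(**{**cfg["synthetic"], "rng_seed": cfg["seed"]})
    events, truth = generate_corpus(synth_cfg)
    write_fixture(events, truth, out_dir)
    seeds = monthly_topk_seed_labels(events, truth)
    rows = [
        {"user": s.user, "stance": s.stance, "month": "", "language": lang}
        for lang in LANGUAGES
        for s in sorted(seeds[lang], key=lambda s: s.user)
    ]
    _write_csv(pd.DataFrame(rows, columns=["user", "stance", "month", "language"]),
               out_dir / "seeds.csv")


def stage_ingest(cfg: Mapping[str, Any], out_dir: Path) -> None:
    events = read_events(out_dir / "events.jsonl")
    language_map = dict(sorted(assign_native_language(events).items()))
    _write_csv(
        pd.DataFrame({"user": list(language_map), "language": list(language_map.values())}),
        out_dir / "user_languages.csv",
    )


def stage_influence(cfg: Mapping[str, Any], out_dir: Path) -> None:
    events = read_events(out_dir / "events.jsonl")
    k = int(cfg["top_k"])
    degree_rows, rank_rows = [], []
    for lang in LANGUAGES:
        stream = [e for e in events if e.stream_language == lang]
        for month, bucket in partition_by_month(stream).items():
            table = build_degree_table(bucket, month)
            for user in sorted(table.degrees):
                degree_rows.append(
                    {"month": month, "language": lang, "user": user, "degree": table.degrees[user]}
                )
            ranking = influence_ranking(table, k)
            for rank, (user, degree) in enumerate(zip(ranking.users, ranking.degrees), 1):
                rank_rows.append(
                    {"month": month, "language": lang, "rank": rank, "user": user,
                     "degree": degree, "short": ranking.short}
                )
    _write_csv(pd.DataFrame(degree_rows, columns=["month", "language", "user", "degree"]),
               out_dir / "degrees.csv")
    _write_csv(pd.DataFrame(rank_rows, columns=["month", "language", "rank", "user", "degree", "short"]),
               out_dir / "rankings.csv")


def stage_keywords(cfg: Mapping[str, Any], out_dir: Path) -> None:
    events = read_events(out_dir / "events.jsonl")
    k = int(cfg["top_k"])
    kwargs = {}
    if cfg.get("stoplist_file"):
        kwargs["stoplist"] = load_stoplist(cfg["stoplist_file"])
    rows = []
    for lang in LANGUAGES:
        stream = [e for e in events if e.stream_language == lang]
        for month, bucket in partition_by_month(stream).items():
            for rank, (keyword, count) in enumerate(count_keywords(bucket, k=k, **kwargs), 1):
                rows.append({"month": month, "language": lang, "rank": rank,
                             "keyword": keyword, "count": count})
    _write_csv(pd.DataFrame(rows, columns=["month", "language", "rank", "keyword", "count"]),
               out_dir / "keywords.csv")


def stage_rbo(cfg: Mapping[str, Any], out_dir: Path) -> None:
    from .influence import RankedList

    rankings = pd.read_csv(out_dir / "rankings.csv", dtype={"user": str})
    p = float(cfg["rbo"]["p"])
    variant = cfg["rbo"]["variant"]
    k = int(cfg["top_k"])
    rows = []
    for lang in LANGUAGES:
        monthly = []
        for month, grp in rankings[rankings.language == lang].groupby("month"):
            grp = grp.sort_values("rank")
            monthly.append(RankedList(month=month, users=tuple(grp.user),
                                      degrees=tuple(grp.degree), short=bool(grp.short.iloc[0])))
        for month, result in monthly_rbo_series(monthly, p=p, k=k, variant=variant):
            rows.append({"language": lang, "month": month, "p": result.p,
                         "depth": result.depth, "variant": result.variant,
                         "score": result.score})
    _write_csv(pd.DataFrame(rows, columns=["language", "month", "p", "depth", "variant", "score"]),
               out_dir / "rbo.csv")


def stage_stance(cfg: Mapping[str, Any], out_dir: Path) -> None:
    events = read_events(out_dir / "events.jsonl")
    seeds_df = pd.read_csv(out_dir / "seeds.csv", dtype=str)
    label_rows, coverage = [], {}
    for lang in LANGUAGES:
        stream = [e for e in events if e.stream_language == lang]
        seeds = [
            StanceLabel(row.user, row.stance, hop=0, is_seed=True)
            for row in seeds_df[seeds_df.language == lang].itertuples(index=False)
        ]
        if not seeds:
            continue
        labels = propagate_stance(stream, seeds, max_hops=int(cfg["max_hops"][lang]))
        total_users = len({u for e in stream for u in (e.retweeter_id, e.source_user_id)})
        coverage[lang] = coverage_stats(labels, total_users).as_report()
        for user in sorted(labels):
            lab = labels[user]
            label_rows.append({"language": lang, "user": user, "stance": lab.stance,
                               "hop": lab.hop, "is_seed": lab.is_seed})
    _write_csv(pd.DataFrame(label_rows, columns=["language", "user", "stance", "hop", "is_seed"]),
               out_dir / "stance_labels.csv")
    (out_dir / "coverage.json").write_text(json.dumps(coverage, indent=2, sort_keys=True) + "\n",
                                           encoding="utf-8")


def _fit_block(observations, which: str) -> dict[str, Any] | None:
    values = [getattr(o, which) for o in observations]
    block: dict[str, Any] = {"n": len(values)}
    if values:
        block["negative_mass_empirical"] = sum(1 for v in values if v < 0) / len(values)
    if len(values) >= 10 and len(set(values)) > 1:
        params = fit_timing_distribution(observations, which)
        block.update(
            location=params.location, rate=params.rate, asymmetry=params.asymmetry,
            log_likelihood=params.log_likelihood,
            negative_mass_model=params.negative_mass(),
        )
    return block


def stage_crosslingual(cfg: Mapping[str, Any], out_dir: Path) -> None:
    events = read_events(out_dir / "events.jsonl")
    labels_by_lang = _read_labels(out_dir)
    labels = {u: lab for by_lang in labels_by_lang.values() for u, lab in by_lang.items()}
    language_map = _read_language_map(out_dir)
    records = build_url_records(events, labels, language_map)
    url_languages = {rec.url.canonical: rec.url_language for rec in records}

    _write_csv(
        pd.DataFrame(
            [
                {
                    "url": rec.url.canonical, "host": rec.url.host,
                    "is_youtube": rec.url.is_youtube, "url_language": rec.url_language,
                    "retweets_en": rec.retweets_en, "retweets_ja": rec.retweets_ja,
                    "first_post_day_en": rec.first_post_day_en or "",
                    "first_post_day_ja": rec.first_post_day_ja or "",
                    "shared": rec.shared,
                }
                for rec in records
            ],
            columns=["url", "host", "is_youtube", "url_language", "retweets_en",
                     "retweets_ja", "first_post_day_en", "first_post_day_ja", "shared"],
        ),
        out_dir / "url_records.csv",
    )

    degrees = build_degree_table(events).degrees
    ranking = nonnative_share_ranking(events, labels, language_map, url_languages,
                                      degrees, top_n=int(cfg["nonnative_top_n"]))
    _write_csv(ranking, out_dir / "nonnative_ranking.csv")

    all_obs = timing_observations(records, youtube_excluded=False)
    _write_csv(
        pd.DataFrame(
            [dataclasses.asdict(o) for o in all_obs],
            columns=["url", "direction", "day_diff_first", "day_diff_peak", "is_youtube"],
        ),
        out_dir / "timing_observations.csv",
    )

    youtube_excluded = bool(cfg["youtube_excluded"])
    fits: dict[str, Any] = {"youtube_excluded": youtube_excluded, "directions": {}}
    primary = [o for o in all_obs if not (youtube_excluded and o.is_youtube)]
    for direction in ("en_url_adopted_by_ja", "ja_url_adopted_by_en"):
        obs = [o for o in primary if o.direction == direction]
        fits["directions"][direction] = {
            "first": _fit_block(obs, "day_diff_first"),
            "peak": _fit_block(obs, "day_diff_peak"),
        }
    fits["pooled"] = {
        "first": _fit_block(primary, "day_diff_first"),
        "peak": _fit_block(primary, "day_diff_peak"),
    }
    (out_dir / "ald_fit.json").write_text(json.dumps(fits, indent=2, sort_keys=True) + "\n",
                                          encoding="utf-8")


STAGES = {
    "ingest": stage_ingest,
    "influence": stage_influence,
    "keywords": stage_keywords,
    "rbo": stage_rbo,
    "stance": stage_stance,
    "crosslingual": stage_crosslingual,
}

_OUTPUT_FILES = (
    "events.jsonl", "user_languages.csv", "degrees.csv", "rankings.csv",
    "keywords.csv", "rbo.csv", "seeds.csv", "stance_labels.csv", "coverage.json",
    "url_records.csv", "nonnative_ranking.csv", "timing_observations.csv", "ald_fit.json",
)


def run_pipeline(config: str | Path | Mapping[str, Any], out_dir: str | Path | None = None) -> Path:
    """Run every stage end-to-end and write a run manifest; returns the artifact dir."""
    cfg = load_config(config)
    out = Path(out_dir if out_dir is not None else cfg.get("out") or "xldiff_run")
    out.mkdir(parents=True, exist_ok=True)

    if cfg["mode"] == "synthetic":
        stage_synth(cfg, out)
    else:
        events = read_events(cfg["events"])
        write_events(events, out / "events.jsonl")
        seeds_df = pd.read_csv(cfg["seeds_file"], dtype=str)
        for col in ("user", "stance"):
            if col not in seeds_df.columns:
                raise ConfigError(f"seeds file missing column {col!r}")
        if "language" not in seeds_df.columns:
            raise ConfigError("seeds file missing column 'language'")
        _write_csv(seeds_df, out / "seeds.csv")

    for name, stage in STAGES.items():
        logger.info("running stage %s", name)
        stage(cfg, out)

    cfg_json = json.dumps(cfg, sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "row_counts": {
            name: (sum(1 for _ in (out / name).open(encoding="utf-8")) if (out / name).exists() else None)
            for name in _OUTPUT_FILES
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                                           encoding="utf-8")
    return out
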