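"""Dataset readers/writers, run configuration and the pipeline driver.

CSV dialects (all comma-separated, UTF-8, header required, labels
serialized lower-case):

* wide traces:    ``user_id,instance_id,label,s000..s179``
* long traces:    ``user_id,instance_id,t,value,label``
* tri-axial long: ``user_id,instance_id,t,ax,ay,az,label`` (converted to
  magnitudes on read)
* features:       ``user_id,instance_id,label,f00..f29`` plus a sidecar
  JSON documenting feature order, filter spec and band edge.

``run_pipeline`` executes the whole loop described by the run config —
load or synthesize traces, featurize, evaluate the selected methods per
user, optionally run the statistics suite — and writes a results table,
stats report, transcript log and a run manifest (config + hash +
versions) so reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .evaluation import DEFAULT_METHODS, evaluate_all
from .inference import NearestShotBackend
from .preprocessing import (
    FeatureVector,
    FilterSpec,
    MagnitudeTrace,
    SEGMENT_FEATURE_NAMES,
    canonical_label,
    featurize_trace,
    magnitude,
)
from .scoring import (
    APIBackend,
    DomainKnowledge,
    HeuristicBackend,
    LLMBackend,
    ScriptedBackend,
    TranscriptLogger,
)
from .selection import PRESETS, SelectionConfig
from .stats import (
    MethodScoreTable,
    cliffs_delta,
    friedman_statistic,
    iman_davenport_f,
    nemenyi_posthoc,
    summarize,
)
from .synth import SyntheticSpec, dataset_to_wide_frame, generate_dataset

__all__ = [
    "load_dataset",
    "write_wide_csv",
    "write_features_csv",
    "read_features_csv",
    "group_by_user",
    "RunConfig",
    "make_backends",
    "run_pipeline",
    "stats_report",
]


# ---------------------------------------------------------------------------
# Trace I/O
# ---------------------------------------------------------------------------


def _fail_row(row_idx, msg: str) -> None:
    raise ValueError(f"row {row_idx}: {msg}")


def load_dataset(path: str | Path, format: str = "wide") -> list[MagnitudeTrace]:
    """Read labeled magnitude traces from CSV.

    ``format`` is one of ``wide``, ``long`` or ``triaxial``. Errors cite
    the offending row.
    """
    df = pd.read_csv(path)
    if format == "wide":
        sample_cols = sorted(c for c in df.columns if c.startswith("s") and c[1:].isdigit())
        required = {"user_id", "instance_id", "label"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"wide CSV missing columns {sorted(missing)}")
        if not sample_cols:
            raise ValueError("wide CSV has no sample columns (s000..)")
        expected = [f"s{i:03d}" for i in range(len(sample_cols))]
        if sample_cols != expected:
            raise ValueError(
                f"sample columns must be contiguous s000..s{len(sample_cols) - 1:03d}"
            )
        traces = []
        for idx, row in df.iterrows():
            vals = row[sample_cols].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                _fail_row(idx, "non-finite sample values")
            try:
                traces.append(
                    MagnitudeTrace(
                        user_id=str(row["user_id"]),
                        instance_id=str(row["instance_id"]),
                        samples=vals,
                        label=canonical_label(row["label"]),
                    )
                )
            except ValueError as exc:
                _fail_row(idx, str(exc))
        return traces

    if format in ("long", "triaxial"):
        value_cols = ["value"] if format == "long" else ["ax", "ay", "az"]
        required = {"user_id", "instance_id", "t", "label", *value_cols}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{format} CSV missing columns {sorted(missing)}")
        traces = []
        for (user_id, instance_id), grp in df.groupby(
            ["user_id", "instance_id"], sort=True
        ):
            grp = grp.sort_values("t")
            labels = set(grp["label"].map(canonical_label))
            if len(labels) != 1:
                raise ValueError(
                    f"instance {user_id}/{instance_id} has inconsistent labels {labels}"
                )
            if format == "long":
                samples = grp["value"].to_numpy(dtype=float)
            else:
                samples = np.array(
                    [
                        magnitude(ax, ay, az)
                        for ax, ay, az in grp[["ax", "ay", "az"]].to_numpy(dtype=float)
                    ]
                )
            traces.append(
                MagnitudeTrace(
                    user_id=str(user_id),
                    instance_id=str(instance_id),
                    samples=samples,
                    label=labels.pop(),
                )
            )
        return traces

    raise ValueError(f"unknown dataset format {format!r}")


def write_wide_csv(traces: Sequence[MagnitudeTrace], path: str | Path) -> None:
    dataset_to_wide_frame(list(traces)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature I/O
# ---------------------------------------------------------------------------


def write_features_csv(
    features: Sequence[FeatureVector],
    path: str | Path,
    filter_spec: Optional[FilterSpec] = None,
    low_band_hz: float = 10.0,
) -> None:
    """Feature table plus a sidecar JSON documenting the feature layout."""
    if not features:
        raise ValueError("no feature vectors to write")
    dim = len(features[0])
    cols = [f"f{i:02d}" for i in range(dim)]
    rows = [
        {"user_id": fv.user_id, "instance_id": fv.instance_id, "label": fv.label}
        | dict(zip(cols, fv.values))
        for fv in features
    ]
    pd.DataFrame(rows, columns=["user_id", "instance_id", "label"] + cols).to_csv(
        path, index=False
    )
    spec = filter_spec or FilterSpec()
    n_segments = dim // len(SEGMENT_FEATURE_NAMES)
    sidecar = {
        "feature_order": [
            f"segment{s}_{name}"
            for s in range(1, n_segments + 1)
            for name in SEGMENT_FEATURE_NAMES
        ],
        "filter": {"cutoff_hz": spec.cutoff_hz, "order": spec.order, "fs": spec.fs},
        "low_band_hz": low_band_hz,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=2))


def read_features_csv(path: str | Path) -> list[FeatureVector]:
    df = pd.read_csv(path)
    cols = sorted(c for c in df.columns if c.startswith("f") and c[1:].isdigit())
    if not cols:
        raise ValueError("feature CSV has no f00.. columns")
    out = []
    for idx, row in df.iterrows():
        label = row.get("label")
        out.append(
            FeatureVector(
                user_id=str(row["user_id"]),
                instance_id=str(row["instance_id"]),
                values=row[cols].to_numpy(dtype=float),
                label=None if pd.isna(label) else canonical_label(label),
            )
        )
    return out


def group_by_user(features: Sequence[FeatureVector]) -> dict[str, list[FeatureVector]]:
    grouped: dict[str, list[FeatureVector]] = {}
    for fv in features:
        grouped.setdefault(fv.user_id, []).append(fv)
    return grouped


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully serializable pipeline configuration."""

    dataset_path: Optional[str] = None  # wide-format trace CSV
    features_path: Optional[str] = None  # precomputed feature CSV
    synthetic: Optional[dict] = None  # kwargs for SyntheticSpec
    methods: tuple[str, ...] = DEFAULT_METHODS
    preset: Optional[str] = None  # overrides distance_k/top_k when set
    distance_k: int = 5
    top_k: int = 3
    n_shots: int = 2
    backend: str = "heuristic"  # heuristic | scripted | api
    model: str = "gpt-4o-mini"
    temperature: float = 0.3
    api_key_env: str = "OPENAI_API_KEY"
    dk_enabled: bool = True
    low_band_hz: float = 10.0
    cutoff_hz: float = 30.0
    filter_order: int = 4
    fs: float = 256.0
    filter_full_trace: bool = False
    seed: int = 0
    out_dir: str = "hedlm_out"
    run_stats: bool = True

    def __post_init__(self) -> None:
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; have {sorted(PRESETS)}")
        if self.backend not in ("heuristic", "scripted", "api"):
            raise ValueError(f"unknown backend kind {self.backend!r}")
        if self.n_shots != 2:
            raise ValueError("only the 2-shot configuration is supported")
        SelectionConfig(self.distance_k, self.top_k)  # validates the pair
        sources = [self.dataset_path, self.features_path, self.synthetic]
        if sum(s is not None for s in sources) != 1:
            raise ValueError(
                "exactly one of dataset_path, features_path or synthetic required"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @property
    def selection(self) -> SelectionConfig:
        if self.preset is not None:
            return PRESETS[self.preset]
        return SelectionConfig(self.distance_k, self.top_k)

    @property
    def filter_spec(self) -> FilterSpec:
        return FilterSpec(cutoff_hz=self.cutoff_hz, order=self.filter_order, fs=self.fs)


def make_backends(cfg: RunConfig) -> tuple[LLMBackend, Optional[LLMBackend]]:
    """(classification backend, scoring backend) for a run config.

    The ``heuristic`` kind pairs the rule scorer with the nearest-shot
    mock predictor — the fully offline, deterministic closed loop. The
    ``api`` kind uses the remote model for both roles.
    """
    if cfg.backend == "heuristic":
        return NearestShotBackend(), HeuristicBackend()
    if cfg.backend == "scripted":
        return ScriptedBackend(), None
    return (
        APIBackend(
            model_name=cfg.model,
            temperature=cfg.temperature,
            api_key_env=cfg.api_key_env,
        ),
        None,
    )


# ---------------------------------------------------------------------------
# Statistics report
# ---------------------------------------------------------------------------


def stats_report(table: MethodScoreTable) -> dict:
    """Full comparison report over a users x methods macro-F1 table."""
    chi2, chi2_p = friedman_statistic(table)
    idf, idf_p = iman_davenport_f(table)
    nem = nemenyi_posthoc(table)
    deltas = {
        f"{a} vs {b}": cliffs_delta(table.column(a), table.column(b))
        for i, a in enumerate(table.methods)
        for b in table.methods[i + 1 :]
    }
    summary = summarize(table)
    return {
        "n_users": len(table.users),
        "methods": list(table.methods),
        "summary": summary.to_dict(orient="records"),
        "friedman": {"chi2": chi2, "p": chi2_p},
        "iman_davenport": {"f": idf, "p": idf_p},
        "nemenyi_p": {
            a: {b: float(nem.loc[a, b]) for b in table.methods} for a in table.methods
        },
        "cliffs_delta": deltas,
    }


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(cfg: RunConfig) -> dict[str, str]:
    """Execute the configured end-to-end run; returns the output paths.

    Outputs in ``cfg.out_dir``: ``scores.csv`` (users x methods macro-F1
    percentages), ``results.jsonl`` (per-method per-user summaries),
    ``transcripts.jsonl``, ``stats.json`` (when enabled and the table is
    large enough) and ``manifest.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash,
        "versions": {
            "package": _pkg_version,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "completed": False,
    }
    manifest_path = out / "manifest.json"
    try:
        if cfg.synthetic is not None:
            traces = generate_dataset(SyntheticSpec(**cfg.synthetic))
        elif cfg.dataset_path is not None:
            traces = load_dataset(cfg.dataset_path, format="wide")
        else:
            traces = None

        if traces is not None:
            features = [
                featurize_trace(
                    tr,
                    cfg.filter_spec,
                    low_band_hz=cfg.low_band_hz,
                    filter_full_trace=cfg.filter_full_trace,
                )
                for tr in traces
            ]
        else:
            features = read_features_csv(cfg.features_path)
        features_path = out / "features.csv"
        write_features_csv(features, features_path, cfg.filter_spec, cfg.low_band_hz)

        dataset = group_by_user(features)
        backend, scoring_backend = make_backends(cfg)
        needs_transcripts = any(m != "ml" for m in cfg.methods)
        transcript = (
            TranscriptLogger(str(out / "transcripts.jsonl")) if needs_transcripts else None
        )
        dk = DomainKnowledge.default() if cfg.dk_enabled else DomainKnowledge.disabled()
        presets = dict(PRESETS)
        if cfg.preset is None:
            presets["custom"] = cfg.selection
        table = evaluate_all(
            dataset,
            cfg.methods,
            backend=backend,
            dk=dk,
            seed=cfg.seed,
            presets=presets,
            scoring_backend=scoring_backend,
            transcript=transcript,
        )
        scores_path = out / "scores.csv"
        df = table.to_dataframe()
        df.to_csv(scores_path, index=False)

        results_path = out / "results.jsonl"
        with open(results_path, "w", encoding="utf-8") as fh:
            for i, user in enumerate(table.users):
                for j, method in enumerate(table.methods):
                    fh.write(
                        json.dumps(
                            {
                                "user_id": user,
                                "method": method,
                                "macro_f1_pct": table.values[i, j],
                                "config_hash": cfg.config_hash,
                            }
                        )
                        + "\n"
                    )

        outputs = {
            "features": str(features_path),
            "scores": str(scores_path),
            "results": str(results_path),
        }
        if transcript is not None:
            outputs["transcripts"] = str(out / "transcripts.jsonl")
        if cfg.run_stats and len(table.users) >= 2 and len(table.methods) >= 2:
            report = stats_report(table)
            report["config_hash"] = cfg.config_hash
            stats_path = out / "stats.json"
            stats_path.write_text(json.dumps(report, indent=2))
            outputs["stats"] = str(stats_path)
        manifest["outputs"] = outputs
        manifest["completed"] = True
        return outputs | {"manifest": str(manifest_path)}
    finally:
        manifest_path.write_text(json.dumps(manifest, indent=2))
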