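"""End-to-end pipeline: curate → featurize → train → cv → importance → design.

A :class:`PipelineConfig` (loadable from YAML or TOML, unknown keys
rejected) plus a seed fully determines every artifact.  Each run writes a
manifest (tool version, config hash, seed, per-stage timings and counts)
and stamps every artifact with the config hash; loading artifacts from a
different configuration is refused.
"""

from __future__ import annotations

import hashlib
import json
import time
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .curation import ColorClass, CurationConfig, curate_training
from .design import design_top_k
from .ensemble import TrainingConfig, cross_validate, train_ensemble
from .features import featurize
from .importance import class_frequencies, net_importance, shadow_importance
from .io import (
    load_training_table,
    save_training_table,
    write_exclusions_csv,
    write_fasta,
    write_labeled_csv,
)
from .synthetic import default_rules, generate_dataset

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "config_hash"]


def _from_mapping(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {where} config keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class ImportanceConfig:
    n_repeats: int = 10
    n_trees: int = 100


@dataclass(frozen=True)
class DesignConfig:
    targets: tuple[str, ...] = ("Green", "FarRed", "NIR")
    k: int = 124
    length: int = 10
    block_size: int = 65536


@dataclass(frozen=True)
class SimulateConfig:
    n: int = 2000
    label_noise: float = 0.0


@dataclass(frozen=True)
class PipelineConfig:
    """Typed configuration for the full pipeline."""

    curation: CurationConfig = field(default_factory=CurationConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    importance: ImportanceConfig = field(default_factory=ImportanceConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    seed: int = 0
    training_table: str | None = None  # path; None -> simulate input data

    def to_dict(self) -> dict:
        d = asdict(self)
        d["curation"]["gap"] = list(d["curation"]["gap"])
        d["design"]["targets"] = list(d["design"]["targets"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sub = {}
        if "curation" in data:
            c = dict(data.pop("curation"))
            if "gap" in c:
                c["gap"] = tuple(c["gap"])
            sub["curation"] = _from_mapping(CurationConfig, c, "curation")
        if "training" in data:
            sub["training"] = _from_mapping(TrainingConfig, dict(data.pop("training")), "training")
        if "importance" in data:
            sub["importance"] = _from_mapping(ImportanceConfig, dict(data.pop("importance")), "importance")
        if "design" in data:
            d = dict(data.pop("design"))
            if "targets" in d:
                d["targets"] = tuple(d["targets"])
            sub["design"] = _from_mapping(DesignConfig, d, "design")
        if "simulate" in data:
            sub["simulate"] = _from_mapping(SimulateConfig, dict(data.pop("simulate")), "simulate")
        top = _from_mapping(
            cls, {**data, **sub}, "pipeline"
        )
        return top

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text) or {}
        elif path.suffix == ".toml":
            data = tomllib.loads(text)
        else:
            raise ValueError(f"config file must be .yaml/.yml or .toml, got {path.suffix}")
        return cls.from_dict(data)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunManifest:
    """Provenance record written for every pipeline run."""

    version: str
    config_hash: str
    seed: int
    input_fingerprints: dict
    stage_seconds: dict
    stage_counts: dict
    failed_stage: str | None = None

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    skip: set[str] | None = None,
) -> RunManifest:
    """Execute the pipeline stages in order, writing artifacts to ``out_dir``.

    Stages: ``simulate`` (only when no training table is configured),
    ``curate``, ``train``, ``cv``, ``importance``, ``design``.  Any stage
    in ``skip`` is omitted (downstream stages needing its output are
    skipped too).  Identical config + seed reproduce identical artifacts.
    """
    skip = skip or set()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    manifest = RunManifest(
        version=__version__,
        config_hash=chash,
        seed=config.seed,
        input_fingerprints={},
        stage_seconds={},
        stage_counts={},
    )
    stamp = f"config_hash={chash}"

    def stage(name):
        class _Timer:
            def __enter__(self_t):
                self_t.t0 = time.perf_counter()
                return self_t

            def __exit__(self_t, et, ev, tb):
                manifest.stage_seconds[name] = round(time.perf_counter() - self_t.t0, 3)
                if et is not None:
                    manifest.failed_stage = name
                    manifest.save(out / "manifest.json")
                return False

        return _Timer()

    try:
        # ---- input ------------------------------------------------------
        if config.training_table is not None:
            path = Path(config.training_table)
            records = load_training_table(path)
            manifest.input_fingerprints[str(path)] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()[:16]
        elif "simulate" not in skip:
            with stage("simulate"):
                rules = default_rules(label_noise=config.simulate.label_noise)
                ds = generate_dataset(rules, n=config.simulate.n, seed=config.seed)
                # one synthetic bright peak per non-Dark record, mid-class
                from .synthetic import CLASS_WAVELENGTH_INTERVALS

                records = []
                rng = np.random.default_rng(config.seed + 1)
                for seq, label in zip(ds.sequences, ds.labels):
                    if label is ColorClass.DARK:
                        records.append((seq, []))
                    else:
                        lo, hi = CLASS_WAVELENGTH_INTERVALS[label]
                        records.append(
                            (seq, [(float(rng.uniform(lo, hi)), 1.0)])
                        )
                save_training_table(records, out / "training_table.csv", comment=stamp)
                with open(out / "rules.json", "w") as fh:
                    json.dump({"config_hash": chash, "rules": rules.to_dict()}, fh, indent=2)
                manifest.stage_counts["simulate"] = len(records)
        else:
            raise ValueError("no training table configured and simulate stage skipped")

        # ---- curate -----------------------------------------------------
        if "curate" in skip:
            manifest.save(out / "manifest.json")
            return manifest
        with stage("curate"):
            result = curate_training(records, config.curation)
            write_labeled_csv(result.labeled, out / "labeled.csv", comment=stamp)
            write_exclusions_csv(result.exclusions, out / "exclusions.csv", comment=stamp)
            manifest.stage_counts["curate"] = {
                "in": len(records),
                "labeled": len(result.labeled),
                "excluded": result.exclusion_counts(),
            }

        X, seqs = featurize([r.sequence for r in result.labeled])
        labels = [r.label for r in result.labeled]

        # ---- train ------------------------------------------------------
        if "train" in skip:
            manifest.save(out / "manifest.json")
            return manifest
        with stage("train"):
            cfg = TrainingConfig(**{**asdict(config.training), "seed": config.seed})
            model = train_ensemble(X, labels, cfg)
            d = model.to_dict()
            d["config_hash"] = chash
            with open(out / "model.json", "w") as fh:
                json.dump(d, fh)
            manifest.stage_counts["train"] = {"members": model.n_members}

        # ---- cv ---------------------------------------------------------
        if "cv" not in skip:
            with stage("cv"):
                report = cross_validate(X, labels, cfg)
                import pandas as pd

                df = pd.DataFrame(report.as_rows())
                with open(out / "cv_report.csv", "w") as fh:
                    fh.write(f"# {stamp}\n")
                    df.to_csv(fh, index=False)
                manifest.stage_counts["cv"] = {"pairs": len(report.entries)}

        # ---- importance -------------------------------------------------
        if "importance" not in skip:
            with stage("importance"):
                from .ensemble import class_pairs

                y_arr = np.array([l.value for l in labels])
                records_by_pair = {}
                rows = []
                iroot = np.random.SeedSequence(config.seed + 2).spawn(10)
                for pair, ss in zip(class_pairs(), iroot):
                    mask = np.isin(y_arr, [pair[0].value, pair[1].value])
                    recs = shadow_importance(
                        X[mask],
                        (y_arr[mask] == pair[0].value).astype(int),
                        pair,
                        n_repeats=config.importance.n_repeats,
                        n_trees=config.importance.n_trees,
                        seed=int(np.random.default_rng(ss).integers(2**31 - 1)),
                    )
                    records_by_pair[pair] = recs
                    rows.extend(
                        {
                            "feature": r.feature,
                            "class_a": r.pair[0].value,
                            "class_b": r.pair[1].value,
                            "misa_mean": r.misa_mean,
                            "misa_sd": r.misa_sd,
                            "max_shadow": r.max_shadow,
                            "selected": r.selected,
                        }
                        for r in recs
                    )
                import pandas as pd

                with open(out / "misa.csv", "w") as fh:
                    fh.write(f"# {stamp}\n")
                    pd.DataFrame(rows).to_csv(fh, index=False)
                nis = net_importance(records_by_pair, class_frequencies(X, labels))
                with open(out / "nis.csv", "w") as fh:
                    fh.write(f"# {stamp}\n")
                    nis.scores.rename_axis("feature").to_csv(fh)
                manifest.stage_counts["importance"] = {
                    "selected_union": len(
                        {r["feature"] for r in rows if r["selected"]}
                    )
                }

        # ---- design -----------------------------------------------------
        if "design" not in skip:
            with stage("design"):
                for target in config.design.targets:
                    run = design_top_k(
                        model,
                        ColorClass(target),
                        k=config.design.k,
                        L=config.design.length,
                        block_size=config.design.block_size,
                    )
                    with open(out / f"design_{target}.csv", "w") as fh:
                        fh.write(f"# {stamp}\n")
                        run.ranking.to_csv(fh, index=False)
                    write_fasta(
                        run.ranking["sequence"].tolist(),
                        out / f"design_{target}.fasta",
                        ids=[f"{target}_{r}" for r in run.ranking["rank"]],
                    )
                manifest.stage_counts["design"] = {
                    "targets": list(config.design.targets),
                    "k": config.design.k,
                }
    except Exception:
        if manifest.failed_stage is None:
            manifest.save(out / "manifest.json")
        raise

    manifest.save(out / "manifest.json")
    return manifest


def check_artifact_hash(path, expected_hash: str) -> None:
    """Refuse to mix artifacts across configurations.

    Artifacts carry ``config_hash=...`` in a leading comment (CSV) or a
    ``config_hash`` field (JSON).
    """
    path = Path(path)
    found = None
    if path.suffix == ".json":
        with open(path) as fh:
            found = json.load(fh).get("config_hash")
    else:
        first = path.read_text().splitlines()[0] if path.stat().st_size else ""
        if "config_hash=" in first:
            found = first.split("config_hash=")[1].strip()
    if found != expected_hash:
        raise ValueError(
            f"artifact {path} was produced under config hash {found!r}, "
            f"expected {expected_hash!r}"
        )
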