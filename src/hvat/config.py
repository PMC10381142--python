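"""Run configuration and the end-to-end pipeline.

A run config is a nested YAML mapping with sections ``simulate``,
``tokenization``, ``feature_selection``, ``model``, ``training`` and
``evaluation``; every field defaults to the prototype's value where one
exists (d=32, 2 blocks, 2 heads, dropout 0.1, token budget 10000, learning
rates 5e-4 / 5e-5 / 1e-4, patience 10, alpha 0.05, 1-year intervals).
Unknown keys are rejected before any computation.  A single top-level seed
feeds every stage through named sub-seeds so stages are individually
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .evaluation import assemble_cohort, run_comparison
from .events import stratified_split
from .features import score_concepts, select_top_k
from .network import HvatConfig
from .simulate import SimConfig, simulate_cohort, window_start_for
from .tokenization import apply_normalization, fit_normalization, tokenize_patient
from .training import TrainConfig

logger = logging.getLogger(__name__)


@dataclass
class TokenizationConfig:
    interval_length: float = 365.25
    window_years: float = 5.0


@dataclass
class FeatureSelectionConfig:
    k: int = 400
    alpha: float = 0.05
    enabled: bool = False


@dataclass
class SplitConfig:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)


@dataclass
class RunConfig:
    seed: int = 0
    simulate: SimConfig = field(default_factory=SimConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    tokenization: TokenizationConfig = field(default_factory=TokenizationConfig)
    feature_selection: FeatureSelectionConfig = field(default_factory=FeatureSelectionConfig)
    model: HvatConfig = field(default_factory=HvatConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    models: tuple[str, ...] = ("full",)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(to_dict(self), sort_keys=True).encode()).hexdigest()[:12]


def _from_mapping(cls, mapping: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} under {path!r}")
    kwargs = {f.name: mapping[f.name] for f in dataclasses.fields(cls) if f.name in mapping}
    return cls(**kwargs)


_SECTIONS = {
    "simulate": SimConfig,
    "split": SplitConfig,
    "tokenization": TokenizationConfig,
    "feature_selection": FeatureSelectionConfig,
    "model": HvatConfig,
    "training": TrainConfig,
}


def parse_config(mapping: dict) -> RunConfig:
    """Build a RunConfig from a nested mapping, rejecting unknown keys."""
    mapping = dict(mapping or {})
    unknown = set(mapping) - (set(_SECTIONS) | {"seed", "models"})
    if unknown:
        raise ValueError(f"unknown top-level config key(s) {sorted(unknown)}")
    kwargs: dict = {}
    if "seed" in mapping:
        kwargs["seed"] = int(mapping["seed"])
    if "models" in mapping:
        kwargs["models"] = tuple(mapping["models"])
    for name, cls in _SECTIONS.items():
        if name in mapping:
            section = mapping[name]
            if isinstance(section, dict) and "fractions" in section:
                section = dict(section)
                section["fractions"] = tuple(section["fractions"])
            kwargs[name] = _from_mapping(cls, section, name)
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return parse_config(yaml.safe_load(fh))


def to_dict(obj) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(obj), default=str))


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(config), fh, sort_keys=False)


def derive_seed(seed: int, stage: str) -> int:
    """Named sub-seed below 2^31, deterministic in (seed, stage)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def build_model_inputs(events, statics, vocabulary, split, window_start, interval_length):
    """Tokenize, fit normalization on the training subset, and assemble
    per-subset model inputs.  Returns (cohort arrays, normalization stats)."""
    by_patient: dict[str, list] = {}
    for e in events:
        by_patient.setdefault(e.patient_id, []).append(e)
    sequences = {
        s.patient_id: tokenize_patient(
            by_patient.get(s.patient_id, []), s, window_start, interval_length, vocabulary
        )
        for s in statics
    }
    subsets = {k: set(split.subset(k)) for k in ("train", "validation", "test")}
    statics_by = {k: [s for s in statics if s.patient_id in ids] for k, ids in subsets.items()}
    seqs_by = {k: [sequences[s.patient_id] for s in statics_by[k]] for k in subsets}
    norm = fit_normalization(seqs_by["train"], vocabulary)
    seqs_by = {k: [apply_normalization(s, norm) for s in v] for k, v in seqs_by.items()}
    return assemble_cohort(seqs_by, statics_by, vocabulary), norm


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """simulate -> split -> (feature-select) -> tokenize -> train -> evaluate.

    Writes events/statics/vocabulary CSVs, truth.json, report.json and the
    config (with its hash) under ``out_dir``; returns the comparison results.
    """
    from . import events as ev
    from .tokenization import sequences_to_jsonl

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sim = dataclasses.replace(config.simulate, seed=derive_seed(config.seed, "simulate"))
    events, statics, vocab, truth = simulate_cohort(sim)
    ev.write_events(events, out_dir / "events.csv")
    ev.write_statics(statics, out_dir / "statics.csv")
    vocab.write_csv(out_dir / "vocabulary.csv")
    (out_dir / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2))

    split = stratified_split(statics, config.split.fractions, derive_seed(config.seed, "split"))
    window_start = window_start_for(sim)
    window_starts = {s.patient_id: window_start for s in statics}

    if config.feature_selection.enabled:
        train_ids = set(split.subset("train"))
        train_statics = [s for s in statics if s.patient_id in train_ids]
        train_events = [e for e in events if e.patient_id in train_ids]
        stats = score_concepts(
            train_events, train_statics, vocab.unvalued_concepts(), window_starts,
            alpha=config.feature_selection.alpha,
        )
        keep = select_top_k(stats, config.feature_selection.k)
        vocab = vocab.subset(keep + vocab.valued_concepts())
        events = [e for e in events if e.concept in vocab]

    cohort, norm = build_model_inputs(
        events, statics, vocab, split, window_start, config.tokenization.interval_length
    )
    sequences_to_jsonl(
        [s for v in cohort.sequences.values() for s in v], out_dir / "sequences.jsonl"
    )
    results = run_comparison(
        cohort,
        model_config=config.model,
        train_config=dataclasses.replace(config.training, seed=derive_seed(config.seed, "train")),
        models=config.models,
        seed=derive_seed(config.seed, "init"),
    )
    payload = {"config_hash": config.config_hash(), "seed": config.seed, "results": results}
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2, default=float))
    save_config(config, out_dir / "config.yaml")
    return results
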