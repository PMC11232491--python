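"""Pipeline configuration (YAML) and the reproducibility manifest.

A run is configured either by a ``simulate`` block (synthetic study) or
by an ``inputs`` block pointing at corpus/PPI/proteome files.  Threshold
defaults mirror the reference analysis: the first-round swarm-cluster
cut at CCSV 0.92, the second-round swarm-axis report threshold 0.69, and
the disease-group threshold 0.76.

Validation collects *all* violations before raising, and unknown keys
are rejected so typos never silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

SIMULATE_KEYS = {
    "n_proteins": 120,
    "n_pathways": 6,
    "n_probes": 40,
    "n_docs": 5000,
    "n_tissues": 5,
    "coverage": 0.8,
    "p_in": 0.5,
    "p_out": 0.02,
    "p_assoc": 0.6,
    "p_bg": 0.02,
}

INPUT_KEYS = {"corpus", "ppi", "proteomes", "probes"}


@dataclass
class PipelineConfig:
    simulate: dict | None = None
    inputs: dict | None = None
    hit_rule: dict = field(default_factory=lambda: {"mode": "any", "k": 1})
    ccsv_threshold_round1: float = 0.92
    swarm_axis_threshold: float = 0.69
    disease_threshold: float = 0.76
    max_swarm_size: int = 5
    seed_proteins: list[str] | str = "pathway-receptors"
    seeds: list[int] = field(default_factory=lambda: [0])
    output_dir: str = "results/pipeline"


def parse_config(path: str | Path) -> PipelineConfig:
    """Read and validate a YAML pipeline configuration."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def validate_config(raw: dict) -> PipelineConfig:
    errors: list[str] = []
    known = {
        "simulate",
        "inputs",
        "hit_rule",
        "ccsv_threshold_round1",
        "swarm_axis_threshold",
        "disease_threshold",
        "max_swarm_size",
        "seed_proteins",
        "seeds",
        "output_dir",
    }
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration must be a mapping")
    for key in raw:
        if key not in known:
            errors.append(f"unknown key {key!r}")
    cfg = PipelineConfig()

    simulate = raw.get("simulate")
    inputs = raw.get("inputs")
    if simulate is None and inputs is None:
        errors.append("one of 'simulate' or 'inputs' is required")
    if simulate is not None and inputs is not None:
        errors.append("'simulate' and 'inputs' are mutually exclusive")
    if simulate is not None:
        if not isinstance(simulate, dict):
            errors.append("'simulate' must be a mapping")
        else:
            block = dict(SIMULATE_KEYS)
            for key, value in simulate.items():
                if key not in SIMULATE_KEYS:
                    errors.append(f"unknown simulate key {key!r}")
                elif not isinstance(value, (int, float)):
                    errors.append(f"simulate.{key} must be numeric, got {value!r}")
                else:
                    block[key] = value
            cfg.simulate = block
    if inputs is not None:
        if not isinstance(inputs, dict):
            errors.append("'inputs' must be a mapping")
        else:
            for key in inputs:
                if key not in INPUT_KEYS:
                    errors.append(f"unknown inputs key {key!r}")
            for req in ("corpus", "ppi", "proteomes"):
                if req not in inputs:
                    errors.append(f"inputs.{req} is required")
            cfg.inputs = dict(inputs)

    hr = raw.get("hit_rule", cfg.hit_rule)
    if not isinstance(hr, dict) or hr.get("mode", "any") not in ("any", "min_k"):
        errors.append("hit_rule must be a mapping with mode 'any' or 'min_k'")
    else:
        cfg.hit_rule = {"mode": hr.get("mode", "any"), "k": int(hr.get("k", 1))}

    for key in ("ccsv_threshold_round1", "swarm_axis_threshold", "disease_threshold"):
        value = raw.get(key, getattr(cfg, key))
        if not isinstance(value, (int, float)) or not (0.0 <= value <= 1.0):
            errors.append(f"{key} must be a number in [0, 1], got {value!r}")
        else:
            setattr(cfg, key, float(value))

    max_size = raw.get("max_swarm_size", cfg.max_swarm_size)
    if not isinstance(max_size, int) or max_size < 1:
        errors.append(f"max_swarm_size must be a positive integer, got {max_size!r}")
    else:
        cfg.max_swarm_size = max_size

    seeds = raw.get("seeds", cfg.seeds)
    if not isinstance(seeds, list) or not seeds or not all(isinstance(s, int) for s in seeds):
        errors.append(f"seeds must be a non-empty list of integers, got {seeds!r}")
    else:
        cfg.seeds = seeds

    sp = raw.get("seed_proteins", cfg.seed_proteins)
    if isinstance(sp, str):
        if sp != "pathway-receptors":
            errors.append(
                "seed_proteins must be a list of symbols or the literal 'pathway-receptors'"
            )
        else:
            cfg.seed_proteins = sp
    elif isinstance(sp, list) and all(isinstance(x, str) for x in sp):
        cfg.seed_proteins = sp
    else:
        errors.append(f"seed_proteins must be a list of symbols, got {sp!r}")

    out = raw.get("output_dir", cfg.output_dir)
    if not isinstance(out, str):
        errors.append(f"output_dir must be a string, got {out!r}")
    else:
        cfg.output_dir = out

    if errors:
        raise ConfigurationError("; ".join(errors))
    return cfg


# ------------------------------------------------------------------ manifest


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def emit_manifest(
    path: str | Path,
    parameters: dict,
    seed: int,
    stage_files: dict[str, dict[str, Path]],
) -> dict:
    """Write the reproducibility manifest: parameters, seed, per-stage
    output checksums.  Identical runs produce identical manifests."""
    from . import __version__

    manifest = {
        "package": "swarmcite",
        "version": __version__,
        "seed": int(seed),
        "parameters": parameters,
        "stages": {
            stage: {name: file_sha256(p) for name, p in sorted(files.items())}
            for stage, files in stage_files.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
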