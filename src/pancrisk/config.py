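"""Experiment configuration: schema, defaults, validation, hashing.

An experiment config is a nested mapping with sections ``sim``, ``prep``,
``encoder``, ``model``, ``train``, ``eval`` and ``attribution``.  Unknown
sections or keys are rejected before any compute; missing keys are filled
with the package defaults (the tuned architecture L=1, H=16, d=64,
lr=0.001, no dropout; a 3-month exclusion window; an 80:10:10 patient
split).  Every stage has an explicit seed.  The canonical-JSON SHA-256 of
the normalized config is embedded in every artifact the pipeline writes.
"""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

from .encoder import DEFAULT_FREQ_END, DEFAULT_FREQ_START

DEFAULTS: dict = {
    "sim": {
        "n_patients": 10_000,
        "target_case_fraction": 0.0013,
        "n_dx_codes": 100,
        "n_rx_codes": 50,
        "planted_risk_codes": [["A60", 8.0], ["M035", 4.0]],
        "order_pairs": [],
        "visit_rate": 18.0,
        "rate_dispersion": 0.8,
        "p_dx": 0.65,
        "record_span_years": [2.0, 14.0],
        "age_range_years": [52.0, 86.0],
        "male_fraction": 0.867,
        "race_fractions": [["White", 0.80], ["Black", 0.17], ["Other", 0.03]],
        "zipf_exponent": 1.1,
        "base_rate": None,
        "seed": 1,
    },
    "prep": {
        "exclusion_months": 3,
        "max_len": 300,
        "censoring": "mask",
        "inactive_stoplist": [],
    },
    "encoder": {
        "freq_start": DEFAULT_FREQ_START,
        "freq_end": DEFAULT_FREQ_END,
        "age_mode": "token",
    },
    "model": {
        "L": 1,
        "H": 16,
        "d": 64,
        "dropout": 0.0,
    },
    "train": {
        "lr": 0.001,
        "weight_decay": 0.0,
        "epochs_max": 20,
        "plateau_patience": 4,
        "k_trajectories": 4,
        "batch_size": 128,
        "split": [0.8, 0.1, 0.1],
        "seed": 2,
    },
    "eval": {
        "horizon_months": 36,
        "top_n": 1000,
        "n_boot": 100,
        "min_age": 50.0,
        "printed_T": False,
        "seed": 3,
    },
    "attribution": {
        "k": 1000,
        "steps": 64,
        "seed": 4,
    },
}

HORIZON_INDEX = {3: 0, 6: 1, 12: 2, 36: 3, 60: 4}


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_config(source) -> dict:
    """Normalize a config (path, YAML string or dict); raise on any violation.

    All schema violations are collected and reported together.
    """
    if isinstance(source, dict):
        raw = copy.deepcopy(source)
    else:
        text = None
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, TypeError):
            text = str(source)
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")

    errors: list[str] = []
    cfg = copy.deepcopy(DEFAULTS)
    for section, values in raw.items():
        if section not in DEFAULTS:
            errors.append(f"unknown section {section!r}")
            continue
        if values is None:
            continue
        if not isinstance(values, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        for key, val in values.items():
            if key not in DEFAULTS[section]:
                errors.append(f"unknown key {section}.{key}")
            else:
                cfg[section][key] = val

    def check(cond, msg):
        if not cond:
            errors.append(msg)

    check(cfg["sim"]["n_patients"] > 0, "sim.n_patients must be positive")
    check(0 <= cfg["sim"]["target_case_fraction"] <= 1, "sim.target_case_fraction must be in [0,1]")
    check(cfg["model"]["L"] >= 1 and cfg["model"]["H"] >= 1 and cfg["model"]["d"] >= 1,
          "model L, H, d must be >= 1")
    check(cfg["train"]["lr"] > 0, "train.lr must be positive")
    check(cfg["train"]["weight_decay"] >= 0, "train.weight_decay must be >= 0")
    check(0 <= cfg["model"]["dropout"] < 1, "model.dropout must be in [0,1)")
    check(abs(sum(cfg["train"]["split"]) - 1.0) < 1e-9, "train.split must sum to 1")
    check(cfg["prep"]["exclusion_months"] in (0, 3, 12), "prep.exclusion_months must be 0, 3 or 12")
    check(cfg["prep"]["censoring"] in ("mask", "zero_fill"), "prep.censoring must be mask|zero_fill")
    check(cfg["eval"]["horizon_months"] in HORIZON_INDEX, "eval.horizon_months must be one of 3,6,12,36,60")
    check(cfg["eval"]["top_n"] > 0, "eval.top_n must be positive")
    check(cfg["attribution"]["steps"] >= 1, "attribution.steps must be >= 1")
    check(0 < cfg["encoder"]["freq_start"] <= cfg["encoder"]["freq_end"],
          "encoder frequencies must satisfy 0 < freq_start <= freq_end")

    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return cfg
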