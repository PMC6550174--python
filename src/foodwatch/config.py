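"""Flat pipeline configuration.

One configuration object carries every stage parameter, loaded from a flat
YAML key/value file. Unknown keys are rejected on load and basic range
validation happens eagerly, so a bad run fails before any simulation work.
The resolved configuration is written next to every pipeline output
together with its hash, making runs reproducible from (config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from foodwatch.exceptions import ParameterError


@dataclass
class PipelineConfig:
    # --- world ---
    n_restaurants: int = 200
    n_users: int = 5000
    horizon_days: float = 60.0
    unsafe_fraction: float = 0.2
    cities: tuple[str, ...] = ("las_vegas", "chicago")
    risk_high: float = 0.5
    risk_medium: float = 0.3
    risk_low: float = 0.2
    p_transmit_unsafe: float = 0.02
    p_transmit_safe: float = 0.002
    zipf_exponent: float = 1.0

    # --- visits / infections ---
    visit_rate: float = 0.2  # visits / user / day
    incubation_window_days: float = 3.0
    incubation_distribution: str = "uniform"  # uniform | lognormal
    incubation_lognorm_median_days: float = 1.0
    incubation_lognorm_sigma: float = 0.8

    # --- queries ---
    q_report: float = 0.7  # P(an infected user searches about the illness)
    extra_illness_queries_rate: float = 0.3  # Poisson extra queries per reporter
    background_illness_rate: float = 0.001  # illness queries / uninfected user / day
    background_query_rate: float = 0.3  # benign queries / user / day
    lookalike_fraction: float = 0.15  # share of benign queries that mimic illness topics
    typo_rate: float = 0.1  # P(a query string gets >=1 character perturbation)
    illness_click_rate: float = 0.85
    illness_dwell_mean_s: float = 90.0
    benign_click_rate: float = 0.6
    benign_dwell_mean_s: float = 20.0
    lookalike_topical_click_rate: float = 0.02
    lookalike_topical_dwell_mean_s: float = 10.0
    concept_tag_rate: float = 0.7  # P(an illness query carries the topical concept tag)

    # --- weak labeling ---
    prominence_threshold: float = 0.5
    min_dwell_seconds: float = 30.0
    negative_ratio: float = 4.0

    # --- classifier ---
    feature_dim: int = 50000
    l2_lambda: float = 1.0
    max_iter: int = 200
    tol: float = 1e-8
    eval_sample_size: int = 200  # must be even; half high-recall, half traffic
    threshold_policy: str = "fixed:0.5"

    # --- raters ---
    md_error_rate: float = 0.03
    nonmd_error_rate: float = 0.06

    # --- location model ---
    score_cutoff: float = 0.5
    epsilon: float = 5.0  # differential-privacy budget; <=0 means privacy off
    signal_cutoff: float = 0.0
    min_visitors: int = 40
    top_k: int = 20

    # --- inspections ---
    inspect_sensitivity: float = 0.85
    inspect_specificity: float = 0.90
    routine_coverage: float = 0.9  # P(a restaurant gets a routine inspection)
    p_complaint: float = 0.05  # P(an infection generates a complaint)
    misattribution_rate: float = 1.0  # P(complaint names last-visited, not source)

    # --- outcome mapping ---
    unsafe_grades: tuple[str, ...] = ("Fail", "PassWithConditions")
    unsafe_critical_threshold: int = 1  # critical_count >= threshold -> unsafe

    # --- io ---
    time_format: str = "days"  # days | iso
    epoch: str = "2016-05-01"  # day 0 when time_format == iso

    def validate(self) -> "PipelineConfig":
        if self.n_restaurants < 0 or self.n_users < 0:
            raise ParameterError("n_restaurants and n_users must be >= 0")
        if not 0.0 <= self.unsafe_fraction <= 1.0:
            raise ParameterError("unsafe_fraction must lie in [0, 1]")
        if self.horizon_days < 1:
            raise ParameterError("horizon_days must be >= 1")
        if self.visit_rate < 0:
            raise ParameterError("visit_rate must be >= 0")
        if self.incubation_window_days <= 0:
            raise ParameterError("incubation_window_days must be > 0")
        if self.incubation_distribution not in ("uniform", "lognormal"):
            raise ParameterError(
                f"unknown incubation_distribution {self.incubation_distribution!r}"
            )
        probs = (self.risk_high, self.risk_medium, self.risk_low)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ParameterError("risk level probabilities must be >= 0 and sum to 1")
        for name in ("p_transmit_unsafe", "p_transmit_safe", "q_report",
                     "typo_rate", "lookalike_fraction", "score_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.feature_dim < 1:
            raise ParameterError("feature_dim must be >= 1")
        if self.negative_ratio <= 0:
            raise ParameterError("negative_ratio must be > 0")
        if self.eval_sample_size % 2:
            raise ParameterError("eval_sample_size must be even")
        if self.min_visitors < 0:
            raise ParameterError("min_visitors must be >= 0")
        if self.time_format not in ("days", "iso"):
            raise ParameterError(f"unknown time_format {self.time_format!r}")
        return self

    # -- serialization --------------------------------------------------

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - set(known))
        if unknown:
            raise ParameterError(f"unknown configuration keys: {', '.join(unknown)}")
        kwargs = {}
        for key, value in mapping.items():
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"{path}: configuration must be a flat mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, value in out.items():
            if isinstance(value, tuple):
                out[key] = list(value)
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(payload).hexdigest()[:16]
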