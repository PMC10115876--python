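"""Pipeline configuration: YAML schema, validation, defaults.

Validation reports every violation found, not just the first, so a config
can be fixed in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .core import GenomicInterval, ProtospacerSpec

DEFAULT_THRESHOLDS: dict[str, float | int] = {
    "alpha": 0.05,
    "p_threshold": 0.2,
    "damage_threshold": 0.1,
    "min_base_quality_amplicon": 20,
    "min_base_quality_capture": 30,
    "min_map_quality": 20,
    "top_n": 250,
    "max_mismatches": 4,
}

_THRESHOLD_RANGES: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 1.0),
    "p_threshold": (0.0, 1.0),
    "damage_threshold": (0.0, 1.0),
    "min_base_quality_amplicon": (0, 93),
    "min_base_quality_capture": (0, 93),
    "min_map_quality": (0, 255),
    "top_n": (1, 10**9),
    "max_mismatches": (0, 8),
}


class ConfigError(ValueError):
    """Raised with the full list of config violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n" + "\n".join(f"- {v}" for v in violations))


@dataclass
class PipelineConfig:
    spec: ProtospacerSpec
    thresholds: dict[str, float | int]
    paths: dict[str, Path]
    codon_interval: GenomicInterval | None
    splice: dict[str, Any] | None
    seed: int
    raw: dict = field(default_factory=dict, repr=False)


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and fully validate a YAML config, filling documented defaults.

    Raises :class:`ConfigError` listing *every* violation: missing required
    keys, out-of-range thresholds (with the allowed range named), and
    referenced paths that do not exist.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    violations: list[str] = []

    spacer = raw.get("spacer")
    if spacer is None:
        violations.append("missing required key 'spacer'")
    window = raw.get("editing_window", [4, 8])
    if (
        not isinstance(window, (list, tuple))
        or len(window) != 2
        or not all(isinstance(x, int) for x in window)
        or not (1 <= window[0] <= window[1] <= 20)
    ):
        violations.append(
            f"editing_window {window!r} invalid: bounds must be integers with "
            "1 <= low <= high <= 20"
        )
        window = [4, 8]
    targets = raw.get("target_positions", [5, 6])

    spec = None
    if spacer is not None:
        try:
            spec = ProtospacerSpec(
                spacer=str(spacer),
                pam_pattern=str(raw.get("pam", "NGG")),
                editing_window=(window[0], window[1]),
                target_positions=frozenset(targets),
            )
        except ValueError as exc:
            violations.append(str(exc))

    thresholds = dict(DEFAULT_THRESHOLDS)
    for key, value in (raw.get("thresholds") or {}).items():
        if key not in _THRESHOLD_RANGES:
            violations.append(f"unknown threshold {key!r}")
            continue
        lo, hi = _THRESHOLD_RANGES[key]
        if not isinstance(value, (int, float)) or not (lo <= value <= hi):
            violations.append(
                f"threshold {key}={value!r} outside allowed range [{lo}, {hi}]"
            )
        else:
            thresholds[key] = value

    paths: dict[str, Path] = {}
    for key, value in (raw.get("paths") or {}).items():
        p = Path(value)
        if key != "out_dir" and not p.exists():
            violations.append(f"path {key}={value!r} does not exist")
        paths[key] = p

    codon = None
    if "codon_interval" in raw:
        ci = raw["codon_interval"]
        try:
            codon = GenomicInterval(
                str(ci["contig"]), int(ci["start"]), int(ci["end"]),
                str(ci.get("strand", "+")),
            )
            if len(codon) != 3:
                violations.append("codon_interval must span exactly 3 bases")
        except (KeyError, TypeError, ValueError) as exc:
            violations.append(f"codon_interval invalid: {exc}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        violations.append(f"seed must be a non-negative integer, got {seed!r}")
        seed = 0

    if violations:
        raise ConfigError(violations)
    assert spec is not None
    return PipelineConfig(
        spec=spec,
        thresholds=thresholds,
        paths=paths,
        codon_interval=codon,
        splice=raw.get("splice"),
        seed=seed,
        raw=raw,
    )
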