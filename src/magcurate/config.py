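"""Pipeline defaults and key=value configuration files."""

from __future__ import annotations

import logging
from pathlib import Path

DEFAULTS: dict[str, object] = {
    # read filtering
    "min_read_length_bp": 2000,
    "min_read_accuracy": 0.99,
    # fragment ANI estimation
    "fragment_length": 3000,
    "kmer_size": 16,
    "min_fragment_identity": 80.0,
    # dereplication stop distances
    "stop_distance_strain": 0.01,
    "stop_distance_species": 0.05,
    # novelty thresholds (percent identity)
    "ani_strain_threshold": 99.0,
    "ani_species_threshold": 95.0,
    "s16_species_threshold": 97.0,
    "s16_genus_threshold": 95.0,
    # RNA completeness
    "min_trna": 18,
    "trna_mode": "copies",
    "max_operon_gap_bp": 5000,
    # quality ranking: strict '<' on contamination unless inclusive
    "contamination_inclusive": False,
    # gene catalog
    "catalog_min_identity": 0.95,
    "catalog_min_coverage": 0.90,
    "catalog_word_size": 10,
    # simulation
    "depth_scale": 300.0,
}


def _coerce(value: str) -> object:
    v = value.strip()
    if v.lower() in ("true", "false"):
        return v.lower() == "true"
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    return v


def load_config(path: str | Path | None) -> dict[str, object]:
    """Defaults overridden by ``key=value`` lines; '#' starts a comment."""
    cfg = dict(DEFAULTS)
    if path is None:
        return cfg
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in DEFAULTS:
                raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
            cfg[key] = _coerce(value)
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
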