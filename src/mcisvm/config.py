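"""Run configuration: one dataclass, loadable from YAML/JSON, hashed into
every report so outputs are traceable to the exact settings that produced
them."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .crossval import DEFAULT_C_GRID, CVConfig

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Settings of the full pipeline, defaulting to the study design:
    55 subjects (41 stable / 14 decline), 51 parcels in 7 networks,
    p < 0.01 fold-internal selection, inner 10-fold C search, 10 repeated
    nested cross-validation permutations."""

    seed: int = 0
    grid_dims: tuple[int, int, int] = (20, 20, 20)
    n_parcels: int = 51
    n_networks: int = 7
    n_stable: int = 41
    n_decline: int = 14
    T: int = 150
    # planted effects
    t1_effect_parcels: tuple[int, ...] = ()
    t1_effect_size: float = 0.0
    conn_effect_pairs: tuple[tuple[int, int], ...] = ()
    conn_effect_size: float = 0.0
    noise_sd: float = 1.0
    # neuropsych
    npsych_group_shift: float = 0.0
    npsych_n_incomplete: int = 27
    # analysis
    alpha: float = 0.01
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    inner_k: int = 10
    n_repeats: int = 10
    modalities: tuple[str, ...] = ("t1", "conn")
    t_variant: str = "student"
    top_fraction: float = 0.5
    output_dir: str = "mcisvm_out"

    def cv_config(self) -> CVConfig:
        return CVConfig(
            alpha=self.alpha,
            C_grid=tuple(self.C_grid),
            inner_k=self.inner_k,
            n_repeats=self.n_repeats,
            seed=self.seed,
            t_variant=self.t_variant,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stamp(self) -> dict:
        """Provenance block embedded in every output file."""
        return {"config_hash": self.config_hash(), "seed": self.seed}


def _coerce(raw: dict) -> dict:
    out = dict(raw)
    for key in ("grid_dims", "t1_effect_parcels", "C_grid", "modalities"):
        if key in out and out[key] is not None:
            out[key] = tuple(out[key])
    if "conn_effect_pairs" in out and out["conn_effect_pairs"] is not None:
        out["conn_effect_pairs"] = tuple(tuple(p) for p in out["conn_effect_pairs"])
    return out


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML/JSON file plus overrides.

    Unknown keys raise with the offending field named.
    """
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    return RunConfig(**_coerce(raw))
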