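"""Run configuration: every tunable of the pipeline in one validated object."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ValidationError


@dataclass
class RunConfig:
    seed: int = 0
    identity_threshold: float = 0.80
    bit_threshold: float = 50.0
    max_gap: float = 0.30
    n_iter: int = 6
    bootstrap_reps: int = 100
    b_min_len: int = 890
    f_min_len: int = 400
    f_max_len: int = 1200
    e_min_len: int = 150
    e_max_len: int = 800
    use_walker_b: bool = False
    g_codirectional: bool = True
    window_slack: int = 0
    per_block_pretrim: bool = False
    stop_on_fixpoint: bool = False
    cluster_refine: bool = True
    apply_edge_filter: bool = True
    genes_per_contig: int = 9
    n_members: int = 12
    min_region_identity: float = 0.20

    def __post_init__(self) -> None:
        checks = [
            (0.0 < self.identity_threshold <= 1.0, "identity_threshold in (0, 1]"),
            (self.bit_threshold >= 0.0, "bit_threshold >= 0"),
            (0.0 <= self.max_gap < 1.0, "max_gap in [0, 1)"),
            (self.n_iter >= 1, "n_iter >= 1"),
            (self.bootstrap_reps >= 1, "bootstrap_reps >= 1"),
            (self.b_min_len > 0, "b_min_len > 0"),
            (0 < self.f_min_len <= self.f_max_len, "MksF length range ordered"),
            (0 < self.e_min_len <= self.e_max_len, "MksE length range ordered"),
            (self.window_slack >= 0, "window_slack >= 0"),
            (self.genes_per_contig >= 5, "genes_per_contig >= 5"),
            (self.n_members >= 4, "n_members >= 4"),
            (0.0 <= self.min_region_identity <= 1.0, "min_region_identity in [0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(f"RunConfig: {msg}")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValidationError(f"RunConfig: unknown keys {unknown}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"RunConfig: {path} is not a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def infer_kwargs(self) -> dict:
        return {
            "g_codirectional": self.g_codirectional,
            "window_slack": self.window_slack,
            "b_min_len": self.b_min_len,
            "f_range": (self.f_min_len, self.f_max_len),
            "e_range": (self.e_min_len, self.e_max_len),
            "use_walker_b": self.use_walker_b,
            "apply_edge_filter": self.apply_edge_filter,
        }
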