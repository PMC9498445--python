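"""Run configuration: kernel weights, model and cross-validation settings."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["Config"]


@dataclass
class Config:
    """All tunable settings of the pipeline.

    Kernel weights follow the integration order (free energy, interaction
    profile, sequence, SSR) for miRNAs and (free energy, accessibility,
    AU content, SSR, interaction profile) for sites; they are normalized
    by their sum, so only ratios matter.  A zero fifth site weight drops
    the site-side interaction-profile kernel, leaving the strict
    four-feature site integration.  ``lam`` is the RLS regularization
    strength.
    """

    # kernel integration
    mirna_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    site_weights: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    phi_prime: float = 1.0
    nw_match: float = 1.0
    nw_mismatch: float = -1.0
    nw_gap: float = -1.0
    ssr_binary: bool = False
    # features
    site_length: int = 40
    accessibility_window: int = 10
    ssr_min_repeats: int = 3
    # model
    lam: float = 35.0
    # cross-validation
    neg_per_pos: int | None = 5
    max_positives: int | None = None
    iterations: int = 100
    fraction: float = 0.1
    seed: int = 0
    per_mirna_quartiles: bool = False
    require_positive_rows: bool = False

    def __post_init__(self) -> None:
        self.mirna_weights = tuple(float(w) for w in self.mirna_weights)
        self.site_weights = tuple(float(w) for w in self.site_weights)
        if len(self.mirna_weights) != 4:
            raise ValueError("mirna_weights must have 4 entries (FE, GP, NW, SSR)")
        if len(self.site_weights) != 5:
            raise ValueError(
                "site_weights must have 5 entries (FE, TA, AU, SSR, GP); "
                "set the last to 0 for the strict four-feature site kernel"
            )
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict):  # allow grouped blocks, e.g. kernels:
                flat.update(value)
            else:
                flat[key] = value
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
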