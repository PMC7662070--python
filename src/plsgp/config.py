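"""Run configuration: one YAML document drives every pipeline stage.

A single master seed is fanned out to named substreams (simulation, MCMC,
cross-validation) through ``numpy.random.SeedSequence`` so a full run is
reproducible from the config alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml


@dataclass
class RunConfig:
    """Settings shared by the selection/fit/cv stages."""

    percentiles: tuple[float, ...] = (90, 80, 70, 60, 50)
    components: tuple[int, ...] | None = None   # default 1..n_traits
    modes: tuple[str, ...] = ("one_tailed", "two_tailed")
    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 10
    n_folds: int = 10
    min_maf: float = 0.05
    min_call_rate: float = 0.6
    matrix_kind: str = "vanraden"   # vanraden | weighted
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        for p in self.percentiles:
            if not 0 < p < 100:
                raise ValueError(f"percentile {p} outside (0, 100)")
        for m in self.modes:
            if m not in ("one_tailed", "two_tailed"):
                raise ValueError(f"unknown mode {m!r}")

    def substream(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        ss = np.random.SeedSequence(
            [self.seed, int.from_bytes(stage.encode()[:4].ljust(4, b"_"),
                                       "big")])
        return int(ss.generate_state(1)[0] % (2 ** 31))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("percentiles", "components", "modes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
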