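"""Run configuration: validated, serializable, embedded in every output."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .entropy import ESTIMATORS, TEConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Full configuration for a command-line run.

    Every output file embeds the resolved configuration (as ``# key=value``
    comment lines) together with the master seed, so any result can be
    regenerated from its own header.
    """

    estimator: str = "cte"
    beta: float = 0.05
    tau: int | None = None
    tau_phase: int | None = None
    max_lag: int = 10
    delay_mode: str = "abs"
    unit: str = "bits"
    hte_bins: int | None = None
    R: int = 100
    p_th: float = 0.05
    p_method: str = "ttest"
    seed: int = 0
    T: int = 146
    n_pairs: int = 1000
    n_groups: int = 10
    families: list = field(default_factory=lambda: ["L1", "L2", "L3",
                                                    "N1", "N2", "N3"])
    snr_grid: list | None = None
    verdict_mode: str = "sign"

    def __post_init__(self):
        if self.estimator not in ESTIMATORS + ("granger",):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if not 0.0 < self.p_th < 1.0:
            raise ValueError("p_th must lie in (0, 1)")
        if self.R < 2:
            raise ValueError("R must be >= 2")
        if self.seed < 0 or self.seed >= 2**31:
            raise ValueError("seed must be a non-negative 31-bit integer")
        # delegate estimator-knob validation
        self.te_config()

    def te_config(self) -> TEConfig:
        return TEConfig(tau=self.tau, tau_phase=self.tau_phase,
                        beta=self.beta, max_lag=self.max_lag,
                        delay_mode=self.delay_mode, unit=self.unit,
                        hte_bins=self.hte_bins)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def updated(self, **overrides) -> "RunConfig":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)

    def header_lines(self) -> list[str]:
        """The resolved configuration as key=value provenance lines."""
        return [f"{k}={v}" for k, v in sorted(asdict(self).items())]
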