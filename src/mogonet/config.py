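"""Run configuration: hyper-parameters, architecture, and the master seed.

Defaults follow the published study conditions: the graph-density parameter
``k`` is tuned over {2, 5, 10} when set to ``"auto"``, and the trade-off
``gamma`` between the omics-specific losses and the integration loss is 1.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]

DEFAULT_K_GRID = [2, 5, 10]


@dataclass
class RunConfig:
    # graph construction
    k: int | str = "auto"  # average retained edges per node, or "auto" to tune
    k_grid: list[int] = field(default_factory=lambda: list(DEFAULT_K_GRID))
    # loss trade-off between per-omics GCN losses and the integration loss
    gamma: float = 1.0
    # architecture
    gcn_hidden: list[int] = field(default_factory=lambda: [400, 400])
    vcdn_hidden: list[int] | None = None  # None -> one hidden layer of input width
    activation_slope: float = 0.25  # leaky-rectifier negative slope
    dropout: float = 0.5
    # optimisation (full-batch adaptive-moment gradient descent)
    lr_pretrain: float = 1.0e-3
    lr_gcn: float = 5.0e-4
    lr_vcdn: float = 1.0e-3
    pretrain_epochs: int = 500
    joint_epochs: int = 1000
    loss_tol: float = 0.0  # relative loss-change tolerance; 0 disables early stop
    patience: int = 20
    # preprocessing
    variance_thresholds: dict[str, float] = field(default_factory=dict)
    preselect_counts: dict[str, int | str] = field(default_factory=dict)
    preselect_grid: list[int] = field(default_factory=lambda: [200, 1000, 2000])
    fdr_alpha: float = 0.05
    pc1_max_fraction: float = 0.5
    # evaluation
    test_fraction: float = 0.30
    n_repeats: int = 5
    positive_class: int = 1
    # integration head: "vcdn" (cross-omics tensor) or "concat" (stacked rows)
    integration_mode: str = "vcdn"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k != "auto" and (not isinstance(self.k, int) or self.k < 1):
            raise ValueError("k must be a positive integer or 'auto'")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.pretrain_epochs < 0:
            raise ValueError("pretrain_epochs must be >= 0 (0 skips pretraining)")
        if self.joint_epochs < 1:
            raise ValueError("joint_epochs must be >= 1")
        if self.integration_mode not in ("vcdn", "concat"):
            raise ValueError("integration_mode must be 'vcdn' or 'concat'")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValueError("fdr_alpha must be in (0, 1)")
        if not (0.0 < self.pc1_max_fraction <= 1.0):
            raise ValueError("pc1_max_fraction must be in (0, 1]")

    def replace(self, **kwargs) -> "RunConfig":
        data = asdict(self)
        data.update(kwargs)
        return RunConfig(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config, filling defaults; unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded:
            data.update(loaded)
    if overrides:
        data.update(overrides)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
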