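"""Closed-form learning-rate decay schedules.

Four strategies are compared when training the classifier from scratch:

* ``standard`` — hyperbolic per-iteration decay
  ``alpha = init_lr / (1 + decay * iteration)`` with ``decay = init_lr / echos``;
* ``step``     — staircase ``alpha = init_lr * F ** floor((1 + E) / D)``
  over epochs E (factor F = 0.25 every D = 10 epochs by default); a
  continuous-exponent reading is available behind ``step_floor=False``;
* ``line``     — linear ``alpha = init_lr * (1 - E / echos)`` (poly with pow=1);
* ``poly``     — polynomial ``alpha = init_lr * (1 - E / echos) ** pow``
  with pow = 5.

``echos`` is the epoch budget (40 by default).  Standard decay is applied per
iteration; the other three are applied once per epoch, as their formulas are
written in the epoch index.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ScheduleConfig", "lr_standard", "lr_step", "lr_line", "lr_poly",
           "learning_rate"]

STRATEGIES = ("standard", "step", "line", "poly")


@dataclass(frozen=True)
class ScheduleConfig:
    strategy: str = "poly"
    init_lr: float = 1e-2
    echos: int = 40          # epoch budget
    F: float = 0.25          # step-decay factor
    D: int = 10              # step-decay period (epochs)
    pow: float = 5.0         # poly exponent (1.0 = line)
    step_floor: bool = True  # staircase (floor) vs continuous exponent

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.init_lr <= 0:
            raise ValueError("init_lr must be positive")
        if self.echos < 1:
            raise ValueError("echos must be >= 1")
        if not (0.0 < self.F < 1.0):
            raise ValueError("F must lie in (0, 1)")
        if self.D < 1:
            raise ValueError("D must be >= 1")
        if self.pow < 1.0:
            raise ValueError("pow must be >= 1")

    @property
    def decay(self) -> float:
        """Per-iteration decay constant of the standard strategy."""
        return self.init_lr / self.echos

    @classmethod
    def for_strategy(cls, strategy: str, **kwargs) -> "ScheduleConfig":
        if strategy == "line":
            kwargs.setdefault("pow", 1.0)
        if strategy == "poly":
            kwargs.setdefault("pow", 5.0)
        return cls(strategy=strategy, **kwargs)


def lr_standard(iteration: int, cfg: ScheduleConfig) -> float:
    """Hyperbolic decay in the (global) iteration counter."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    return cfg.init_lr / (1.0 + cfg.decay * iteration)


def lr_step(epoch: int, cfg: ScheduleConfig) -> float:
    """Staircase decay: the rate drops by factor F every D epochs."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    expo = (1 + epoch) // cfg.D if cfg.step_floor else (1 + epoch) / cfg.D
    return cfg.init_lr * cfg.F ** expo


def lr_poly(epoch: int, cfg: ScheduleConfig) -> float:
    """Polynomial decay, reaching zero at ``echos``; pow=1 is linear."""
    if not (0 <= epoch <= cfg.echos):
        raise ValueError("epoch must lie in [0, echos]")
    return cfg.init_lr * (1.0 - epoch / cfg.echos) ** cfg.pow


def lr_line(epoch: int, cfg: ScheduleConfig) -> float:
    """Linear decay (poly with exponent 1, regardless of cfg.pow)."""
    return cfg.init_lr * (1.0 - epoch / cfg.echos)


def learning_rate(cfg: ScheduleConfig, epoch: int, iteration: int) -> float:
    """The rate in force for a given epoch / global iteration."""
    if cfg.strategy == "standard":
        return lr_standard(iteration, cfg)
    if cfg.strategy == "step":
        return lr_step(epoch, cfg)
    if cfg.strategy == "line":
        return lr_line(epoch, cfg)
    return lr_poly(epoch, cfg)
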