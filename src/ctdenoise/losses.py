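"""Adversarial, cycle-consistency and identity losses, and their weighted sum.

The adversarial objective averages, over N discriminator scales, the
binary-cross-entropy value  E[log D_i(real)] + E[log(1 - D_i(fake))]  with
expectations taken as arithmetic means over batch and spatial score
positions.  Scores are clipped to [eps, 1-eps] before the logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = [
    "EPS",
    "LossWeights",
    "LossBreakdown",
    "adversarial_loss",
    "generator_adversarial_loss",
    "l1_distance",
    "cycle_consistency_loss",
    "identity_loss",
    "joint_loss",
]

EPS = 1e-7


@dataclass
class LossWeights:
    lambda_adv: float = 0.1
    lambda_cyc: float = 10.0
    lambda_idt: float = 2.0

    def __post_init__(self):
        if min(self.lambda_adv, self.lambda_cyc, self.lambda_idt) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class LossBreakdown:
    adv_G: float
    adv_F: float
    cyc: float
    idt: float
    total: float
    d_losses: tuple[float, ...] = ()

    def check_identity(self, weights: LossWeights, atol: float = 1e-9) -> None:
        expected = (weights.lambda_adv * (self.adv_G + self.adv_F)
                    + weights.lambda_cyc * self.cyc
                    + weights.lambda_idt * self.idt)
        if not np.isclose(self.total, expected, atol=atol, rtol=1e-9):
            raise AssertionError(
                f"loss breakdown identity violated: total={self.total}, "
                f"recombined={expected}"
            )


def _clipped_log(scores: Tensor) -> Tensor:
    return scores.clip(EPS, 1.0 - EPS).log()


def adversarial_loss(scores_real: list, scores_fake: list) -> Tensor:
    """Value of the discriminator objective (maximized by D):
    (1/N) sum_i [ mean log D_i(real) + mean log(1 - D_i(fake)) ].
    """
    if len(scores_real) != len(scores_fake):
        raise ValueError(
            f"score list lengths differ: {len(scores_real)} vs {len(scores_fake)}"
        )
    n = len(scores_real)
    total = None
    for sr, sf in zip(scores_real, scores_fake):
        sr, sf = as_tensor(sr), as_tensor(sf)
        term = _clipped_log(sr).mean() + _clipped_log(1.0 - sf).mean()
        total = term if total is None else total + term
    return total / float(n)


def generator_adversarial_loss(scores_fake: list, mode: str = "non_saturating") -> Tensor:
    """Generator-side adversarial term (minimized by G).

    saturating: (1/N) sum mean log(1 - D(fake));
    non_saturating: -(1/N) sum mean log D(fake).
    """
    n = len(scores_fake)
    if n == 0:
        raise ValueError("empty score list")
    total = None
    for sf in scores_fake:
        sf = as_tensor(sf)
        if mode == "saturating":
            term = _clipped_log(1.0 - sf).mean()
        elif mode == "non_saturating":
            term = -(_clipped_log(sf).mean())
        else:
            raise ValueError(f"unknown mode {mode!r}")
        total = term if total is None else total + term
    return total / float(n)


def l1_distance(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return (a - b).abs().mean()


def cycle_consistency_loss(x, y, G, F) -> Tensor:
    """mean |G(F(y)) - y| + mean |F(G(x)) - x|."""
    x, y = as_tensor(x), as_tensor(y)
    return l1_distance(G(F(y)), y) + l1_distance(F(G(x)), x)


def identity_loss(x, y, G, F) -> Tensor:
    """mean |G(y) - y| + mean |F(x) - x|."""
    x, y = as_tensor(x), as_tensor(y)
    return l1_distance(G(y), y) + l1_distance(F(x), x)


def joint_loss(adv_G, adv_F, cyc, idt, weights: LossWeights,
               d_losses: tuple[float, ...] = ()) -> tuple[Tensor, LossBreakdown]:
    """Weighted combination; returns the differentiable total and a breakdown
    whose recombination identity is asserted."""
    parts = {"adv_G": adv_G, "adv_F": adv_F, "cyc": cyc, "idt": idt}
    for name, part in parts.items():
        value = part.item() if isinstance(part, Tensor) else float(part)
        if not np.isfinite(value):
            raise ValueError(f"non-finite loss part {name!r}: {value}")
    adv_G, adv_F = as_tensor(adv_G), as_tensor(adv_F)
    cyc, idt = as_tensor(cyc), as_tensor(idt)
    total = (weights.lambda_adv * (adv_G + adv_F)
             + weights.lambda_cyc * cyc + weights.lambda_idt * idt)
    breakdown = LossBreakdown(
        adv_G=adv_G.item(), adv_F=adv_F.item(), cyc=cyc.item(), idt=idt.item(),
        total=total.item(), d_losses=tuple(float(d) for d in d_losses),
    )
    breakdown.check_identity(weights, atol=1e-6)
    return total, breakdown
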