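"""Training loop: RMSprop with Nesterov momentum, sub-epoch schedule.

The recipe mirrors the published configuration of the network family this
package re-implements: batch size 10, L1 1e-6 and L2 1e-4 weight penalties,
RMSprop (rho 0.9, epsilon 1e-4) combined with Nesterov momentum 0.6, 35
epochs of 15 sub-epochs, initial learning rate 1e-3 halved at eight
predefined epochs, and sagittal-reflection augmentation.  Desk-scale runs
shrink the epoch counts and network, not the recipe.

The composed update used here (per parameter, gradient g including the
penalty terms)::

    r <- rho * r + (1 - rho) * g^2
    g_hat <- g / (sqrt(r) + eps)
    v <- mu * v - lr * g_hat
    theta <- theta + mu * v - lr * g_hat
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import MultiScalePatchNet
from .layers import softmax_cross_entropy
from .sampling import SampleableCase, sample_training_batch


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 10
    l1_coeff: float = 1e-6
    l2_coeff: float = 1e-4
    rmsprop_rho: float = 0.9
    rmsprop_epsilon: float = 1e-4
    nesterov_momentum: float = 0.6
    n_epochs: int = 35
    subepochs_per_epoch: int = 15
    batches_per_subepoch: int = 20
    initial_lr: float = 1e-3
    lr_halving_epochs: tuple[int, ...] = (17, 19, 21, 23, 25, 27, 29, 31)
    augment_sagittal_reflection: bool = True
    swap_channel_roles: bool = False
    foreground_sampling_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("l1_coeff", "l2_coeff", "rmsprop_rho", "rmsprop_epsilon",
                     "nesterov_momentum", "initial_lr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.foreground_sampling_fraction <= 1.0):
            raise ValueError("foreground_sampling_fraction must lie in [0,1]")

    def learning_rate(self, epoch: int) -> float:
        """LR in force during 1-based ``epoch``; halved at each scheduled epoch."""
        halvings = sum(1 for e in self.lr_halving_epochs if epoch >= e)
        return self.initial_lr * 0.5**halvings


class RMSpropNesterov:
    """RMSprop-scaled gradients fed through a Nesterov momentum step."""

    def __init__(self, net: MultiScalePatchNet, config: TrainingConfig):
        self.net = net
        self.cfg = config
        self.r = [np.zeros_like(p) for p, _, _ in net.parameters()]
        self.v = [np.zeros_like(p) for p, _, _ in net.parameters()]

    def penalty(self) -> float:
        c = self.cfg
        total = 0.0
        for p, _, reg in self.net.parameters():
            if reg:
                total += c.l1_coeff * np.abs(p).sum() + c.l2_coeff * (p**2).sum()
        return float(total)

    def step(self, lr: float) -> None:
        c = self.cfg
        for (p, g, reg), r, v in zip(self.net.parameters(), self.r, self.v):
            grad = g + c.l1_coeff * np.sign(p) + 2.0 * c.l2_coeff * p if reg else g
            r *= c.rmsprop_rho
            r += (1.0 - c.rmsprop_rho) * grad**2
            g_hat = grad / (np.sqrt(r) + c.rmsprop_epsilon)
            v *= c.nesterov_momentum
            v -= lr * g_hat
            p += c.nesterov_momentum * v - lr * g_hat


@dataclass
class LossTrace:
    """Per-sub-epoch record of the optimization."""

    records: list = field(default_factory=list)  # dicts: epoch, subepoch, lr, loss

    def append(self, epoch, subepoch, lr, loss):
        self.records.append({"epoch": epoch, "subepoch": subepoch, "lr": lr, "loss": loss})

    @property
    def losses(self) -> np.ndarray:
        return np.array([r["loss"] for r in self.records])

    def to_text(self) -> str:
        lines = ["epoch\tsubepoch\tlr\tloss"]
        lines += [f"{r['epoch']}\t{r['subepoch']}\t{r['lr']:.6g}\t{r['loss']:.6f}" for r in self.records]
        return "\n".join(lines) + "\n"


def train(
    net: MultiScalePatchNet,
    cases: list[SampleableCase],
    config: TrainingConfig = TrainingConfig(),
) -> LossTrace:
    """Optimize the network on sampled patches; returns the loss trace.

    Fully deterministic for a fixed config seed.  Aborts with a diagnostic
    ``RuntimeError`` if the loss turns non-finite.
    """
    if not cases:
        raise ValueError("training needs at least one case")
    rng = np.random.default_rng(config.seed)
    opt = RMSpropNesterov(net, config)
    trace = LossTrace()
    for epoch in range(1, config.n_epochs + 1):
        lr = config.learning_rate(epoch)
        for sub in range(1, config.subepochs_per_epoch + 1):
            sub_losses = []
            for _ in range(config.batches_per_subepoch):
                xn, xc, y = sample_training_batch(
                    cases,
                    net.config,
                    rng,
                    batch_size=config.batch_size,
                    foreground_fraction=config.foreground_sampling_fraction,
                    augment=config.augment_sagittal_reflection,
                    swap_roles=config.swap_channel_roles,
                )
                logits = net.forward_logits(xn, xc)
                data_loss, dlogits = softmax_cross_entropy(logits, y)
                loss = data_loss + opt.penalty()
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} sub-epoch {sub}: "
                        f"data={data_loss}, penalty={opt.penalty()}, lr={lr}"
                    )
                net.zero_grad()
                net.backward(dlogits)
                opt.step(lr)
                sub_losses.append(loss)
            trace.append(epoch, sub, lr, float(np.mean(sub_losses)))
    return trace
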