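"""The differentiable matching optimization loop.

Each species block k owns a real parameterization matrix X_k whose hard
matching M(X_k) defines the current candidate pairing.  One gradient step:
add scaled Gumbel noise to every X_k, pair the alignments under the hard
permutations (straight-through to the Sinkhorn relaxation), sample a mask
on one side, compute the MLM loss, backpropagate, and update the X_k with
AdaDelta (learning rate 9, weight decay 0.1, reduce-on-plateau schedule).
After every update the X_k are mean-centered — the matching operator is
invariant under adding a constant, so this only removes a flat direction.

Because zero-initialized runs explore very different loss-landscape paths,
a full run first performs several short probe runs from X = 0, averages
their final parameterizations, and warm-starts a longer run from that
average.  The hard permutations seen at the q lowest-loss steps of the
long run are averaged into per-block "confidence matrices"; the consensus
pairing is the hard matching of each confidence matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from ._tape import Var, backward
from .matching import add_gumbel_noise, hard_soft_bridge, matching_operator
from .msa import InteractionDataset
from .scoring import (
    PairedTemplate,
    ScorerInterface,
    apply_perms,
    choose_masked_side,
    encode_dataset,
    mlm_loss,
    sample_mask,
)

__all__ = [
    "OptimizerConfig",
    "RunLedger",
    "RunResult",
    "StepResult",
    "gradient_step",
    "probe_and_warm_start",
    "run_diffpalm",
    "confidence_from_entries",
    "consensus_from_confidence",
]


@dataclass
class OptimizerConfig:
    """Hyperparameters of the matching optimization.

    Defaults are the published operating point: AdaDelta with initial
    learning rate 9, a reduce-on-plateau scheduler (factor 0.8, patience
    20 steps), weight decay 0.1, 20 zero-initialized probe runs of 20
    steps warm-starting a 400-step main run, masking probability 0.7, and
    confidence aggregation over the q lowest-loss steps (q = main_steps).
    """

    lr_init: float = 9.0
    plateau_factor: float = 0.8
    plateau_patience: int = 20
    plateau_threshold: float = 1e-4
    weight_decay: float = 0.1
    n_probe_runs: int = 20
    probe_steps: int = 20
    main_steps: int = 400
    q: int | None = None
    p_mask: float = 0.7
    mask_side: str | None = None
    tau: float = 1.0
    sinkhorn_iters: int = 20
    rho: float = 0.9
    eps: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if min(self.lr_init, self.plateau_factor, self.weight_decay + 1e-12) <= 0:
            raise ValueError("optimizer constants must be positive")
        if self.q is not None and self.q > self.main_steps:
            raise ValueError("q cannot exceed main_steps")

    @property
    def q_eff(self) -> int:
        return self.main_steps if self.q is None else self.q


class _OptState:
    """AdaDelta accumulators plus the plateau scheduler."""

    def __init__(self, shapes, cfg: OptimizerConfig):
        self.acc_grad = [np.zeros(s) for s in shapes]
        self.acc_delta = [np.zeros(s) for s in shapes]
        self.cfg = cfg
        self.lr = cfg.lr_init
        self.best_loss = np.inf
        self.bad_steps = 0

    @property
    def lr_factor(self) -> float:
        """Current learning rate relative to the initial one."""
        return self.lr / self.cfg.lr_init

    def update(self, X: list[np.ndarray], grads: list[np.ndarray]) -> None:
        cfg = self.cfg
        for k, (x, g) in enumerate(zip(X, grads)):
            g = g + cfg.weight_decay * x
            self.acc_grad[k] = cfg.rho * self.acc_grad[k] + (1 - cfg.rho) * g * g
            delta = np.sqrt(self.acc_delta[k] + cfg.eps) / np.sqrt(self.acc_grad[k] + cfg.eps) * g
            self.acc_delta[k] = cfg.rho * self.acc_delta[k] + (1 - cfg.rho) * delta * delta
            x -= self.lr * delta
            x -= x.mean()  # matching is shift-invariant; remove the flat mode

    def observe_loss(self, loss: float) -> None:
        if loss < self.best_loss - self.cfg.plateau_threshold * abs(self.best_loss):
            self.best_loss = loss
            self.bad_steps = 0
        else:
            self.bad_steps += 1
            if self.bad_steps > self.cfg.plateau_patience:
                self.lr *= self.cfg.plateau_factor
                self.bad_steps = 0


@dataclass
class RunLedger:
    """Per-step record of an optimization run: (step, loss, hard perms)."""

    entries: list[tuple[int, float, list[np.ndarray]]] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)

    def append(self, step: int, loss: float, perms: list[np.ndarray], lr: float | None = None) -> None:
        if not np.isfinite(loss):
            raise ValueError(f"non-finite loss at step {step}")
        self.entries.append((step, float(loss), perms))
        if lr is not None:
            self.lrs.append(float(lr))

    def lowest(self, q: int) -> list[tuple[int, float, list[np.ndarray]]]:
        return sorted(self.entries, key=lambda e: e[1])[:q]

    @property
    def losses(self) -> np.ndarray:
        return np.array([loss for _, loss, _ in self.entries])


class StepResult(NamedTuple):
    X: list[np.ndarray]
    loss: float
    perms: list[np.ndarray]
    opt_state: "_OptState"


class RunResult(NamedTuple):
    ledger: RunLedger
    confidence: list[np.ndarray]
    consensus: list[np.ndarray]


def _as_template(dataset) -> PairedTemplate:
    if isinstance(dataset, PairedTemplate):
        return dataset
    if isinstance(dataset, InteractionDataset):
        return encode_dataset(dataset)
    raise TypeError(f"expected InteractionDataset or PairedTemplate, got {type(dataset)!r}")


def gradient_step(
    X: list[np.ndarray],
    scorer: ScorerInterface,
    dataset,
    cfg: OptimizerConfig,
    rng: np.random.Generator,
    opt_state: _OptState | None = None,
) -> StepResult:
    """One optimization step; returns the updated parameterizations.

    Noise is drawn first (its scale tied to the current learning rate), the
    loss of the resulting hard pairing is backpropagated through the
    Sinkhorn relaxation, and AdaDelta applies the update.  The hard
    permutations actually used for the loss are returned for the ledger.
    """
    template = _as_template(dataset)
    if opt_state is None:
        opt_state = _OptState([x.shape for x in X], cfg)
    X = [add_gumbel_noise(x, opt_state.lr_factor, rng) for x in X]
    xvars = [Var(x) for x in X]
    bridges = [hard_soft_bridge(xv, tau=cfg.tau, n_iter=cfg.sinkhorn_iters, rng=rng) for xv in xvars]
    perms = [b.data.copy() for b in bridges]
    paired = apply_perms(template, bridges)
    side = cfg.mask_side or choose_masked_side(paired, rng)
    mask = sample_mask(paired, cfg.p_mask, side, rng)
    while mask.n_masked == 0:  # vanishingly rare at the default p
        mask = sample_mask(paired, cfg.p_mask, side, rng)
    loss_var = mlm_loss(scorer, paired, mask)
    backward(loss_var)
    grads = [xv.grad if xv.grad is not None else np.zeros_like(xv.data) for xv in xvars]
    X = [xv.data.copy() for xv in xvars]
    opt_state.update(X, grads)
    loss = float(loss_var.data)
    opt_state.observe_loss(loss)
    return StepResult(X=X, loss=loss, perms=perms, opt_state=opt_state)


def probe_and_warm_start(
    scorer: ScorerInterface,
    dataset,
    cfg: OptimizerConfig,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Average of several short zero-initialized probe runs.

    Each probe starts from X_k = 0 (Gumbel noise breaks the tie, so the
    first hard matching is a uniformly random permutation) and runs for
    `probe_steps` gradient steps; the final parameterizations of all
    probes are averaged entrywise to warm-start the main run.
    """
    template = _as_template(dataset)
    shapes = [(b.b_tokens.shape[0],) * 2 for b in template.blocks]
    finals = []
    for _ in range(cfg.n_probe_runs):
        X = [np.zeros(s) for s in shapes]
        state = None
        for _ in range(cfg.probe_steps):
            X, _, _, state = gradient_step(X, scorer, template, cfg, rng, state)
        finals.append(X)
    return [np.mean([f[k] for f in finals], axis=0) for k in range(len(shapes))]


def confidence_from_entries(entries, n_blocks: int) -> list[np.ndarray]:
    """Average the hard permutations of ledger entries into confidences."""
    if not entries:
        raise ValueError("no ledger entries to aggregate")
    return [np.mean([perms[k] for _, _, perms in entries], axis=0) for k in range(n_blocks)]


def consensus_from_confidence(
    confidence: list[np.ndarray], rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Hard matching of each confidence matrix (the consensus pairing)."""
    return [matching_operator(C, rng=rng) for C in confidence]


def run_diffpalm(
    scorer: ScorerInterface,
    dataset,
    cfg: OptimizerConfig,
    rng: np.random.Generator,
) -> RunResult:
    """One full optimization run: probes, warm-started main run, consensus."""
    template = _as_template(dataset)
    if not template.blocks:
        return RunResult(RunLedger(), [], [])
    X = probe_and_warm_start(scorer, template, cfg, rng)
    ledger = RunLedger()
    state = None
    for step in range(cfg.main_steps):
        X, loss, perms, state = gradient_step(X, scorer, template, cfg, rng, state)
        ledger.append(step, loss, perms, lr=state.lr)
    confidence = confidence_from_entries(ledger.lowest(cfg.q_eff), len(template.blocks))
    consensus = consensus_from_confidence(confidence, rng=rng)
    return RunResult(ledger=ledger, confidence=confidence, consensus=consensus)
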