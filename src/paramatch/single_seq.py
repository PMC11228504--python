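"""Single-sequence pairing baseline.

A scorer that looks at one concatenated sequence pair at a time (no MSA
context) only needs the Nk^2 candidate pair scores per species, not the
Nk! permutations: each candidate pair (A_i, B_j) is scored by its average
MLM loss over several random masks, and the optimal one-to-one matching is
the exact solution of a linear assignment problem on the resulting cost
matrix.  No gradients are involved; the scorer runs in evaluation mode.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .msa import InteractionDataset, SpeciesBlock, pairs_table
from .scoring import (
    BlockRows,
    PairedBlocks,
    ScorerInterface,
    _onehot,
    mlm_loss,
    sample_mask,
)

__all__ = ["pair_cost_matrix", "lap_pair", "pair_by_single_sequence"]


def _single_pair(a_tokens: np.ndarray, b_tokens: np.ndarray) -> PairedBlocks:
    """A one-row paired MSA holding a single candidate pair."""
    block = BlockRows(
        species="",
        mixed_a=_to_var(a_tokens),
        b_tokens=b_tokens[None, :],
        a_is_pad=np.array([False]),
        b_is_pad=np.array([False]),
    )
    return PairedBlocks(blocks=[block], len_a=a_tokens.size, len_b=b_tokens.size)


def _to_var(a_tokens: np.ndarray):
    from ._tape import asvar

    return asvar(_onehot(a_tokens[None, :]))


def pair_cost_matrix(
    scorer: ScorerInterface,
    dataset: InteractionDataset,
    block: SpeciesBlock,
    p: float = 0.5,
    n_masks: int = 10,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Nk x Nk cost matrix of a species block.

    Entry (i, j) is the MLM loss of the concatenated pair (A_i, B_j) —
    indices into the block's A and B sides — averaged over `n_masks`
    random masks drawn across the whole concatenated sequence.  Exactly
    one scorer evaluation is made per candidate pair and mask.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    tok_a = dataset.msa_a.to_tokens()
    tok_b = dataset.msa_b.to_tokens()
    n = block.nk
    cost = np.empty((n, n))
    for i, ra in enumerate(block.side_a):
        for j, rb in enumerate(block.side_b):
            paired = _single_pair(tok_a[ra], tok_b[rb])
            acc = 0.0
            for _ in range(n_masks):
                mask = sample_mask(paired, p, "both", rng)
                while mask.n_masked == 0:
                    mask = sample_mask(paired, p, "both", rng)
                acc += float(mlm_loss(scorer, paired, mask).data)
            cost[i, j] = acc / n_masks
    return cost


def lap_pair(cost: np.ndarray) -> np.ndarray:
    """Exact minimum-cost one-to-one assignment of a square cost matrix."""
    cost = np.asarray(cost, dtype=np.float64)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError(f"cost matrix must be square, got shape {cost.shape}")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost entries must be finite")
    rows, cols = linear_sum_assignment(cost)
    P = np.zeros(cost.shape)
    P[rows, cols] = 1.0
    return P


def pair_by_single_sequence(
    scorer: ScorerInterface,
    dataset: InteractionDataset,
    p: float = 0.5,
    n_masks: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[list[np.ndarray], list[dict]]:
    """Pair every block independently from single-pair scores.

    Returns the per-block permutations (in the same B-row-indexed
    convention as the optimizer) and the predicted-pairs table, with the
    negated mean loss of each selected pair as its confidence score.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    perms, confidences = [], []
    for block in dataset.blocks:
        cost = pair_cost_matrix(scorer, dataset, block, p=p, n_masks=n_masks, rng=rng)
        assignment = lap_pair(cost)  # assignment[i, j]: pair (A_i, B_j)
        perms.append(assignment.T)  # B-row-indexed convention
        conf = np.zeros_like(cost)
        sel = assignment.astype(bool)
        conf[sel] = -cost[sel]
        confidences.append(conf.T)
    pairs = pairs_table(dataset, perms, confidences)
    return perms, pairs
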