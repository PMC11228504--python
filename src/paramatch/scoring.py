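"""Masked-token scoring of paired MSAs.

The optimization target is a masked-language-modeling (MLM) loss: hide a
random subset of tokens on one side of the paired alignment and average
the surprisal of a model's predictions at the hidden positions.  Pairing
quality enters because the predictive distribution at a masked position may
condition on the partner sequence placed on the same row.

Scorers implement :class:`ScorerInterface`.  The bundled
:class:`SyntheticCouplingScorer` is a self-contained generative model of
inter-family coevolution: designated column pairs (one column in each
family) are coupled through a per-pair substitution table concentrated on a
random bijection of the alphabet with leakage ``epsilon``, all other
columns follow a background distribution.  It is fully differentiable with
respect to soft row mixtures, which is what lets gradients reach the
parameterization matrices.  An adapter hook for an external MSA-based
protein language model is provided as a contract: it fails loudly when no
weights/backend are available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import _tape as T
from ._tape import Var, asvar
from .msa import GAP, N_TOKENS, InteractionDataset

__all__ = [
    "MaskSpec",
    "BlockRows",
    "PairedBlocks",
    "CouplingModel",
    "ScorerInterface",
    "SyntheticCouplingScorer",
    "UnavailableBackendError",
    "language_model_adapter",
    "get_scorer",
    "encode_dataset",
    "apply_perms",
    "choose_masked_side",
    "sample_mask",
    "mlm_loss",
]

#: "comparable lengths" threshold for side selection (max/min column ratio)
COMPARABLE_LENGTH_RATIO = 1.25
#: "considerably more padding" threshold (ratio of padding-row counts)
PADDING_RATIO = 2.0


# ---------------------------------------------------------------------------
# encoded paired representation
# ---------------------------------------------------------------------------


def _onehot(tokens: np.ndarray) -> np.ndarray:
    out = np.zeros(tokens.shape + (N_TOKENS,))
    np.put_along_axis(out, tokens[..., None], 1.0, axis=-1)
    return out


@dataclass
class BlockTemplate:
    """Pre-encoded rows of one species block (permutation not yet applied)."""

    species: str
    a_onehot: np.ndarray  # (nk, L_A, N_TOKENS), real rows then padding
    b_tokens: np.ndarray  # (nk, L_B)
    a_is_pad: np.ndarray  # (nk,) bool
    b_is_pad: np.ndarray


@dataclass
class PairedTemplate:
    """Encoded dataset ready to be paired under any permutation set."""

    blocks: list[BlockTemplate]
    len_a: int
    len_b: int
    n_pad_a: int
    n_pad_b: int
    ctx_a_tokens: np.ndarray  # (n_pos, L_A) positive-example context
    ctx_b_tokens: np.ndarray


@dataclass
class BlockRows:
    """One block of the paired MSA: (soft) A rows against hard B rows."""

    species: str
    mixed_a: Var  # (nk, L_A, N_TOKENS), convex mixtures of one-hot rows
    b_tokens: np.ndarray
    a_is_pad: np.ndarray
    b_is_pad: np.ndarray


@dataclass
class PairedBlocks:
    """The paired MSA in scoring form, plus non-maskable context rows."""

    blocks: list[BlockRows]
    len_a: int
    len_b: int
    n_pad_a: int = 0
    n_pad_b: int = 0
    ctx_a_tokens: np.ndarray | None = None
    ctx_b_tokens: np.ndarray | None = None

    @property
    def n_rows(self) -> int:
        return sum(b.b_tokens.shape[0] for b in self.blocks)


def encode_dataset(dataset: InteractionDataset) -> PairedTemplate:
    """Integer/one-hot encode a grouped (and padded) dataset."""
    tok_a = dataset.msa_a.to_tokens()
    tok_b = dataset.msa_b.to_tokens()
    blocks = []
    for block in dataset.blocks:
        side_a, side_b = block.side_a, block.side_b
        if len(side_a) != block.nk or len(side_b) != block.nk:
            raise ValueError(f"block {block.species!r} sides not equalized; run pad_species")
        blocks.append(
            BlockTemplate(
                species=block.species,
                a_onehot=_onehot(tok_a[side_a]),
                b_tokens=tok_b[side_b],
                a_is_pad=np.array([i >= block.nk_a for i in range(block.nk)]),
                b_is_pad=np.array([i >= block.nk_b for i in range(block.nk)]),
            )
        )
    if dataset.positives:
        ctx_a = tok_a[[ra for ra, _ in dataset.positives]]
        ctx_b = tok_b[[rb for _, rb in dataset.positives]]
    else:
        ctx_a = np.zeros((0, dataset.msa_a.length), dtype=np.int64)
        ctx_b = np.zeros((0, dataset.msa_b.length), dtype=np.int64)
    return PairedTemplate(
        blocks=blocks,
        len_a=dataset.msa_a.length,
        len_b=dataset.msa_b.length,
        n_pad_a=sum(int(b.a_is_pad.sum()) for b in blocks),
        n_pad_b=sum(int(b.b_is_pad.sum()) for b in blocks),
        ctx_a_tokens=ctx_a,
        ctx_b_tokens=ctx_b,
    )


def apply_perms(template: PairedTemplate, perms) -> PairedBlocks:
    """Pair the template under one (hard or bridged) permutation per block.

    Each permutation acts on the A side: paired row i mixes the A rows with
    weights from row i of the permutation and sits next to B row i.  Tape
    variables keep the result differentiable.
    """
    if len(perms) != len(template.blocks):
        raise ValueError("need one permutation per block")
    rows = []
    for tmpl, P in zip(template.blocks, perms):
        Pv = asvar(P)
        n = tmpl.b_tokens.shape[0]
        if Pv.data.shape != (n, n):
            raise ValueError(
                f"permutation shape {Pv.data.shape} mismatches block {tmpl.species!r} size {n}"
            )
        rows.append(
            BlockRows(
                species=tmpl.species,
                mixed_a=T.mix_rows(Pv, tmpl.a_onehot),
                b_tokens=tmpl.b_tokens,
                a_is_pad=tmpl.a_is_pad,
                b_is_pad=tmpl.b_is_pad,
            )
        )
    return PairedBlocks(
        blocks=rows,
        len_a=template.len_a,
        len_b=template.len_b,
        n_pad_a=template.n_pad_a,
        n_pad_b=template.n_pad_b,
        ctx_a_tokens=template.ctx_a_tokens,
        ctx_b_tokens=template.ctx_b_tokens,
    )


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


@dataclass
class MaskSpec:
    """Masked positions, per block and side.

    Context (positive-example) rows are never masked and carry no arrays.
    ``side`` is 'A', 'B', or 'both' (the latter used by the single-sequence
    baseline, which masks across the whole concatenated pair).
    """

    side: str
    masks_a: list[np.ndarray]
    masks_b: list[np.ndarray]
    p: float = 0.0

    @property
    def n_masked(self) -> int:
        return int(sum(m.sum() for m in self.masks_a) + sum(m.sum() for m in self.masks_b))


def choose_masked_side(
    paired: PairedBlocks,
    rng: np.random.Generator,
    comparable_ratio: float = COMPARABLE_LENGTH_RATIO,
    padding_ratio: float = PADDING_RATIO,
) -> str:
    """Pick which family to mask.

    With no padding rows, mask the shorter family (random on a tie).  With
    padding present and comparable lengths, mask the family with
    considerably more padding rows; otherwise choose uniformly at random.
    """
    la, lb = paired.len_a, paired.len_b
    pad_a, pad_b = paired.n_pad_a, paired.n_pad_b
    if pad_a == 0 and pad_b == 0:
        if la < lb:
            return "A"
        if lb < la:
            return "B"
        return "A" if rng.random() < 0.5 else "B"
    if max(la, lb) <= comparable_ratio * min(la, lb):
        if pad_a > padding_ratio * pad_b:
            return "A"
        if pad_b > padding_ratio * pad_a:
            return "B"
    return "A" if rng.random() < 0.5 else "B"


def sample_mask(
    paired: PairedBlocks,
    p: float,
    side: str,
    rng: np.random.Generator,
) -> MaskSpec:
    """Mask each token on `side` independently with probability p.

    Padding (all-gap) tokens are masked with the same probability as
    ordinary ones; positive-example context rows are never masked.
    """
    if not 0 < p <= 1:
        raise ValueError("masking probability must be in (0, 1]")
    if side not in ("A", "B", "both"):
        raise ValueError(f"unknown side {side!r}")
    masks_a, masks_b = [], []
    for block in paired.blocks:
        n = block.b_tokens.shape[0]
        ma = np.zeros((n, paired.len_a), dtype=bool)
        mb = np.zeros((n, paired.len_b), dtype=bool)
        if side in ("A", "both"):
            ma = rng.random((n, paired.len_a)) < p
        if side in ("B", "both"):
            mb = rng.random((n, paired.len_b)) < p
        masks_a.append(ma)
        masks_b.append(mb)
    return MaskSpec(side=side, masks_a=masks_a, masks_b=masks_b, p=p)


# ---------------------------------------------------------------------------
# the synthetic coupling model and scorer
# ---------------------------------------------------------------------------


@dataclass
class CouplingModel:
    """Pairwise inter-family coupling between designated column pairs.

    ``tables[j]`` is a row-stochastic matrix over the amino-acid alphabet:
    given the A-side state at column ``column_pairs[j][0]``, it is the
    distribution of the B-side state at ``column_pairs[j][1]``.  Tables are
    concentrated on a bijection with leakage epsilon.  All remaining
    columns are background noise.  ``smoothing`` mixes every predictive
    distribution with the background so that gap tokens (padding rows) and
    leaked states keep nonzero probability.
    """

    column_pairs: list[tuple[int, int]]
    tables: np.ndarray  # (C, 20, 20) row-stochastic
    background: np.ndarray  # (20,)
    gap_freq: float = 0.02
    smoothing: float = 0.01

    def __post_init__(self):
        self.tables = np.asarray(self.tables, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if not np.allclose(self.tables.sum(axis=-1), 1.0, atol=1e-8):
            raise ValueError("coupling table rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")
        if not 0 <= self.gap_freq < 1 or not 0 <= self.smoothing < 1:
            raise ValueError("gap_freq and smoothing must lie in [0, 1)")
        # background over the full token set (letters scaled, gap appended)
        self.bg_full = np.append(self.background * (1 - self.gap_freq), self.gap_freq)
        self.log_bg_full = np.log(self.bg_full)
        # reverse conditionals P(a | b) ~ background[a] * tables[a, b]
        rev = self.background[None, :, None] * self.tables  # (C, a, b)
        rev = np.moveaxis(rev, 1, 2)  # (C, b, a)
        norm = rev.sum(axis=-1, keepdims=True)
        # context letters with no coupling mass fall back to a uniform guess
        rev = np.where(norm > 0, rev / np.where(norm > 0, norm, 1.0), 1.0 / GAP)
        # log predictive rows for a masked A token given B context token
        # (C, N_TOKENS context, N_TOKENS predicted); gap context -> background
        pred = np.tile(self.bg_full, (len(self.column_pairs), N_TOKENS, 1))
        eta = self.smoothing
        pred[:, :GAP, :GAP] = (1 - eta) * rev
        pred[:, :GAP, GAP] = 0.0
        pred[:, :GAP, :] += eta * self.bg_full
        self.log_pred_a = np.log(pred)

    def to_json(self, path) -> None:
        payload = {
            "column_pairs": [list(cp) for cp in self.column_pairs],
            "tables": self.tables.tolist(),
            "background": self.background.tolist(),
            "gap_freq": self.gap_freq,
            "smoothing": self.smoothing,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CouplingModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            column_pairs=[tuple(cp) for cp in payload["column_pairs"]],
            tables=np.array(payload["tables"]),
            background=np.array(payload["background"]),
            gap_freq=payload["gap_freq"],
            smoothing=payload["smoothing"],
        )


class ScorerInterface:
    """Behavioral contract for MLM scorers.

    ``score_sum`` returns the summed per-token surprisal over masked
    positions (a tape Var, differentiable with respect to any soft row
    mixtures in `paired`) together with the number of masked tokens.
    """

    def score_sum(self, paired: PairedBlocks, mask: MaskSpec) -> tuple[Var, int]:
        raise NotImplementedError

    def score(self, paired: PairedBlocks, mask: MaskSpec) -> Var:
        """Mean surprisal over masked tokens."""
        total, count = self.score_sum(paired, mask)
        if count == 0:
            raise ValueError("mask contains no masked tokens")
        return total * (1.0 / count)


class SyntheticCouplingScorer(ScorerInterface):
    """Exact MLM scorer under a :class:`CouplingModel`.

    The predictive distribution for a masked B token at a coupled column is
    the partner's (possibly soft) A state pushed through the coupling
    table; a masked A token at a coupled column is predicted from the B
    context through the reverse conditional; everything else is predicted
    from the background.  A coupled partner that is itself masked is not
    used as context.  Predictions are row-independent: each paired row is
    scored on its own.
    """

    def __init__(self, model: CouplingModel):
        self.model = model

    def score_sum(self, paired: PairedBlocks, mask: MaskSpec) -> tuple[Var, int]:
        m = self.model
        eta = m.smoothing
        total: Var | float = 0.0
        const = 0.0
        count = 0
        for block, ma, mb in zip(paired.blocks, mask.masks_a, mask.masks_b):
            count += int(ma.sum()) + int(mb.sum())
            btok = block.b_tokens
            mixed = block.mixed_a
            # --- masked B tokens --------------------------------------
            if mb.any():
                coev_b = np.zeros(paired.len_b, dtype=bool)
                for ca, cb in m.column_pairs:
                    coev_b[cb] = True
                for j, (ca, cb) in enumerate(m.column_pairs):
                    rows = np.flatnonzero(mb[:, cb])
                    if rows.size == 0:
                        continue
                    usable = rows[~ma[rows, ca]]
                    blocked = rows[ma[rows, ca]]  # context masked -> background
                    if blocked.size:
                        const -= m.log_bg_full[btok[blocked, cb]].sum()
                    if usable.size == 0:
                        continue
                    pa = T.index(mixed, (usable, ca))  # (u, N_TOKENS)
                    p_letters = T.index(pa, (slice(None), slice(0, GAP)))
                    p_gap = T.index(pa, (slice(None), GAP))
                    coupled = T.matmul(p_letters, m.tables[j])  # (u, 20)
                    tok = btok[usable, cb]
                    letters = np.flatnonzero(tok < GAP)
                    gaps = np.flatnonzero(tok == GAP)
                    if letters.size:
                        sel, tsel = letters, tok[letters]
                        pred = (
                            (T.index(coupled, (sel, tsel)) + T.index(p_gap, (sel,)) * m.bg_full[tsel])
                            * (1 - eta)
                            + eta * m.bg_full[tsel]
                        )
                        total = total + -T.vsum(T.log(pred))
                    if gaps.size:
                        pred = (1 - eta) * T.index(p_gap, (gaps,)) * m.bg_full[GAP] + eta * m.bg_full[GAP]
                        total = total + -T.vsum(T.log(pred))
                # background columns: constant surprisal
                bg_mask = mb & ~coev_b[None, :]
                if bg_mask.any():
                    const -= m.log_bg_full[btok[bg_mask]].sum()
            # --- masked A tokens (soft targets) ------------------------
            if ma.any():
                ri, ci = np.nonzero(ma)
                logpred = np.tile(m.log_bg_full, (ri.size, 1))
                for j, (ca, cb) in enumerate(m.column_pairs):
                    at_ca = np.flatnonzero(ci == ca)
                    if at_ca.size == 0:
                        continue
                    ctx_ok = at_ca[~mb[ri[at_ca], cb]]
                    if ctx_ok.size:
                        logpred[ctx_ok] = m.log_pred_a[j, btok[ri[ctx_ok], cb]]
                targets = T.index(mixed, (ri, ci))  # (mA, N_TOKENS)
                total = total + -T.vsum(targets * logpred)
        total = total + const if isinstance(total, Var) else asvar(total + const)
        return total, count


def mlm_loss(
    scorer: ScorerInterface,
    paired: PairedBlocks,
    mask: MaskSpec,
    reduction: str = "mean",
) -> Var:
    """MLM loss of a paired MSA under a scorer.

    Mean (default) or sum of the per-masked-token surprisal.  The result is
    a tape Var: call ``.data`` for the value, or backpropagate through it
    when `paired` holds soft mixtures.
    """
    if mask.n_masked == 0:
        raise ValueError("undefined MLM loss: mask contains no masked tokens")
    total, count = scorer.score_sum(paired, mask)
    if reduction == "mean":
        return total * (1.0 / count)
    if reduction == "sum":
        return total
    raise ValueError(f"unknown reduction {reduction!r}")


# ---------------------------------------------------------------------------
# external language-model adapter (contract only)
# ---------------------------------------------------------------------------


class UnavailableBackendError(RuntimeError):
    """An external scorer backend is not available in this environment."""


def language_model_adapter(weights_handle=None) -> ScorerInterface:
    """Adapter for an MSA-based protein language model backend.

    The adapter tokenizes paired rows (soft mixtures become probability-
    weighted embedding averages), runs the model, and returns the masked
    cross-entropy.  Loading requires external pretrained weights and their
    runtime; when these are missing the adapter refuses loudly instead of
    silently degrading.
    """
    if weights_handle is None:
        raise UnavailableBackendError(
            "no language-model weights supplied; use the 'synthetic' scorer or provide weights"
        )
    try:  # pragma: no cover - only reachable with an external runtime
        import esm  # noqa: F401
        import torch  # noqa: F401
    except ImportError as err:
        raise UnavailableBackendError(
            f"language-model runtime not importable: {err}"
        ) from err
    raise UnavailableBackendError(
        "language-model adapter requires an external runtime; not available here"
    )  # pragma: no cover


def get_scorer(name: str, **kwargs) -> ScorerInterface:
    """Scorer registry: 'synthetic' (CouplingModel) or 'external-lm'."""
    if name == "synthetic":
        model = kwargs.get("model")
        if model is None:
            raise ValueError("synthetic scorer needs a CouplingModel via model=")
        return SyntheticCouplingScorer(model)
    if name == "external-lm":
        return language_model_adapter(kwargs.get("weights_handle"))
    raise ValueError(f"unknown scorer backend {name!r}")
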