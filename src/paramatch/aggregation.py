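"""Precision-improving procedures: multi-run aggregation and iterative pairing.

Multi-Run Aggregation (MRA) pools the step ledgers of several independent
optimization runs and aggregates the q lowest-loss hard permutations from
the pooled collection into confidence matrices, exactly as a single run
does with its own ledger.

The Iterative Pairing Algorithm (IPA) alternates optimization with
promotion: after each accepted iteration the five highest-confidence
predicted pairs (pooled across species) become positive examples — fixed,
unmasked context — and are removed from the matching problem.  Acceptance
is guarded by comparing average MLM losses of the new and previous
consensus matchings over 200 random masks (a one-sided Welch test at
alpha = 0.05); a failed comparison first triggers up to three fresh
optimization attempts, then a revert to the previous moving-average
confidence, and a failed termination check ends the procedure.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats

from .matching import matching_operator
from .msa import (
    InteractionDataset,
    PAD_PREFIX,
    group_species,
    pad_species,
    pairs_table,
    perms_from_pairs,
    strip_padding,
)
from .optim import (
    OptimizerConfig,
    RunLedger,
    RunResult,
    confidence_from_entries,
    consensus_from_confidence,
    run_diffpalm,
)
from .scoring import (
    ScorerInterface,
    apply_perms,
    choose_masked_side,
    encode_dataset,
    mlm_loss,
    sample_mask,
)

__all__ = [
    "mra",
    "ipa",
    "IpaResult",
    "loss_under_matching",
    "significantly_higher",
]


def mra(
    scorer: ScorerInterface,
    dataset,
    cfg: OptimizerConfig,
    n_runs: int,
    rng: np.random.Generator,
) -> RunResult:
    """Multi-run aggregation over `n_runs` independent optimization runs."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    template = dataset if not isinstance(dataset, InteractionDataset) else None
    pooled = RunLedger()
    n_blocks = None
    for _ in range(n_runs):
        result = run_diffpalm(scorer, dataset, cfg, rng)
        n_blocks = len(result.confidence)
        pooled.entries.extend(result.ledger.entries)
    if not pooled.entries:
        return RunResult(pooled, [], [])
    confidence = confidence_from_entries(pooled.lowest(cfg.q_eff), n_blocks)
    consensus = consensus_from_confidence(confidence)
    return RunResult(ledger=pooled, confidence=confidence, consensus=consensus)


def loss_under_matching(
    scorer: ScorerInterface,
    dataset,
    perms: list[np.ndarray],
    n_masks: int = 200,
    p: float = 0.7,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray]:
    """Average MLM loss of a fixed matching over random masks.

    The pairing is held fixed, `n_masks` independent masks are drawn (the
    masked side re-chosen per draw), and the mean together with the
    per-mask sample is returned for significance testing.
    """
    if n_masks < 2:
        raise ValueError("n_masks must be >= 2")
    rng = np.random.default_rng(0) if rng is None else rng
    template = encode_dataset(dataset) if isinstance(dataset, InteractionDataset) else dataset
    paired = apply_perms(template, perms)
    losses = np.empty(n_masks)
    for m in range(n_masks):
        side = choose_masked_side(paired, rng)
        mask = sample_mask(paired, p, side, rng)
        while mask.n_masked == 0:
            mask = sample_mask(paired, p, side, rng)
        losses[m] = float(mlm_loss(scorer, paired, mask).data)
    return float(losses.mean()), losses


def _degenerate(a: np.ndarray, b: np.ndarray) -> bool:
    """Both samples flat to within floating-point noise."""
    scale = max(1.0, abs(a.mean()), abs(b.mean()))
    return a.std() + b.std() < 1e-9 * scale


def significantly_higher(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> bool:
    """One-sided Welch t-test: is mean(a) significantly above mean(b)?"""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if _degenerate(a, b):
        return a.mean() > b.mean() + 1e-9 * max(1.0, abs(b.mean()))
    result = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return bool(result.pvalue < alpha)


def _certified_not_worse(new: np.ndarray, old: np.ndarray, alpha: float = 0.05) -> bool:
    """Accept `new` only with evidence it is not worse than `old`.

    Strictly lower mean passes outright; otherwise the Welch test must be
    informative — two flat, equal samples certify nothing and fail.
    """
    new, old = np.asarray(new, float), np.asarray(old, float)
    if _degenerate(new, old):
        return new.mean() < old.mean() - 1e-9 * max(1.0, abs(old.mean()))
    if new.mean() < old.mean():
        return True
    return not significantly_higher(new, old, alpha)


class IpaResult(NamedTuple):
    pairs: list[dict]
    history: list[dict]
    n_iterations: int


_strip_padding = strip_padding


def _confidence_dict(dataset: InteractionDataset, confidence: list[np.ndarray]) -> dict:
    """Confidence matrices as a (id_B, id_A) -> value mapping."""
    out = {}
    for block, C in zip(dataset.blocks, confidence):
        for i, rb in enumerate(block.side_b):
            for j, ra in enumerate(block.side_a):
                out[(dataset.msa_b.ids[rb], dataset.msa_a.ids[ra])] = float(C[i, j])
    return out


def _matrices_from_dict(dataset: InteractionDataset, values: dict) -> list[np.ndarray]:
    mats = []
    for block in dataset.blocks:
        n = block.nk
        M = np.zeros((n, n))
        for i, rb in enumerate(block.side_b):
            for j, ra in enumerate(block.side_a):
                M[i, j] = values.get((dataset.msa_b.ids[rb], dataset.msa_a.ids[ra]), 0.0)
        mats.append(M)
    return mats


def _consensus_pairs(dataset: InteractionDataset, perms: list[np.ndarray], conf_dict: dict):
    """(id_a, id_b, confidence, is_padding) tuples of a consensus pairing."""
    out = []
    for row in pairs_table(dataset, perms, include_trivial=False, include_positives=False):
        conf = conf_dict.get((row["id_B"], row["id_A"]), 0.0)
        out.append((row["id_A"], row["id_B"], conf, row["is_padding"], row["species"]))
    return out


def ipa(
    scorer: ScorerInterface,
    dataset: InteractionDataset,
    cfg: OptimizerConfig,
    rng: np.random.Generator,
    n_promote: int = 5,
    max_retries: int = 3,
    n_masks: int = 200,
    alpha: float = 0.05,
) -> IpaResult:
    """Iterative pairing: promote high-confidence pairs to positives.

    Each iteration runs the optimizer on the remaining rows, updates the
    moving-average confidence, accepts or reverts the new consensus based
    on 200-mask loss comparisons, checks for termination against the
    previous iteration's positives, and finally promotes the top
    `n_promote` confidence entries (pooled across species, greedily kept
    row-disjoint) to positive examples, shrinking the problem.
    """
    msa_a, msa_b = strip_padding(dataset)
    id_row_a = {rid: i for i, rid in enumerate(msa_a.ids)}
    id_row_b = {rid: i for i, rid in enumerate(msa_b.ids)}
    base_positives = [
        (id_row_a[dataset.msa_a.ids[ra]], id_row_b[dataset.msa_b.ids[rb]])
        for ra, rb in dataset.positives
    ]
    cur_pos = list(base_positives)
    history_sum: dict = {}
    n_hist = 0
    promoted: list[tuple[str, str, float, str]] = []  # id_a, id_b, conf, species
    history: list[dict] = []
    prev = None  # state of the previous iteration
    final_consensus: list = []
    n_iter = 0

    while True:
        cur_ds = pad_species(group_species(msa_a, msa_b, cur_pos))
        if not cur_ds.blocks:
            final_consensus = []
            break
        n_iter += 1
        ctil = None
        accepted = False
        prev_restricted = None
        if prev is not None:
            prev_restricted = {
                pair: val
                for pair, val in prev["ctil"].items()
                if pair in _support(cur_ds)
            }
        for _ in range(max_retries):
            run = run_diffpalm(scorer, cur_ds, cfg, rng)
            c_n = _confidence_dict(cur_ds, run.confidence)
            ctil = {
                pair: (val + history_sum.get(pair, 0.0)) / (n_hist + 1)
                for pair, val in c_n.items()
            }
            perms_n = [matching_operator(M) for M in _matrices_from_dict(cur_ds, ctil)]
            if prev is None:
                accepted = True
                break
            old_perms = [
                matching_operator(M) for M in _matrices_from_dict(cur_ds, prev_restricted)
            ]
            _, new_losses = loss_under_matching(scorer, cur_ds, perms_n, n_masks, cfg.p_mask, rng)
            _, old_losses = loss_under_matching(scorer, cur_ds, old_perms, n_masks, cfg.p_mask, rng)
            if _certified_not_worse(new_losses, old_losses, alpha):
                accepted = True
                break
        if not accepted:  # revert to the previous moving average
            ctil = prev_restricted
            perms_n = [matching_operator(M) for M in _matrices_from_dict(cur_ds, ctil)]
        consensus = _consensus_pairs(cur_ds, perms_n, ctil)

        # termination check against the positives of the previous iteration
        if prev is not None:
            ds6 = prev["dataset"]
            new_pairs = [(a, b) for a, b, _, _, _ in consensus] + [
                (a, b) for a, b, _, _ in prev["promoted"]
            ]
            perms6_new = perms_from_pairs(ds6, new_pairs)
            perms6_old = perms_from_pairs(ds6, [(a, b) for a, b, _, _, _ in prev["consensus"]])
            _, l_new = loss_under_matching(scorer, ds6, perms6_new, n_masks, cfg.p_mask, rng)
            _, l_old = loss_under_matching(scorer, ds6, perms6_old, n_masks, cfg.p_mask, rng)
            if not _certified_not_worse(l_new, l_old, alpha):
                final_consensus = consensus
                break

        history_sum = {pair: history_sum.get(pair, 0.0) + val for pair, val in ctil.items()}
        n_hist += 1

        # promotion: top confidence entries pooled across species
        candidates = sorted(
            (
                (val, pair)
                for pair, val in ctil.items()
                if not pair[0].startswith(PAD_PREFIX) and not pair[1].startswith(PAD_PREFIX)
            ),
            key=lambda t: -t[0],
        )
        chosen: list[tuple[str, str, float, str]] = []
        used_a, used_b = set(), set()
        for val, (id_b, id_a) in candidates:
            if id_a in used_a or id_b in used_b:
                continue
            chosen.append((id_a, id_b, val, msa_a.species[id_row_a[id_a]]))
            used_a.add(id_a)
            used_b.add(id_b)
            if len(chosen) == n_promote:
                break
        remaining_pairs = sum(
            min(block.nk_a, block.nk_b) for block in cur_ds.blocks
        )
        for id_a, id_b, val, sp in chosen:
            history.append(
                {
                    "iteration": n_iter,
                    "species": sp,
                    "id_A": id_a,
                    "id_B": id_b,
                    "confidence": val,
                    "accepted": accepted,
                }
            )
        promoted.extend(chosen)
        cur_pos = cur_pos + [(id_row_a[a], id_row_b[b]) for a, b, _, _ in chosen]
        prev = {
            "dataset": cur_ds,
            "ctil": ctil,
            "consensus": consensus,
            "promoted": [(a, b, v, s) for a, b, v, s in chosen],
        }
        if remaining_pairs <= n_promote or not chosen:
            final_consensus = [
                row for row in consensus if row[0] not in {a for a, _, _, _ in chosen}
            ]
            break

    # assemble the final pairing: promoted predictions + last consensus +
    # trivia of the final grouping + the originally supplied positives
    final_ds = pad_species(group_species(msa_a, msa_b, cur_pos))
    pairs: list[dict] = []
    for id_a, id_b, conf, sp in promoted:
        pairs.append(
            {
                "species": sp,
                "id_A": id_a,
                "id_B": id_b,
                "confidence": conf,
                "is_positive": False,
                "is_padding": False,
                "promoted": True,
            }
        )
    seen_a = {p["id_A"] for p in pairs}
    for id_a, id_b, conf, is_pad, sp in final_consensus:
        if id_a in seen_a:
            continue
        pairs.append(
            {
                "species": sp,
                "id_A": id_a,
                "id_B": id_b,
                "confidence": conf,
                "is_positive": False,
                "is_padding": is_pad,
                "promoted": False,
            }
        )
    for ra, rb in final_ds.trivial_pairs:
        if msa_a.ids[ra] in seen_a or (ra, rb) in base_positives:
            continue
        pairs.append(
            {
                "species": msa_a.species[ra],
                "id_A": msa_a.ids[ra],
                "id_B": msa_b.ids[rb],
                "confidence": 1.0,
                "is_positive": False,
                "is_padding": False,
                "promoted": False,
            }
        )
    for ra, rb in base_positives:
        pairs.append(
            {
                "species": msa_a.species[ra],
                "id_A": msa_a.ids[ra],
                "id_B": msa_b.ids[rb],
                "confidence": 1.0,
                "is_positive": True,
                "is_padding": False,
                "promoted": False,
            }
        )
    return IpaResult(pairs=pairs, history=history, n_iterations=n_iter)


def _support(dataset: InteractionDataset) -> set:
    pairs = set()
    for block in dataset.blocks:
        for rb in block.side_b:
            for ra in block.side_a:
                pairs.add((dataset.msa_b.ids[rb], dataset.msa_a.ids[ra]))
    return pairs
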