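"""Planted-pairing benchmark generator and precision metrics.

The generator emulates the geometry of curated interacting-family
benchmarks (a few dozen interacting pairs spread over species with a
handful of paralogs each): for every planted pair, designated coevolving
column pairs carry a shared latent state — the A-side residue is drawn
from the background and pushed through a per-column-pair bijection table
with leakage epsilon to produce the B-side residue — while all other
columns are background noise.  Rows are shuffled within species so that
input order carries no information.  The same coupling tables double as
the synthetic scorer's model, so every stage of the pipeline can be tested
offline, without pretrained weights.

Metrics follow the field's conventions: precision-100 is the fraction of
correct pairs among all predicted (non-padding) pairs, precision-10 the
same fraction over the top 10% of pairs ranked by confidence, and the
chance expectation of random within-species matching is K / sum_k N_k
(a uniform random permutation has one expected fixed point per species).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .msa import AA_ALPHABET, InteractionDataset, Msa, group_species, pad_species
from .scoring import CouplingModel

__all__ = [
    "SyntheticSpec",
    "generate_dataset",
    "planted_perms",
    "pairing_with_fraction",
    "sample_positive_examples",
    "precision_scores",
    "chance_expectation",
    "random_matching_precision",
]


@dataclass
class SyntheticSpec:
    """Geometry and signal strength of a planted benchmark.

    Defaults give ~40 pairable rows (10 species of 3-5 paralogs), two
    alignments of 60 and 40 columns over the 20-letter alphabet, and 10
    coevolving column pairs with 5% leakage — a regime where the planted
    signal is strong but not deterministic.
    """

    n_species: int = 10
    min_size: int = 3
    max_size: int = 5
    species_sizes: list[int] | None = None
    len_a: int = 60
    len_b: int = 40
    alphabet_size: int = 20
    n_coevolving: int = 10
    leakage: float = 0.05
    gap_freq: float = 0.02
    smoothing: float = 0.01
    drop_prob_b: float = 0.0  # per-row chance of an unpairable B orphan

    def __post_init__(self):
        if not 2 <= self.alphabet_size <= len(AA_ALPHABET):
            raise ValueError("alphabet_size must be in [2, 20]")
        if not 0 <= self.leakage < 1:
            raise ValueError("leakage must be in [0, 1)")
        if self.n_coevolving > min(self.len_a, self.len_b):
            raise ValueError("more coevolving pairs than columns")
        if self.species_sizes is None and self.min_size < 1:
            raise ValueError("species sizes must be >= 1")


def _coupling_model(spec: SyntheticSpec, rng: np.random.Generator) -> CouplingModel:
    n_letters = len(AA_ALPHABET)
    a_cols = rng.choice(spec.len_a, size=spec.n_coevolving, replace=False)
    b_cols = rng.choice(spec.len_b, size=spec.n_coevolving, replace=False)
    column_pairs = [(int(a), int(b)) for a, b in zip(a_cols, b_cols)]
    asize, eps = spec.alphabet_size, spec.leakage
    # background: uniform over the used letters, tiny floor elsewhere
    background = np.full(n_letters, 1e-8)
    background[:asize] = 1.0 / asize
    background /= background.sum()
    tables = np.zeros((spec.n_coevolving, n_letters, n_letters))
    for j in range(spec.n_coevolving):
        bij = rng.permutation(asize)
        tables[j, :, :asize] = eps / asize
        for a in range(asize):
            tables[j, a, bij[a]] += 1 - eps
        tables[j, asize:, :asize] = 1.0 / asize  # unused letters: uniform
    return CouplingModel(
        column_pairs=column_pairs,
        tables=tables,
        background=background,
        gap_freq=spec.gap_freq,
        smoothing=spec.smoothing,
    )


def generate_dataset(
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> tuple[InteractionDataset, dict[str, str], CouplingModel]:
    """Generate a planted benchmark.

    Returns the grouped-and-padded dataset, the ground-truth pairing as an
    ``id_A -> id_B`` mapping, and the coupling model that produced the
    coevolving columns (hand it to the synthetic scorer).
    """
    model = _coupling_model(spec, rng)
    sizes = (
        list(spec.species_sizes)
        if spec.species_sizes is not None
        else rng.integers(spec.min_size, spec.max_size + 1, size=spec.n_species).tolist()
    )
    chars = np.array(list(AA_ALPHABET))
    ids_a, sp_a, seqs_a = [], [], []
    ids_b, sp_b, seqs_b = [], [], []
    truth: dict[str, str] = {}
    for k, size in enumerate(sizes):
        species = f"s{k:03d}"
        rows_a, rows_b = [], []
        for i in range(size):
            a_row = rng.choice(len(chars), size=spec.len_a, p=model.background)
            b_row = rng.choice(len(chars), size=spec.len_b, p=model.background)
            for j, (ca, cb) in enumerate(model.column_pairs):
                b_row[cb] = rng.choice(len(chars), p=model.tables[j, a_row[ca]])
            id_a, id_b = f"A{k}_{i}", f"B{k}_{i}"
            rows_a.append((id_a, "".join(chars[a_row])))
            if spec.drop_prob_b > 0 and rng.random() < spec.drop_prob_b and size > 1:
                continue  # orphan A row: its partner is dropped from M(B)
            rows_b.append((id_b, "".join(chars[b_row])))
            truth[id_a] = id_b
        rng.shuffle(rows_a)
        rng.shuffle(rows_b)
        for rid, seq in rows_a:
            ids_a.append(rid)
            sp_a.append(species)
            seqs_a.append(seq)
        for rid, seq in rows_b:
            ids_b.append(rid)
            sp_b.append(species)
            seqs_b.append(seq)
    msa_a = Msa(ids=ids_a, species=sp_a, seqs=seqs_a)
    msa_b = Msa(ids=ids_b, species=sp_b, seqs=seqs_b)
    dataset = pad_species(group_species(msa_a, msa_b))
    return dataset, truth, model


def planted_perms(dataset: InteractionDataset, truth: dict[str, str]) -> list[np.ndarray]:
    """Per-block permutation matrices of the ground-truth pairing.

    Only defined when every B row of every block has its true partner in
    the block (symmetric benchmarks).
    """
    perms = []
    for block in dataset.blocks:
        n = block.nk
        id_pos_a = {dataset.msa_a.ids[r]: j for j, r in enumerate(block.side_a)}
        P = np.zeros((n, n))
        partner_of_b = {v: k for k, v in truth.items()}
        for i, rb in enumerate(block.side_b):
            id_b = dataset.msa_b.ids[rb]
            id_a = partner_of_b.get(id_b)
            if id_a is None or id_a not in id_pos_a:
                raise ValueError(f"no planted partner for row {id_b!r}")
            P[i, id_pos_a[id_a]] = 1.0
        perms.append(P)
    return perms


def pairing_with_fraction(
    dataset: InteractionDataset,
    truth: dict[str, str],
    fraction: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """A pairing with a prescribed fraction of correct pairs.

    Starting from the planted permutations, cyclic rotations are applied
    to randomly chosen row subsets so that exactly ``round((1 - fraction)
    * N)`` rows are mispaired (subject to the constraint that a block
    cannot contain exactly one mispaired row).
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    perms = [P.copy() for P in planted_perms(dataset, truth)]
    sizes = [P.shape[0] for P in perms]
    n_total = sum(sizes)
    n_wrong = int(round((1 - fraction) * n_total))
    # per-block mispair counts: each in {0, 2, .., nk}, summing to n_wrong
    counts = [0] * len(sizes)
    order = rng.permutation(len(sizes))
    remaining = n_wrong
    for idx in order:
        if remaining < 2:
            break
        take = min(remaining, sizes[idx])
        if remaining - take == 1:  # never leave a single leftover row
            take -= 1
        if take < 2:
            continue
        counts[idx] = take
        remaining -= take
    if remaining > 0:
        for idx in order:  # absorb a leftover of 1 by extending a block
            if 0 < counts[idx] < sizes[idx]:
                counts[idx] += 1
                remaining -= 1
                break
    if remaining > 0:
        raise ValueError(f"cannot place {n_wrong} mispaired rows in blocks {sizes}")
    for idx, c in enumerate(counts):
        if c < 2:
            continue
        rows = rng.choice(sizes[idx], size=c, replace=False)
        rotated = np.roll(rows, 1)
        P = perms[idx]
        new_rows = P[rows].copy()
        P[rotated] = new_rows  # row i now takes the A partner of another row
    return perms


def sample_positive_examples(
    dataset: InteractionDataset,
    truth: dict[str, str],
    n: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Sample `n` planted pairs as known positives, as (row_a, row_b)."""
    pos_a = {rid: i for i, rid in enumerate(dataset.msa_a.ids)}
    pos_b = {rid: i for i, rid in enumerate(dataset.msa_b.ids)}
    candidates = [
        (pos_a[a], pos_b[b]) for a, b in truth.items() if a in pos_a and b in pos_b
    ]
    if n > len(candidates):
        raise ValueError(f"only {len(candidates)} planted pairs available")
    chosen = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in chosen]


def _filter_predicted(predicted):
    rows = []
    for row in predicted:
        if row.get("is_padding") or row.get("is_positive"):
            continue
        rows.append((row["id_A"], row["id_B"], float(row.get("confidence", 1.0))))
    return rows


def precision_scores(predicted, truth: dict[str, str], top_fraction: float | None = None) -> float:
    """Fraction of correct pairs among predicted (non-padding) pairs.

    With ``top_fraction`` set, only the top ``ceil(top_fraction * n)``
    pairs ranked by confidence are scored (ties resolved by confidence
    then stable input order).  Positive examples and padding-assigned
    pairs are excluded.
    """
    rows = _filter_predicted(predicted)
    if not rows:
        raise ValueError("no predicted pairs to score")
    if top_fraction is not None:
        k = math.ceil(top_fraction * len(rows))
        order = np.argsort([-conf for _, _, conf in rows], kind="stable")[:k]
        rows = [rows[i] for i in order]
    correct = sum(1 for id_a, id_b, _ in rows if truth.get(id_a) == id_b)
    return correct / len(rows)


def chance_expectation(dataset: InteractionDataset) -> float:
    """Expected precision of uniform random within-species matching.

    A uniform random permutation of n items has one expected fixed point,
    so the expectation is K / sum_k N_k over the optimizable blocks.
    """
    total = sum(block.nk for block in dataset.blocks)
    if total == 0:
        raise ValueError("dataset has no optimizable blocks")
    return dataset.n_species / total


def random_matching_precision(
    dataset: InteractionDataset,
    truth: dict[str, str],
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo precision-100 of uniform random within-species matching."""
    planted = planted_perms(dataset, truth)
    sizes = [P.shape[0] for P in planted]
    out = np.empty(n_draws)
    for d in range(n_draws):
        correct = 0
        for P, n in zip(planted, sizes):
            perm = rng.permutation(n)
            correct += int(P[np.arange(n), perm].sum())
        out[d] = correct / sum(sizes)
    return out
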