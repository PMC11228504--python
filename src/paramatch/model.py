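"""Model-style front end for paralog matching.

:class:`ParalogMatching` holds the matching problem (two annotated
alignments, optional known pairs, a scorer backend); its :meth:`fit`
runs one of the pairing methods and returns a :class:`MatchingResults`
carrying the predicted pairs, per-pair confidences, the optimization
ledger and a printable summary — in the spirit of the model/results split
used by statistical modelling packages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aggregation import ipa, mra
from .msa import (
    InteractionDataset,
    Msa,
    group_species,
    pad_species,
    pairs_table,
    read_msa,
    write_pairs_tsv,
)
from .optim import OptimizerConfig, run_diffpalm
from .scoring import ScorerInterface
from .single_seq import pair_by_single_sequence
from .synth import chance_expectation, precision_scores

__all__ = ["ParalogMatching", "MatchingResults"]


class ParalogMatching:
    """The within-species one-to-one matching problem for two families.

    Parameters
    ----------
    msa_a, msa_b
        Annotated single-chain alignments of the two interacting families.
    scorer
        A :class:`~paramatch.scoring.ScorerInterface` backend.
    positives
        Known interacting pairs, as (id_A, id_B) or (row_a, row_b); they
        are excluded from optimization and used as unmasked context.
    max_block_size
        Species larger than this on either side are left unpaired.
    """

    def __init__(
        self,
        msa_a: Msa,
        msa_b: Msa,
        scorer: ScorerInterface,
        positives=None,
        max_block_size: int = 50,
    ):
        self.msa_a = msa_a
        self.msa_b = msa_b
        self.scorer = scorer
        rows = self._resolve_positives(positives)
        self.dataset: InteractionDataset = pad_species(
            group_species(msa_a, msa_b, rows, max_block_size=max_block_size)
        )

    def _resolve_positives(self, positives):
        if not positives:
            return []
        idx_a = {rid: i for i, rid in enumerate(self.msa_a.ids)}
        idx_b = {rid: i for i, rid in enumerate(self.msa_b.ids)}
        rows = []
        for a, b in positives:
            if isinstance(a, str):
                rows.append((idx_a[a], idx_b[b]))
            else:
                rows.append((int(a), int(b)))
        return rows

    @classmethod
    def from_files(
        cls,
        fasta_a,
        fasta_b,
        scorer: ScorerInterface,
        delimiter: str = "|",
        species_table=None,
        positives=None,
        max_block_size: int = 50,
    ) -> "ParalogMatching":
        msa_a = read_msa(fasta_a, delimiter=delimiter, species_table=species_table)
        msa_b = read_msa(fasta_b, delimiter=delimiter, species_table=species_table)
        return cls(msa_a, msa_b, scorer, positives=positives, max_block_size=max_block_size)

    @property
    def chance_expectation(self) -> float:
        return chance_expectation(self.dataset)

    def fit(
        self,
        method: str = "diffpalm",
        config: OptimizerConfig | None = None,
        n_runs: int = 1,
        seed: int | np.random.Generator = 0,
        **kwargs,
    ) -> "MatchingResults":
        """Solve the matching problem.

        method is one of ``"diffpalm"`` (one optimization run), ``"mra"``
        (`n_runs` pooled runs), ``"ipa"`` (iterative promotion of
        high-confidence pairs), or ``"single-sequence"`` (per-pair scores
        plus exact linear assignment).
        """
        cfg = config or OptimizerConfig()
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        ledger = None
        confidence = None
        history = None
        if method == "diffpalm":
            result = run_diffpalm(self.scorer, self.dataset, cfg, rng)
            pairs = pairs_table(self.dataset, result.consensus, result.confidence)
            ledger, confidence = result.ledger, result.confidence
        elif method == "mra":
            result = mra(self.scorer, self.dataset, cfg, n_runs, rng)
            pairs = pairs_table(self.dataset, result.consensus, result.confidence)
            ledger, confidence = result.ledger, result.confidence
        elif method == "ipa":
            result = ipa(self.scorer, self.dataset, cfg, rng, **kwargs)
            pairs = result.pairs
            history = result.history
        elif method == "single-sequence":
            _, pairs = pair_by_single_sequence(
                self.scorer,
                self.dataset,
                p=kwargs.get("p", 0.5),
                n_masks=kwargs.get("n_masks", 10),
                rng=rng,
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        return MatchingResults(
            model=self,
            method=method,
            pairs=pairs,
            confidence=confidence,
            ledger=ledger,
            history=history,
            config=cfg,
        )


class MatchingResults:
    """Predicted pairing plus diagnostics from one fit."""

    def __init__(self, model, method, pairs, confidence, ledger, history, config):
        self.model = model
        self.method = method
        self._pairs = list(pairs)
        self.confidence = confidence
        self.ledger = ledger
        self.history = history
        self.config = config

    @property
    def pairs(self) -> pd.DataFrame:
        return pd.DataFrame(self._pairs)

    def precision(self, truth: dict[str, str], top_fraction: float | None = None) -> float:
        """Precision against a ground-truth id_A -> id_B mapping."""
        return precision_scores(self._pairs, truth, top_fraction)

    def to_tsv(self, path) -> None:
        write_pairs_tsv(path, self._pairs)

    def summary(self) -> str:
        ds = self.model.dataset
        n_pairs = sum(1 for r in self._pairs if not r["is_positive"] and not r["is_padding"])
        lines = [
            "Paralog Matching Results",
            "=" * 38,
            f"method:              {self.method}",
            f"species blocks (K):  {ds.n_species}",
            f"rows under matching: {sum(b.nk for b in ds.blocks)}",
            f"trivial pairs:       {len(ds.trivial_pairs)}",
            f"positive examples:   {len(ds.positives)}",
            f"predicted pairs:     {n_pairs}",
            f"chance expectation:  {self.model.chance_expectation:.4f}",
        ]
        if self.ledger is not None and self.ledger.entries:
            losses = self.ledger.losses
            lines += [
                f"ledger entries:      {len(losses)}",
                f"best step loss:      {losses.min():.4f}",
                f"final step loss:     {losses[-1]:.4f}",
            ]
        if self.history is not None:
            lines.append(f"promotion events:    {len(self.history)}")
        top = sorted(
            (r for r in self._pairs if not r["is_positive"] and not r["is_padding"]),
            key=lambda r: -r["confidence"],
        )[:5]
        lines.append("top pairs by confidence:")
        for r in top:
            lines.append(
                f"  {r['species']:<10} {r['id_A']:<12} {r['id_B']:<12} {r['confidence']:.3f}"
            )
        return "\n".join(lines)

    def __repr__(self):
        return f"<MatchingResults method={self.method!r} pairs={len(self._pairs)}>"
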