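"""MSA input/output and species bookkeeping for paralog matching.

Two single-chain alignments M(A) and M(B) of interacting protein families
are read from aligned FASTA, with a species label per row (parsed from the
header or supplied as a sidecar TSV).  Rows are grouped by species:
species present in only one alignment are discarded, species with a single
unmatched sequence on each side are paired trivially, and the remaining
species become the blocks of the within-species matching problem.  When a
species has unequal counts in the two families, the smaller side is
augmented with all-gap "padding sequences" so the block is square.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AA_ALPHABET",
    "GAP_CHAR",
    "GAP",
    "N_TOKENS",
    "Msa",
    "SpeciesBlock",
    "InteractionDataset",
    "PairedMsa",
    "MsaLengthError",
    "SpeciesAnnotationError",
    "read_msa",
    "write_msa",
    "group_species",
    "pad_species",
    "build_paired_msa",
    "strip_padding",
    "pairs_table",
    "perms_from_pairs",
    "write_pairs_tsv",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHAR = "-"
#: integer code of the gap token; amino acids are 0..19 in AA_ALPHABET order
GAP = len(AA_ALPHABET)
#: tokens a sequence row may contain (mask/pad symbols are internal only)
N_TOKENS = GAP + 1

_TOKEN_OF = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_TOKEN_OF[GAP_CHAR] = GAP
PAD_PREFIX = "__pad__"


class MsaLengthError(ValueError):
    """Raised when alignment rows do not all share the same length."""


class SpeciesAnnotationError(ValueError):
    """Raised when a record's species label cannot be recovered."""


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace(".", GAP_CHAR)


@dataclass
class Msa:
    """An aligned set of sequences with per-row ids and species labels."""

    ids: list[str]
    species: list[str]
    seqs: list[str]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not (len(self.ids) == len(self.species) == len(self.seqs)):
            raise ValueError("ids, species and seqs must have equal lengths")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise MsaLengthError(f"alignment is ragged: row lengths {sorted(lengths)}")
        for rid, seq in zip(self.ids, self.seqs):
            bad = set(seq) - set(AA_ALPHABET) - {GAP_CHAR}
            if bad:
                raise ValueError(f"record {rid!r} contains tokens outside the alphabet: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        """Number of aligned columns L."""
        return len(self.seqs[0]) if self.seqs else 0

    def to_tokens(self) -> np.ndarray:
        """Integer-encode as an (n, L) array; gap is the last token."""
        out = np.empty((len(self), self.length), dtype=np.int64)
        for i, seq in enumerate(self.seqs):
            out[i] = [_TOKEN_OF[c] for c in seq]
        return out


def read_msa(path, delimiter: str = "|", species_table=None) -> Msa:
    """Read an aligned FASTA with species annotations.

    Species labels come either from the header (``id<delimiter>species``,
    default delimiter ``|``) or, when `species_table` is given, from a
    two-column sidecar TSV mapping id to species (the full header is then
    the id).  Sequences are uppercased and ``.`` gaps normalized to ``-``.
    """
    table = None
    if species_table is not None:
        table = {}
        with open(species_table) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise SpeciesAnnotationError(f"malformed species table line: {line!r}")
                table[parts[0]] = parts[1]
    ids, species, seqs = [], [], []
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.description or record.id
        if table is not None:
            rid = header
            if rid not in table:
                raise SpeciesAnnotationError(f"record {rid!r} missing from species table")
            sp = table[rid]
        else:
            if delimiter not in header:
                raise SpeciesAnnotationError(
                    f"record {header!r} has no {delimiter!r}-delimited species label"
                )
            rid, sp = header.rsplit(delimiter, 1)
        ids.append(rid)
        species.append(sp)
        seqs.append(_normalize_seq(str(record.seq)))
    return Msa(ids=ids, species=species, seqs=seqs)


def write_msa(msa: Msa, path, delimiter: str = "|") -> None:
    """Write an Msa as aligned FASTA with ``id<delimiter>species`` headers."""
    records = [
        SeqRecord(Seq(seq), id=f"{rid}{delimiter}{sp}", description="")
        for rid, sp, seq in zip(msa.ids, msa.species, msa.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class SpeciesBlock:
    """Rows of one species on both sides of the matching problem.

    `rows_a` / `rows_b` index real sequences in the dataset's alignments;
    `padding_a` / `padding_b` index synthetic all-gap rows appended when
    the two sides are unbalanced.  After padding both sides have
    `nk = max(nk_a, nk_b)` rows.
    """

    species: str
    rows_a: list[int]
    rows_b: list[int]
    padding_a: list[int] = field(default_factory=list)
    padding_b: list[int] = field(default_factory=list)

    @property
    def nk_a(self) -> int:
        return len(self.rows_a)

    @property
    def nk_b(self) -> int:
        return len(self.rows_b)

    @property
    def nk(self) -> int:
        return max(self.nk_a, self.nk_b)

    @property
    def side_a(self) -> list[int]:
        """All A-side rows (real then padding)."""
        return self.rows_a + self.padding_a

    @property
    def side_b(self) -> list[int]:
        return self.rows_b + self.padding_b


@dataclass
class InteractionDataset:
    """Grouped matching problem: alignments, blocks, positives, trivia."""

    msa_a: Msa
    msa_b: Msa
    blocks: list[SpeciesBlock]
    positives: list[tuple[int, int]] = field(default_factory=list)
    trivial_pairs: list[tuple[int, int]] = field(default_factory=list)
    oversized_species: list[str] = field(default_factory=list)
    padded: bool = False

    @property
    def n_species(self) -> int:
        """K: number of optimizable species blocks."""
        return len(self.blocks)


def group_species(
    msa_a: Msa,
    msa_b: Msa,
    positives: list[tuple[int, int]] | None = None,
    max_block_size: int = 50,
) -> InteractionDataset:
    """Group rows by species into the matching problem.

    Species present in only one alignment are discarded.  Rows listed in
    `positives` (known interacting pairs, as (row_a, row_b) indices) are
    removed from the problem and kept as fixed context.  Species left with
    exactly one unmatched sequence on each side become trivial pairs.
    Species exceeding `max_block_size` on either side are excluded from
    optimization and reported in `oversized_species`.
    """
    positives = list(positives or [])
    pos_a = {ra for ra, _ in positives}
    pos_b = {rb for _, rb in positives}
    by_species_a: dict[str, list[int]] = {}
    by_species_b: dict[str, list[int]] = {}
    for i, sp in enumerate(msa_a.species):
        if i not in pos_a:
            by_species_a.setdefault(sp, []).append(i)
    for i, sp in enumerate(msa_b.species):
        if i not in pos_b:
            by_species_b.setdefault(sp, []).append(i)

    blocks, trivial, oversized = [], [], []
    for sp in sorted(set(by_species_a) & set(by_species_b)):
        rows_a, rows_b = by_species_a[sp], by_species_b[sp]
        if len(rows_a) == 1 and len(rows_b) == 1:
            trivial.append((rows_a[0], rows_b[0]))
        elif max(len(rows_a), len(rows_b)) > max_block_size:
            oversized.append(sp)
        else:
            blocks.append(SpeciesBlock(species=sp, rows_a=rows_a, rows_b=rows_b))
    return InteractionDataset(
        msa_a=msa_a,
        msa_b=msa_b,
        blocks=blocks,
        positives=positives,
        trivial_pairs=trivial,
        oversized_species=oversized,
    )


def pad_species(dataset: InteractionDataset) -> InteractionDataset:
    """Equalize block sides with all-gap padding sequences.

    For each block with nk_a < nk_b, nk_b - nk_a all-gap rows are appended
    to M(A) (and symmetrically), so every block has square size nk.
    """
    msa_a, msa_b = dataset.msa_a, dataset.msa_b
    gap_a = GAP_CHAR * msa_a.length
    gap_b = GAP_CHAR * msa_b.length
    new_a = Msa(list(msa_a.ids), list(msa_a.species), list(msa_a.seqs))
    new_b = Msa(list(msa_b.ids), list(msa_b.species), list(msa_b.seqs))
    counter = itertools.count()
    blocks = []
    for block in dataset.blocks:
        pad_a, pad_b = [], []
        for _ in range(block.nk - block.nk_a):
            new_a.ids.append(f"{PAD_PREFIX}{block.species}_{next(counter)}")
            new_a.species.append(block.species)
            new_a.seqs.append(gap_a)
            pad_a.append(len(new_a.seqs) - 1)
        for _ in range(block.nk - block.nk_b):
            new_b.ids.append(f"{PAD_PREFIX}{block.species}_{next(counter)}")
            new_b.species.append(block.species)
            new_b.seqs.append(gap_b)
            pad_b.append(len(new_b.seqs) - 1)
        blocks.append(replace(block, padding_a=pad_a, padding_b=pad_b))
    return InteractionDataset(
        msa_a=new_a,
        msa_b=new_b,
        blocks=blocks,
        positives=dataset.positives,
        trivial_pairs=dataset.trivial_pairs,
        oversized_species=dataset.oversized_species,
        padded=True,
    )


@dataclass
class PairedMsa:
    """Concatenated (A + B) rows under a given within-species matching."""

    rows: list[str]
    boundary: int
    maskable: np.ndarray
    provenance: list[tuple[str, int, int]]
    is_padding: list[bool]
    is_positive: list[bool]


def _perm_pairs(P: np.ndarray, n: int) -> list[tuple[int, int]]:
    """(a_pos, b_pos) index pairs from a permutation matrix P (A shuffled)."""
    P = np.asarray(P)
    if P.shape != (n, n):
        raise ValueError(f"permutation shape {P.shape} does not match block size {n}")
    cols = np.argmax(P, axis=1)
    if not np.array_equal(np.sort(cols), np.arange(n)):
        raise ValueError("not a valid permutation matrix")
    return [(int(cols[i]), i) for i in range(n)]


def build_paired_msa(
    dataset: InteractionDataset,
    perms: list[np.ndarray],
    include_positives: bool = False,
) -> PairedMsa:
    """Assemble the paired MSA for one permutation per block.

    Row i of block k concatenates the A-side row selected by the
    permutation with B-side row i.  When `include_positives` is set, known
    interacting pairs are appended as context rows whose tokens are flagged
    non-maskable.
    """
    if len(perms) != len(dataset.blocks):
        raise ValueError("need exactly one permutation per block")
    boundary = dataset.msa_a.length
    rows, provenance, is_padding, is_positive, maskable = [], [], [], [], []
    for block, P in zip(dataset.blocks, perms):
        side_a, side_b = block.side_a, block.side_b
        for a_pos, b_pos in _perm_pairs(P, block.nk):
            ra, rb = side_a[a_pos], side_b[b_pos]
            rows.append(dataset.msa_a.seqs[ra] + dataset.msa_b.seqs[rb])
            provenance.append((block.species, ra, rb))
            is_padding.append(a_pos >= block.nk_a or b_pos >= block.nk_b)
            is_positive.append(False)
            maskable.append(True)
    if include_positives:
        for ra, rb in dataset.positives:
            rows.append(dataset.msa_a.seqs[ra] + dataset.msa_b.seqs[rb])
            provenance.append((dataset.msa_a.species[ra], ra, rb))
            is_padding.append(False)
            is_positive.append(True)
            maskable.append(False)
    mask = np.zeros((len(rows), boundary + dataset.msa_b.length), dtype=bool)
    for i, ok in enumerate(maskable):
        mask[i, :] = ok
    return PairedMsa(
        rows=rows,
        boundary=boundary,
        maskable=mask,
        provenance=provenance,
        is_padding=is_padding,
        is_positive=is_positive,
    )


def strip_padding(dataset: InteractionDataset) -> tuple[Msa, Msa]:
    """Recover the original alignments (padding rows are always appended)."""

    def _strip(msa: Msa) -> Msa:
        keep = [i for i, rid in enumerate(msa.ids) if not rid.startswith(PAD_PREFIX)]
        return Msa(
            ids=[msa.ids[i] for i in keep],
            species=[msa.species[i] for i in keep],
            seqs=[msa.seqs[i] for i in keep],
        )

    return _strip(dataset.msa_a), _strip(dataset.msa_b)


def pairs_table(
    dataset: InteractionDataset,
    perms: list[np.ndarray],
    confidence: list[np.ndarray] | None = None,
    include_trivial: bool = True,
    include_positives: bool = True,
) -> list[dict]:
    """Tabulate the predicted pairing as rows of species/id_A/id_B/confidence.

    Block pairs come from `perms`; their confidence is read off the
    matching entry of `confidence` (1.0 when absent).  Trivial pairs and
    supplied positives are appended with confidence 1.0.
    """
    rows = []
    for b_idx, (block, P) in enumerate(zip(dataset.blocks, perms)):
        side_a, side_b = block.side_a, block.side_b
        for a_pos, b_pos in _perm_pairs(P, block.nk):
            conf = 1.0 if confidence is None else float(confidence[b_idx][b_pos, a_pos])
            rows.append(
                {
                    "species": block.species,
                    "id_A": dataset.msa_a.ids[side_a[a_pos]],
                    "id_B": dataset.msa_b.ids[side_b[b_pos]],
                    "confidence": conf,
                    "is_positive": False,
                    "is_padding": a_pos >= block.nk_a or b_pos >= block.nk_b,
                }
            )
    if include_trivial:
        for ra, rb in dataset.trivial_pairs:
            rows.append(
                {
                    "species": dataset.msa_a.species[ra],
                    "id_A": dataset.msa_a.ids[ra],
                    "id_B": dataset.msa_b.ids[rb],
                    "confidence": 1.0,
                    "is_positive": False,
                    "is_padding": False,
                }
            )
    if include_positives:
        for ra, rb in dataset.positives:
            rows.append(
                {
                    "species": dataset.msa_a.species[ra],
                    "id_A": dataset.msa_a.ids[ra],
                    "id_B": dataset.msa_b.ids[rb],
                    "confidence": 1.0,
                    "is_positive": True,
                    "is_padding": False,
                }
            )
    return rows


def perms_from_pairs(dataset: InteractionDataset, pairs) -> list[np.ndarray]:
    """Per-block permutation matrices realizing a list of (id_A, id_B) pairs.

    Rows not covered by `pairs` (e.g. padding) are completed arbitrarily in
    index order so each block is a full permutation.
    """
    want = {id_b: id_a for id_a, id_b in pairs}
    perms = []
    for block in dataset.blocks:
        n = block.nk
        pos_a = {dataset.msa_a.ids[r]: j for j, r in enumerate(block.side_a)}
        P = np.zeros((n, n))
        used_cols = set()
        unmatched_rows = []
        for i, rb in enumerate(block.side_b):
            id_a = want.get(dataset.msa_b.ids[rb])
            j = pos_a.get(id_a) if id_a is not None else None
            if j is not None and j not in used_cols:
                P[i, j] = 1.0
                used_cols.add(j)
            else:
                unmatched_rows.append(i)
        free_cols = [j for j in range(n) if j not in used_cols]
        for i, j in zip(unmatched_rows, free_cols):
            P[i, j] = 1.0
        perms.append(P)
    return perms


def write_pairs_tsv(path, pairs) -> None:
    """Write predicted pairs: species, id_A, id_B, confidence, flags."""
    with open(path, "w") as fh:
        fh.write("species\tid_A\tid_B\tconfidence\tis_positive\tis_padding\n")
        for row in pairs:
            fh.write(
                "\t".join(
                    [
                        str(row["species"]),
                        str(row["id_A"]),
                        str(row["id_B"]),
                        f"{row['confidence']:.6f}",
                        str(bool(row["is_positive"])),
                        str(bool(row["is_padding"])),
                    ]
                )
                + "\n"
            )
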