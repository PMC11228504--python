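"""Mask sampling and the synthetic-coupling MLM loss."""

import numpy as np
import pytest

from paramatch._tape import Var, backward
from paramatch.msa import GAP
from paramatch.scoring import (
    BlockRows,
    CouplingModel,
    MaskSpec,
    PairedBlocks,
    SyntheticCouplingScorer,
    UnavailableBackendError,
    _onehot,
    apply_perms,
    choose_masked_side,
    encode_dataset,
    get_scorer,
    language_model_adapter,
    mlm_loss,
    sample_mask,
)
from paramatch.synth import (
    SyntheticSpec,
    generate_dataset,
    pairing_with_fraction,
    planted_perms,
    sample_positive_examples,
)


def _paired(len_a, len_b, n_rows=3, pad_a=0, pad_b=0):
    """A minimal PairedBlocks shell for side-selection tests."""
    block = BlockRows(
        species="s",
        mixed_a=Var(np.zeros((n_rows, len_a, 21))),
        b_tokens=np.zeros((n_rows, len_b), dtype=int),
        a_is_pad=np.zeros(n_rows, dtype=bool),
        b_is_pad=np.zeros(n_rows, dtype=bool),
    )
    return PairedBlocks(blocks=[block], len_a=len_a, len_b=len_b, n_pad_a=pad_a, n_pad_b=pad_b)


class TestSideChoice:
    def test_shorter_side_masked_without_padding(self, rng):
        assert choose_masked_side(_paired(120, 300), rng) == "A"
        assert choose_masked_side(_paired(300, 120), rng) == "B"

    def test_padding_heavy_side_masked_at_comparable_lengths(self, rng):
        assert choose_masked_side(_paired(100, 110, pad_b=5), rng) == "B"
        assert choose_masked_side(_paired(110, 100, pad_a=7, pad_b=2), rng) == "A"

    def test_tie_is_roughly_uniform(self):
        rng = np.random.default_rng(0)
        sides = [choose_masked_side(_paired(100, 100), rng) for _ in range(400)]
        frac_a = sides.count("A") / len(sides)
        assert 0.4 < frac_a < 0.6


class TestSampleMask:
    def test_full_probability_masks_everything(self, small_problem, rng):
        dataset, truth, scorer = small_problem
        paired = apply_perms(encode_dataset(dataset), planted_perms(dataset, truth))
        mask = sample_mask(paired, 1.0, "B", rng)
        total_b = sum(b.b_tokens.size for b in paired.blocks)
        assert mask.n_masked == total_b
        assert not any(m.any() for m in mask.masks_a)

    def test_masked_count_is_binomial(self, small_problem):
        dataset, truth, scorer = small_problem
        paired = apply_perms(encode_dataset(dataset), planted_perms(dataset, truth))
        total = sum(b.b_tokens.size for b in paired.blocks)
        p = 0.7
        counts = [
            sample_mask(paired, p, "B", np.random.default_rng(s)).n_masked
            for s in range(60)
        ]
        se = np.sqrt(total * p * (1 - p))
        assert abs(np.mean(counts) - p * total) < 3 * se / np.sqrt(len(counts))

    def test_positive_example_rows_never_masked(self):
        spec = SyntheticSpec(n_species=3, min_size=3, max_size=3, len_a=16, len_b=12, n_coevolving=4)
        rng = np.random.default_rng(11)
        dataset, truth, coupling = generate_dataset(spec, rng)
        from paramatch.msa import group_species, pad_species

        positives = sample_positive_examples(dataset, truth, 2, rng)
        from paramatch.aggregation import _strip_padding

        msa_a, msa_b = _strip_padding(dataset)
        ds_pos = pad_species(group_species(msa_a, msa_b, positives))
        paired = apply_perms(
            encode_dataset(ds_pos), [np.eye(b.nk) for b in ds_pos.blocks]
        )
        assert paired.ctx_a_tokens.shape[0] == 2  # context rows present
        mask = sample_mask(paired, 1.0, "B", np.random.default_rng(0))
        # even at p=1 only block rows are masked, never the context rows
        assert mask.n_masked == sum(b.b_tokens.size for b in paired.blocks)

    def test_probability_bounds(self, small_problem, rng):
        dataset, truth, _ = small_problem
        paired = apply_perms(encode_dataset(dataset), planted_perms(dataset, truth))
        with pytest.raises(ValueError):
            sample_mask(paired, 0.0, "B", rng)
        with pytest.raises(ValueError):
            sample_mask(paired, 0.5, "C", rng)


def _mask_at_columns(paired, side, cols):
    masks_a, masks_b = [], []
    for block in paired.blocks:
        n = block.b_tokens.shape[0]
        ma = np.zeros((n, paired.len_a), dtype=bool)
        mb = np.zeros((n, paired.len_b), dtype=bool)
        if side == "A":
            ma[:, cols] = True
        else:
            mb[:, cols] = True
        masks_a.append(ma)
        masks_b.append(mb)
    return MaskSpec(side=side, masks_a=masks_a, masks_b=masks_b, p=1.0)


class TestSyntheticLoss:
    @pytest.fixture
    def problem(self):
        spec = SyntheticSpec(
            n_species=3, min_size=3, max_size=3, len_a=18, len_b=14, n_coevolving=5, leakage=0.0
        )
        return generate_dataset(spec, np.random.default_rng(21))

    def test_background_columns_have_closed_form_loss(self, problem):
        dataset, truth, coupling = problem
        scorer = SyntheticCouplingScorer(coupling)
        template = encode_dataset(dataset)
        coev_b = {cb for _, cb in coupling.column_pairs}
        bg_cols = [c for c in range(template.len_b) if c not in coev_b][:4]
        correct = apply_perms(template, planted_perms(dataset, truth))
        mask = _mask_at_columns(correct, "B", bg_cols)
        loss = float(mlm_loss(scorer, correct, mask).data)
        toks = np.concatenate([b.b_tokens[:, bg_cols].ravel() for b in correct.blocks])
        expected = -coupling.log_bg_full[toks].mean()
        assert np.isclose(loss, expected, atol=1e-12)

    def test_background_loss_permutation_invariant(self, problem):
        dataset, truth, coupling = problem
        scorer = SyntheticCouplingScorer(coupling)
        template = encode_dataset(dataset)
        coev_b = {cb for _, cb in coupling.column_pairs}
        bg_cols = [c for c in range(template.len_b) if c not in coev_b]
        losses = []
        for frac in (1.0, 0.0):
            perms = pairing_with_fraction(dataset, truth, frac, np.random.default_rng(5))
            paired = apply_perms(template, perms)
            mask = _mask_at_columns(paired, "B", bg_cols)
            losses.append(float(mlm_loss(scorer, paired, mask).data))
        assert abs(losses[0] - losses[1]) < 1e-9

    def test_exact_coupling_gives_near_zero_loss_when_correct(self, problem):
        dataset, truth, coupling = problem
        scorer = SyntheticCouplingScorer(coupling)
        template = encode_dataset(dataset)
        coev_cols = [cb for _, cb in coupling.column_pairs]
        correct = apply_perms(template, planted_perms(dataset, truth))
        loss = float(mlm_loss(scorer, correct, _mask_at_columns(correct, "B", coev_cols)).data)
        assert loss < 0.05  # only the smoothing floor remains
        wrong = apply_perms(
            template, pairing_with_fraction(dataset, truth, 0.0, np.random.default_rng(1))
        )
        loss_wrong = float(mlm_loss(scorer, wrong, _mask_at_columns(wrong, "B", coev_cols)).data)
        assert loss_wrong > loss + 1.0

    def test_loss_decreases_with_correct_fraction(self):
        spec = SyntheticSpec(
            n_species=4, min_size=4, max_size=4, len_a=24, len_b=18, n_coevolving=6, leakage=0.05
        )
        for seed in range(3):
            dataset, truth, coupling = generate_dataset(spec, np.random.default_rng(100 + seed))
            scorer = SyntheticCouplingScorer(coupling)
            template = encode_dataset(dataset)
            means = []
            for frac in (0.0, 0.5, 1.0):
                perms = pairing_with_fraction(dataset, truth, frac, np.random.default_rng(seed))
                paired = apply_perms(template, perms)
                mask_rng = np.random.default_rng(7)
                losses = [
                    float(mlm_loss(scorer, paired, sample_mask(paired, 0.7, "B", mask_rng)).data)
                    for _ in range(30)
                ]
                means.append(np.mean(losses))
            assert means[0] > means[1] > means[2]

    def test_species_relabeling_invariance(self, problem):
        dataset, truth, coupling = problem
        scorer = SyntheticCouplingScorer(coupling)
        perms = planted_perms(dataset, truth)
        paired = apply_perms(encode_dataset(dataset), perms)
        mask = sample_mask(paired, 0.7, "B", np.random.default_rng(3))
        base = float(mlm_loss(scorer, paired, mask).data)
        relabeled = [
            BlockRows(
                species=f"renamed_{i}",
                mixed_a=b.mixed_a,
                b_tokens=b.b_tokens,
                a_is_pad=b.a_is_pad,
                b_is_pad=b.b_is_pad,
            )
            for i, b in enumerate(paired.blocks)
        ]
        paired2 = PairedBlocks(
            blocks=relabeled, len_a=paired.len_a, len_b=paired.len_b
        )
        assert float(mlm_loss(scorer, paired2, mask).data) == base

    def test_uniform_soft_permutation_sits_between_extremes(self, problem):
        dataset, truth, coupling = problem
        scorer = SyntheticCouplingScorer(coupling)
        template = encode_dataset(dataset)
        coev_cols = [cb for _, cb in coupling.column_pairs]
        planted = planted_perms(dataset, truth)
        n = planted[0].shape[0]
        uniform = [np.full((b.shape[0],) * 2, 1.0 / b.shape[0]) for b in planted]
        worst = pairing_with_fraction(dataset, truth, 0.0, np.random.default_rng(2))

        def loss_of(perms):
            paired = apply_perms(template, perms)
            return float(mlm_loss(scorer, paired, _mask_at_columns(paired, "B", coev_cols)).data)

        assert loss_of(planted) < loss_of(uniform) < loss_of(worst)

    def test_gradient_wrt_soft_permutation_matches_finite_differences(self, problem):
        dataset, truth, coupling = problem
        scorer = SyntheticCouplingScorer(coupling)
        template = encode_dataset(dataset)
        rng = np.random.default_rng(9)
        n = template.blocks[0].b_tokens.shape[0]
        Ps = [rng.dirichlet(np.ones(b.b_tokens.shape[0]), size=b.b_tokens.shape[0]) for b in template.blocks]

        def loss_of(mats, want_grad=False):
            pvars = [Var(m) for m in mats]
            paired = apply_perms(template, pvars)
            mask_rng = np.random.default_rng(13)
            mask = sample_mask(paired, 0.6, "B", mask_rng)
            lv = mlm_loss(scorer, paired, mask)
            if want_grad:
                backward(lv)
                return lv, pvars
            return float(lv.data)

        lv, pvars = loss_of(Ps, want_grad=True)
        h = 1e-6
        num = np.zeros_like(Ps[0])
        for i in range(n):
            for j in range(n):
                Pp = [m.copy() for m in Ps]
                Pm = [m.copy() for m in Ps]
                Pp[0][i, j] += h
                Pm[0][i, j] -= h
                num[i, j] = (loss_of(Pp) - loss_of(Pm)) / (2 * h)
        assert np.abs(pvars[0].grad - num).max() < 1e-6

    def test_empty_mask_is_an_error(self, problem):
        dataset, truth, coupling = problem
        scorer = SyntheticCouplingScorer(coupling)
        paired = apply_perms(encode_dataset(dataset), planted_perms(dataset, truth))
        empty = _mask_at_columns(paired, "B", [])
        with pytest.raises(ValueError):
            mlm_loss(scorer, paired, empty)

    def test_sum_reduction_scales_by_count(self, problem):
        dataset, truth, coupling = problem
        scorer = SyntheticCouplingScorer(coupling)
        paired = apply_perms(encode_dataset(dataset), planted_perms(dataset, truth))
        mask = sample_mask(paired, 0.5, "B", np.random.default_rng(17))
        mean = float(mlm_loss(scorer, paired, mask).data)
        total = float(mlm_loss(scorer, paired, mask, reduction="sum").data)
        assert np.isclose(total, mean * mask.n_masked)


class TestCouplingModel:
    def test_rejects_non_stochastic_tables(self):
        with pytest.raises(ValueError):
            CouplingModel(
                column_pairs=[(0, 0)],
                tables=np.ones((1, 20, 20)),
                background=np.full(20, 0.05),
            )

    def test_json_roundtrip(self, tmp_path):
        spec = SyntheticSpec(n_species=2, min_size=2, max_size=2, len_a=10, len_b=8, n_coevolving=3)
        _, _, coupling = generate_dataset(spec, np.random.default_rng(1))
        path = tmp_path / "model.json"
        coupling.to_json(path)
        back = CouplingModel.from_json(path)
        assert back.column_pairs == coupling.column_pairs
        assert np.allclose(back.tables, coupling.tables)
        assert np.allclose(back.background, coupling.background)


class TestBackendRegistry:
    def test_missing_weights_raise_unavailable(self):
        with pytest.raises(UnavailableBackendError):
            language_model_adapter(None)
        with pytest.raises(UnavailableBackendError):
            get_scorer("external-lm")

    def test_synthetic_requires_model(self):
        with pytest.raises(ValueError):
            get_scorer("synthetic")

    def test_unknown_backend(self):
        with pytest.raises(ValueError):
            get_scorer("quantum")
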