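"""L1 magnitude pruning: oracle equivalence, masks, reports."""
import numpy as np
import pytest

from hprnet import (ModelConfig, PruneConfig, build_model, count_parameters,
                    nonzero_count, prune_l1, select_prunable, sparsity_report)
from hprnet.prune import _l1_mask
import hprnet.nn as hnn


def _brute_force_mask(w, ratio):
    """Independent oracle: stable sort of |w| by (magnitude, flat index)."""
    n_prune = round(ratio * w.size)
    flat = np.abs(w.ravel())
    order = sorted(range(flat.size), key=lambda i: (flat[i], i))
    mask = np.ones(flat.size, dtype=bool)
    mask[order[:n_prune]] = False
    return mask.reshape(w.shape)


class TestMask:
    def test_worked_example(self):
        w = np.array([0.5, -0.1, 0.3, -0.4])
        mask = _l1_mask(w, 0.5)
        np.testing.assert_array_equal(w * mask, [0.5, 0.0, 0.0, -0.4])

    @pytest.mark.parametrize("ratio", [0.0, 0.1, 0.5, 0.9, 0.99])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_tensors(self, ratio, seed):
        rng = np.random.default_rng(seed)
        w = rng.normal(size=(13, 7)).astype(np.float32)
        np.testing.assert_array_equal(_l1_mask(w, ratio),
                                      _brute_force_mask(w, ratio))

    def test_stable_tie_break_prunes_lower_flat_index_first(self):
        w = np.array([0.2, 0.2, 0.2, 0.2, 1.0, 0.2])
        mask = _l1_mask(w, 0.5)  # prune 3 of 6; all candidates tie at 0.2
        np.testing.assert_array_equal(mask,
                                      [False, False, False, True, True, True])

    def test_removed_amount_is_round_of_ratio_times_numel(self):
        w = np.random.default_rng(3).normal(size=1000)
        for r in (0.1, 0.25, 0.9):
            assert (~_l1_mask(w, r)).sum() == round(r * 1000)


class TestScopes:
    def test_none_scope_selects_nothing(self, small_model):
        assert select_prunable(small_model, "none") == []

    def test_batchnorm_and_bias_never_selected(self, small_model):
        names = [n for n, _, _ in select_prunable(small_model, "mlpo")]
        assert names, "mlpo scope must be non-empty"
        assert not any(("bn" in n) or n.endswith("gamma") or n.endswith("beta")
                       or n.endswith("bias") for n in names)

    def test_network_scope_is_front_conv_plus_fc(self, small_model):
        names = [n for n, _, _ in select_prunable(small_model,
                                                  "network_level")]
        assert names == ["front.conv1.weight", "head.fc.weight"]

    def test_unknown_scope_rejected(self, small_model):
        with pytest.raises(ValueError, match="scope"):
            select_prunable(small_model, "channel")


class TestPruneModel:
    def test_ratio_zero_changes_nothing(self, small_cfg):
        model = build_model(small_cfg, seed=1)
        before = {n: m.params[k].copy() for n, m, k in model.named_params()}
        prune_l1(model, PruneConfig(ratio=0.0, scope="mlpo"))
        for n, m, k in model.named_params():
            np.testing.assert_array_equal(m.params[k], before[n])
        assert all(mask.all() for mask in model.masks.values())

    def test_nonzero_count_matches_closed_form(self, small_cfg):
        for r in (0.1, 0.5, 0.9):
            for scope in ("network_level", "block_level", "mlpo"):
                model = build_model(small_cfg, seed=2)
                prune_l1(model, PruneConfig(ratio=r, scope=scope))
                assert nonzero_count(model) == count_parameters(
                    small_cfg, PruneConfig(ratio=r, scope=scope))

    def test_monotone_in_ratio_and_idempotent(self, small_cfg):
        counts = []
        for r in (0.1, 0.3, 0.5, 0.7, 0.9):
            model = build_model(small_cfg, seed=3)
            prune_l1(model, PruneConfig(ratio=r, scope="mlpo"))
            counts.append(nonzero_count(model))
        assert counts == sorted(counts, reverse=True)
        model = build_model(small_cfg, seed=3)
        prune_l1(model, PruneConfig(ratio=0.5, scope="mlpo"))
        once = nonzero_count(model)
        prune_l1(model, PruneConfig(ratio=0.5, scope="mlpo"))
        assert nonzero_count(model) == once

    def test_masked_positions_survive_weight_updates(self, small_cfg):
        model = build_model(small_cfg, seed=4)
        prune_l1(model, PruneConfig(ratio=0.5, scope="mlpo"))
        # simulate optimizer drift, then re-apply masks
        for _, m, k in model.named_params():
            m.params[k] += 0.1
        model.apply_masks()
        for name, m, k in model.named_params():
            if name in model.masks:
                assert np.all(m.params[k][~model.masks[name]] == 0)


class TestSparsityReport:
    def test_unpruned_report_is_all_zero_fraction(self, small_cfg):
        a = build_model(small_cfg, seed=5)
        b = build_model(small_cfg, seed=5)
        rep = sparsity_report(a, b)
        assert all(f == 0 for _, _, _, f in rep.per_tensor)
        assert rep.nonzero == rep.total

    def test_pruned_tensor_reports_exact_zero_count(self):
        cfg = ModelConfig(
            front_channels=2, layer_channels=((2, 4),), layer_strides=(1,),
            reb_counts=(1,), kernel=5, padding=2, num_classes=2)
        before = build_model(cfg, seed=6)
        after = build_model(cfg, seed=6)
        prune_l1(after, PruneConfig(ratio=0.9, scope="block_level"))
        rep = sparsity_report(before, after)
        by_name = {n: (t, nz) for n, t, nz, _ in rep.per_tensor}
        t, nz = by_name["layers.0.blocks.0.conv1.weight"]
        assert t - nz == round(0.9 * t)

    def test_no_survivor_below_its_tensor_threshold(self, small_cfg):
        before = build_model(small_cfg, seed=7)
        after = build_model(small_cfg, seed=7)
        prune_l1(after, PruneConfig(ratio=0.5, scope="mlpo"))
        by_name = {n: m.params[k] for n, m, k in before.named_params()}
        for name, m, k in after.named_params():
            if name not in after.masks:
                continue
            w0 = by_name[name]
            # recompute the threshold independently by sorting
            n_prune = round(0.5 * w0.size)
            thr = np.sort(np.abs(w0.ravel()))[n_prune - 1]
            survivors = np.abs(m.params[k][after.masks[name]])
            assert np.all(survivors >= thr)

    def test_architecture_mismatch_rejected(self, small_cfg):
        a = build_model(small_cfg, seed=8)
        b = build_model(ModelConfig(
            front_channels=2, layer_channels=((2, 4),), layer_strides=(1,),
            reb_counts=(1,), kernel=5, padding=2, num_classes=2), seed=8)
        with pytest.raises(ValueError, match="architecture"):
            sparsity_report(a, b)
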