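"""Pruning contracts: norm importance, prune counts, survivor-set plans,
weight transfer, and the residual index-sharing constraint."""

import numpy as np
import pytest

from cacpnet.archspec import ArchSpec, peanut_spec
from cacpnet.backbone import build_model
from cacpnet.complexity import profile
from cacpnet.pruning import (
    DEFAULT_RATIOS,
    PruningPlan,
    RatioSchedule,
    apply_plan,
    channel_importance,
    make_pruning_plan,
    prune_count,
    residual_prune_count,
)


class TestChannelImportance:
    def test_single_channel_l1_l2(self):
        w = np.array([1.0, -2.0]).reshape(1, 2, 1, 1)
        assert channel_importance(w, "l1").scores[0] == pytest.approx(3.0)
        assert channel_importance(w, "l2").scores[0] == pytest.approx(np.sqrt(5.0))

    def test_all_zero_weights(self):
        assert (channel_importance(np.zeros((3, 2, 3, 3))).scores == 0).all()

    @pytest.mark.parametrize("norm_kind", ["l1", "l2"])
    def test_ranking_matches_bruteforce_oracle(self, norm_kind, rng):
        w = rng.normal(size=(4, 3, 3, 3))
        got = channel_importance(w, norm_kind).ranking()
        brute = []
        for c in range(4):
            acc = 0.0
            for i in range(3):
                for h in range(3):
                    for j in range(3):
                        acc += abs(w[c, i, h, j]) if norm_kind == "l1" else w[c, i, h, j] ** 2
            brute.append(acc if norm_kind == "l1" else np.sqrt(acc))
        np.testing.assert_array_equal(got, np.argsort(-np.array(brute), kind="stable"))

    def test_wrong_rank_is_an_error(self):
        with pytest.raises(ValueError, match="4-D"):
            channel_importance(np.zeros((3, 3)))


class TestPruneCounts:
    @pytest.mark.parametrize("ratio, n, expected", [(0.3, 512, 153), (0.0, 77, 0), (0.1, 128, 12)])
    def test_tabulated_cases(self, ratio, n, expected):
        assert prune_count(ratio, n) == expected

    def test_at_least_one_channel_survives(self):
        assert prune_count(0.999, 4) == 3

    def test_ratio_domain(self):
        with pytest.raises(ValueError):
            prune_count(1.0, 8)
        with pytest.raises(ValueError):
            prune_count(-0.1, 8)

    def test_monotone_in_ratio_and_width(self):
        grid = np.linspace(0, 0.95, 16)
        for n in (1, 7, 64, 512):
            counts = [prune_count(r, n) for r in grid]
            assert counts == sorted(counts)
            assert all(c <= n - 1 for c in counts)
        for r in (0.1, 0.5, 0.9):
            by_width = [prune_count(r, n) for n in range(1, 80)]
            assert by_width == sorted(by_width)

    @pytest.mark.parametrize("o_r, o_conv2, expected", [(512, 359, 153), (64, 64, 0), (256, 205, 51)])
    def test_residual_prune_count(self, o_r, o_conv2, expected):
        assert residual_prune_count(o_r, o_conv2) == expected

    def test_residual_consistency_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            residual_prune_count(100, 128)


class TestMakePlan:
    def test_zero_schedule_is_identity(self, tiny_net, tiny_spec):
        plan = make_pruning_plan(tiny_net, [0.0] * 4)
        assert plan.spec.stage_widths == tiny_spec.stage_widths
        for s, keep in enumerate(plan.stage_keep):
            assert keep == list(range(tiny_spec.stage_widths[s]))

    def test_default_schedule_yields_printed_widths(self):
        net = build_model(peanut_spec(attention=True), seed=0)
        plan = make_pruning_plan(net, DEFAULT_RATIOS)
        assert plan.spec.stage_widths == [64, 116, 205, 359]
        assert plan.spec.inner_widths == [[64, 64], [116, 116], [205, 205], [359, 359]]
        # stage width minus conv2 width is exactly the shortcut removal count
        for before, after in zip([64, 128, 256, 512], plan.spec.stage_widths):
            assert residual_prune_count(before, after) == before - after

    def test_schedule_length_mismatch(self, tiny_net):
        with pytest.raises(ValueError, match="basic blocks"):
            make_pruning_plan(tiny_net, [0.0] * 7)

    def test_survivors_match_bruteforce_on_small_network(self):
        """On a <=8-channel two-block toy, the shared stage survivor set is
        the top-(n-P) of the summed per-conv importances."""
        spec = ArchSpec(num_classes=2, stem_channels=4, stage_widths=[4, 8, 8, 8],
                        blocks_per_stage=[1, 1, 1, 1], input_size=32)
        net = build_model(spec, seed=3)
        ratios = [0.0, 0.25, 0.5, 0.5]
        plan = make_pruning_plan(net, ratios, norm_kind="l1")
        # stage 2 (index 1): importance = conv2 + projection rows
        blk = net.stages[1][0]
        scores = np.abs(blk.conv2.weight.data.reshape(8, -1)).sum(1) + np.abs(
            blk.downsample_conv.weight.data.reshape(8, -1)
        ).sum(1)
        expected = sorted(np.argsort(-scores, kind="stable")[: 8 - 2])
        assert plan.stage_keep[1] == [int(i) for i in expected]
        # conv1 inner set comes from conv1's own importance
        inner_scores = np.abs(blk.conv1.weight.data.reshape(8, -1)).sum(1)
        expected_inner = sorted(np.argsort(-inner_scores, kind="stable")[: 8 - 2])
        assert plan.inner_keep[1][0] == [int(i) for i in expected_inner]

    def test_plan_round_trips_through_json(self, tiny_net):
        plan = make_pruning_plan(tiny_net, [0.0, 0.2, 0.2, 0.4])
        restored = PruningPlan.from_json(plan.to_json())
        assert restored.stage_keep == plan.stage_keep
        assert restored.inner_keep == plan.inner_keep
        assert restored.spec == plan.spec
        assert restored.schedule.ratios == plan.schedule.ratios


class TestApplyPlan:
    def test_identity_plan_preserves_outputs_exactly(self, tiny_net, rng):
        x = rng.normal(size=(2, 3, 32, 32)).astype(np.float32)
        tiny_net.eval()
        before = tiny_net(x).data
        plan = make_pruning_plan(tiny_net, [0.0] * 4)
        pruned = apply_plan(tiny_net, plan, seed=1)
        pruned.eval()
        np.testing.assert_array_equal(pruned(x).data, before)

    def test_zeroed_channel_oracle(self, rng):
        """Zero the channels slated for removal everywhere they appear
        (conv rows, BN affine+stats, downstream conv columns, head columns);
        pruning those channels must then leave the function unchanged."""
        spec = ArchSpec(num_classes=3, stem_channels=8, stage_widths=[8, 8, 8, 8],
                        blocks_per_stage=[1, 1, 1, 1], stage_strides=[1, 2, 2, 2],
                        input_size=32)
        net = build_model(spec, seed=5)
        net.eval()
        # warm the BN buffers with a forward in train mode
        warm = rng.normal(size=(8, 3, 32, 32)).astype(np.float32)
        net.train()
        net(warm)
        net.eval()

        plan = make_pruning_plan(net, [0.0, 0.0, 0.25, 0.5])
        # zero everything the plan would remove
        for s, keep in enumerate(plan.stage_keep):
            drop = sorted(set(range(spec.stage_widths[s])) - set(keep))
            if not drop:
                continue
            for b, block in enumerate(net.stages[s]):
                block.conv2.weight.data[drop] = 0.0
                block.bn2.weight.data[drop] = 0.0
                block.bn2.bias.data[drop] = 0.0
                block.bn2.running_mean[drop] = 0.0
                if block.has_projection:
                    block.downsample_conv.weight.data[drop] = 0.0
                    block.downsample_bn.weight.data[drop] = 0.0
                    block.downsample_bn.bias.data[drop] = 0.0
                    block.downsample_bn.running_mean[drop] = 0.0
            # downstream consumers of this stage's output
            if s + 1 < 4:
                nxt = net.stages[s + 1][0]
                nxt.conv1.weight.data[:, drop] = 0.0
                if nxt.has_projection:
                    nxt.downsample_conv.weight.data[:, drop] = 0.0
            else:
                net.head.weight.data[:, drop] = 0.0
        for s in range(4):
            for b, block in enumerate(net.stages[s]):
                drop_in = sorted(set(range(block.conv1.out_channels)) - set(plan.inner_keep[s][b]))
                if not drop_in:
                    continue
                block.conv1.weight.data[drop_in] = 0.0
                block.bn1.weight.data[drop_in] = 0.0
                block.bn1.bias.data[drop_in] = 0.0
                block.bn1.running_mean[drop_in] = 0.0
                block.conv2.weight.data[:, drop_in] = 0.0

        # the plan must still select exactly the surviving channels
        plan2 = make_pruning_plan(net, [0.0, 0.0, 0.25, 0.5])
        assert plan2.stage_keep == plan.stage_keep
        pruned = apply_plan(net, plan2, seed=1)
        pruned.eval()
        x = rng.normal(size=(4, 3, 32, 32)).astype(np.float32)
        np.testing.assert_allclose(pruned(x).data, net(x).data, rtol=1e-5, atol=1e-5)

    def test_pruned_parameter_count_matches_spec_closed_form(self, tiny_net):
        plan = make_pruning_plan(tiny_net, [0.0, 0.3, 0.3, 0.5])
        pruned = apply_plan(tiny_net, plan, seed=1)
        assert pruned.num_parameters() == profile(plan.spec).params

    def test_flops_and_params_shrink_strictly_when_pruning(self, tiny_net):
        before = profile(tiny_net.spec)
        plan = make_pruning_plan(tiny_net, [0.0, 0.0, 0.0, 0.25])
        after = profile(plan.spec)
        assert after.flops < before.flops
        assert after.params < before.params

    def test_prune_then_zero_schedule_is_idempotent(self, tiny_net):
        plan = make_pruning_plan(tiny_net, [0.0, 0.2, 0.2, 0.4])
        pruned = apply_plan(tiny_net, plan, seed=1)
        plan2 = make_pruning_plan(pruned, [0.0] * 4)
        assert plan2.spec == pruned.spec
        repruned = apply_plan(pruned, plan2, seed=2)
        x = np.random.default_rng(0).normal(size=(2, 3, 32, 32)).astype(np.float32)
        pruned.eval(), repruned.eval()
        np.testing.assert_array_equal(repruned(x).data, pruned(x).data)

    def test_plan_for_wrong_network_is_rejected(self, tiny_net, tiny_spec):
        other = build_model(tiny_spec.with_updates(num_classes=7), seed=0)
        plan = make_pruning_plan(other, [0.0] * 4)
        with pytest.raises(ValueError, match="different architecture"):
            apply_plan(tiny_net, plan)
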