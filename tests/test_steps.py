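"""Step-model fitting, selection and pattern labelling.

The brute-force oracle here re-enumerates every breakpoint set with plain
itertools/numpy arithmetic, independently of the implementation's fitting
code, and is reused for the selection-equivalence checks.
"""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stepcourse import (
    PipelineConfig,
    ValidationError,
    classify_pattern,
    enumerate_fits,
    profile_genes,
    select_model,
)
from stepcourse.steps import LABEL_DOWN, LABEL_DOWN_UP, LABEL_FLAT, LABEL_UP, LABEL_UP_DOWN


def brute_force_best(values_per_stage, criterion="bic", min_delta=1.0, f_alpha=0.01):
    """Independent re-derivation of the selected (k, breakpoints, levels)."""
    from scipy import stats as sps

    S = len(values_per_stage)
    n = sum(len(v) for v in values_per_stage)
    cands = {}
    for k in range(min(2, S - 1) + 1):
        for bps in combinations(range(1, S), k):
            edges = (0, *bps, S)
            levels, sse = [], 0.0
            for lo, hi in zip(edges[:-1], edges[1:]):
                pts = np.concatenate([np.asarray(values_per_stage[i], float)
                                      for i in range(lo, hi)])
                levels.append(pts.mean())
                sse += float(((pts - pts.mean()) ** 2).sum())
            cands[(k, bps)] = (tuple(levels), sse)

    def bic(sse, k):
        return n * np.log(max(sse, 1e-300) / n) + (k + 2) * np.log(n)

    best_by_k = {}
    for (k, bps), (levels, sse) in sorted(cands.items()):
        if k not in best_by_k or sse < best_by_k[k][2] - 1e-12:
            best_by_k[k] = (bps, levels, sse)

    if criterion == "bic":
        chosen = min(
            sorted(cands.items()),
            key=lambda kv: (bic(kv[1][1], kv[0][0]), kv[0][0], kv[0][1]),
        )
        k, bps = chosen[0]
    else:
        k = 0
        for knext in sorted(best_by_k):
            if knext == 0:
                continue
            sse_small = best_by_k[k][2]
            sse_large = best_by_k[knext][2]
            df1, df2 = knext - k, n - (knext + 1)
            if sse_large <= 1e-12:
                sig = sse_small > 1e-12
            else:
                f = ((sse_small - sse_large) / df1) / (sse_large / df2)
                sig = sps.f.sf(f, df1, df2) < f_alpha
            if not sig:
                break
            k = knext
        bps = best_by_k[k][0]

    levels, sse = cands[(k, bps)]
    while k > 0 and any(
        abs(levels[i + 1] - levels[i]) < min_delta for i in range(len(levels) - 1)
    ):
        k -= 1
        bps, levels, sse = best_by_k[k]
    return k, tuple(bps), levels


def reps(*stage_means, r=3, noise=0.0, rng=None):
    out = []
    for m in stage_means:
        if noise and rng is not None:
            out.append(m + rng.normal(0, noise, r))
        else:
            out.append(np.full(r, float(m)))
    return out


class TestEnumeration:
    def test_four_stages_give_seven_candidates(self):
        models = enumerate_fits(reps(1, 2, 3, 4))
        assert len(models) == 7
        assert sorted(m.k for m in models) == [0, 1, 1, 1, 2, 2, 2]

    def test_constant_input_all_levels_equal_sse_zero(self):
        models = enumerate_fits(reps(5, 5, 5, 5))
        for m in models:
            assert np.allclose(m.levels, 5.0)
            assert m.sse == 0.0

    def test_sse_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(0)
        vals = [rng.normal(size=3) for _ in range(4)]
        for m in enumerate_fits(vals):
            edges = (0, *m.breakpoints, 4)
            sse = 0.0
            for seg, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
                pts = np.concatenate(vals[lo:hi])
                assert np.isclose(m.levels[seg], pts.mean())
                sse += ((pts - pts.mean()) ** 2).sum()
            assert np.isclose(m.sse, sse)

    def test_sse_is_monotone_in_k(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vals = [rng.normal(size=3) for _ in range(4)]
            best = {}
            for m in enumerate_fits(vals):
                best[m.k] = min(best.get(m.k, np.inf), m.sse)
            assert best[2] <= best[1] + 1e-12 <= best[0] + 2e-12

    def test_single_stage_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_fits([np.ones(3)])


class TestSelection:
    def test_noiseless_one_step(self):
        fit = select_model(enumerate_fits(reps(2, 2, 8, 8)))
        assert (fit.k, fit.breakpoints) == (1, (2,))
        assert np.allclose(fit.levels, (2, 8))

    def test_noiseless_impulse(self):
        fit = select_model(enumerate_fits(reps(2, 8, 2, 2)))
        assert (fit.k, fit.breakpoints) == (2, (1, 2))
        assert np.allclose(fit.levels, (2, 8, 2))

    def test_small_step_demoted_to_flat(self):
        fit = select_model(enumerate_fits(reps(5, 5, 5, 5.3)), step_min_delta=1.0)
        assert fit.k == 0

    def test_constant_input_ties_resolve_to_flat(self):
        for criterion in ("bic", "ftest"):
            fit = select_model(enumerate_fits(reps(5, 5, 5, 5)), criterion=criterion)
            assert fit.k == 0

    @pytest.mark.parametrize("criterion", ["bic", "ftest"])
    def test_matches_independent_brute_force(self, criterion):
        rng = np.random.default_rng(2)
        for _ in range(100):
            vals = [rng.normal(rng.uniform(0, 8), 0.5, size=3) for _ in range(4)]
            fit = select_model(enumerate_fits(vals), criterion=criterion)
            k, bps, levels = brute_force_best(vals, criterion=criterion)
            assert (fit.k, fit.breakpoints) == (k, bps)
            assert np.allclose(fit.levels, levels)

    def test_five_stage_selection_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            vals = [rng.normal(rng.uniform(0, 8), 0.5, size=2) for _ in range(5)]
            fit = select_model(enumerate_fits(vals))
            k, bps, _ = brute_force_best(vals)
            assert (fit.k, fit.breakpoints) == (k, bps)


class TestPatternLabels:
    STAGES = ("MBC", "prePB", "PB", "PC")

    def test_one_step_up_at_prepb(self):
        fit = select_model(enumerate_fits(reps(2, 8, 8, 8)))
        pat = classify_pattern(fit, self.STAGES)
        assert (pat.label, pat.transition_stage) == (LABEL_UP, "prePB")

    def test_impulse_up_down_at_prepb(self):
        fit = select_model(enumerate_fits(reps(2, 8, 2, 2)))
        pat = classify_pattern(fit, self.STAGES)
        assert (pat.label, pat.transition_stage) == (LABEL_UP_DOWN, "prePB")

    def test_same_sign_two_step_collapses_to_major_transition(self):
        from stepcourse import StepModel

        fit = StepModel(k=2, breakpoints=(1, 2), levels=(2.0, 4.0, 8.0),
                        sse=0.0, n_points=12)
        pat = classify_pattern(fit, self.STAGES)
        assert pat.label == LABEL_UP
        assert pat.transition_stage == "PB"  # larger delta (4) at breakpoint 2
        tie = StepModel(k=2, breakpoints=(1, 3), levels=(2.0, 4.0, 6.0),
                        sse=0.0, n_points=12)
        pat = classify_pattern(tie, self.STAGES)
        assert (pat.label, pat.transition_stage) == (LABEL_UP, "prePB")  # earlier bp

    def test_flat_has_no_transition_stage(self):
        fit = select_model(enumerate_fits(reps(5, 5, 5, 5)))
        pat = classify_pattern(fit, self.STAGES)
        assert (pat.label, pat.transition_stage) == (LABEL_FLAT, None)

    @given(
        means=st.lists(st.floats(-8, 8), min_size=4, max_size=4),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_negation_swaps_up_and_down_labels(self, means, seed):
        rng = np.random.default_rng(seed)
        vals = [m + rng.normal(0, 0.4, 3) for m in means]
        neg = [-v for v in vals]
        f1 = select_model(enumerate_fits(vals))
        f2 = select_model(enumerate_fits(neg))
        p1 = classify_pattern(f1, self.STAGES)
        p2 = classify_pattern(f2, self.STAGES)
        swap = {LABEL_UP: LABEL_DOWN, LABEL_DOWN: LABEL_UP,
                LABEL_UP_DOWN: LABEL_DOWN_UP, LABEL_DOWN_UP: LABEL_UP_DOWN,
                LABEL_FLAT: LABEL_FLAT}
        assert f1.breakpoints == f2.breakpoints
        assert p2.label == swap[p1.label]

    @given(
        means=st.lists(st.floats(-8, 8), min_size=4, max_size=4),
        shift=st.floats(-20, 20),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_constant_shift_changes_nothing_but_levels(self, means, shift, seed):
        rng = np.random.default_rng(seed)
        vals = [m + rng.normal(0, 0.4, 3) for m in means]
        shifted = [v + shift for v in vals]
        f1 = select_model(enumerate_fits(vals))
        f2 = select_model(enumerate_fits(shifted))
        assert f1.breakpoints == f2.breakpoints
        assert np.allclose(f1.deltas, f2.deltas, atol=1e-7)
        assert classify_pattern(f1, self.STAGES).label == classify_pattern(f2, self.STAGES).label


class TestProfileGenes:
    def test_single_gene_table_matches_direct_fit(self, four_stage_design):
        import pandas as pd

        from stepcourse.normalization import StageProfile

        vals = np.array([[2, 2, 2, 2, 2, 2, 8, 8, 8, 8, 8, 8]], dtype=float)
        log_expr = pd.DataFrame(vals, index=["g0"], columns=four_stage_design.sample_ids)
        prof = StageProfile(
            stage_means=pd.DataFrame(
                2.0 ** vals.reshape(1, 4, 3).mean(axis=2),
                index=["g0"], columns=list(four_stage_design.stages),
            ),
            log_expr=log_expr,
            design=four_stage_design,
        )
        table = profile_genes(prof)
        row = table.iloc[0]
        assert row["k"] == 1 and row["breakpoints"] == "2"
        assert row["label"] == LABEL_UP and row["transition_stage"] == "PB"

    def test_empty_subset_gives_empty_table(self, four_stage_design):
        import pandas as pd

        from stepcourse.normalization import StageProfile

        log_expr = pd.DataFrame(
            np.ones((2, 12)), index=["a", "b"], columns=four_stage_design.sample_ids
        )
        prof = StageProfile(
            stage_means=pd.DataFrame(
                1.0, index=["a", "b"], columns=list(four_stage_design.stages)
            ),
            log_expr=log_expr,
            design=four_stage_design,
        )
        table = profile_genes(prof, gene_subset=[])
        assert table.empty
        assert list(table.columns)[:3] == ["gene", "k", "breakpoints"]
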