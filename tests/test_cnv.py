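import numpy as np
import pandas as pd
import pytest

import dendropy

from sctme.cnv import (
    ArmEvent,
    CNVProfile,
    Subclone,
    build_clonal_tree,
    call_malignant,
    cnv_score,
    collapse_subclones,
    estimate_cnv_residuals,
    map_events_to_arms,
    serialize_newick,
)
from sctme.core_io import CytobandTable, ValidationError
from sctme.synthetic import (
    CNVSimulationConfig,
    SubcloneSpec,
    generate_cnv_profiles,
    make_toy_genome,
)


def toy_profile(residuals, windows=None, ref=0):
    residuals = np.asarray(residuals, float)
    n_cells, n_w = residuals.shape
    windows = windows or [("chr1", i * 10, (i + 1) * 10) for i in range(n_w)]
    cell_ids = [f"c{i}" for i in range(n_cells)]
    return CNVProfile(
        residuals=residuals,
        windows=windows,
        cell_ids=cell_ids,
        reference_cell_ids=cell_ids[:ref],
    )


class TestScore:
    def test_zero_row(self):
        s = cnv_score(toy_profile([[0, 0, 0]]))
        assert s.iloc[0] == 0.0

    def test_hand_sum_of_squares(self):
        s = cnv_score(toy_profile([[0.5, -0.5, 1.0]]))
        assert s.iloc[0] == pytest.approx(1.5)

    def test_homogeneity_degree_two(self, rng):
        row = rng.normal(size=8)
        s1 = cnv_score(toy_profile([row])).iloc[0]
        s2 = cnv_score(toy_profile([2 * row])).iloc[0]
        assert s2 == pytest.approx(4 * s1)

    def test_window_permutation_invariance(self, rng):
        row = rng.normal(size=6)
        perm = rng.permutation(6)
        assert cnv_score(toy_profile([row])).iloc[0] == pytest.approx(
            cnv_score(toy_profile([row[perm]])).iloc[0]
        )


class TestMalignant:
    def test_threshold_formula(self):
        scores = pd.Series(
            [2.0, 1.5, 2.5, 3.5, 2.9],
            index=["r1", "r2", "r3", "q_high", "q_low"],
        )
        # reference mean 2.0, sample SD 0.5 -> threshold 3.0
        ref = pd.Series([1.5, 2.0, 2.5], index=["r1", "r2", "r3"])
        assert ref.mean() == 2.0 and ref.std(ddof=1) == 0.5
        calls = call_malignant(scores, ["r1", "r2", "r3"])
        assert bool(calls["q_high"]) is True
        assert bool(calls["q_low"]) is False

    def test_all_identical_none_malignant(self):
        scores = pd.Series([1.0] * 5, index=[f"c{i}" for i in range(5)])
        with pytest.warns(UserWarning, match="zero variance"):
            calls = call_malignant(scores, ["c0", "c1"])
        assert not calls.any()

    def test_simulation_sensitivity_specificity(self):
        windows, cents, _ = make_toy_genome(n_chroms=3, windows_per_arm=25)
        sens, spec = [], []
        for seed in range(5):
            cfg = CNVSimulationConfig(
                windows=windows,
                centromeres=cents,
                subclones=(
                    SubcloneSpec(
                        frozenset({("chr1", "p", "gain"), ("chr1", "q", "gain"),
                                   ("chr2", "p", "loss"), ("chr2", "q", "loss")}),
                        1.0, 1.0,
                    ),
                ),
                n_cells=150,
                noise_sd=0.1,
                n_reference_cells=100,
                seed=seed,
            )
            profile, truth = generate_cnv_profiles(cfg)
            calls = call_malignant(cnv_score(profile), profile.reference_cell_ids)
            is_tumour = (truth["subclone"].str.startswith("subclone")).to_numpy()
            is_ref = (truth["subclone"] == "reference").to_numpy()
            sens.append(calls.to_numpy()[is_tumour].mean())
            spec.append(1 - calls.to_numpy()[is_ref].mean())
        assert np.mean(sens) >= 0.95
        assert np.mean(spec) >= 0.95


class TestResidualEstimate:
    def _positions(self, n, chrom="chr1"):
        return pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(n)],
                "chrom": chrom,
                "start": np.arange(n) * 10,
                "end": np.arange(n) * 10 + 5,
                "col": np.arange(n),
            }
        )

    def test_self_baseline_window_means_near_zero(self, rng):
        X = rng.normal(size=(120, 30))
        pos = self._positions(30)
        cells = [f"c{i}" for i in range(120)]
        prof = estimate_cnv_residuals(X, pos, cells, cells, window_size_genes=10)
        assert np.all(np.abs(prof.residuals.mean(axis=0)) < 0.05)

    def test_window_size_one_identity(self, rng):
        X = rng.normal(size=(20, 5))
        pos = self._positions(5)
        cells = [f"c{i}" for i in range(20)]
        prof = estimate_cnv_residuals(X, pos, cells, cells, window_size_genes=1)
        ref_mean = X.mean(axis=0)
        lim = 3 * X.std(axis=0, ddof=1)
        expected = np.clip(X - ref_mean, -lim, lim)
        expected = expected - np.median(expected, axis=1, keepdims=True)
        np.testing.assert_allclose(prof.residuals, expected, atol=1e-12)

    def test_planted_gain_shows_on_right_arm(self):
        # 40 genes on chr1: second half elevated in the tumour cells
        n_ref, n_tum = 30, 10
        X = np.zeros((n_ref + n_tum, 40))
        rngl = np.random.default_rng(0)
        X += rngl.normal(0, 0.01, X.shape)
        X[n_ref:, 20:] += 1.0
        pos = self._positions(40)
        cells = [f"c{i}" for i in range(n_ref + n_tum)]
        prof = estimate_cnv_residuals(X, pos, cells[:n_ref], cells, window_size_genes=10)
        tum = prof.residuals[n_ref:]
        assert np.all(tum[:, 2:] > 0.3)  # windows covering genes 20-39
        assert np.all(np.abs(tum[:, :2]) < 0.6)


class TestArmEvents:
    def _profile_with_arm_signal(self):
        windows, cents, cyto = make_toy_genome(n_chroms=1, windows_per_arm=5)
        res = np.zeros((2, 10))
        res[0, 5:] = 0.5  # q arm of chr1 gained in cell 0
        return toy_profile(res, windows=list(windows)), cyto

    def test_q_arm_gain_called(self):
        prof, cyto = self._profile_with_arm_signal()
        events = map_events_to_arms(prof, cyto)
        assert events[0] == frozenset({ArmEvent("chr1", "q", "gain")})
        assert events[1] == frozenset()

    def test_all_zero_profile(self):
        windows, _, cyto = make_toy_genome(n_chroms=1, windows_per_arm=3)
        prof = toy_profile(np.zeros((3, 6)), windows=list(windows))
        assert all(e == frozenset() for e in map_events_to_arms(prof, cyto))

    def test_straddling_window_majority_rule(self):
        # centromere at 50; window [20, 70) is 60% p / 40% q
        cyto = CytobandTable(
            pd.DataFrame(
                {
                    "chrom": ["chrS", "chrS"],
                    "start": [0, 50],
                    "end": [50, 100],
                    "band": ["p11", "q11"],
                }
            )
        )
        prof = toy_profile(np.array([[0.6]]), windows=[("chrS", 20, 70)])
        events = map_events_to_arms(prof, cyto)
        assert events[0] == frozenset({ArmEvent("chrS", "p", "gain")})


A = ArmEvent("chr1", "q", "gain")
B = ArmEvent("chr2", "p", "loss")
C = ArmEvent("chr3", "q", "loss")


class TestCollapse:
    def test_enumeration(self):
        subs = collapse_subclones([frozenset({A, B}), frozenset({A, B}), frozenset({A})])
        by_events = {s.events: s for s in subs}
        assert by_events[frozenset({A, B})].fraction == pytest.approx(2 / 3)
        assert by_events[frozenset({A})].fraction == pytest.approx(1 / 3)

    def test_all_identical(self):
        subs = collapse_subclones([frozenset({A})] * 4)
        assert len(subs) == 1 and subs[0].fraction == 1.0

    def test_all_empty_is_diploid_root(self):
        subs = collapse_subclones([frozenset()] * 3)
        assert len(subs) == 1 and subs[0].events == frozenset()

    def test_fractions_sum_to_one(self, rng):
        pool = [frozenset(), frozenset({A}), frozenset({A, B}), frozenset({B})]
        sets = [pool[i] for i in rng.integers(0, 4, size=50)]
        subs = collapse_subclones(sets)
        assert sum(s.fraction for s in subs) == pytest.approx(1.0)


def _sub(events, frac, n=10):
    return Subclone(events=frozenset(events), n_cells=n, fraction=frac)


class TestClonalTree:
    def test_chain(self):
        tree = build_clonal_tree([_sub([], 0.0, 0), _sub([A], 1 / 3), _sub([A, B], 2 / 3)])
        labels = {i: s.label() for i, s in enumerate(tree.nodes)}
        parent_labels = {
            labels[i]: (labels[p] if p is not None else None)
            for i, p in tree.parent.items()
        }
        assert parent_labels["1q+"] == "root"
        assert parent_labels["1q+|2p-"] == "1q+"

    def test_incomparable_attach_to_root(self):
        tree = build_clonal_tree([_sub([A], 0.5), _sub([B], 0.5)])
        root = tree.root_index
        assert set(tree.children(root)) == {0, 1}

    def test_tie_break_by_fraction(self):
        subs = [
            _sub([A], 0.4),
            _sub([A, B], 0.3),
            _sub([A, C], 0.2),
            _sub([A, B, C], 0.1),
        ]
        tree = build_clonal_tree(subs)
        # {A,B} and {A,C} are both maximal proper subsets; {A,B} has larger fraction
        assert tree.parent[3] == 1

    def test_strict_superset_invariant(self, rng):
        pool = [frozenset(), frozenset({A}), frozenset({B}), frozenset({A, B}),
                frozenset({A, C}), frozenset({A, B, C})]
        sets = [pool[i] for i in rng.integers(0, len(pool), size=60)]
        tree = build_clonal_tree(collapse_subclones(sets))
        for child, parent in tree.parent.items():
            if parent is None:
                continue
            assert tree.nodes[parent].events < tree.nodes[child].events


class TestNewick:
    def test_root_only(self):
        tree = build_clonal_tree([_sub([], 1.0)])
        assert serialize_newick(tree) == "root:0;"

    def test_chain_shape(self):
        tree = build_clonal_tree(
            [_sub([], 0.0, 0), _sub([A], 1 / 3), _sub([A, B], 2 / 3)]
        )
        assert serialize_newick(tree) == "((1q+|2p-:0.6667)1q+:0.3333)root:0;"

    def test_round_trip_with_standard_parser(self):
        tree = build_clonal_tree(
            [_sub([], 0.2), _sub([A], 0.3), _sub([A, B], 0.4), _sub([B], 0.1)]
        )
        nwk = serialize_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        got = {
            (n.taxon.label if n.taxon else n.label): n.edge.length
            for n in parsed
            if n.label or n.taxon
        }
        for idx, sub in enumerate(tree.nodes):
            if tree.parent[idx] is None:
                continue
            assert got[sub.label()] == pytest.approx(sub.fraction, abs=1e-4)


class TestGeneratorRecovery:
    def test_noiseless_collapse_recovers_planted_truth(self):
        windows, cents, cyto = make_toy_genome(n_chroms=2, windows_per_arm=5)
        planted = (
            SubcloneSpec(frozenset({("chr1", "q", "gain")}), 0.5, 1.0),
            SubcloneSpec(
                frozenset({("chr1", "q", "gain"), ("chr2", "p", "loss")}), 0.3, 1.0
            ),
        )
        cfg = CNVSimulationConfig(
            windows=windows,
            centromeres=cents,
            subclones=planted,
            n_cells=100,
            noise_sd=0.0,
            n_reference_cells=20,
            seed=0,
        )
        profile, truth = generate_cnv_profiles(cfg)
        tumour = ~profile.reference_mask()
        events = map_events_to_arms(profile, cyto)
        subs = collapse_subclones([e for e, t in zip(events, tumour) if t])
        by_events = {s.events: s.fraction for s in subs}
        assert by_events[frozenset({ArmEvent("chr1", "q", "gain")})] == pytest.approx(0.5)
        assert by_events[
            frozenset({ArmEvent("chr1", "q", "gain"), ArmEvent("chr2", "p", "loss")})
        ] == pytest.approx(0.3)
        assert by_events[frozenset()] == pytest.approx(0.2)

    def test_noiseless_residual_equals_effect(self):
        windows, cents, _ = make_toy_genome(n_chroms=1, windows_per_arm=4)
        cfg = CNVSimulationConfig(
            windows=windows,
            centromeres=cents,
            subclones=(SubcloneSpec(frozenset({("chr1", "q", "gain")}), 1.0, 1.0),),
            n_cells=5,
            noise_sd=0.0,
            n_reference_cells=2,
            seed=0,
        )
        profile, _ = generate_cnv_profiles(cfg)
        assert np.all(profile.residuals[:5, 4:] == 1.0)
        assert np.all(profile.residuals[:5, :4] == 0.0)

    def test_same_seed_identical(self):
        windows, cents, _ = make_toy_genome(1, 3)
        cfg = dict(
            windows=windows, centromeres=cents,
            subclones=(SubcloneSpec(frozenset({("chr1", "p", "loss")}), 0.5, 1.0),),
            n_cells=20, noise_sd=0.2, n_reference_cells=10, seed=42,
        )
        p1, _ = generate_cnv_profiles(CNVSimulationConfig(**cfg))
        p2, _ = generate_cnv_profiles(CNVSimulationConfig(**cfg))
        np.testing.assert_array_equal(p1.residuals, p2.residuals)

    def test_arm_mean_tail_bound(self):
        # effect 1.0, noise 0.1, 50-window gained arm: mean within 0.05 of 1.0
        windows, cents, _ = make_toy_genome(n_chroms=1, windows_per_arm=50)
        cfg = CNVSimulationConfig(
            windows=windows,
            centromeres=cents,
            subclones=(SubcloneSpec(frozenset({("chr1", "q", "gain")}), 1.0, 1.0),),
            n_cells=400,
            noise_sd=0.1,
            n_reference_cells=10,
            seed=1,
        )
        profile, _ = generate_cnv_profiles(cfg)
        arm_mean = profile.residuals[:400, 50:].mean(axis=1)
        assert (np.abs(arm_mean - 1.0) < 0.05).mean() >= 0.99

    def test_fraction_overflow_rejected(self):
        windows, cents, _ = make_toy_genome(1, 2)
        with pytest.raises(ValidationError):
            CNVSimulationConfig(
                windows=windows,
                centromeres=cents,
                subclones=(
                    SubcloneSpec(frozenset({("chr1", "p", "gain")}), 0.7, 1.0),
                    SubcloneSpec(frozenset({("chr1", "q", "gain")}), 0.7, 1.0),
                ),
            ).validate()
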