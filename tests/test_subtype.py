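import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.metrics import adjusted_rand_score

from methorigin.containers import BetaMatrix, ValidationError
from methorigin.diffmeth import DMParams, differential_methylation
from methorigin.simulate import _clamped_logit
from methorigin.subtype import (
    ConsensusParams,
    ConsensusResult,
    TFCheckpointSpec,
    build_signature,
    consensus_cluster,
    pac_score,
    select_k,
    select_tf_probes,
)

from conftest import make_annotation


def _beta(values):
    values = np.asarray(values, float)
    return BetaMatrix(
        pd.DataFrame(
            values,
            index=[f"cg{i:05d}" for i in range(values.shape[0])],
            columns=[f"s{j}" for j in range(values.shape[1])],
        )
    )


def _planted_fixture(seed, n_groups=4, n_per=20, n_feat=500, delta=0.3, noise=0.3):
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.2, 0.6, n_feat)
    cols = {}
    block = n_feat // n_groups
    for g in range(n_groups):
        shift = np.zeros(n_feat)
        shift[g * block : (g + 1) * block] = delta
        mu = np.clip(base + shift, 0.01, 0.99)
        for i in range(n_per):
            cols[f"g{g}_s{i}"] = expit(_clamped_logit(mu) + rng.normal(0, noise, n_feat))
    labels = np.repeat(np.arange(n_groups), n_per)
    return BetaMatrix(pd.DataFrame(cols)), labels


class TestConsensusParams:
    def test_consensusclusterplus_style_defaults(self):
        p = ConsensusParams()
        assert (p.k_max, p.reps, p.p_item, p.p_feature) == (20, 1000, 0.8, 1.0)
        assert p.distance == "pearson"

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValidationError):
            ConsensusParams(p_item=0.0)
        with pytest.raises(ValidationError):
            ConsensusParams(p_feature=1.5)


class TestConsensusCluster:
    def test_duplicated_blocks_give_binary_consensus(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.1, 0.4, 50)
        b = rng.uniform(0.6, 0.9, 50)
        arr = np.column_stack([a] * 5 + [b] * 5)
        arr += rng.normal(0, 1e-4, arr.shape)  # break exact ties only
        beta = _beta(np.clip(arr, 0, 1))
        res = consensus_cluster(beta, None, ConsensusParams(k_max=2, reps=50, seed=1))
        C = res.consensus[2]
        within = C[:5, :5][np.triu_indices(5, 1)]
        between = C[:5, 5:]
        assert np.allclose(within, 1.0)
        assert np.allclose(between, 0.0)

    def test_full_subsampling_gives_binary_entries(self):
        beta, _ = _planted_fixture(1, n_per=6, n_feat=100)
        res = consensus_cluster(
            beta, None, ConsensusParams(k_max=3, reps=20, p_item=1.0, seed=2)
        )
        for C in res.consensus.values():
            assert np.all(np.isin(np.round(C, 12), [0.0, 1.0]))

    def test_planted_clusters_recovered(self):
        beta, labels = _planted_fixture(2)
        res = consensus_cluster(beta, None, ConsensusParams(k_max=6, reps=100, seed=3))
        ari = adjusted_rand_score(labels, res.assignments[4])
        assert ari >= 0.95
        assert select_k(res) == 4

    def test_seed_fixes_consensus_exactly(self):
        beta, _ = _planted_fixture(3, n_per=8, n_feat=100)
        p = ConsensusParams(k_max=4, reps=30, seed=11)
        r1 = consensus_cluster(beta, None, p)
        r2 = consensus_cluster(beta, None, p)
        for k in r1.consensus:
            assert np.array_equal(r1.consensus[k], r2.consensus[k])

    def test_sample_relabelling_permutes_consensus(self):
        beta, _ = _planted_fixture(4, n_per=8, n_feat=100)
        p = ConsensusParams(k_max=3, reps=40, p_item=1.0, seed=5)
        r1 = consensus_cluster(beta, None, p)
        perm = list(np.random.default_rng(6).permutation(beta.values.columns))
        r2 = consensus_cluster(beta.select_samples(perm), None, p)
        idx = [list(beta.values.columns).index(s) for s in perm]
        for k in r1.consensus:
            assert np.allclose(r1.consensus[k][np.ix_(idx, idx)], r2.consensus[k])

    def test_too_few_samples_rejected(self):
        beta = _beta(np.random.default_rng(7).uniform(0, 1, (20, 4)))
        with pytest.raises(ValidationError):
            consensus_cluster(beta, None, ConsensusParams(k_max=2, reps=10))


class TestSelectK:
    @staticmethod
    def _block_consensus(n_blocks, per_block, wobble=0.0, seed=0):
        rng = np.random.default_rng(seed)
        n = n_blocks * per_block
        C = np.zeros((n, n))
        for b in range(n_blocks):
            sl = slice(b * per_block, (b + 1) * per_block)
            C[sl, sl] = 1.0
        if wobble:
            noise = rng.uniform(0, wobble, (n, n))
            C = np.clip(np.abs(C - (noise + noise.T) / 2), 0, 1)
        np.fill_diagonal(C, 1.0)
        return C

    def test_saturated_profile_selects_true_k(self):
        # perfect 4-block consensus for every k >= 4, degraded for k < 4
        consensus = {}
        for k in range(2, 9):
            consensus[k] = self._block_consensus(min(k, 4), 80 // min(k, 4), wobble=0.02, seed=k)
        params = ConsensusParams(k_max=8, reps=10)
        from methorigin.subtype import _stability_profile

        area, delta = _stability_profile(consensus)
        res = ConsensusResult(
            sample_ids=[f"s{i}" for i in range(80)],
            consensus=consensus,
            assignments={k: np.zeros(80, int) for k in consensus},
            area=area,
            delta_area=delta,
            params=params,
        )
        assert select_k(res) == 4
        assert all(delta[k] < 0.025 for k in range(5, 9))

    def test_forced_k_bypasses_selection(self):
        beta, labels = _planted_fixture(5, n_per=10, n_feat=200)
        res = consensus_cluster(beta, None, ConsensusParams(k_max=6, reps=60, seed=8))
        forced = res.assignments[2]
        assert len(np.unique(forced)) == 2


class TestTFProbeSelection:
    def _ann(self):
        states = [
            "open strong enhancer", "genic enhancer", "insulator",
            "active promoter", "open weak enhancer", "quiescent",
            "polycomb repressed", "closed weak enhancer",
        ]
        return make_annotation(
            [f"cg{i}" for i in range(8)],
            chromosomes=["1", "2", "3", "4", "5", "6", "X", "7"],
            states=states,
            genes=["FEV", "FEV", "FEV", "FEV", "MAFA", "IRX2", "IRX2", "GENE1"],
        )

    def test_state_and_gene_filter(self):
        probes = select_tf_probes(self._ann(), TFCheckpointSpec(), "alpha")
        # FEV probes in enhancer/insulator states pass (cg0..cg2); cg3 fails
        # the state gate ("active promoter"), cg5 is quiescent, and the
        # polycomb IRX2 probe cg6 sits on chromosome X so autosomes_only
        # drops it
        assert probes == ["cg0", "cg1", "cg2"]

    def test_beta_gene_list(self):
        probes = select_tf_probes(self._ann(), TFCheckpointSpec(), "beta")
        assert probes == ["cg4"]

    def test_empty_gene_list_gives_empty_output(self):
        spec = TFCheckpointSpec(alpha_genes=(), beta_genes=("MAFA",))
        assert select_tf_probes(self._ann(), spec, "alpha") == []

    def test_state_superset_never_shrinks_output(self):
        ann = self._ann()
        base = TFCheckpointSpec()
        wider = TFCheckpointSpec(
            allowed_states=base.allowed_states + ("active promoter",)
        )
        a = set(select_tf_probes(ann, base, "alpha"))
        b = set(select_tf_probes(ann, wider, "alpha"))
        assert a <= b

    def test_overlapping_gene_lists_rejected(self):
        with pytest.raises(ValidationError):
            TFCheckpointSpec(alpha_genes=("FEV",), beta_genes=("FEV",))


class TestBuildSignature:
    def test_identical_groups_give_empty_signature(self):
        rng = np.random.default_rng(9)
        block = rng.uniform(0.2, 0.8, (100, 2))
        beta = _beta(np.tile(block, (1, 3)))
        labels = ["a", "a", "b", "b", "c", "c"]
        assert build_signature(beta, labels) == []

    def test_disjoint_contrast_union_size(self):
        rng = np.random.default_rng(10)
        n = 1000
        mu = rng.uniform(0.3, 0.5, n)
        groups = {"a": mu.copy(), "b": mu.copy(), "c": mu.copy()}
        # 100 probes high only in a; 100 only in b; 100 only in c:
        # every pairwise contrast finds 200, union of all is 300
        groups["a"][:100] += 0.4
        groups["b"][100:200] += 0.4
        groups["c"][200:300] += 0.4
        cols = {}
        labels = []
        rng2 = np.random.default_rng(11)
        for g, m in groups.items():
            for i in range(3):
                cols[f"{g}{i}"] = np.clip(m + rng2.normal(0, 0.01, n), 0, 1)
                labels.append(g)
        beta = BetaMatrix(pd.DataFrame(cols, index=[f"cg{i:05d}" for i in range(n)]))
        sig = build_signature(beta, labels)
        assert len(sig) == 300

    def test_union_matches_set_oracle(self):
        beta, labels = _planted_fixture(12, n_groups=3, n_per=4, n_feat=300, noise=0.05)
        labels = [f"g{l}" for l in labels]
        sig = build_signature(beta, labels)
        expected = set()
        groups = pd.Series(labels, index=beta.sample_ids)
        for a, b in (("g0", "g1"), ("g0", "g2"), ("g1", "g2")):
            sel_samples = groups.index[groups.isin([a, b])].tolist()
            _, s = differential_methylation(
                beta.select_samples(sel_samples), groups[sel_samples], DMParams()
            )
            expected |= set(s)
        assert sig == sorted(expected)

    def test_small_group_rejected(self):
        beta, _ = _planted_fixture(13, n_groups=2, n_per=3, n_feat=100)
        labels = ["a"] * 5 + ["b"] * 1
        with pytest.raises(ValidationError):
            build_signature(beta, labels)
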