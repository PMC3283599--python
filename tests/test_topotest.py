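"""Likelihood machinery and the topology-confidence tests."""

import itertools

import dendropy
import numpy as np
import pytest

from paleoamp import topotest as tt


# ---------------------------------------------------------------------------
# independent oracle: enumerate internal-node state assignments


def enumeration_site_loglik(tree, aln, model):
    """Sum over every internal-node state combination (<= 5 taxa only)."""
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    pi = np.asarray(model.base_freqs)
    rates = tt.discrete_gamma_rates(model.alpha, model.n_gamma_cat)
    if model.p_inv > 0:
        rates = rates / (1.0 - model.p_inv)
    out = []
    for site in range(aln.n_sites):
        obs = {
            n: tt._tip_partial(aln.sequence_of(n.taxon.label)[site]) for n in leaves
        }
        mix = 0.0
        for r in rates:
            P = {
                n: tt.transition_matrix(model, r * (n.edge.length or 0.0))
                for n in nodes
                if n.parent_node is not None
            }
            total = 0.0
            for states in itertools.product(range(4), repeat=len(internal)):
                smap = dict(zip(internal, states))
                prob = pi[smap[tree.seed_node]]
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    ps = smap[n.parent_node]
                    if n.is_leaf():
                        prob *= (P[n][ps] * obs[n]).sum()
                    else:
                        prob *= P[n][ps, smap[n]]
                total += prob
            mix += total
        lik = (1.0 - model.p_inv) * mix / len(rates)
        if model.p_inv > 0:
            inv = sum(
                pi[x] * np.prod([obs[n][x] for n in leaves]) for x in range(4)
            )
            lik += model.p_inv * inv
        out.append(np.log(lik))
    return np.array(out)


def random_model(rng, p_inv_max=0.4):
    fr = rng.dirichlet([5.0] * 4)
    fr = fr / fr.sum()
    return tt.PartitionModel(
        exchangeabilities=tuple(rng.uniform(0.3, 3.0, 6)),
        base_freqs=tuple(fr),
        alpha=float(rng.uniform(0.2, 2.0)),
        p_inv=float(rng.uniform(0.0, p_inv_max)),
        n_gamma_cat=4,
    )


def random_alignment(rng, taxa, n_sites, alphabet="ACGT-RYN"):
    return tt.PartitionedAlignment(
        taxa=list(taxa),
        sequences=["".join(rng.choice(list(alphabet), n_sites)) for _ in taxa],
        partition=["all"] * n_sites,
    )


class TestRateMatrix:
    def test_transition_matrix_matches_scipy_expm(self):
        """The eigendecomposition path agrees with a direct matrix
        exponential, including for skewed base frequencies."""
        from scipy.linalg import expm

        rng = np.random.default_rng(77)
        for _ in range(5):
            m = random_model(rng)
            Q = tt.gtr_rate_matrix(m)
            for t in (0.01, 0.2, 1.5):
                assert np.abs(tt.transition_matrix(m, t) - expm(Q * t)).max() < 1e-10

    def test_rows_stochastic_and_stationary(self):
        m = tt.PartitionModel(
            exchangeabilities=(1.0, 2.0, 0.5, 0.8, 3.0, 1.0),
            base_freqs=(0.4, 0.3, 0.2, 0.1),
            alpha=1.0,
        )
        P = tt.transition_matrix(m, 0.7)
        assert np.allclose(P.sum(axis=1), 1.0)
        pi = np.asarray(m.base_freqs)
        assert np.allclose(pi @ P, pi)
        # unit expected rate at stationarity
        Q = tt.gtr_rate_matrix(m)
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)


class TestSiteLoglik:
    def test_zero_branch_identical_tips_give_log_base_freq(self):
        aln = tt.PartitionedAlignment(
            taxa=["a", "b"], sequences=["A", "A"], partition=["all"]
        )
        lnl = tt.site_loglik("(a:0,b:0);", aln, tt.jukes_cantor_model())
        assert lnl[0] == pytest.approx(np.log(0.25), abs=1e-10)

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_pruning_equals_state_enumeration(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        taxa = [f"t{i}" for i in range(n_taxa)]
        for _ in range(4):
            model = random_model(rng)
            bl = rng.uniform(0.01, 0.6, 2 * n_taxa - 2)
            if n_taxa == 4:
                nwk = "((t0:{:.3f},t1:{:.3f}):{:.3f},(t2:{:.3f},t3:{:.3f}):{:.3f});".format(*bl[:6])
            else:
                nwk = (
                    "(((t0:{:.3f},t1:{:.3f}):{:.3f},t2:{:.3f}):{:.3f},"
                    "(t3:{:.3f},t4:{:.3f}):{:.3f});".format(*bl[:8])
                )
            tree = dendropy.Tree.get(data=nwk, schema="newick")
            aln = random_alignment(rng, taxa, 12)
            got = tt.site_loglik(tree, aln, model)
            want = enumeration_site_loglik(tree, aln, model)
            assert np.abs(got - want).max() < 1e-8

    def test_large_alpha_converges_to_single_rate(self):
        rng = np.random.default_rng(3)
        aln = random_alignment(rng, ["a", "b", "c", "d"], 30, alphabet="ACGT")
        nwk = "((a:0.1,b:0.2):0.05,(c:0.15,d:0.3):0.05);"
        base = dict(
            exchangeabilities=(1.0, 2.0, 1.0, 1.0, 2.0, 1.0),
            base_freqs=(0.3, 0.2, 0.2, 0.3),
            p_inv=0.0,
        )
        smooth = tt.PartitionModel(alpha=1e7, n_gamma_cat=4, **base)
        single = tt.PartitionModel(alpha=1.0, n_gamma_cat=1, **base)
        a = tt.site_loglik(nwk, aln, smooth)
        b = tt.site_loglik(nwk, aln, single)
        assert np.abs(a - b).max() < 1e-6

    def test_total_invariant_under_rerooting(self):
        """Time reversibility: the same unrooted tree scored from two
        different rootings gives identical totals."""
        rng = np.random.default_rng(4)
        aln = random_alignment(rng, ["a", "b", "c", "d"], 40, alphabet="ACGTR-")
        model = random_model(rng)
        root_u = "(a:0.1,b:0.2,(c:0.15,d:0.3):0.25);"
        root_v = "((a:0.1,b:0.2):0.25,c:0.15,d:0.3);"
        lu = tt.site_loglik(root_u, aln, model).sum()
        lv = tt.site_loglik(root_v, aln, model).sum()
        assert lu == pytest.approx(lv, abs=1e-9)

    def test_per_partition_models_applied_by_label(self):
        rng = np.random.default_rng(5)
        aln = tt.PartitionedAlignment(
            taxa=["a", "b"],
            sequences=["AC", "AC"],
            partition=["p1", "p2"],
        )
        m1 = tt.PartitionModel(
            exchangeabilities=(1.0,) * 6,
            base_freqs=(0.7, 0.1, 0.1, 0.1),
            alpha=1.0,
            n_gamma_cat=1,
        )
        m2 = tt.jukes_cantor_model()
        lnl = tt.site_loglik("(a:0,b:0);", aln, {"p1": m1, "p2": m2})
        assert lnl[0] == pytest.approx(np.log(0.7))
        assert lnl[1] == pytest.approx(np.log(0.25))

    def test_unknown_taxon_and_negative_branch_rejected(self):
        aln = tt.PartitionedAlignment(
            taxa=["a", "b"], sequences=["A", "A"], partition=["all"]
        )
        with pytest.raises(ValueError, match="not in alignment"):
            tt.site_loglik("(a:0,x:0);", aln, tt.jukes_cantor_model())
        with pytest.raises(ValueError, match="negative"):
            tt.site_loglik("(a:-0.1,b:0);", aln, tt.jukes_cantor_model())


class TestRestrictToCovered:
    def test_fully_covered_focal_is_identity(self):
        aln = tt.PartitionedAlignment(
            taxa=["x", "y"], sequences=["ACGT", "ACGT"], partition=["a"] * 4
        )
        out = tt.restrict_to_covered(aln, "x")
        assert out.sequences == aln.sequences

    def test_missing_columns_dropped_with_labels(self):
        aln = tt.PartitionedAlignment(
            taxa=["x", "y"],
            sequences=["A-?GN", "CCCCC"],
            partition=["p1", "p1", "p2", "p2", "p2"],
        )
        out = tt.restrict_to_covered(aln, "x")
        assert out.sequences == ["AG", "CC"]
        assert out.partition == ["p1", "p2"]

    def test_all_missing_focal_warns_empty(self):
        aln = tt.PartitionedAlignment(
            taxa=["x", "y"], sequences=["---", "ACG"], partition=["a"] * 3
        )
        with pytest.warns(UserWarning):
            out = tt.restrict_to_covered(aln, "x")
        assert out.n_sites == 0

    def test_absent_taxon_is_an_error(self):
        aln = tt.PartitionedAlignment(
            taxa=["x"], sequences=["A"], partition=["a"]
        )
        with pytest.raises(KeyError):
            tt.restrict_to_covered(aln, "zz")


class TestRell:
    def test_single_site_replicate_is_that_site(self):
        M = tt.SiteLogLikMatrix(values=[[-1.5], [-2.5]])
        reps = tt.rell_bootstrap(M, B=1, seed=0)
        assert reps[0, 0] == -1.5 and reps[1, 0] == -2.5

    def test_replicate_mean_matches_row_sums(self):
        """CLT: mean replicate total per tree approximates the row sum."""
        rng = np.random.default_rng(1)
        M = tt.SiteLogLikMatrix(values=rng.normal(-3, 1, size=(3, 200)))
        reps = tt.rell_bootstrap(M, B=4000, seed=2)
        for i in range(3):
            se = reps[i].std() / np.sqrt(reps.shape[1])
            assert abs(reps[i].mean() - M.values[i].sum()) < 4 * se

    def test_fixed_seed_reproducible_and_scale_size(self):
        M = tt.SiteLogLikMatrix(values=np.zeros((2, 10)))
        a = tt.rell_bootstrap(M, B=5, seed=3, scale=0.5)
        b = tt.rell_bootstrap(M, B=5, seed=3, scale=0.5)
        assert np.array_equal(a, b)
        assert a.shape == (2, 5)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            tt.SiteLogLikMatrix(values=np.zeros((2, 0))).totals()
            tt.rell_bootstrap(tt.SiteLogLikMatrix(values=np.zeros((2, 0))), 1, 0)


class TestShTest:
    def test_identical_rows_give_p_one(self):
        M = tt.SiteLogLikMatrix(values=np.tile(np.linspace(-3, -1, 50), (3, 1)))
        out = tt.sh_test(M, B=500, seed=0)
        assert (out["p_sh"] == 1.0).all()

    def test_dominated_tree_is_rejected(self):
        rng = np.random.default_rng(7)
        good = rng.normal(-2, 0.3, 100)
        M = tt.SiteLogLikMatrix(values=np.vstack([good, good - 10.0]))
        out = tt.sh_test(M, B=2000, seed=1)
        assert out["p_sh"][1] < 0.001
        assert out["p_sh"][0] > 0.5

    def test_p_values_in_unit_interval_and_reproducible(self):
        rng = np.random.default_rng(9)
        M = tt.SiteLogLikMatrix(values=rng.normal(-2, 1, (4, 80)))
        a = tt.sh_test(M, B=500, seed=5)
        b = tt.sh_test(M, B=500, seed=5)
        assert a["p_sh"].between(0, 1).all()
        assert (a["p_sh"] == b["p_sh"]).all()

    def test_small_b_warns(self):
        M = tt.SiteLogLikMatrix(values=np.zeros((2, 5)))
        with pytest.warns(UserWarning, match="unstable"):
            tt.sh_test(M, B=50, seed=0)


class TestAuTest:
    def test_symmetric_pair_gives_half(self):
        """Two identical rows tie in every replicate; BP = 0.5 at every
        scale, so the regression is flat and p = 0.5 exactly."""
        row = np.linspace(-3, -1, 60)
        M = tt.SiteLogLikMatrix(values=np.vstack([row, row]))
        out = tt.au_test(M, B=400, seed=0)
        assert out["p_au"].tolist() == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_dominated_tree_rejected_supported_tree_accepted(self):
        rng = np.random.default_rng(11)
        good = rng.normal(-2, 0.3, 100)
        M = tt.SiteLogLikMatrix(values=np.vstack([good, good - 10.0]))
        out = tt.au_test(M, B=1000, seed=3)
        assert out["p_au"][1] < 0.01
        assert out["p_au"][0] > 0.9

    def test_moderate_signal_tracks_sh(self):
        """On a two-tree problem with moderate signal the AU and SH
        p-values agree to within 0.05."""
        rng = np.random.default_rng(13)
        base = rng.normal(-2, 1.0, 300)
        M = tt.SiteLogLikMatrix(
            values=np.vstack([base, base + rng.normal(0.02, 0.6, 300)])
        )
        sh = tt.sh_test(M, B=4000, seed=17)
        au = tt.au_test(M, B=4000, seed=17)
        worse = int(np.argmin(M.totals()))
        assert abs(au["p_au"][worse] - sh["p_sh"][worse]) < 0.05

    def test_p_values_in_unit_interval(self):
        rng = np.random.default_rng(15)
        M = tt.SiteLogLikMatrix(values=rng.normal(-2, 1, (4, 60)))
        out = tt.au_test(M, B=300, seed=1)
        assert out["p_au"].between(0, 1).all()

    def test_scales_must_straddle_one(self):
        M = tt.SiteLogLikMatrix(values=np.zeros((2, 5)))
        with pytest.raises(ValueError):
            tt.au_test(M, scales=[0.5, 0.8], B=10, seed=0)


class TestBayesFactorLayer:
    def test_constant_trace_is_exact(self):
        ps = tt.PosteriorSample("r1", np.full(50, -100.0))
        assert tt.harmonic_mean_lnl(ps) == pytest.approx(-100.0, abs=1e-12)

    def test_two_point_trace_hand_value(self):
        ps = tt.PosteriorSample("r1", np.log([1.0, 3.0]))
        assert tt.harmonic_mean_lnl(ps) == pytest.approx(np.log(1.5), abs=1e-12)

    def test_pooling_equals_concatenation_and_permutation_invariance(self):
        rng = np.random.default_rng(2)
        tr = rng.normal(-500, 5, 100)
        a = tt.PosteriorSample("a", tr[:60])
        b = tt.PosteriorSample("b", tr[60:])
        pooled = tt.harmonic_mean_lnl([a, b])
        concat = tt.harmonic_mean_lnl(tt.PosteriorSample("c", tr))
        shuffled = tt.harmonic_mean_lnl(
            tt.PosteriorSample("d", rng.permutation(tr))
        )
        assert pooled == pytest.approx(concat, abs=1e-10)
        assert shuffled == pytest.approx(concat, abs=1e-10)

    def test_burnin_removed(self):
        ps = tt.PosteriorSample("r1", np.array([0.0, -100.0, -100.0]), burnin=1)
        assert tt.harmonic_mean_lnl(ps) == pytest.approx(-100.0)
        with pytest.raises(ValueError):
            tt.PosteriorSample("r1", np.zeros(3), burnin=3)

    @pytest.mark.parametrize(
        "delta, category",
        [(0.0, "weak"), (1.5, "positive"), (3.5, "strong"), (5.76, "very strong")],
    )
    def test_kass_raftery_bands(self, delta, category):
        value, cat = tt.bayes_factor(-100.0 + delta, -100.0)
        assert value == pytest.approx(2 * delta)
        assert cat == category

    def test_antisymmetry(self):
        a, _ = tt.bayes_factor(-10.0, -13.0)
        b, _ = tt.bayes_factor(-13.0, -10.0)
        assert a == -b

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            tt.bayes_factor(np.inf, 0.0)


class TestFileFormats:
    def test_fasta_and_phylip_roundtrip(self, tmp_path):
        fasta = tmp_path / "a.fasta"
        fasta.write_text(">x\nACGT\n>y\nACGA\n")
        a = tt.read_alignment(fasta)
        phylip = tmp_path / "a.phy"
        phylip.write_text("2 4\nx ACGT\ny ACGA\n")
        b = tt.read_alignment(phylip)
        assert a.taxa == b.taxa and a.sequences == b.sequences

    def test_charset_partition_with_codon_step(self, tmp_path):
        parts = tmp_path / "p.txt"
        parts.write_text(
            "charset g1_pos1 = 1-6\\3;\ncharset g1_pos2 = 2-6\\3;\n"
            "charset g1_pos3 = 3-6\\3;\n"
        )
        labels = tt.parse_partition_file(parts, 6)
        assert labels == ["g1_pos1", "g1_pos2", "g1_pos3"] * 2

    def test_partition_must_cover_every_site(self, tmp_path):
        parts = tmp_path / "p.txt"
        parts.write_text("g = 1-3\n")
        with pytest.raises(ValueError, match="without partition"):
            tt.parse_partition_file(parts, 4)

    def test_sitelik_matrix_tsv_roundtrip(self, tmp_path):
        M = tt.SiteLogLikMatrix(
            values=np.array([[-1.0, -2.0], [-3.0, -4.0]]), tree_ids=["t1", "t2"]
        )
        path = tmp_path / "m.tsv"
        M.to_tsv(path)
        back = tt.SiteLogLikMatrix.from_tsv(path)
        assert back.tree_ids == ["t1", "t2"]
        assert np.allclose(back.values, M.values)

    def test_model_yaml(self, tmp_path):
        y = tmp_path / "m.yaml"
        y.write_text(
            "partitions:\n  all:\n    exchangeabilities: [1,2,1,1,2,1]\n"
            "    base_freqs: [0.3, 0.2, 0.2, 0.3]\n    alpha: 0.7\n    p_inv: 0.1\n"
        )
        model = tt.load_model_yaml(y)
        assert model["all"].alpha == 0.7
        assert model["all"].p_inv == 0.1
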