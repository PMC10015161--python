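"""Likelihood engine: gamma categories, pruning, optimization."""

import itertools
import subprocess
import textwrap

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import gamma as gamma_dist

from dupsplit.phylolik import (AA_ORDER, MSA, SubstModel, discrete_gamma_rates,
                               optimize_tree, site_loglik)
from dupsplit.seqsim import SimSpec, simulate_alignment
from dupsplit.treespace import TreeError, parse_newick
from tests._oracles import brute_force_site_lik


class TestDiscreteGamma:
    def test_single_category_is_rate_one(self):
        assert discrete_gamma_rates(0.37, 1) == pytest.approx([1.0])

    def test_large_alpha_degenerates_to_point_mass(self):
        rates = discrete_gamma_rates(1e6, 4)
        assert np.allclose(rates, 1.0, atol=1e-2)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    def test_bin_means_match_quadrature(self, alpha):
        k = 4
        rates = discrete_gamma_rates(alpha, k)
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha,
                               scale=1 / alpha)
        edges[-1] = np.inf
        oracle = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m, _ = integrate.quad(
                lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1 / alpha),
                lo, min(hi, 1e3))
            oracle.append(k * m)
        assert rates == pytest.approx(oracle, abs=1e-6)
        assert rates.mean() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_bad_alpha(self):
        with pytest.raises(ValueError):
            discrete_gamma_rates(float("nan"), 4)
        with pytest.raises(ValueError):
            discrete_gamma_rates(-1.0, 4)


class TestSiteLoglik:
    def test_two_leaf_poisson_closed_form(self):
        # P_aa(t) = 1/20 + (19/20) e^(-20 t / 19) under the rate-1 Poisson model
        model = SubstModel.poisson()
        tree = parse_newick("(A:0.05,B:0.15);", rooted=True)
        msa = MSA.from_sequences([("A", "A"), ("B", "A")])
        got = site_loglik(tree, msa, model)[0]
        t = 0.2
        expected = np.log(0.05 * (1 / 20 + (19 / 20) * np.exp(-20 * t / 19)))
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("model", [
        SubstModel.poisson(),
        SubstModel.jtt(alpha=0.7, k=4, p_inv=0.2),
    ], ids=["poisson", "jtt_ig4"])
    def test_matches_brute_force_three_leaves(self, model):
        tree = parse_newick("(A:0.1,B:0.3,C:0.5);")
        msa = MSA.from_sequences([("A", "ARW-A"), ("B", "RRWXA"),
                                  ("C", "WNWAA")])
        got = np.exp(site_loglik(tree, msa, model))
        oracle = brute_force_site_lik(tree, msa, model)
        assert np.max(np.abs(got - oracle) / oracle) < 1e-10

    def test_matches_brute_force_four_leaves(self):
        model = SubstModel.jtt(alpha=1.2, k=4, p_inv=0.1)
        tree = parse_newick("((A:0.2,B:0.4):0.15,C:0.1,D:0.6);")
        msa = MSA.from_sequences([("A", "ACDE"), ("B", "AC-E"),
                                  ("C", "AWDE"), ("D", "ACDY")])
        got = np.exp(site_loglik(tree, msa, model))
        oracle = brute_force_site_lik(tree, msa, model)
        assert np.max(np.abs(got - oracle) / oracle) < 1e-10

    def test_zero_branches_constant_pattern_gives_pi(self):
        model = SubstModel.jtt()
        tree = parse_newick("(A:0,B:0,C:0);")
        msa = MSA.from_sequences([("A", "A"), ("B", "A"), ("C", "A")])
        got = site_loglik(tree, msa, model)[0]
        # zero lengths are clamped to the 1e-8 floor, hence the tolerance
        assert got == pytest.approx(np.log(model.freqs[AA_ORDER.index("A")]),
                                    abs=1e-6)

    def test_all_ambiguous_column_has_likelihood_one(self):
        model = SubstModel.jtt(alpha=1.0, k=4, p_inv=0.3)
        tree = parse_newick("(A:0.2,B:0.1,C:0.4);")
        msa = MSA.from_sequences([("A", "-"), ("B", "X"), ("C", "-")])
        assert site_loglik(tree, msa, model)[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_leaves", [2, 3])
    def test_pattern_probabilities_sum_to_one(self, n_leaves):
        # exhaustive sum over all 20^n patterns; no +I, no gaps
        model = SubstModel.jtt(alpha=0.8, k=4, p_inv=0.0)
        if n_leaves == 2:
            tree = parse_newick("(A:0.2,B:0.7);", rooted=True)
        else:
            tree = parse_newick("(A:0.2,B:0.7,C:0.05);")
        labels = [v.label for v in tree.leaves()]
        patterns = list(itertools.product(AA_ORDER, repeat=n_leaves))
        seqs = ["".join(p[i] for p in patterns) for i in range(n_leaves)]
        msa = MSA(labels, np.array(
            [[AA_ORDER.index(c) for c in s] for s in seqs], dtype=np.int8))
        pat, counts = msa.patterns
        total = float(np.exp(site_loglik(tree, msa, model)) @ counts)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_rooting_invariance(self):
        model = SubstModel.jtt(alpha=0.9, k=4, p_inv=0.15)
        tree = parse_newick(
            "(((a:0.1,b:0.2):0.12,(c:0.3,d:0.05):0.2):0.08,e:0.4,f:0.25);")
        msa = simulate_alignment(SimSpec(tree=tree, model=model,
                                         n_sites=300, seed=5))
        counts = msa.patterns[1].astype(float)
        totals = []
        for leaf in tree.leaf_labels():
            rt = tree.rerooted_adjacent_to_leaf(leaf)
            totals.append(float(site_loglik(rt, msa, model) @ counts))
        assert np.max(totals) - np.min(totals) < 1e-8

    def test_requires_branch_lengths(self):
        with pytest.raises(TreeError):
            site_loglik(parse_newick("(A,B,C);"),
                        MSA.from_sequences([("A", "A"), ("B", "A"),
                                            ("C", "A")]),
                        SubstModel.jtt())


class TestPhangornCrossCheck:
    def test_total_loglik_matches_phangorn(self, tmp_path):
        """Independent implementation check: R/phangorn's pml on one fixture."""
        model = SubstModel.jtt(alpha=0.8, k=4, p_inv=0.0)
        tree = parse_newick(
            "(((a:0.1,b:0.2):0.12,(c:0.3,d:0.05):0.2):0.08,e:0.4,f:0.25);")
        msa = simulate_alignment(SimSpec(tree=tree, model=model,
                                         n_sites=200, seed=42))
        ours = float(site_loglik(tree, msa, model) @ msa.patterns[1])

        fasta = tmp_path / "aln.fasta"
        nwk = tmp_path / "tree.nwk"
        msa.to_fasta(fasta)
        nwk.write_text(tree.to_newick() + "\n")
        rscript = textwrap.dedent(f"""
            suppressMessages(library(phangorn))
            aln <- read.phyDat("{fasta}", format = "fasta", type = "AA")
            tr <- read.tree("{nwk}")
            fit <- pml(tr, aln, model = "JTT", k = 4, shape = 0.8)
            cat(sprintf("%.8f", logLik(fit)))
        """)
        out = subprocess.run(["Rscript", "-e", rscript],
                             capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        theirs = float(out.stdout.strip().split()[-1])
        assert ours == pytest.approx(theirs, abs=0.05)


class TestOptimizeTree:
    def test_deterministic(self):
        model = SubstModel.jtt(alpha=1.0, k=4, p_inv=0.1)
        tree = parse_newick("((a:0.1,b:0.2):0.1,c:0.3,d:0.2);")
        msa = simulate_alignment(SimSpec(tree=tree, model=model,
                                         n_sites=500, seed=9))
        topo = tree.copy()
        for v in topo.postorder():
            v.length = None
        r1 = optimize_tree(topo, msa, model)
        r2 = optimize_tree(topo, msa, model)
        assert r1.loglik == pytest.approx(r2.loglik, abs=1e-9)

    def test_column_duplication_doubles_loglik(self):
        model = SubstModel.jtt(alpha=1.0, k=4, p_inv=0.1)
        tree = parse_newick("((a:0.1,b:0.2):0.1,c:0.3,d:0.2);")
        msa = simulate_alignment(SimSpec(tree=tree, model=model,
                                         n_sites=400, seed=3))
        doubled = MSA(msa.labels, np.concatenate([msa.codes, msa.codes],
                                                 axis=1))
        topo = tree.copy()
        for v in topo.postorder():
            v.length = None
        r1 = optimize_tree(topo, msa, model, tol=1e-6)
        r2 = optimize_tree(topo, doubled, model, tol=1e-6)
        assert r2.loglik == pytest.approx(2 * r1.loglik, rel=1e-5)
        assert r2.alpha == pytest.approx(r1.alpha, rel=0.05)

    def test_fitted_loglik_beats_truth(self):
        # ML fit must dominate the generating parameters' likelihood
        model = SubstModel.jtt(alpha=1.0, k=4, p_inv=0.1)
        tree = parse_newick(
            "(((a:0.1,b:0.2):0.12,(c:0.3,d:0.05):0.2):0.08,e:0.4,f:0.25);")
        msa = simulate_alignment(SimSpec(tree=tree, model=model,
                                         n_sites=800, seed=21))
        truth_ll = float(site_loglik(tree, msa, model) @ msa.patterns[1])
        topo = tree.copy()
        for v in topo.postorder():
            v.length = None
        res = optimize_tree(topo, msa, model)
        assert res.converged
        assert res.loglik >= truth_ll - 1e-6

    def test_branch_recovery_small(self):
        model = SubstModel.jtt(alpha=1.0, k=4, p_inv=0.0)
        tree = parse_newick("((a:0.15,b:0.3):0.1,c:0.25,d:0.4);")
        msa = simulate_alignment(SimSpec(tree=tree, model=model,
                                         n_sites=2000, seed=11))
        topo = tree.copy()
        for v in topo.postorder():
            v.length = None
        res = optimize_tree(topo, msa, model, optimize_pinv=False)
        true_bl = {v.label: v.length for v in tree.leaves()}
        fit_bl = {v.label: v.length for v in res.tree.leaves()}
        rel = [abs(fit_bl[l] - true_bl[l]) / true_bl[l] for l in true_bl]
        assert np.mean(np.array(rel) < 0.2) >= 0.75
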