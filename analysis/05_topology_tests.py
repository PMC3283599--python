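"""Topology-confidence tests on a self-contained example.

Evolves a 1,200-site alignment down a known 5-taxon tree under GTR+Gamma
(using the package's own transition matrices), then treats three candidate
topologies — the true one and two rearrangements — as fixed hypotheses:
site log-likelihoods by Felsenstein pruning, RELL-based SH and AU tests,
and a harmonic-mean 2lnBF comparison from synthetic posterior traces
centred on each topology's log-likelihood.

The expected outcome: the true topology is not rejected, the wrong ones
are, and the 2lnBF exceeds the very-strong-evidence threshold of 10.

Writes results/topology_tests.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from paleoamp import topotest as tt

ROOT = Path(__file__).resolve().parent.parent / "results"

TRUE_TREE = "((a:0.08,b:0.12):0.15,(c:0.1,d:0.09):0.12,e:0.3);"
CANDIDATES = {
    "true": TRUE_TREE,
    "swap_bc": "((a:0.08,c:0.12):0.15,(b:0.1,d:0.09):0.12,e:0.3);",
    "swap_bd": "((a:0.08,d:0.12):0.15,(c:0.1,b:0.09):0.12,e:0.3);",
}
MODEL = tt.PartitionModel(
    exchangeabilities=(1.0, 4.0, 1.0, 1.0, 4.0, 1.0),  # transition-biased
    base_freqs=(0.3, 0.25, 0.15, 0.3),
    alpha=0.8,
    p_inv=0.0,
    n_gamma_cat=4,
)


def evolve_alignment(newick: str, model: tt.PartitionModel, n_sites: int, rng):
    """Simulate sites down a tree by drawing the root from the stationary
    distribution and applying P(r t) edge by edge."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    rates = tt.discrete_gamma_rates(model.alpha, model.n_gamma_cat)
    pi = np.asarray(model.base_freqs)
    site_rates = rng.choice(rates, size=n_sites)
    states = {tree.seed_node: rng.choice(4, size=n_sites, p=pi)}
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        child, bl = edge.head_node, edge.length or 0.0
        out = np.empty(n_sites, dtype=int)
        for r in np.unique(site_rates):
            P = tt.transition_matrix(model, r * bl)
            idx = np.flatnonzero(site_rates == r)
            for i in idx:
                out[i] = rng.choice(4, p=P[states[edge.tail_node][i]])
        states[child] = out
    taxa, seqs = [], []
    for leaf in tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        seqs.append("".join("ACGT"[s] for s in states[leaf]))
    return tt.PartitionedAlignment(taxa=taxa, sequences=seqs, partition=["all"] * n_sites)


def main(seed: int = 0) -> None:
    rng = np.random.default_rng(seed)
    aln = evolve_alignment(TRUE_TREE, MODEL, n_sites=1200, rng=rng)
    M = tt.site_loglik_matrix(
        list(CANDIDATES.values()), aln, MODEL, tree_ids=list(CANDIDATES)
    )
    sh = tt.sh_test(M, B=5000, seed=seed)
    au = tt.au_test(M, B=2000, seed=seed)
    table = sh.merge(au[["tree", "p_au"]], on="tree")

    # harmonic-mean 2lnBF from synthetic posterior traces around each lnL
    totals = M.totals()
    traces = {
        t: tt.PosteriorSample(t, totals[i] + rng.normal(-2.0, 1.5, 4000), burnin=1000)
        for i, t in enumerate(CANDIDATES)
    }
    lnm = {t: tt.harmonic_mean_lnl(ps) for t, ps in traces.items()}
    bf_rows = []
    for t in CANDIDATES:
        value, category = tt.bayes_factor(lnm["true"], lnm[t])
        bf_rows.append({"tree": t, "two_ln_bf_vs_true": value, "category": category})
    table = table.merge(pd.DataFrame(bf_rows), on="tree")

    out = ROOT / "topology_tests.tsv"
    ROOT.mkdir(exist_ok=True)
    table.to_csv(out, sep="\t", index=False, float_format="%.4f")
    print(table.to_string(index=False))
    print(f"-> {out}")
    print(
        "reading: the generating topology keeps high SH/AU p-values; the "
        "rearrangements are rejected and their 2lnBF against the true tree "
        "exceeds the very-strong threshold of 10"
    )


if __name__ == "__main__":
    main()
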