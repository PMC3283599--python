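"""Site log-likelihoods on fixed trees and topology-confidence tests.

Given a partitioned alignment, candidate topologies with branch lengths,
and per-partition GTR+I+Gamma parameters, this module computes site-wise
log-likelihoods by Felsenstein pruning and feeds them to the classical
resampling tests of topology selection:

* RELL bootstrap — resample alignment columns, re-sum the stored site
  log-likelihoods (no re-optimization);
* SH test — simultaneous comparison of every candidate against the best,
  with the null generated from centred RELL replicates;
* AU test — multiscale bootstrap: the bootstrap proportion of each tree is
  tracked across resample sizes r*n, its normal quantile is regressed on
  d*sqrt(r) + c/sqrt(r), and p = 1 - Phi(d - c);
* harmonic-mean marginal-likelihood estimates from posterior traces and
  the 2 ln BF scale (values above 10 read as very strong evidence).

Branch lengths and model parameters are *inputs*; nothing here optimizes
them.  All logarithms are natural.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.special import gammainc, logsumexp, ndtr, ndtri

from . import iupac

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_MISSING = set("-.?NnXx")

#: order of the six exchangeability rates
EXCHANGE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")


# ---------------------------------------------------------------------------
# alignment + model containers


@dataclass
class PartitionedAlignment:
    """Equal-length sequences with one partition label per site."""

    taxa: list[str]
    sequences: list[str]
    partition: list[str]  # label per site, e.g. "cytb_pos1"

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("one sequence per taxon required")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        if self.sequences and len(self.partition) != len(self.sequences[0]):
            raise ValueError("one partition label per site required")

    @property
    def n_sites(self) -> int:
        return len(self.partition)

    def sequence_of(self, taxon: str) -> str:
        try:
            return self.sequences[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None


@dataclass(frozen=True)
class PartitionModel:
    """GTR+I+Gamma parameters for one partition."""

    exchangeabilities: tuple[float, ...]  # AC, AG, AT, CG, CT, GT
    base_freqs: tuple[float, float, float, float]  # A, C, G, T
    alpha: float
    p_inv: float = 0.0
    n_gamma_cat: int = 4

    def __post_init__(self):
        if len(self.exchangeabilities) != 6:
            raise ValueError("six exchangeability rates required")
        if any(r < 0 for r in self.exchangeabilities):
            raise ValueError("negative exchangeability")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must be in [0, 1)")


GTRIGModel = Mapping[str, PartitionModel]


def jukes_cantor_model(alpha: float = 1e6, p_inv: float = 0.0, n_gamma_cat: int = 1) -> PartitionModel:
    """Equal-rates, equal-frequencies parameterization (handy in tests)."""
    return PartitionModel(
        exchangeabilities=(1.0,) * 6,
        base_freqs=(0.25,) * 4,
        alpha=alpha,
        p_inv=p_inv,
        n_gamma_cat=n_gamma_cat,
    )


# ---------------------------------------------------------------------------
# GTR machinery


def gtr_rate_matrix(model: PartitionModel) -> np.ndarray:
    """GTR generator Q with rows summing to zero, scaled so the expected
    substitution rate at stationarity is one per unit branch length."""
    s = model.exchangeabilities
    pi = np.asarray(model.base_freqs)
    Q = np.zeros((4, 4))
    pairs = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
    for rate, (i, j) in zip(s, pairs):
        Q[i, j] = rate * pi[j]
        Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    if scale <= 0:
        raise ValueError("degenerate rate matrix")
    return Q / scale


def _eigen_gtr(model: PartitionModel):
    """Symmetrized eigendecomposition of the scaled GTR generator."""
    Q = gtr_rate_matrix(model)
    pi = np.asarray(model.base_freqs)
    sqrt_pi = np.sqrt(pi)
    # S = D^(1/2) Q D^(-1/2) is symmetric for a reversible Q
    S = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
    lam, V = np.linalg.eigh((S + S.T) / 2.0)
    right = V / sqrt_pi[:, None]
    left = V.T * sqrt_pi[None, :]
    return lam, right, left


def transition_matrix(model: PartitionModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for the scaled GTR generator."""
    lam, right, left = _eigen_gtr(model)
    return (right * np.exp(lam * t)[None, :]) @ left


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rate of each of k equal-probability Gamma(alpha) categories.

    Category boundaries are the i/k quantiles of Gamma(alpha, mean 1);
    each category's rate is its conditional mean, so the rates average
    exactly one (the convention of the standard ML programs).
    """
    if k == 1:
        return np.ones(1)
    from scipy.stats import gamma as gamma_dist

    cuts = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([gammainc(alpha + 1.0, alpha * cuts), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1.0, alpha * cuts)])
    return k * (upper - lower)


def _tip_partial(ch: str) -> np.ndarray:
    """Partial likelihood vector for one observed character: indicator of
    the IUPAC base set, all-ones for gap/missing."""
    if ch in _MISSING:
        return np.ones(4)
    vec = np.zeros(4)
    for b in iupac.base_set(ch):
        vec[_BASE_INDEX[b]] = 1.0
    return vec


# ---------------------------------------------------------------------------
# pruning


def _resolve_tree(tree: "str | Path | dendropy.Tree") -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    text = str(tree)
    if "(" not in text:  # a path, not a newick string
        text = Path(text).read_text()
    return dendropy.Tree.get(data=text, schema="newick")


def site_loglik(
    tree: "str | Path | dendropy.Tree",
    aln: PartitionedAlignment,
    model: GTRIGModel | PartitionModel,
) -> np.ndarray:
    """Natural-log site likelihoods of one fixed tree.

    Felsenstein pruning with, per partition, a mixture over the discrete-
    Gamma rate categories plus an invariant class of weight p_inv; the
    variable-category rates are divided by (1 - p_inv) so the expected
    rate over all classes is one and branch lengths keep their usual
    substitutions-per-site meaning.  Ambiguity codes contribute the
    indicator of their base set; gaps and missing data contribute ones.
    """
    t = _resolve_tree(tree)
    if isinstance(model, PartitionModel):
        model = {lab: model for lab in set(aln.partition)}
    labels = set(aln.partition)
    missing_models = labels - set(model)
    if missing_models:
        raise ValueError(f"no model for partition(s) {sorted(missing_models)}")

    tip_names = [lf.taxon.label for lf in t.leaf_node_iter()]
    unknown = [n for n in tip_names if n not in aln.taxa]
    if unknown:
        raise ValueError(f"tree taxa not in alignment: {unknown}")
    for edge in t.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")

    part = np.asarray(aln.partition)
    out = np.empty(aln.n_sites)
    for label in sorted(labels):
        cols = np.flatnonzero(part == label)
        m = model[label]
        pi = np.asarray(m.base_freqs)
        rates = discrete_gamma_rates(m.alpha, m.n_gamma_cat)
        if m.p_inv > 0:
            rates = rates / (1.0 - m.p_inv)
        lam, right, left = _eigen_gtr(m)

        # tip partials for this partition's columns: taxon -> (4, n_cols)
        tips = {}
        for name in tip_names:
            seq = aln.sequence_of(name)
            tips[name] = np.stack(
                [_tip_partial(seq[c].upper()) for c in cols], axis=1
            )

        mix = np.zeros(len(cols))
        for r in rates:
            partials = {}
            for node in t.postorder_node_iter():
                if node.is_leaf():
                    partials[node] = tips[node.taxon.label]
                    continue
                prod = np.ones((4, len(cols)))
                for child in node.child_nodes():
                    bl = child.edge.length or 0.0
                    P = (right * np.exp(lam * r * bl)[None, :]) @ left
                    prod *= P @ partials[child]
                partials[node] = prod
            mix += pi @ partials[t.seed_node]
        site_like = (1.0 - m.p_inv) * mix / len(rates)
        if m.p_inv > 0:
            inv = np.ones((4, len(cols)))
            for name in tip_names:
                inv *= tips[name]
            site_like = site_like + m.p_inv * (pi @ inv)
        out[cols] = np.log(site_like)
    return out


def site_loglik_matrix(
    trees: Sequence,
    aln: PartitionedAlignment,
    model: GTRIGModel | PartitionModel,
    tree_ids: Sequence[str] | None = None,
) -> "SiteLogLikMatrix":
    rows = np.vstack([site_loglik(t, aln, model) for t in trees])
    ids = list(tree_ids) if tree_ids is not None else [f"tree{i+1}" for i in range(len(trees))]
    return SiteLogLikMatrix(values=rows, tree_ids=ids)


@dataclass
class SiteLogLikMatrix:
    """Trees x sites matrix of natural-log site likelihoods."""

    values: np.ndarray
    tree_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("matrix must be 2-D (trees x sites)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite site log-likelihoods")
        if not self.tree_ids:
            self.tree_ids = [f"tree{i+1}" for i in range(self.values.shape[0])]
        if len(self.tree_ids) != self.values.shape[0]:
            raise ValueError("one id per tree required")

    @property
    def n_trees(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values.T, columns=self.tree_ids)
        df.insert(0, "site", np.arange(1, self.n_sites + 1))
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SiteLogLikMatrix":
        df = pd.read_csv(path, sep="\t")
        cols = [c for c in df.columns if c != "site"]
        return cls(values=df[cols].to_numpy().T, tree_ids=cols)


# ---------------------------------------------------------------------------
# alignment utilities


def restrict_to_covered(
    aln: PartitionedAlignment, focal_taxon: str
) -> PartitionedAlignment:
    """Keep only sites where the focal taxon is non-missing.

    This mirrors re-running an analysis "limited to the data available"
    for a sparsely covered taxon; partition labels travel with the kept
    columns.  An all-missing focal taxon yields an empty alignment with a
    warning.
    """
    import warnings

    focal = aln.sequence_of(focal_taxon)
    keep = [i for i, ch in enumerate(focal) if ch not in _MISSING]
    if not keep:
        warnings.warn(f"focal taxon {focal_taxon} has no covered sites")
    return PartitionedAlignment(
        taxa=list(aln.taxa),
        sequences=["".join(s[i] for i in keep) for s in aln.sequences],
        partition=[aln.partition[i] for i in keep],
    )


# ---------------------------------------------------------------------------
# resampling tests


def rell_bootstrap(
    M: SiteLogLikMatrix, B: int, seed: int, scale: float = 1.0
) -> np.ndarray:
    """RELL replicate totals, shape (n_trees, B).

    Each replicate draws ceil(scale * n_sites) columns with replacement —
    the same columns for every tree — and sums the stored site
    log-likelihoods; no likelihood re-evaluation is involved.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if M.n_sites == 0:
        raise ValueError("empty site matrix")
    rng = np.random.default_rng(seed)
    m = int(np.ceil(scale * M.n_sites))
    totals = np.empty((M.n_trees, B))
    for b in range(B):
        cols = rng.integers(0, M.n_sites, size=m)
        totals[:, b] = M.values[:, cols].sum(axis=1)
    return totals


def sh_test(M: SiteLogLikMatrix, B: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Shimodaira-Hasegawa test of every tree against the best one.

    The observed statistic for tree i is max_j L_j - L_i on the full-data
    totals; the null distribution comes from RELL replicates centred per
    tree (each tree's replicate totals minus their own mean), and the
    p-value is the fraction of replicates whose statistic reaches the
    observed one.  Valid only when the candidate set plausibly contains
    the true topology, which is why the AU test is usually run alongside.
    """
    import warnings

    if M.n_trees < 2:
        raise ValueError("need at least two trees")
    if B < 100:
        warnings.warn("B < 100 gives unstable SH p-values")
    totals = M.totals()
    T_obs = totals.max() - totals
    reps = rell_bootstrap(M, B=B, seed=seed)
    centred = reps - reps.mean(axis=1, keepdims=True)
    T_null = centred.max(axis=0)[None, :] - centred
    p = (T_null >= T_obs[:, None]).mean(axis=1)
    return pd.DataFrame(
        {"tree": M.tree_ids, "lnL": totals, "delta": T_obs, "p_sh": p}
    )


DEFAULT_AU_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))


def au_test(
    M: SiteLogLikMatrix,
    scales: Sequence[float] = DEFAULT_AU_SCALES,
    B: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Approximately unbiased test via multiscale RELL bootstrap.

    For each tree, the proportion BP(r) of replicates in which it attains
    the maximum total is computed at every scale r; z(r) = Phi^-1(1-BP) is
    fitted by weighted least squares to d*sqrt(r) + c/sqrt(r) (binomial-
    variance weights), and p_AU = 1 - Phi(d - c).  Bootstrap proportions
    of exactly 0 or 1 at a scale get the 1/(2B) continuity correction; a
    tree at BP 0 (or 1) at *every* scale is reported as p = 0 (or 1).
    """
    if M.n_trees < 2:
        raise ValueError("need at least two trees")
    scales = [float(r) for r in scales]
    if len([r for r in scales if r < 1.0]) == 0 or len([r for r in scales if r > 1.0]) == 0:
        raise ValueError("scales should span values below and above 1")
    rng = np.random.default_rng(seed)
    bp = np.zeros((M.n_trees, len(scales)))
    for k, r in enumerate(scales):
        reps = rell_bootstrap(M, B=B, seed=int(rng.integers(2**31 - 1)), scale=r)
        best = reps.max(axis=0)
        hits = reps >= best[None, :] - 1e-9
        # split ties evenly so the proportions sum to one
        bp[:, k] = (hits / hits.sum(axis=0)[None, :]).sum(axis=1) / reps.shape[1]
    rows = []
    sq = np.sqrt(np.asarray(scales))
    X = np.column_stack([sq, 1.0 / sq])
    for i, tree_id in enumerate(M.tree_ids):
        raw = bp[i]
        if np.all(raw <= 0.0):
            rows.append((tree_id, 0.0, np.nan, np.nan))
            continue
        if np.all(raw >= 1.0):
            rows.append((tree_id, 1.0, np.nan, np.nan))
            continue
        adj = np.clip(raw, 1.0 / (2 * B), 1.0 - 1.0 / (2 * B))
        z = ndtri(1.0 - adj)
        dens = np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
        w = B * dens**2 / (adj * (1.0 - adj))
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)
        d, c = coef
        rows.append((tree_id, float(1.0 - ndtr(d - c)), float(d), float(c)))
    return pd.DataFrame(rows, columns=["tree", "p_au", "d", "c"])


# ---------------------------------------------------------------------------
# Bayes-factor layer


@dataclass
class PosteriorSample:
    """A posterior log-likelihood trace with its burn-in."""

    run_id: str
    lnl_trace: np.ndarray
    burnin: int = 0

    def __post_init__(self):
        self.lnl_trace = np.asarray(self.lnl_trace, dtype=float)
        if self.burnin >= len(self.lnl_trace):
            raise ValueError("burn-in not shorter than the trace")

    def post_burnin(self) -> np.ndarray:
        return self.lnl_trace[self.burnin :]


def harmonic_mean_lnl(samples: "PosteriorSample | Iterable[PosteriorSample]") -> float:
    """Harmonic-mean estimate of the ln marginal likelihood.

    ln m = -( logsumexp(-lnL_k) - ln n ) over the pooled post-burn-in
    samples; numerically stabilized, exact for a constant trace.  A rough
    estimator, used only to rank constrained against unconstrained
    topologies on the 2 ln BF scale.
    """
    if isinstance(samples, PosteriorSample):
        samples = [samples]
    pooled = np.concatenate([s.post_burnin() for s in samples])
    if pooled.size == 0:
        raise ValueError("no post-burn-in samples")
    return float(-(logsumexp(-pooled) - np.log(pooled.size)))


def bayes_factor(lnm1: float, lnm0: float) -> tuple[float, str]:
    """2 ln BF for model 1 over model 0, with its Kass-Raftery category.

    Positive favours model 1; > 10 is read as very strong evidence, > 6
    strong, > 2 positive, otherwise weak.
    """
    if not (np.isfinite(lnm1) and np.isfinite(lnm0)):
        raise ValueError("marginal likelihoods must be finite")
    two_ln_bf = 2.0 * (lnm1 - lnm0)
    if two_ln_bf > 10:
        category = "very strong"
    elif two_ln_bf > 6:
        category = "strong"
    elif two_ln_bf > 2:
        category = "positive"
    else:
        category = "weak"
    return two_ln_bf, category


# ---------------------------------------------------------------------------
# file formats


def read_alignment(
    path: str | Path, partition_path: str | Path | None = None
) -> PartitionedAlignment:
    """Read a FASTA or relaxed-PHYLIP alignment, with optional partitions.

    Without a partition file every site is labelled "all".
    """
    path = Path(path)
    taxa: list[str] = []
    seqs: list[str] = []
    text = path.read_text()
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            seqs.append(str(rec.seq).upper())
    else:
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split()
        n_taxa = int(header[0])
        for ln in lines[1 : 1 + n_taxa]:
            name, seq = ln.split(None, 1)
            taxa.append(name)
            seqs.append(seq.replace(" ", "").upper())
    n_sites = len(seqs[0]) if seqs else 0
    if partition_path is None:
        partition = ["all"] * n_sites
    else:
        partition = parse_partition_file(partition_path, n_sites)
    return PartitionedAlignment(taxa=taxa, sequences=seqs, partition=partition)


def parse_partition_file(path: str | Path, n_sites: int) -> list[str]:
    """Parse charset-style range definitions into per-site labels.

    Accepted lines (case-insensitive, trailing ';' optional)::

        charset cytb_pos1 = 1-992\\3;
        irbp = 993-1266

    Ranges are 1-based inclusive; "\\k" applies a step.  Every site must
    end up with exactly one label.
    """
    labels: list[str | None] = [None] * n_sites
    for raw in Path(path).read_text().splitlines():
        line = raw.strip().rstrip(";")
        if not line or line.startswith("#"):
            continue
        if line.lower().startswith("charset "):
            line = line[8:]
        if "=" not in line:
            continue
        name, ranges = (s.strip() for s in line.split("=", 1))
        for chunk in ranges.split(","):
            chunk = chunk.strip()
            step = 1
            if "\\" in chunk:
                chunk, step_s = chunk.split("\\")
                step = int(step_s)
            if "-" in chunk:
                lo, hi = (int(x) for x in chunk.split("-"))
            else:
                lo = hi = int(chunk)
            for p in range(lo, hi + 1, step):
                if not 1 <= p <= n_sites:
                    raise ValueError(f"site {p} outside alignment of {n_sites}")
                if labels[p - 1] is not None:
                    raise ValueError(f"site {p} assigned to two partitions")
                labels[p - 1] = name
    missing = [i + 1 for i, v in enumerate(labels) if v is None]
    if missing:
        raise ValueError(f"sites without partition label, e.g. {missing[:5]}")
    return [str(v) for v in labels]


def load_model_yaml(path: str | Path) -> dict[str, PartitionModel]:
    """Per-partition GTR+I+Gamma parameters from a YAML file."""
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    parts = doc.get("partitions", doc)
    out = {}
    for name, p in parts.items():
        out[name] = PartitionModel(
            exchangeabilities=tuple(p["exchangeabilities"]),
            base_freqs=tuple(p["base_freqs"]),
            alpha=float(p["alpha"]),
            p_inv=float(p.get("p_inv", 0.0)),
            n_gamma_cat=int(p.get("n_gamma_cat", 4)),
        )
    return out


def read_trees(path: str | Path) -> tuple[list[dendropy.Tree], list[str]]:
    """All newick trees in a file, with labels tree1..treeN."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    return list(trees), [f"tree{i+1}" for i in range(len(trees))]


def read_posterior_trace(path: str | Path, run_id: str = "run1", burnin: int = 0) -> PosteriorSample:
    """Posterior lnL trace from a TSV with a generation and a lnL column."""
    df = pd.read_csv(path, sep="\t")
    col = "lnL" if "lnL" in df.columns else df.columns[-1]
    return PosteriorSample(run_id=run_id, lnl_trace=df[col].to_numpy(), burnin=burnin)
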