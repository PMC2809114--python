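"""Goldman-Yang (GY94) codon substitution models over the 61 sense codons.

The instantaneous rate from codon i to codon j is zero unless they differ at
exactly one nucleotide, and otherwise proportional to

    pi_j * kappa^[transition] * omega^[nonsynonymous],

scaled so the expected number of substitutions per codon site per unit
branch length is one.  omega (dN/dS) measures selective pressure: omega < 1
purifying, omega = 1 neutral, omega > 1 positive selection.

Implemented model parameterisations (the classic codeml family):

* ``M0`` -- one omega for the whole tree.
* ``two_ratio`` -- a foreground omega on designated branches, omega_0 elsewhere.
* ``free_ratio`` -- an independent omega per branch.
* ``M1a`` / ``M2a`` -- nearly-neutral / positive-selection site mixtures.
* ``M8`` / ``M8a`` -- beta-distributed omega (10 equal-probability
  categories) plus one extra class with omega_s >= 1 (M8a fixes omega_s = 1).
* ``branch_site_A`` / ``branch_site_A_null`` -- the branch-site model A and
  its omega_2 = 1 null.

Likelihoods are computed by Felsenstein pruning over unique site patterns,
with transition probabilities from the spectral decomposition of the
reversible rate matrix.  Fits use multi-start bounded quasi-Newton
optimisation of all free parameters (branch lengths included) and are
reproducible given a seed.  Empirical-Bayes site posteriors are naive
(plug-in) rather than Bayes empirical Bayes.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import optimize, stats

from .codonseq import (
    NT_INDEX,
    CodonAlignment,
    GeneticCode,
    alignment_codon_matrix,
    standard_code,
)

OMEGA_MAX = 50.0
KAPPA_BOUNDS = (0.01, 100.0)
BRLEN_BOUNDS = (1e-8, 20.0)
_PROP_EPS = 1e-6

MODEL_NAMES = (
    "M0",
    "two_ratio",
    "free_ratio",
    "M1a",
    "M2a",
    "M8",
    "M8a",
    "branch_site_A",
    "branch_site_A_null",
)


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# rate matrix


@functools.lru_cache(maxsize=None)
def _neighbors(code: GeneticCode):
    """Single-nucleotide neighbor pairs among sense codons.

    Returns arrays (rows, cols, is_ts, is_syn) over ordered pairs i != j.
    """
    sense = code.sense_codons
    n = len(sense)
    rows, cols, ts, syn = [], [], [], []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a, b = sense[i], sense[j]
            diffs = [p for p in range(3) if a[p] != b[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            s = NT_INDEX[a[p]] + NT_INDEX[b[p]]
            rows.append(i)
            cols.append(j)
            ts.append(s in (2, 4))  # A<->G or C<->T
            syn.append(code.codon_to_aa[a] == code.codon_to_aa[b])
    return (
        np.array(rows), np.array(cols),
        np.array(ts, dtype=bool), np.array(syn, dtype=bool),
    )


def build_q(kappa: float, omega: float, pi: np.ndarray, code: GeneticCode | None = None) -> np.ndarray:
    """Scaled GY94 rate matrix (61x61); rows sum to zero, mean rate one.

    States with pi = 0 are excluded from the scaling (they are absorbing and
    never reached from the support).
    """
    code = code or standard_code()
    if kappa <= 0 or omega < 0:
        raise ModelError("require kappa > 0 and omega >= 0")
    pi = np.asarray(pi, dtype=float)
    n = len(code.sense_codons)
    if pi.shape != (n,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise ModelError("pi must be a simplex over the sense codons")
    rows, cols, ts, syn = _neighbors(code)
    Q = np.zeros((n, n))
    rates = pi[cols] * np.where(ts, kappa, 1.0) * np.where(syn, 1.0, omega)
    Q[rows, cols] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    if mu <= 0:
        # no substitution is possible on the support (e.g. single-codon pi):
        # the process is frozen and the rate matrix is identically zero
        return np.zeros_like(Q)
    return Q / mu


class Propagator:
    """Transition probabilities P(t) = exp(Qt) for a reversible Q.

    Operates on the support (pi > 0) via the symmetrised eigendecomposition;
    :meth:`expm` returns the full-size matrix with identity on zero-frequency
    states.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.n = Q.shape[0]
        self.pi = np.asarray(pi, dtype=float)
        self.support = np.flatnonzero(self.pi > 0)
        s = self.support
        d = np.sqrt(self.pi[s])
        S = (Q[np.ix_(s, s)] * d[:, None]) / d[None, :]
        S = 0.5 * (S + S.T)
        self.w, self.U = np.linalg.eigh(S)
        self._left = self.U / d[:, None]
        self._right = self.U.T * d[None, :]

    def expm(self, t: float) -> np.ndarray:
        if t < 0:
            raise ModelError("negative branch length")
        s = self.support
        Ps = (self._left * np.exp(self.w * t)) @ self._right
        np.clip(Ps, 0.0, None, out=Ps)
        P = np.eye(self.n)
        P[np.ix_(s, s)] = Ps
        return P

    def expm_many(self, ts) -> list:
        """P(t) for an array of branch lengths (one batched matmul)."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ModelError("negative branch length")
        s = self.support
        E = np.exp(np.multiply.outer(ts, self.w))  # (k, m)
        Ps = (self._left[None, :, :] * E[:, None, :]) @ self._right
        np.clip(Ps, 0.0, None, out=Ps)
        if len(s) == self.n:
            return list(Ps)
        out = []
        for k in range(len(ts)):
            P = np.eye(self.n)
            P[np.ix_(s, s)] = Ps[k]
            out.append(P)
        return out


# ---------------------------------------------------------------------------
# frequencies and data packing


def f3x4_frequencies(aln: CodonAlignment, code: GeneticCode | None = None) -> np.ndarray:
    """F3x4 codon frequencies: positional nucleotide frequencies multiplied
    per codon and renormalised over the sense codons."""
    code = code or standard_code()
    counts = np.zeros((3, 4))
    for seq in aln.sequences:
        for k in range(0, len(seq) - 2, 3):
            for p in range(3):
                i = NT_INDEX.get(seq[k + p])
                if i is not None:
                    counts[p, i] += 1
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ModelError("cannot estimate F3x4 frequencies from empty data")
    freqs = counts / totals
    pi = np.array(
        [
            freqs[0, NT_INDEX[c[0]]] * freqs[1, NT_INDEX[c[1]]] * freqs[2, NT_INDEX[c[2]]]
            for c in code.sense_codons
        ]
    )
    tot = pi.sum()
    if tot <= 0:
        raise ModelError("F3x4 frequencies vanish on all sense codons")
    return pi / tot


def _pack_patterns(aln: CodonAlignment, code: GeneticCode):
    """Compress codon columns into unique patterns.

    Returns (patterns (n_taxa, n_pat) int, weights (n_pat,), site_to_pattern).
    Missing/ambiguous codons are -1.
    """
    mat = alignment_codon_matrix(aln, code)  # (n_taxa, n_codons)
    cols = [tuple(mat[:, s]) for s in range(mat.shape[1])]
    uniq = {}
    site_to_pattern = np.empty(len(cols), dtype=np.int64)
    for s, c in enumerate(cols):
        if c not in uniq:
            uniq[c] = len(uniq)
        site_to_pattern[s] = uniq[c]
    patterns = np.array(list(uniq.keys()), dtype=np.int64).T
    weights = np.bincount(site_to_pattern, minlength=len(uniq)).astype(float)
    return patterns, weights, site_to_pattern


# ---------------------------------------------------------------------------
# pruning engine


class _TreeIndex:
    """Flat postorder indexing of a dendropy tree for vectorised pruning."""

    def __init__(self, tree: dendropy.Tree, taxa: Sequence[str]):
        taxon_row = {t: i for i, t in enumerate(taxa)}
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(nd): i for i, nd in enumerate(self.nodes)}
        self.root = len(self.nodes) - 1
        self.children = []
        self.leaf_row = []
        self.lengths0 = []
        missing = []
        for nd in self.nodes:
            self.children.append([self.index[id(c)] for c in nd.child_nodes()])
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon else nd.label
                if label not in taxon_row:
                    missing.append(label)
                    self.leaf_row.append(-1)
                else:
                    self.leaf_row.append(taxon_row[label])
            else:
                self.leaf_row.append(-1)
            self.lengths0.append(
                nd.edge.length if nd.edge.length is not None else 0.05
            )
        if missing:
            raise ModelError(f"tree leaves not in alignment: {sorted(missing)}")
        present = {self.leaf_row[i] for i, nd in enumerate(self.nodes) if nd.is_leaf()}
        absent = [t for t, i in taxon_row.items() if i not in present]
        if absent:
            raise ModelError(f"alignment taxa not in tree: {sorted(absent)}")
        self.n_edges = len(self.nodes) - 1  # every non-root node owns its edge
        self.edge_nodes = [i for i in range(len(self.nodes)) if i != self.root]
        self.edge_of_node = {n: e for e, n in enumerate(self.edge_nodes)}

    def edge_labels(self) -> list:
        """A stable label per edge: child's taxon/label, else its sorted leaf set."""
        labels = []
        for i in self.edge_nodes:
            nd = self.nodes[i]
            if nd.is_leaf():
                labels.append(nd.taxon.label if nd.taxon else nd.label)
            elif nd.label:
                labels.append(nd.label)
            else:
                labels.append(
                    "+".join(sorted(lf.taxon.label for lf in nd.leaf_iter()))
                )
        return labels


class PruningEngine:
    """Per-pattern log-likelihoods by Felsenstein pruning on the support states."""

    def __init__(self, aln: CodonAlignment, tree: dendropy.Tree,
                 pi: np.ndarray, code: GeneticCode | None = None):
        self.code = code or standard_code()
        self.pi = np.asarray(pi, dtype=float)
        self.support = np.flatnonzero(self.pi > 0)
        self.m = len(self.support)
        full_to_sub = -np.ones(len(self.code.sense_codons) + 1, dtype=np.int64)
        full_to_sub[self.support] = np.arange(self.m)
        patterns, weights, s2p = _pack_patterns(aln, self.code)
        bad = (patterns >= 0) & (full_to_sub[patterns] < 0)
        if np.any(bad):
            t, p = np.argwhere(bad)[0]
            raise ModelError(
                f"observed codon with zero equilibrium frequency (taxon row {t}, "
                f"pattern {p}); widen the frequency model"
            )
        self.patterns = np.where(patterns >= 0, full_to_sub[patterns], self.m)
        self.weights = weights
        self.site_to_pattern = s2p
        self.idx = _TreeIndex(tree, aln.taxa)
        self.pi_sub = self.pi[self.support]

    def _sub_P(self, P: np.ndarray) -> np.ndarray:
        """Restrict a full 61x61 P to the support, with a trailing all-ones
        row used for missing data."""
        sub = P[np.ix_(self.support, self.support)]
        return np.vstack([sub.T, np.ones(self.m)])  # (m+1, m): row = child state

    def site_loglikes(self, edge_P: Sequence[np.ndarray],
                      return_partials: bool = False):
        """Per-pattern log-likelihood given one P matrix per edge.

        ``edge_P[e]`` is the full-size transition matrix for edge ``e`` in
        ``self.idx.edge_nodes`` order (parent -> child).
        """
        idx = self.idx
        n_pat = self.patterns.shape[1]
        partials = [None] * len(idx.nodes)
        scales = np.zeros(n_pat)
        subs = [self._sub_P(edge_P[e]) for e in range(idx.n_edges)]
        for i, nd in enumerate(idx.nodes):
            if not idx.children[i]:
                continue
            acc = np.ones((n_pat, self.m))
            for c in idx.children[i]:
                sp = subs[idx.edge_of_node[c]]
                if not idx.children[c]:  # leaf child: direct row lookup
                    acc *= sp[self.patterns[idx.leaf_row[c]]]
                else:
                    acc *= partials[c] @ sp[:-1]
            smax = acc.max(axis=1)
            smax[smax == 0] = 1.0
            acc /= smax[:, None]
            scales += np.log(smax)
            partials[i] = acc
            if not return_partials:
                for c in idx.children[i]:
                    partials[c] = None
        like = partials[idx.root] @ self.pi_sub
        if np.any(like <= 0):
            bad = int(np.flatnonzero(like <= 0)[0])
            site = int(np.flatnonzero(self.site_to_pattern == bad)[0]) + 1
            raise ModelError(f"zero site likelihood at codon site {site}")
        out = np.log(like) + scales
        if return_partials:
            return out, partials, scales, subs
        return out

    def mixture_loglike(self, classes: Sequence[tuple]) -> float:
        """Total lnL for a mixture: classes = [(weight, edge_P list), ...]."""
        logs = np.stack([np.log(w) + self.site_loglikes(eP) for w, eP in classes])
        sitewise = logsumexp_axis0(logs)
        return float(np.dot(self.weights, sitewise))


def logsumexp_axis0(a: np.ndarray) -> np.ndarray:
    amax = a.max(axis=0)
    return amax + np.log(np.exp(a - amax).sum(axis=0))


# ---------------------------------------------------------------------------
# model fits


@dataclass
class ModelFit:
    """A fitted codon model: parameters, branch lengths and log-likelihood."""

    model_name: str
    kappa: float
    lnL: float
    n_params: int
    pi: np.ndarray
    tree: dendropy.Tree
    branch_lengths: Mapping[str, float]
    omega: float | None = None
    site_class_omegas: np.ndarray | None = None
    proportions: np.ndarray | None = None
    branch_omegas: Mapping[str, float] | None = None
    foreground: tuple = ()
    beta_p: float | None = None
    beta_q: float | None = None
    omega_s: float | None = None
    # branch-site: per-class (background, foreground) omegas
    class_branch_omegas: Sequence[tuple] | None = None
    #: raw optimiser parameters on the natural scale (for warm starts)
    params: Mapping | None = None
    n_starts: int = 1
    converged: bool = True

    def describe(self) -> str:
        bits = [f"{self.model_name}: lnL={self.lnL:.6f} np={self.n_params} "
                f"kappa={self.kappa:.4f}"]
        if self.omega is not None:
            bits.append(f"omega={self.omega:.4f}")
        if self.site_class_omegas is not None:
            om = " ".join(f"{w:.4f}" for w in self.site_class_omegas)
            pr = " ".join(f"{p:.4f}" for p in self.proportions)
            bits.append(f"class omegas=[{om}] proportions=[{pr}]")
        if self.branch_omegas:
            bits.append(f"branch omegas={dict(self.branch_omegas)}")
        return "  ".join(bits)


@dataclass
class LRTResult:
    """Likelihood-ratio test between nested fits: 2*dlnL ~ chi^2_df."""

    lnL_null: float
    lnL_alt: float
    two_delta_lnL: float
    df: int
    p_value: float


@dataclass
class SitePosterior:
    """Naive empirical-Bayes posteriors over site classes (rows sum to 1)."""

    class_omegas: np.ndarray
    proportions: np.ndarray
    posteriors: np.ndarray  # (n_sites, n_classes)
    positive_classes: np.ndarray  # boolean mask over classes (omega > 1)

    @property
    def pr_positive(self) -> np.ndarray:
        return self.posteriors[:, self.positive_classes].sum(axis=1)

    def flagged_sites(self, threshold: float = 0.5) -> np.ndarray:
        """1-based codon sites with Pr(omega > 1) above the threshold."""
        return np.flatnonzero(self.pr_positive > threshold) + 1


def _resolve_foreground(idx: _TreeIndex, foreground_branches) -> np.ndarray:
    """Boolean foreground mask over edges.

    Branches are named by a leaf label, an internal-node label, or a
    set/list of leaf labels (the stem edge of that clade).
    """
    mask = np.zeros(idx.n_edges, dtype=bool)
    if not foreground_branches:
        return mask
    leafsets = []
    for i in idx.edge_nodes:
        nd = idx.nodes[i]
        leafsets.append(frozenset(lf.taxon.label for lf in nd.leaf_iter()))
    labels = idx.edge_labels()
    for item in foreground_branches:
        if isinstance(item, str):
            hits = [e for e, lab in enumerate(labels) if lab == item]
        else:
            want = frozenset(item)
            hits = [e for e, ls in enumerate(leafsets) if ls == want]
        if not hits:
            raise ModelError(f"foreground branch {item!r} not found on the tree")
        for e in hits:
            mask[e] = True
    return mask


def _beta_category_omegas(p: float, q: float, k: int = 10) -> np.ndarray:
    """k equal-probability category means approximated by mid-quantiles."""
    quantiles = (np.arange(k) + 0.5) / k
    return stats.beta.ppf(quantiles, p, q)


class _ModelDef:
    """Free parameters (beyond branch lengths) and class structure per model.

    Parameters are optimised on transformed scales: log for kappa/omegas,
    raw (bounded) for proportions and beta shapes.
    """

    def __init__(self, model_name, fg_mask, n_edges, fixed):
        self.name = model_name
        self.fg = fg_mask
        self.n_edges = n_edges
        self.fixed = dict(fixed or {})
        logk = (np.log(KAPPA_BOUNDS[0]), np.log(KAPPA_BOUNDS[1]))
        logw = (np.log(1e-6), np.log(OMEGA_MAX))
        logw_gt1 = (np.log(1.0 + 1e-8), np.log(OMEGA_MAX))
        logw_lt1 = (np.log(1e-6), np.log(1.0 - 1e-8))
        prop = (_PROP_EPS, 1.0 - _PROP_EPS)
        shape = (0.005, 99.0)
        # name -> (init, bounds); omitted when fixed
        specs = {"kappa": (np.log(2.0), logk)}
        if model_name == "M0":
            specs["omega"] = (np.log(0.2), logw)
        elif model_name == "two_ratio":
            specs["omega0"] = (np.log(0.2), logw)
            if "omega_fg" not in self.fixed:
                specs["omega_fg"] = (np.log(0.5), logw)
        elif model_name == "free_ratio":
            for e in range(n_edges):
                specs[f"omega_{e}"] = (np.log(0.2), logw)
        elif model_name in ("M1a",):
            specs["omega0"] = (np.log(0.1), logw_lt1)
            specs["p0"] = (0.8, prop)
        elif model_name == "M2a":
            specs["omega0"] = (np.log(0.1), logw_lt1)
            specs["p0"] = (0.8, prop)
            specs["p1"] = (0.5, prop)  # fraction of the remainder in class 1
            specs["omega2"] = (np.log(2.0), logw_gt1)
        elif model_name in ("M8", "M8a"):
            specs["p0"] = (0.9, prop)
            specs["beta_p"] = (0.5, shape)
            specs["beta_q"] = (2.0, shape)
            if model_name == "M8":
                specs["omega_s"] = (np.log(2.0), logw_gt1)
        elif model_name in ("branch_site_A", "branch_site_A_null"):
            specs["omega0"] = (np.log(0.1), logw_lt1)
            specs["p0"] = (0.8, prop)
            specs["p1"] = (0.5, prop)
            if model_name == "branch_site_A":
                specs["omega2"] = (np.log(2.0), logw_gt1)
        else:
            raise ModelError(f"unknown model {model_name!r}")
        for k in list(specs):
            if k in self.fixed:
                del specs[k]
        self.param_names = list(specs)
        self.x0 = np.array([specs[k][0] for k in self.param_names])
        self.bounds = [specs[k][1] for k in self.param_names]

    def unpack(self, x: np.ndarray) -> dict:
        params = dict(self.fixed)
        for name, v in zip(self.param_names, x):
            if name.startswith(("kappa", "omega")):
                params[name] = float(np.exp(v))
            else:
                params[name] = float(v)
        # fixed omegas are given on the natural scale
        return params

    def classes(self, params: dict):
        """[(weight, omega spec)] where the omega spec is a scalar or a
        per-edge vector."""
        fg = self.fg
        if self.name == "M0":
            return [(1.0, params["omega"])]
        if self.name == "two_ratio":
            w = np.full(self.n_edges, params["omega0"])
            w[fg] = params["omega_fg"]
            return [(1.0, w)]
        if self.name == "free_ratio":
            w = np.array([params[f"omega_{e}"] for e in range(self.n_edges)])
            return [(1.0, w)]
        if self.name == "M1a":
            p0 = params["p0"]
            return [(p0, params["omega0"]), (1.0 - p0, 1.0)]
        if self.name == "M2a":
            p0, p1 = params["p0"], params["p1"]
            return [
                (p0, params["omega0"]),
                ((1.0 - p0) * p1, 1.0),
                ((1.0 - p0) * (1.0 - p1), params["omega2"]),
            ]
        if self.name in ("M8", "M8a"):
            p0 = params["p0"]
            ws = params.get("omega_s", 1.0)
            cats = _beta_category_omegas(params["beta_p"], params["beta_q"])
            out = [(p0 / len(cats), w) for w in cats]
            out.append((1.0 - p0, ws))
            return out
        # branch-site classes carry per-branch omegas and are expanded by the
        # caller via _branch_site_class_table
        raise ModelError(f"no site-class expansion for {self.name}")

    def n_free(self) -> int:
        return len(self.param_names)


def _branch_site_class_table(params: dict, fg: np.ndarray, n_edges: int):
    """Branch-site model A classes: (weight, background omega, foreground omega)."""
    p0, p1 = params["p0"], params["p1"]
    # p0, p1 are optimised as sticks: q0 = p0, q1 = (1-p0)*p1 are the class-0/1
    # weights; the remainder splits proportionally between 2a and 2b.
    q0 = p0
    q1 = (1.0 - p0) * p1
    rest = 1.0 - q0 - q1
    denom = q0 + q1
    q2a = rest * q0 / denom
    q2b = rest * q1 / denom
    w0 = params["omega0"]
    w2 = params.get("omega2", 1.0)
    return [
        (q0, w0, w0),
        (q1, 1.0, 1.0),
        (q2a, w0, w2),
        (q2b, 1.0, w2),
    ]


def _clone_for_fit(tree: dendropy.Tree) -> dendropy.Tree:
    """Deep clone, derooted so branch lengths are identifiable (a bifurcating
    root's two edges are merged)."""
    t = tree.clone(depth=1)
    if len(t.seed_node.child_nodes()) == 2:
        t.deroot()
    return t


def fit_model(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    model_name: str,
    foreground_branches: Iterable | None = None,
    fixed_params: Mapping | None = None,
    n_starts: int = 3,
    seed: int = 0,
    code: GeneticCode | None = None,
    pi: np.ndarray | None = None,
    init: "ModelFit | None" = None,
    maxiter: int = 500,
) -> ModelFit:
    """Maximum-likelihood fit of a codon model on a fixed topology.

    Branch lengths and all model parameters are optimised jointly with
    L-BFGS-B from ``n_starts`` seeded starting points (the first start is a
    deterministic heuristic; an optional ``init`` fit contributes a warm
    start, which also guarantees nesting relations like lnL(M2a) >= lnL(M1a)).
    """
    if model_name not in MODEL_NAMES:
        raise ModelError(f"unsupported model {model_name!r}")
    if model_name in ("two_ratio", "branch_site_A", "branch_site_A_null") and not foreground_branches:
        raise ModelError(f"{model_name} requires foreground_branches")
    code = code or standard_code()
    if pi is None:
        pi = f3x4_frequencies(aln, code)
    work = _clone_for_fit(tree)
    engine = PruningEngine(aln, work, pi, code)
    idx = engine.idx
    fg = _resolve_foreground(idx, foreground_branches)
    mdef = _ModelDef(model_name, fg, idx.n_edges, fixed_params)
    is_bs = model_name in ("branch_site_A", "branch_site_A_null")

    t0 = np.clip(np.array([idx.lengths0[i] for i in idx.edge_nodes]),
                 *BRLEN_BOUNDS)
    x0 = np.concatenate([np.log(t0), mdef.x0])
    bounds = [(np.log(BRLEN_BOUNDS[0]), np.log(BRLEN_BOUNDS[1]))] * idx.n_edges
    bounds += mdef.bounds
    E = idx.n_edges

    def edge_P_for(omega_spec, kappa, t, props):
        """One P matrix per edge for a scalar or per-edge omega; props caches
        propagators by omega within one objective evaluation."""

        def prop_for(key):
            if key not in props:
                props[key] = Propagator(build_q(kappa, key, pi, code), pi)
            return props[key]

        if np.isscalar(omega_spec) or np.ndim(omega_spec) == 0:
            return prop_for(float(omega_spec)).expm_many(t)
        om = np.asarray(omega_spec, dtype=float)
        out = [None] * E
        for key in np.unique(om):
            idx = np.flatnonzero(om == key)
            for e, P in zip(idx, prop_for(float(key)).expm_many(t[idx])):
                out[e] = P
        return out

    def mixture_for(x):
        t = np.exp(x[:E])
        params = mdef.unpack(x[E:])
        kappa = params["kappa"]
        props = {}
        if is_bs:
            table = _branch_site_class_table(params, fg, E)
            classes = [
                (max(w, 1e-300), edge_P_for(np.where(fg, wf, wb), kappa, t, props))
                for w, wb, wf in table
            ]
            return classes, params
        classes = []
        for w, om in mdef.classes(params):
            classes.append((max(w, 1e-300), edge_P_for(om, kappa, t, props)))
        return classes, params

    def negloglike(x):
        try:
            classes, _ = mixture_for(x)
            return -engine.mixture_loglike(classes)
        except (ModelError, np.linalg.LinAlgError):
            return 1e12

    starts = [x0]
    if init is not None:
        starts.insert(0, _warm_start(init, mdef, idx, E))
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts:
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        width = np.minimum(hi - lo, 2.0)
        pert = x0 + rng.uniform(-0.5, 0.5, size=len(x0)) * width
        starts.append(np.clip(pert, lo, hi))

    best_x, best_f, success = None, np.inf, False
    for s in starts:
        f0 = negloglike(s)
        if f0 < best_f:
            best_x, best_f = s, f0
        res = optimize.minimize(
            negloglike, s, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
            success = bool(res.success)
    if best_x is None or not np.isfinite(best_f):
        raise ModelError(f"optimisation failed for {model_name}")

    x = best_x
    t_hat = np.exp(x[:E])
    params = mdef.unpack(x[E:])
    labels = idx.edge_labels()
    # write fitted lengths back onto the work tree
    for e, i in enumerate(idx.edge_nodes):
        idx.nodes[i].edge.length = float(t_hat[e])
    branch_lengths = {labels[e]: float(t_hat[e]) for e in range(E)}

    fit = ModelFit(
        model_name=model_name,
        kappa=params["kappa"],
        lnL=-float(best_f),
        n_params=E + mdef.n_free(),
        pi=pi,
        tree=work,
        branch_lengths=branch_lengths,
        foreground=tuple(np.flatnonzero(fg)),
        params=params,
        n_starts=len(starts),
        converged=success,
    )
    if model_name == "M0":
        fit.omega = params["omega"]
    elif model_name == "two_ratio":
        fit.omega = params["omega0"]
        fit.branch_omegas = {
            labels[e]: (params.get("omega_fg", 1.0) if fg[e] else params["omega0"])
            for e in range(E)
        }
    elif model_name == "free_ratio":
        fit.branch_omegas = {labels[e]: params[f"omega_{e}"] for e in range(E)}
    elif model_name in ("M1a", "M2a"):
        cls = mdef.classes(params)
        fit.site_class_omegas = np.array([c[1] for c in cls])
        fit.proportions = np.array([c[0] for c in cls])
    elif model_name in ("M8", "M8a"):
        cls = mdef.classes(params)
        fit.site_class_omegas = np.array([c[1] for c in cls])
        fit.proportions = np.array([c[0] for c in cls])
        fit.beta_p = params["beta_p"]
        fit.beta_q = params["beta_q"]
        fit.omega_s = params.get("omega_s", 1.0)
    elif is_bs:
        table = _branch_site_class_table(params, fg, E)
        fit.proportions = np.array([c[0] for c in table])
        fit.class_branch_omegas = [(wb, wf) for _, wb, wf in table]
        fit.site_class_omegas = np.array([wf for _, _, wf in table])
        fit.omega = params["omega0"]
    return fit


def _warm_start(init: ModelFit, mdef: _ModelDef, idx: _TreeIndex, E: int) -> np.ndarray:
    """Map a previous fit's parameters into this model's start vector."""
    labels = idx.edge_labels()
    t = np.array([
        np.clip(init.branch_lengths.get(lab, 0.05), *BRLEN_BOUNDS)
        for lab in labels
    ])
    x = [np.log(t)]
    vals = []
    src = dict(init.params or {})
    src.setdefault("kappa", init.kappa)
    defaults = {
        "kappa": init.kappa,
        "omega": init.omega if init.omega is not None else 0.2,
        "omega0": None,
        "p0": None,
        "p1": 0.5,
        "omega2": 1.5,
        "omega_fg": init.omega if init.omega is not None else 0.5,
        "omega_s": init.omega_s if init.omega_s else 1.5,
        "beta_p": init.beta_p if init.beta_p else 0.5,
        "beta_q": init.beta_q if init.beta_q else 2.0,
    }
    for k, v in defaults.items():
        src.setdefault(k, v)
    if init.site_class_omegas is not None and init.proportions is not None:
        # fall back to class summaries only when raw parameters are absent
        src.setdefault(
            "omega0", float(min(max(init.site_class_omegas[0], 1e-5), 1 - 1e-6))
        )
        src.setdefault(
            "p0", float(np.clip(init.proportions[0], _PROP_EPS, 1 - _PROP_EPS))
        )
    for name in mdef.param_names:
        if name.startswith("omega_") and name[6:].isdigit():
            v = init.omega if init.omega is not None else 0.2
            vals.append(np.log(max(v, 1e-6)))
            continue
        v = src.get(name)
        if v is None:
            v = {"omega0": 0.1, "p0": 0.8}.get(name, 0.5)
        if name.startswith(("kappa", "omega")):
            vals.append(np.log(max(float(v), 1e-6)))
        else:
            vals.append(float(v))
    x.append(np.array(vals))
    out = np.concatenate(x)
    lo = np.array([np.log(BRLEN_BOUNDS[0])] * E + [b[0] for b in mdef.bounds])
    hi = np.array([np.log(BRLEN_BOUNDS[1])] * E + [b[1] for b in mdef.bounds])
    return np.clip(out, lo, hi)


def log_likelihood(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    fit: ModelFit | None = None,
    *,
    kappa: float | None = None,
    omega=None,
    pi: np.ndarray | None = None,
    code: GeneticCode | None = None,
    site_classes: Sequence[tuple] | None = None,
) -> float:
    """Log-likelihood of the alignment on the tree at fixed parameters.

    Either pass a :class:`ModelFit` (its kappa/omega/pi are used with the
    *given* tree's branch lengths) or kappa/omega (scalar, per-edge mapping,
    or ``site_classes`` = [(weight, omega), ...]).
    """
    code = code or standard_code()
    if fit is not None:
        kappa = fit.kappa
        pi = fit.pi if pi is None else pi
        if omega is None and site_classes is None:
            if fit.site_class_omegas is not None:
                site_classes = list(zip(fit.proportions, fit.site_class_omegas))
            elif fit.branch_omegas is not None:
                omega = fit.branch_omegas
            else:
                omega = fit.omega
    if kappa is None:
        raise ModelError("kappa required")
    if pi is None:
        pi = f3x4_frequencies(aln, code)
    engine = PruningEngine(aln, tree, pi, code)
    idx = engine.idx
    t = np.array([idx.lengths0[i] for i in idx.edge_nodes], dtype=float)
    if np.any(t < 0):
        raise ModelError("negative branch length on the tree")
    labels = idx.edge_labels()

    def per_edge(omega_spec):
        if isinstance(omega_spec, Mapping):
            return np.array([omega_spec[lab] for lab in labels])
        return omega_spec

    if site_classes is None:
        site_classes = [(1.0, omega)]
    classes = []
    props = {}

    def prop_for(key):
        if key not in props:
            props[key] = Propagator(build_q(kappa, key, pi, code), pi)
        return props[key]

    for w, om in site_classes:
        om = per_edge(om)
        if np.isscalar(om) or np.ndim(om) == 0:
            eP = prop_for(float(om)).expm_many(t)
        else:
            om = np.asarray(om, dtype=float)
            eP = [None] * idx.n_edges
            for key in np.unique(om):
                sel = np.flatnonzero(om == key)
                for e, P in zip(sel, prop_for(float(key)).expm_many(t[sel])):
                    eP[e] = P
        classes.append((w, eP))
    return engine.mixture_loglike(classes)


def lrt(fit_null: ModelFit, fit_alt: ModelFit) -> LRTResult:
    """Likelihood-ratio test of nested fits: 2*dlnL against chi^2."""
    df = fit_alt.n_params - fit_null.n_params
    if df <= 0:
        raise ModelError("alternative model must have more parameters than the null")
    delta = 2.0 * (fit_alt.lnL - fit_null.lnL)
    if delta < -1e-4:
        warnings.warn(
            f"alternative lnL below null by {-delta / 2:.6g}; consider refitting "
            f"with more starts",
            RuntimeWarning,
            stacklevel=2,
        )
    stat = max(delta, 0.0)
    return LRTResult(
        lnL_null=fit_null.lnL,
        lnL_alt=fit_alt.lnL,
        two_delta_lnL=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
    )


def site_posteriors(fit: ModelFit, aln: CodonAlignment,
                    tree: dendropy.Tree | None = None,
                    code: GeneticCode | None = None) -> SitePosterior:
    """Naive empirical-Bayes posterior site-class probabilities.

    Per-class site likelihoods at the fitted parameters are weighted by the
    fitted class proportions and normalised per site.
    """
    if fit.site_class_omegas is None:
        raise ModelError("site posteriors require a site-class mixture model")
    code = code or standard_code()
    tree = tree if tree is not None else fit.tree
    engine = PruningEngine(aln, tree, fit.pi, code)
    idx = engine.idx
    t = np.array([idx.lengths0[i] for i in idx.edge_nodes], dtype=float)
    fg_omegas = fit.site_class_omegas
    loglikes = []
    if fit.class_branch_omegas is not None:  # branch-site: per-edge omegas
        fg_mask = np.zeros(idx.n_edges, dtype=bool)
        for e in fit.foreground:
            if e < idx.n_edges:
                fg_mask[e] = True
        for (wb, wf) in fit.class_branch_omegas:
            om = np.where(fg_mask, wf, wb)
            props = {}
            eP = []
            for e in range(idx.n_edges):
                key = float(om[e])
                if key not in props:
                    props[key] = Propagator(build_q(fit.kappa, key, fit.pi, code), fit.pi)
                eP.append(props[key].expm(t[e]))
            loglikes.append(engine.site_loglikes(eP))
    else:
        for om in fg_omegas:
            prop = Propagator(build_q(fit.kappa, float(om), fit.pi, code), fit.pi)
            eP = [prop.expm(te) for te in t]
            loglikes.append(engine.site_loglikes(eP))
    L = np.stack(loglikes)  # (n_classes, n_patterns)
    logw = np.log(np.maximum(fit.proportions, 1e-300))[:, None]
    post = L + logw
    post -= logsumexp_axis0(post)[None, :]
    post = np.exp(post).T  # (n_patterns, n_classes)
    post_sites = post[engine.site_to_pattern]
    return SitePosterior(
        class_omegas=np.asarray(fg_omegas, dtype=float),
        proportions=np.asarray(fit.proportions, dtype=float),
        posteriors=post_sites,
        positive_classes=np.asarray(fg_omegas, dtype=float) > 1.0,
    )
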