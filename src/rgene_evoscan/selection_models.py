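"""GY94 codon-model likelihood engine.

Implements the Goldman–Yang (1994) codon substitution process and the two
fits used throughout the selection screen:

* **M0** — a single dN/dS ratio (omega) shared by all sites and branches.
* **M7 vs M8** — the beta site-model pair: M7 draws per-site omega from a
  Beta(p, q) on (0, 1); M8 adds one extra class with omega_s >= 1 and
  proportion p1. Twice the log-likelihood difference (``2Δln``) is referred
  to a chi-square with 2 degrees of freedom; the conventional critical
  values are 5.991 (P < 0.05) and 9.210 (P < 0.01).

The rate generator is reversible, so likelihoods are invariant to the root
placement. Transition probabilities are obtained from a symmetric
eigendecomposition, which makes repeated evaluation across branches and
site classes cheap enough for simulation studies.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from ._codons import (
    AMINO_ACID,
    CODON_INDEX,
    N_SENSE,
    SENSE_CODONS,
    is_transition,
    ng86_site_fractions,
)

# critical values of chi-square(df=2): 5.991 (alpha=.05), 9.210 (alpha=.01)
LRT_DF = 2


def chi2_critical(alpha: float, df: int = LRT_DF) -> float:
    """Upper-tail chi-square critical value used by the likelihood-ratio
    test between nested site models."""
    return float(stats.chi2.ppf(1.0 - alpha, df))


def tier_from_two_delta_ln(two_delta_ln: float) -> str:
    """Map a 2Δln statistic to its significance tier.

    ``"**"`` above the P<0.01 critical value (9.210), ``"*"`` above the
    P<0.05 value (5.991), else ``"ns"``.
    """
    if two_delta_ln > chi2_critical(0.01):
        return "**"
    if two_delta_ln > chi2_critical(0.05):
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# rate generator
# ---------------------------------------------------------------------------

def _change_structure():
    """Static 61x61 masks: single-position changes, transitions, synonymy."""
    single = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    ts = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    syn = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if a[k] != b[k]]
            if len(diff) != 1:
                continue
            single[i, j] = True
            k = diff[0]
            if is_transition(a[k], b[k]):
                ts[i, j] = True
            if AMINO_ACID[a] == AMINO_ACID[b]:
                syn[i, j] = True
    return single, ts, syn


_SINGLE, _TS, _SYN = _change_structure()


def uniform_codon_frequencies() -> np.ndarray:
    return np.full(N_SENSE, 1.0 / N_SENSE)


def f3x4_frequencies(codon_matrix: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from an integer codon matrix (gaps = -1).

    Position-specific nucleotide frequencies are taken over all observed
    codons and multiplied across the three positions, then renormalized over
    the 61 sense codons.
    """
    counts = np.zeros((3, 4))
    nt_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    observed = codon_matrix[codon_matrix >= 0]
    if observed.size == 0:
        return uniform_codon_frequencies()
    for idx in observed.ravel():
        codon = SENSE_CODONS[idx]
        for pos in range(3):
            counts[pos, nt_index[codon[pos]]] += 1
    freqs = (counts + 0.5) / (counts + 0.5).sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, nt_index[c[0]]] * freqs[1, nt_index[c[1]]] * freqs[2, nt_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def gy94_generator(
    kappa: float,
    omega: float,
    pi: np.ndarray | None = None,
    scale: str = "codon",
) -> np.ndarray:
    """Build the 61x61 GY94 rate generator.

    Off-diagonal rates are zero between codons differing at more than one
    position; otherwise ``pi_j * kappa^[transition] * omega^[nonsynonymous]``.
    Rows sum to zero.

    scale:
        ``"codon"``      — expected substitutions per codon per unit branch = 1
        ``"synonymous"`` — expected synonymous substitutions per synonymous
                           site (Nei–Gojobori site counting) per unit branch
                           = 1, i.e. branch lengths are on the Ks scale
        ``"none"``       — raw rates
    """
    if kappa < 0 or omega < 0:
        raise ValueError("kappa and omega must be nonnegative")
    if pi is None:
        pi = uniform_codon_frequencies()
    pi = np.asarray(pi, dtype=float)
    q = np.where(_SINGLE, np.tile(pi, (N_SENSE, 1)), 0.0)
    q = q * np.where(_TS, kappa, 1.0)
    q = q * np.where(_SYN, 1.0, omega)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale == "codon":
        rate = -(pi * np.diag(q)).sum()
        if rate > 0:
            q = q / rate
    elif scale == "synonymous":
        syn_flow = (pi[:, None] * np.where(_SYN, q, 0.0)).sum()
        syn_sites = float((pi * ng86_site_fractions()).sum())
        if syn_flow > 0:
            q = q * (syn_sites / syn_flow)
    elif scale != "none":
        raise ValueError(f"unknown scale {scale!r}")
    return q


class TransitionKernel:
    """Eigendecomposition of a reversible generator, giving P(t) cheaply.

    For a reversible Q with stationary distribution pi, ``D^1/2 Q D^-1/2``
    is symmetric; one ``eigh`` then yields P(t) for any t via two matrix
    products.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        b = (q * d[:, None]) / d[None, :]
        b = 0.5 * (b + b.T)  # symmetrize roundoff
        lam, v = np.linalg.eigh(b)
        self.lam = lam
        self.left = v / d[:, None]
        self.right = v.T * d[None, :]

    def probability(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.lam * t)) @ self.right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


# ---------------------------------------------------------------------------
# alignment and tree plumbing
# ---------------------------------------------------------------------------

def encode_codon_alignment(sequences: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Encode gene -> aligned codon string into an integer matrix.

    Codons containing gaps or ambiguity characters become -1 (missing data).
    """
    names = list(sequences)
    if not names:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    (length,) = lengths
    if length % 3:
        raise ValueError("alignment length must be a multiple of 3")
    nsites = length // 3
    mat = np.full((len(names), nsites), -1, dtype=np.int16)
    for r, name in enumerate(names):
        seq = sequences[name].upper()
        for k in range(nsites):
            codon = seq[3 * k : 3 * k + 3]
            mat[r, k] = CODON_INDEX.get(codon, -1)
    return names, mat


def _site_patterns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(mat.T, axis=0, return_counts=True)
    return patterns.T.copy(), counts.astype(float)


@dataclasses.dataclass
class _FlatTree:
    """Postorder flattening of a dendropy tree for pruning."""

    n_leaves: int
    n_nodes: int
    postorder: list[tuple[int, list[int]]]  # (node, children) internal only
    branch_lengths: np.ndarray  # per node, length of edge above
    root: int
    leaf_row: dict[int, int]  # node id -> alignment row


def flatten_tree(tree, names: Sequence[str]) -> _FlatTree:
    row_of = {n: i for i, n in enumerate(names)}
    ids: dict = {}
    post = []
    lengths = []
    leaf_row = {}
    for node in tree.postorder_node_iter():
        ids[node] = len(ids)
        lengths.append(node.edge.length or 0.0)
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            if label not in row_of:
                raise KeyError(f"leaf {label!r} not found in alignment")
            leaf_row[ids[node]] = row_of[label]
        else:
            post.append((ids[node], [ids[c] for c in node.child_nodes()]))
    return _FlatTree(
        n_leaves=len(leaf_row),
        n_nodes=len(ids),
        postorder=post,
        branch_lengths=np.asarray(lengths),
        root=ids[tree.seed_node],
        leaf_row=leaf_row,
    )


class StackedKernels:
    """Eigendecompositions for all site classes at once.

    The classes share a single rate normalization — one expected
    substitution per codon per unit branch *averaged over classes* — so a
    class with higher omega genuinely evolves faster, as in the standard
    site-model construction. Normalizing each class separately would
    silently remove the between-class rate signal the M7/M8 contrast
    relies on.
    """

    def __init__(self, kappa, omegas, weights, pi):
        qs = np.stack(
            [gy94_generator(kappa, w, pi=pi, scale="none") for w in omegas]
        )
        diag = np.einsum("kii->ki", qs)
        rates = -(diag @ pi)
        mean_rate = float(np.dot(np.asarray(weights, dtype=float), rates))
        if mean_rate <= 0:
            mean_rate = 1.0
        qs /= mean_rate
        d = np.sqrt(pi)
        b = qs * d[None, :, None] / d[None, None, :]
        b = 0.5 * (b + np.transpose(b, (0, 2, 1)))
        lam, v = np.linalg.eigh(b)
        self.lam = lam  # (k, 61)
        self.left = v / d[None, :, None]
        self.right = np.transpose(v, (0, 2, 1)) * d[None, None, :]

    def probability(self, t: float) -> np.ndarray:
        """Stacked P(t), shape (n_classes, 61, 61)."""
        p = (self.left * np.exp(self.lam * t)[:, None, :]) @ self.right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p


def mixture_kernels(
    kappa: float,
    omegas: Sequence[float],
    weights: Sequence[float],
    pi: np.ndarray,
) -> StackedKernels:
    return StackedKernels(kappa, omegas, weights, pi)


def _class_pattern_loglik(
    flat: _FlatTree,
    patterns: np.ndarray,
    kernels: StackedKernels,
    pi: np.ndarray,
    branch_scale: float,
) -> np.ndarray:
    """Per-(class, pattern) log-likelihoods via Felsenstein pruning,
    all site classes propagated together."""
    npat = patterns.shape[1]
    nclass = kernels.lam.shape[0]
    leaf_partial = {}
    for node_id, row in flat.leaf_row.items():
        partial = np.zeros((N_SENSE, npat))
        obs = patterns[row]
        missing = obs < 0
        partial[:, missing] = 1.0
        cols = np.nonzero(~missing)[0]
        partial[obs[cols], cols] = 1.0
        leaf_partial[node_id] = partial
    pmats = {
        node_id: kernels.probability(flat.branch_lengths[node_id] * branch_scale)
        for node_id in range(flat.n_nodes)
        if node_id != flat.root
    }
    partials: dict[int, np.ndarray] = {}  # (nclass, 61, npat)
    logscale = np.zeros((nclass, npat))
    for node_id, children in flat.postorder:
        acc = np.ones((nclass, N_SENSE, npat))
        for child in children:
            child_partial = partials.get(child)
            if child_partial is None:
                child_partial = leaf_partial[child]  # broadcast over classes
            acc *= pmats[child] @ child_partial
        mx = acc.max(axis=1)
        mx[mx == 0.0] = 1.0
        acc /= mx[:, None, :]
        logscale += np.log(mx)
        partials[node_id] = acc
    site_lik = np.einsum("i,kip->kp", pi, partials[flat.root])
    return np.log(np.maximum(site_lik, 1e-300)) + logscale


def log_likelihood(
    sequences: dict[str, str],
    tree,
    kappa: float,
    omegas: Sequence[float] = (1.0,),
    weights: Sequence[float] | None = None,
    pi: np.ndarray | None = None,
    branch_scale: float = 1.0,
) -> float:
    """Log-likelihood of a codon alignment on a tree under a (mixture of)
    GY94 models. ``omegas``/``weights`` define the site-class mixture; gap
    codons are treated as missing data."""
    names, mat = encode_codon_alignment(sequences)
    if pi is None:
        pi = uniform_codon_frequencies()
    if weights is None:
        weights = np.full(len(omegas), 1.0 / len(omegas))
    weights = np.asarray(weights, dtype=float)
    patterns, counts = _site_patterns(mat)
    if len(names) == 1:
        obs = patterns[0]
        site_ll = np.where(obs >= 0, np.log(pi[np.maximum(obs, 0)]), 0.0)
        return float((site_ll * counts).sum())
    flat = flatten_tree(tree, names)
    kernels = mixture_kernels(kappa, omegas, weights, pi)
    ll = _class_pattern_loglik(flat, patterns, kernels, pi, branch_scale)
    site = logsumexp(ll + np.log(weights)[:, None], axis=0)
    return float((site * counts).sum())


# ---------------------------------------------------------------------------
# site-class constructions
# ---------------------------------------------------------------------------

def beta_class_omegas(p: float, q: float, k: int = 10) -> np.ndarray:
    """Discretize Beta(p, q) on (0,1) into k equal-probability classes,
    with each class omega at the bin median."""
    if k < 3:
        raise ValueError("k must be >= 3")
    quantiles = (2 * np.arange(k) + 1) / (2 * k)
    return stats.beta.ppf(quantiles, p, q)


def m8_classes(
    p: float, q: float, p1: float, omega_s: float, k: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    omegas = np.concatenate([beta_class_omegas(p, q, k), [omega_s]])
    weights = np.concatenate([np.full(k, (1.0 - p1) / k), [p1]])
    return omegas, weights


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FitResult:
    log_likelihood: float
    params: dict
    converged: bool
    n_eval: int = 0


@dataclasses.dataclass
class SelectionTestResult:
    """Per-family selection summary mirroring the screen's report columns."""

    family_id: str
    omega_m0: float | None
    kappa_m0: float | None
    lnl_m7: float | None
    lnl_m8: float | None
    two_delta_ln: float | None
    tier: str | None
    positive_sites: list[int] = dataclasses.field(default_factory=list)
    converged: bool = True


class _LikelihoodMachine:
    """Caches the pattern table and tree flattening across optimizer calls."""

    def __init__(self, sequences, tree, pi=None, ncat: int = 10):
        self.names, mat = encode_codon_alignment(sequences)
        self.pi = f3x4_frequencies(mat) if pi is None else np.asarray(pi)
        self.patterns, self.counts = _site_patterns(mat)
        self.flat = flatten_tree(tree, self.names)
        self.ncat = ncat
        self.n_eval = 0
        if mat.shape[0] < 2:
            raise ValueError("need at least 2 sequences")
        a = mat[:, None, :]
        self.any_variation = bool(
            np.any((a >= 0) & (mat[None, :, :] >= 0) & (a != mat[None, :, :]))
        )

    def class_loglik(self, kappa, omegas, weights, branch_scale) -> np.ndarray:
        self.n_eval += 1
        kernels = mixture_kernels(kappa, np.atleast_1d(omegas), weights, self.pi)
        return _class_pattern_loglik(
            self.flat, self.patterns, kernels, self.pi, branch_scale
        )

    def mixture_lnl(self, kappa, omegas, weights, branch_scale) -> float:
        ll = self.class_loglik(kappa, omegas, weights, branch_scale)
        site = logsumexp(ll + np.log(np.asarray(weights))[:, None], axis=0)
        return float((site * self.counts).sum())


def _minimize_multistart(fun, starts, bounds, maxiter=150, ftol=1e-8):
    best = None
    for x0 in starts:
        res = optimize.minimize(
            fun,
            np.asarray(x0, dtype=float),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": ftol},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_m0(
    sequences: dict[str, str],
    tree,
    pi: np.ndarray | None = None,
    min_members: int = 3,
) -> FitResult:
    """Fit the single-ratio model: free (omega, kappa, branch scale).

    Families with fewer than ``min_members`` sequences are not estimated
    (the screen reports them as "–"); alignments with no observed
    substitutions leave omega unidentifiable and are flagged unconverged.
    """
    if len(sequences) < min_members:
        raise ValueError(f"M0 requires at least {min_members} sequences")
    machine = _LikelihoodMachine(sequences, tree, pi=pi)
    if not machine.any_variation:
        return FitResult(
            log_likelihood=machine.mixture_lnl(2.0, [1.0], [1.0], 1.0),
            params={"omega": float("nan"), "kappa": float("nan"), "branch_scale": 1.0},
            converged=False,
        )

    def nll(x):
        lomega, lkappa, lscale = x
        return -machine.mixture_lnl(
            math.exp(lkappa), [math.exp(lomega)], [1.0], math.exp(lscale)
        )

    bounds = [(-8.0, 3.0), (-3.0, 3.5), (-6.0, 4.0)]
    starts = [
        (math.log(0.3), math.log(2.0), 0.0),
        (math.log(1.0), math.log(1.0), 0.0),
        (math.log(0.05), math.log(4.0), math.log(0.5)),
    ]
    res = _minimize_multistart(nll, starts, bounds)
    lomega, lkappa, lscale = res.x
    return FitResult(
        log_likelihood=-res.fun,
        params={
            "omega": math.exp(lomega),
            "kappa": math.exp(lkappa),
            "branch_scale": math.exp(lscale),
        },
        converged=bool(res.success),
        n_eval=machine.n_eval,
    )


def fit_m7(
    sequences: dict[str, str],
    tree,
    pi: np.ndarray | None = None,
    ncat: int = 10,
    fixed_kappa: float | None = None,
    fixed_branch_scale: float | None = None,
) -> FitResult:
    """Fit the beta site model M7: omega ~ Beta(p, q) on (0, 1).

    ``fixed_kappa``/``fixed_branch_scale`` hold the nuisance parameters at
    supplied values (typically profiled from an M0 fit), reducing the
    search to (p, q).
    """
    machine = _LikelihoodMachine(sequences, tree, pi=pi, ncat=ncat)
    weights = np.full(ncat, 1.0 / ncat)
    fix = fixed_kappa is not None and fixed_branch_scale is not None

    def nll(x):
        lp, lq = x[0], x[1]
        kappa = fixed_kappa if fix else math.exp(x[2])
        scale = fixed_branch_scale if fix else math.exp(x[3])
        omegas = beta_class_omegas(math.exp(lp), math.exp(lq), machine.ncat)
        return -machine.mixture_lnl(kappa, omegas, weights, scale)

    if fix:
        bounds = [(-3.0, 4.6), (-3.0, 4.6)]
        starts = [
            (math.log(0.5), math.log(1.5)),
            (math.log(1.0), math.log(1.0)),
            (math.log(2.0), math.log(5.0)),
        ]
    else:
        bounds = [(-3.0, 4.6), (-3.0, 4.6), (-3.0, 3.5), (-6.0, 4.0)]
        starts = [
            (math.log(0.5), math.log(1.5), math.log(2.0), 0.0),
            (math.log(1.0), math.log(1.0), math.log(1.0), 0.0),
            (math.log(2.0), math.log(5.0), math.log(3.0), math.log(0.5)),
        ]
    res = _minimize_multistart(nll, starts, bounds)
    return FitResult(
        log_likelihood=-res.fun,
        params={
            "p": math.exp(res.x[0]),
            "q": math.exp(res.x[1]),
            "kappa": fixed_kappa if fix else math.exp(res.x[2]),
            "branch_scale": fixed_branch_scale if fix else math.exp(res.x[3]),
        },
        converged=bool(res.success),
        n_eval=machine.n_eval,
    )


def fit_m8(
    sequences: dict[str, str],
    tree,
    pi: np.ndarray | None = None,
    ncat: int = 10,
    warm_start: dict | None = None,
    fixed_kappa: float | None = None,
    fixed_branch_scale: float | None = None,
) -> FitResult:
    """Fit M8: M7 plus an extra class (proportion p1) with omega_s >= 1.

    ``warm_start`` may carry fitted M7 parameters (p, q); they seed an
    additional deterministic start near the null boundary, which speeds
    the nested fit considerably. ``fixed_kappa``/``fixed_branch_scale``
    profile the nuisance parameters as in :func:`fit_m7`.
    """
    machine = _LikelihoodMachine(sequences, tree, pi=pi, ncat=ncat)
    fix = fixed_kappa is not None and fixed_branch_scale is not None
    clip = lambda v, lo, hi: min(max(v, lo + 1e-6), hi - 1e-6)

    def unpack(x):
        if fix:
            lp, lq, logit_p1, ls = x
            kappa, scale = fixed_kappa, fixed_branch_scale
        else:
            lp, lq, lkappa, lscale, logit_p1, ls = x
            kappa, scale = math.exp(lkappa), math.exp(lscale)
        p1 = 1.0 / (1.0 + math.exp(-logit_p1))
        omega_s = 1.0 + math.exp(ls)
        return math.exp(lp), math.exp(lq), kappa, scale, p1, omega_s

    def nll(x):
        p, q, kappa, scale, p1, omega_s = unpack(x)
        omegas, weights = m8_classes(p, q, p1, omega_s, machine.ncat)
        return -machine.mixture_lnl(kappa, omegas, weights, scale)

    if fix:
        bounds = [(-3.0, 4.6), (-3.0, 4.6), (-7.0, 4.0), (-7.0, 3.0)]
        starts = [
            (math.log(0.5), math.log(1.5), -2.0, 0.0),
            (math.log(2.0), math.log(5.0), -1.0, 1.0),
        ]
        if warm_start is not None:
            starts.insert(
                0,
                (
                    clip(math.log(warm_start["p"]), *bounds[0]),
                    clip(math.log(warm_start["q"]), *bounds[1]),
                    -4.0,
                    0.0,
                ),
            )
        else:
            starts.append((0.0, 0.0, -4.0, -2.0))
    else:
        bounds = [
            (-3.0, 4.6), (-3.0, 4.6), (-3.0, 3.5),
            (-6.0, 4.0), (-7.0, 4.0), (-7.0, 3.0),
        ]
        starts = [
            (math.log(0.5), math.log(1.5), math.log(2.0), 0.0, -2.0, 0.0),
            (math.log(2.0), math.log(5.0), math.log(3.0), math.log(0.5), -1.0, 1.0),
        ]
        if warm_start is not None:
            starts.insert(
                0,
                (
                    clip(math.log(warm_start["p"]), *bounds[0]),
                    clip(math.log(warm_start["q"]), *bounds[1]),
                    clip(math.log(warm_start["kappa"]), *bounds[2]),
                    clip(math.log(warm_start["branch_scale"]), *bounds[3]),
                    -4.0,
                    0.0,
                ),
            )
        else:
            starts.append(
                (math.log(1.0), math.log(1.0), math.log(1.0), 0.0, -4.0, -2.0)
            )
    res = _minimize_multistart(nll, starts, bounds)
    p, q, kappa, scale, p1, omega_s = unpack(res.x)
    return FitResult(
        log_likelihood=-res.fun,
        params={
            "p": p,
            "q": q,
            "kappa": kappa,
            "branch_scale": scale,
            "p1": p1,
            "omega_s": omega_s,
        },
        converged=bool(res.success),
        n_eval=machine.n_eval,
    )


def positive_site_posteriors(
    sequences: dict[str, str],
    tree,
    m8_params: dict,
    pi: np.ndarray | None = None,
    ncat: int = 10,
) -> np.ndarray:
    """Naive empirical-Bayes posterior, per site, of belonging to a class
    with omega > 1 under the fitted M8 parameters."""
    machine = _LikelihoodMachine(sequences, tree, pi=pi, ncat=ncat)
    omegas, weights = m8_classes(
        m8_params["p"], m8_params["q"], m8_params["p1"], m8_params["omega_s"], ncat
    )
    ll = machine.class_loglik(
        m8_params["kappa"], omegas, weights, m8_params["branch_scale"]
    )
    logpost = ll + np.log(weights)[:, None]
    logpost -= logsumexp(logpost, axis=0)
    pos_mask = omegas > 1.0
    pattern_post = np.exp(logsumexp(logpost[pos_mask], axis=0)) if pos_mask.any() else np.zeros(
        ll.shape[1]
    )
    # map patterns back to sites
    _, mat = encode_codon_alignment(sequences)
    patterns, _ = _site_patterns(mat)
    key = {tuple(patterns[:, j]): pattern_post[j] for j in range(patterns.shape[1])}
    return np.array([key[tuple(mat[:, s])] for s in range(mat.shape[1])])


def lrt_m7_m8(
    sequences: dict[str, str],
    tree,
    family_id: str = "",
    pi: np.ndarray | None = None,
    ncat: int = 10,
    site_cutoff: float = 0.95,
    min_members: int = 3,
    profile_nuisance: bool = True,
) -> SelectionTestResult:
    """Likelihood-ratio test of M8 against M7 for one family alignment.

    With ``profile_nuisance`` (default) the transition/transversion ratio
    and branch scale are estimated once under the single-ratio model and
    held fixed in both site-model fits; both hypotheses share the same
    nuisance values so the test stays nested. Negative 2Δln within
    optimizer tolerance is clamped to zero. Families below ``min_members``
    raise, matching the screen's "three or more members" gate.
    """
    if len(sequences) < min_members:
        raise ValueError(f"LRT requires at least {min_members} sequences")
    fixed_kappa = fixed_scale = None
    m0 = None
    if profile_nuisance:
        m0 = fit_m0(sequences, tree, pi=pi, min_members=min_members)
        if m0.converged:
            fixed_kappa = m0.params["kappa"]
            fixed_scale = m0.params["branch_scale"]
    m7 = fit_m7(
        sequences, tree, pi=pi, ncat=ncat,
        fixed_kappa=fixed_kappa, fixed_branch_scale=fixed_scale,
    )
    m8 = fit_m8(
        sequences, tree, pi=pi, ncat=ncat, warm_start=m7.params,
        fixed_kappa=fixed_kappa, fixed_branch_scale=fixed_scale,
    )
    # M7 is nested in M8 (p1 -> 0), so the alternative's optimum can never
    # be below the null's; a small optimizer deficit is clamped there
    lnl_m8 = max(m8.log_likelihood, m7.log_likelihood)
    m8 = dataclasses.replace(m8, log_likelihood=lnl_m8)
    two_delta = 2.0 * (m8.log_likelihood - m7.log_likelihood)
    if two_delta < 0:
        two_delta = 0.0
    tier = tier_from_two_delta_ln(two_delta)
    sites: list[int] = []
    if tier != "ns":
        post = positive_site_posteriors(sequences, tree, m8.params, pi=pi, ncat=ncat)
        sites = [int(i) for i in np.nonzero(post > site_cutoff)[0]]
    return SelectionTestResult(
        family_id=family_id,
        omega_m0=(m0.params["omega"] if m0 is not None and m0.converged else None),
        kappa_m0=(m0.params["kappa"] if m0 is not None and m0.converged else None),
        lnl_m7=m7.log_likelihood,
        lnl_m8=m8.log_likelihood,
        two_delta_ln=two_delta,
        tier=tier,
        positive_sites=sites,
        converged=m7.converged and m8.converged,
    )
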