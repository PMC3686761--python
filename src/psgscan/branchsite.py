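"""Branch-site codon model A: rate matrices, likelihood, fitting, LRT.

The model follows the Goldman-Yang codon substitution framework on the 61
sense codons. Sites fall into four latent classes with proportions
(p0, p1, p2a, p2b); background branches evolve with omega drawn from
{omega0, 1} and the single foreground branch may use omega2 >= 1 in classes
2a/2b. The null hypothesis fixes omega2 = 1; the alternative estimates it.
Twice the log-likelihood difference is referred to chi-squared with one
degree of freedom (a 50:50 {0, chi2_1} mixture reference is available as an
option for the boundary-respecting variant).

Likelihoods are computed by Felsenstein pruning over site patterns, with
per-node rescaling for numerical stability. Gap and ambiguous codons enter
as missing data: their partial likelihood is 1 over every compatible state.

Branch lengths are measured in expected substitutions per codon under the
background site-class mixture: a single scale factor per parameter vector
normalizes the mixture-averaged substitution rate to 1 (so lengths are
comparable between the null and alternative fits).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .codon_align import CodonAlignment
from .codons import (
    N_CODONS,
    SENSE_CODONS,
    SINGLE_DIFF_PAIRS,
    SINGLE_DIFF_SYNONYMOUS,
    SINGLE_DIFF_TRANSITION,
    codon_state_vector,
)
from .trees import ArrayTree, LabeledTree

__all__ = [
    "CodonFrequencies",
    "BranchSiteParams",
    "FitResult",
    "LRTResult",
    "estimate_codon_frequencies_f3x4",
    "build_rate_matrix",
    "substitution_rate",
    "transition_matrix",
    "model_a_loglik",
    "fit_branch_site",
    "fit_m0",
    "likelihood_ratio_test",
    "branch_site_lrt",
]


# ---------------------------------------------------------------------------
# codon frequencies


@dataclass
class CodonFrequencies:
    """Equilibrium frequencies over the 61 sense codons.

    ``zero_codons`` lists codons assigned zero frequency because a
    position-specific nucleotide frequency was zero (F3x4 artifact); those
    states are excluded from the substitution process.
    """

    pi: np.ndarray
    zero_codons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (N_CODONS,):
            raise ValueError(f"pi must have length {N_CODONS}")
        if (self.pi < 0).any():
            raise ValueError("negative codon frequency")
        total = self.pi.sum()
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"codon frequencies sum to {total}, not 1")

    @classmethod
    def uniform(cls) -> "CodonFrequencies":
        return cls(np.full(N_CODONS, 1.0 / N_CODONS))


def estimate_codon_frequencies_f3x4(caln: CodonAlignment) -> CodonFrequencies:
    """F3x4 codon frequencies: products of position-specific base frequencies.

    Base frequencies are counted per codon position over non-gap, unambiguous
    cells; pi_xyz proportional to f1(x) f2(y) f3(z) over sense codons, then
    normalized. Codons containing a never-observed base get frequency zero
    and are reported in ``zero_codons``.
    """
    counts = np.zeros((3, 4))
    base_index = {b: i for i, b in enumerate("ACGT")}
    for species in caln.species:
        for codon in caln.codons(species):
            codon = codon.upper().replace("U", "T")
            if any(ch not in base_index for ch in codon):
                continue  # gap or ambiguous cell: excluded from counts
            for k, ch in enumerate(codon):
                counts[k, base_index[ch]] += 1
    if counts.sum() == 0:
        raise ValueError("no unambiguous codons in alignment")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, base_index[c[0]]]
            * freqs[1, base_index[c[1]]]
            * freqs[2, base_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    pi /= pi.sum()
    zero = tuple(c for c, p in zip(SENSE_CODONS, pi) if p == 0.0)
    return CodonFrequencies(pi, zero)


# ---------------------------------------------------------------------------
# rate and transition matrices


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unscaled 61x61 Goldman-Yang generator.

    q_ij = pi_j x kappa^[transition] x omega^[nonsynonymous] for codon pairs
    differing at one position, 0 for pairs differing at more than one;
    diagonal entries make rows sum to zero. Scaling to substitutions per
    codon is applied at the site-class-mixture level, not here.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    pi = np.asarray(pi, dtype=float)
    Q = np.zeros((N_CODONS, N_CODONS))
    i, j = SINGLE_DIFF_PAIRS[:, 0], SINGLE_DIFF_PAIRS[:, 1]
    rate = pi[j] * np.where(SINGLE_DIFF_TRANSITION, kappa, 1.0)
    rate *= np.where(SINGLE_DIFF_SYNONYMOUS, 1.0, omega)
    Q[i, j] = rate
    Q[np.diag_indices_from(Q)] = -Q.sum(axis=1)
    return Q


def substitution_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitution rate -sum_i pi_i q_ii of an unscaled generator."""
    return float(-(np.asarray(pi) * np.diag(Q)).sum())


def transition_matrix(Q_scaled: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Q t) for a scaled generator; rows sum to 1, entries >= 0."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    return linalg.expm(np.asarray(Q_scaled) * t)


class _ReversibleExponentiator:
    """Eigendecomposition-based exp(Qt) for a reversible generator.

    Works in the support of pi (states with pi > 0). Since pi_i q_ij =
    pi_j q_ji, B = D^1/2 Q D^-1/2 is symmetric and a single symmetric
    eigendecomposition serves every branch length.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] / sqrt_pi[None, :]) * Q
        evals, U = np.linalg.eigh((B + B.T) / 2.0)
        self._left = U / sqrt_pi[:, None]
        self._right = U.T * sqrt_pi[None, :]
        self._evals = evals

    def matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for an array of branch lengths, shape (n, d, d)."""
        expd = np.exp(np.outer(ts, self._evals))  # (n, d)
        P = np.matmul(self._left[None, :, :] * expd[:, None, :], self._right)
        np.clip(P, 0.0, None, out=P)
        return P


# ---------------------------------------------------------------------------
# model parameters


@dataclass
class BranchSiteParams:
    """Parameters of branch-site model A.

    kappa: transition/transversion rate ratio (> 0).
    omega0: background purifying dN/dS, in [0, 1].
    omega2: foreground dN/dS for classes 2a/2b (>= 1; fixed 1 in the null).
    p0, p1: proportions of the purely-purifying and purely-neutral classes;
    the remainder 1 - p0 - p1 splits into p2a, p2b proportional to p0 : p1.
    """

    kappa: float
    omega0: float
    omega2: float
    p0: float
    p1: float

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0.0 <= self.omega0 <= 1.0:
            raise ValueError("omega0 must lie in [0, 1]")
        if self.omega2 < 1.0 - 1e-12:
            raise ValueError("omega2 must be >= 1")
        if self.p0 < 0 or self.p1 < 0 or self.p0 + self.p1 > 1.0 + 1e-12:
            raise ValueError("need p0, p1 >= 0 and p0 + p1 <= 1")
        if self.p0 + self.p1 == 0:
            raise ValueError("p0 + p1 must be positive")

    @property
    def proportions(self) -> np.ndarray:
        """Class proportions (p0, p1, p2a, p2b); they sum to 1."""
        rest = max(0.0, 1.0 - self.p0 - self.p1)
        denom = self.p0 + self.p1
        return np.array(
            [
                self.p0,
                self.p1,
                rest * self.p0 / denom,
                rest * self.p1 / denom,
            ]
        )

    @property
    def background_omegas(self) -> tuple[float, float, float, float]:
        return (self.omega0, 1.0, self.omega0, 1.0)

    @property
    def foreground_omegas(self) -> tuple[float, float, float, float]:
        return (self.omega0, 1.0, self.omega2, self.omega2)


def mixture_scale(params: BranchSiteParams, pi: np.ndarray) -> float:
    """Expected substitutions/codon/unit-time under the background mixture."""
    props = params.proportions
    r0 = substitution_rate(build_rate_matrix(params.kappa, params.omega0, pi), pi)
    r1 = substitution_rate(build_rate_matrix(params.kappa, 1.0, pi), pi)
    return float((props[0] + props[2]) * r0 + (props[1] + props[3]) * r1)


# ---------------------------------------------------------------------------
# likelihood engine


def _as_pi_array(pi) -> np.ndarray:
    if isinstance(pi, CodonFrequencies):
        return pi.pi
    return np.asarray(pi, dtype=float)


class BranchSiteLikelihood:
    """Pruning likelihood for one alignment/tree pair, reusable across fits.

    Compresses site patterns once and caches leaf partial vectors in the
    support of pi, so repeated evaluations during optimization only rebuild
    transition matrices.
    """

    def __init__(self, caln: CodonAlignment, tree: LabeledTree | ArrayTree, pi):
        self.atree = tree if isinstance(tree, ArrayTree) else ArrayTree.from_labeled(tree)
        pi = _as_pi_array(pi)
        missing = [
            name
            for name in self.atree.leaf_names.values()
            if name not in caln.rows
        ]
        if missing:
            raise ValueError(f"tree species missing from alignment: {sorted(missing)}")
        self.support = pi > 0
        self.pi = pi[self.support]
        self._build_patterns(caln)

    def _build_patterns(self, caln: CodonAlignment) -> None:
        leaf_ids = sorted(self.atree.leaf_names)
        columns = []
        for site in range(caln.n_sites):
            columns.append(
                tuple(
                    caln.codon(self.atree.leaf_names[v], site).upper().replace("U", "T")
                    for v in leaf_ids
                )
            )
        pattern_index: dict[tuple[str, ...], int] = {}
        weights: list[int] = []
        site_to_pattern = []
        for col in columns:
            if col not in pattern_index:
                pattern_index[col] = len(pattern_index)
                weights.append(0)
            weights[pattern_index[col]] += 1
            site_to_pattern.append(pattern_index[col])
        self.n_sites = caln.n_sites
        self.weights = np.array(weights, dtype=float)
        self.site_to_pattern = np.array(site_to_pattern, dtype=np.intp)
        n_patterns = len(pattern_index)
        d = int(self.support.sum())
        self.leaf_partials = {}
        for k, v in enumerate(leaf_ids):
            part = np.empty((d, n_patterns))
            cache: dict[str, np.ndarray] = {}
            for col, p in pattern_index.items():
                codon = col[k]
                if codon not in cache:
                    vec = codon_state_vector(codon)[self.support]
                    if not vec.any():
                        raise ValueError(
                            f"codon {codon} observed but has zero equilibrium "
                            "frequency under pi"
                        )
                    cache[codon] = vec
                part[:, p] = cache[codon]
            self.leaf_partials[v] = part

    # -- core pruning ------------------------------------------------------

    def _prune_classes(
        self, P_stack: np.ndarray, P_fg: np.ndarray | None
    ) -> np.ndarray:
        """Per-class log site-likelihoods by pruning with shared subtrees.

        P_stack has shape (C, n_nodes, d, d) with one slice per background
        class (the root slot is unused). When ``P_fg`` (d, d) is given, the
        foreground-branch variants of all C classes are obtained by
        recomputing only the nodes on the path from the foreground branch to
        the root with P_fg substituted on that branch; the result then has
        2C rows (background classes first, foreground variants after).
        """
        atree = self.atree
        C = P_stack.shape[0]
        partials: list[np.ndarray] = [None] * atree.n_nodes  # type: ignore[list-item]
        cum_ls: list[np.ndarray | None] = [None] * atree.n_nodes
        S = self.weights.shape[0]

        def combine(v: int, child_P) -> tuple[np.ndarray, np.ndarray]:
            acc = None
            ls = np.zeros((C, S))
            for ch in atree.children[v]:
                term = np.matmul(child_P(ch), partials[ch])
                if cum_ls[ch] is not None:
                    ls += cum_ls[ch]
                acc = term if acc is None else acc * term
            m = acc.max(axis=1)  # (C, S)
            m_safe = np.where(m > 0, m, 1.0)
            acc = acc / m_safe[:, None, :]
            with np.errstate(divide="ignore"):
                ls += np.where(m > 0, np.log(m_safe), -np.inf)
            return acc, ls

        for v in range(atree.n_nodes):
            if not atree.children[v]:
                partials[v] = np.broadcast_to(
                    self.leaf_partials[v], (C,) + self.leaf_partials[v].shape
                )
                continue
            partials[v], cum_ls[v] = combine(v, lambda ch: P_stack[:, ch])

        def root_loglik(partial_root, ls_root) -> np.ndarray:
            class_lik = np.einsum("i,cis->cs", self.pi, partial_root)
            with np.errstate(divide="ignore"):
                return np.log(class_lik) + ls_root

        out = [root_loglik(partials[atree.root], cum_ls[atree.root])]
        if P_fg is not None:
            fg = atree.foreground_node
            if fg < 0:
                raise ValueError("tree has no foreground branch label")
            path = []
            v = atree.parent[fg]
            while v != -1:
                path.append(v)
                v = atree.parent[v]
            saved = {v: (partials[v], cum_ls[v]) for v in path}
            for v in path:
                partials[v], cum_ls[v] = combine(
                    v,
                    lambda ch: (
                        np.broadcast_to(P_fg, (C,) + P_fg.shape)
                        if ch == fg
                        else P_stack[:, ch]
                    ),
                )
            out.append(root_loglik(partials[atree.root], cum_ls[atree.root]))
            for v, state in saved.items():
                partials[v], cum_ls[v] = state
        return np.vstack(out)

    def _transition_stacks(
        self, omegas: dict[str, float], kappa: float, lengths: np.ndarray, scale: float
    ) -> dict[str, np.ndarray]:
        """P(t/scale) per branch for each named omega; key -> (n_nodes, d, d)."""
        ts = lengths.copy()
        ts[self.atree.root] = 0.0
        if np.isnan(ts).any() or (ts < 0).any():
            raise ValueError("tree must carry non-negative branch lengths")
        out = {}
        for name, w in omegas.items():
            Q = build_rate_matrix(kappa, w, _expand(self.pi, self.support))
            Qs = Q[np.ix_(self.support, self.support)]
            out[name] = _ReversibleExponentiator(Qs, self.pi).matrices(ts / scale)
        return out

    def _mixture_total(self, logL: np.ndarray, props: np.ndarray) -> float:
        with np.errstate(divide="ignore"):
            A = np.log(props)[:, None] + logL
        M = A.max(axis=0)
        finite = np.isfinite(M)
        site_ll = np.full(M.shape, -np.inf)
        site_ll[finite] = M[finite] + np.log(
            np.exp(A[:, finite] - M[finite]).sum(axis=0)
        )
        return float((self.weights * site_ll).sum())

    def loglik(
        self, params: BranchSiteParams, lengths: np.ndarray | None = None
    ) -> float:
        """Branch-site model A log-likelihood at the given parameter point."""
        atree = self.atree
        if atree.foreground_node < 0:
            raise ValueError("tree has no foreground branch label")
        lengths = atree.lengths if lengths is None else np.asarray(lengths, float)
        scale = mixture_scale(params, _expand(self.pi, self.support))
        need = {"w0": params.omega0, "one": 1.0}
        if params.omega2 not in (params.omega0, 1.0):
            need["w2"] = params.omega2
        stacks = self._transition_stacks(need, params.kappa, lengths, scale)
        w2_key = (
            "w2"
            if "w2" in stacks
            else ("w0" if params.omega2 == params.omega0 else "one")
        )
        # classes 0/1 use background omegas everywhere (foreground included);
        # classes 2a/2b are their foreground-branch variants with omega2
        P_stack = np.stack([stacks["w0"], stacks["one"]])
        P_fg = stacks[w2_key][atree.foreground_node]
        logL = self._prune_classes(P_stack, P_fg)  # rows: 0, 1, 2a, 2b
        return self._mixture_total(logL, params.proportions)

    def loglik_m0(
        self, kappa: float, omega: float, lengths: np.ndarray
    ) -> float:
        """One-ratio (M0) log-likelihood: a single omega on every branch."""
        pi_full = _expand(self.pi, self.support)
        Q = build_rate_matrix(kappa, omega, pi_full)
        scale = substitution_rate(Q, pi_full)
        stacks = self._transition_stacks({"w": omega}, kappa, np.asarray(lengths, float), scale)
        logL = self._prune_classes(stacks["w"][None], None)
        return self._mixture_total(logL, np.array([1.0]))


def _expand(pi_support: np.ndarray, support: np.ndarray) -> np.ndarray:
    pi = np.zeros(support.shape[0])
    pi[support] = pi_support
    return pi


def model_a_loglik(
    caln: CodonAlignment, tree: LabeledTree, params: BranchSiteParams, pi
) -> float:
    """Log-likelihood of branch-site model A (convenience one-shot wrapper)."""
    return BranchSiteLikelihood(caln, tree, pi).loglik(params)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class StartResult:
    omega2_start: float
    params: BranchSiteParams
    lnL: float
    converged: bool
    message: str = ""


@dataclass
class FitResult:
    """All optimization starts plus the index of the best (highest lnL)."""

    starts: list[StartResult]
    best_index: int

    @property
    def best(self) -> StartResult:
        return self.starts[self.best_index]

    @property
    def params(self) -> BranchSiteParams:
        return self.best.params

    @property
    def lnL(self) -> float:
        return self.best.lnL


class FitError(RuntimeError):
    pass


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _pack_init(kappa, omega0, p0, p1, omega2, null: bool) -> np.ndarray:
    p2 = max(1e-4, 1.0 - p0 - p1)
    x = [
        np.log(kappa),
        np.log(omega0 / (1.0 - omega0)),
        np.log(p0 / p2),
        np.log(p1 / p2),
    ]
    if not null:
        x.append(np.log(max(omega2 - 1.0, 1e-6)))
    return np.array(x)


def _unpack(x: np.ndarray, null: bool) -> BranchSiteParams:
    kappa = float(np.exp(x[0]))
    omega0 = float(_sigmoid(x[1]))
    e2, e3 = np.exp(x[2]), np.exp(x[3])
    z = 1.0 + e2 + e3
    p0, p1 = float(e2 / z), float(e3 / z)
    omega2 = 1.0 if null else float(1.0 + np.exp(x[4]))
    return BranchSiteParams(kappa=kappa, omega0=omega0, omega2=omega2, p0=p0, p1=p1)


_BOUNDS = [(-4.6, 4.6), (-16.0, 16.0), (-12.0, 12.0), (-12.0, 12.0)]
_OMEGA2_BOUND = (-13.0, 6.0)  # omega2 in [1 + 2e-6, ~400]


def fit_branch_site(
    caln: CodonAlignment,
    tree: LabeledTree,
    *,
    null: bool = False,
    pi=None,
    omega2_starts: tuple[float, ...] = (0.5, 1.0, 2.0),
    extra_starts: list[BranchSiteParams] | None = None,
    engine: BranchSiteLikelihood | None = None,
    fix_kappa: float | None = None,
) -> FitResult:
    """Maximize the branch-site likelihood from several omega starts.

    Free parameters are (kappa, omega0, p0, p1) and, in the alternative
    model, omega2 >= 1. Each start seeds omega0 (capped below 1) and omega2
    (floored at 1) with the same starting omega; the run with the best
    log-likelihood wins, ties broken by start order. The null model fixes
    omega2 = 1. `fix_kappa` pins kappa instead of estimating it.
    """
    if pi is None:
        pi = estimate_codon_frequencies_f3x4(caln)
    if engine is None:
        engine = BranchSiteLikelihood(caln, tree, pi)
    if not engine.atree.has_lengths:
        raise ValueError("tree must carry branch lengths (fit M0 first)")

    def objective(x: np.ndarray) -> float:
        try:
            if fix_kappa is not None:
                x = np.concatenate([[np.log(fix_kappa)], x])
            params = _unpack(x, null)
            return -engine.loglik(params)
        except (ValueError, FloatingPointError):
            return 1e12

    starts: list[StartResult] = []
    inits: list[tuple[float, np.ndarray]] = []
    for w in omega2_starts:
        omega0_init = min(max(w, 0.05), 0.9)
        omega2_init = max(w, 1.001)
        inits.append(
            (w, _pack_init(2.0, omega0_init, 0.75, 0.15, omega2_init, null))
        )
    for p in extra_starts or []:
        inits.append(
            (
                p.omega2,
                _pack_init(
                    p.kappa,
                    min(max(p.omega0, 1e-6), 1.0 - 1e-9),
                    max(p.p0, 1e-6),
                    max(p.p1, 1e-6),
                    max(p.omega2, 1.0 + 1e-5),
                    null,
                ),
            )
        )
    bounds = _BOUNDS + ([] if null else [_OMEGA2_BOUND])
    if fix_kappa is not None:
        bounds = bounds[1:]
        inits = [(w, x0[1:]) for w, x0 in inits]
    n_failed = 0
    for w_start, x0 in inits:
        res = optimize.minimize(
            objective,
            np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-11, "gtol": 1e-6, "eps": 1e-6, "maxiter": 500},
        )
        if not np.isfinite(res.fun):
            n_failed += 1
            continue
        x_full = (
            np.concatenate([[np.log(fix_kappa)], res.x])
            if fix_kappa is not None
            else res.x
        )
        starts.append(
            StartResult(
                omega2_start=w_start,
                params=_unpack(x_full, null),
                lnL=-float(res.fun),
                converged=bool(res.success),
                message=str(res.message),
            )
        )
    if not starts:
        raise FitError(f"all {n_failed} optimization starts failed")
    lnls = [s.lnL for s in starts]
    best = int(np.argmax(lnls))  # argmax takes the first among ties
    return FitResult(starts=starts, best_index=best)


@dataclass
class M0Result:
    kappa: float
    omega: float
    lengths: np.ndarray
    lnL: float


def fit_m0(
    caln: CodonAlignment,
    tree: LabeledTree,
    *,
    pi=None,
    engine: BranchSiteLikelihood | None = None,
    init_length: float = 0.1,
) -> M0Result:
    """One-ratio model fit: single omega, kappa, and all branch lengths.

    Used to obtain per-gene branch lengths that are then held fixed in the
    branch-site fits.
    """
    if pi is None:
        pi = estimate_codon_frequencies_f3x4(caln)
    if engine is None:
        engine = BranchSiteLikelihood(caln, tree, pi)
    atree = engine.atree
    free_nodes = [v for v in range(atree.n_nodes) if v != atree.root]
    t_init = np.where(
        np.isnan(atree.lengths[free_nodes]), init_length, atree.lengths[free_nodes]
    )
    t_init = np.clip(t_init, 1e-4, 20.0)
    x0 = np.concatenate([[np.log(2.0), np.log(0.3)], np.log(t_init)])
    bounds = [(-4.6, 4.6), (-9.2, 2.3)] + [(-11.5, 3.9)] * len(free_nodes)

    def objective(x: np.ndarray) -> float:
        lengths = np.zeros(atree.n_nodes)
        lengths[free_nodes] = np.exp(x[2:])
        try:
            return -engine.loglik_m0(np.exp(x[0]), np.exp(x[1]), lengths)
        except (ValueError, FloatingPointError):
            return 1e12

    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": 1e-10, "gtol": 1e-6, "eps": 1e-6, "maxiter": 1000},
    )
    lengths = np.full(atree.n_nodes, 0.0)
    lengths[free_nodes] = np.exp(res.x[2:])
    lengths[atree.root] = np.nan
    return M0Result(
        kappa=float(np.exp(res.x[0])),
        omega=float(np.exp(res.x[1])),
        lengths=lengths,
        lnL=-float(res.fun),
    )


# ---------------------------------------------------------------------------
# likelihood ratio test


@dataclass
class LRTResult:
    lnL_alt: float
    lnL_null: float
    statistic: float
    df: int
    p_value: float
    significant: bool
    alpha: float = 0.05


def likelihood_ratio_test(
    lnL_alt: float,
    lnL_null: float,
    *,
    alpha: float = 0.05,
    tolerance: float = 1e-6,
    null_distribution: str = "chi2",
) -> LRTResult:
    """LRT of the alternative against the null, one degree of freedom.

    statistic = max(0, 2 (lnL_alt - lnL_null)). ``null_distribution`` is
    "chi2" (chi-squared, df=1; the default decision rule) or "mixture" (the
    boundary-respecting 50:50 mix of a point mass at 0 and chi2_1, which
    halves nonzero p-values).
    """
    if lnL_alt < lnL_null - max(tolerance, 1e-12):
        raise ValueError(
            f"alternative log-likelihood {lnL_alt} below null {lnL_null}: "
            "optimization failure"
        )
    statistic = max(0.0, 2.0 * (lnL_alt - lnL_null))
    p = float(stats.chi2.sf(statistic, df=1))
    if null_distribution == "mixture":
        p = 1.0 if statistic == 0.0 else 0.5 * p
    elif null_distribution != "chi2":
        raise ValueError(f"unknown null distribution {null_distribution!r}")
    return LRTResult(
        lnL_alt=lnL_alt,
        lnL_null=lnL_null,
        statistic=statistic,
        df=1,
        p_value=min(p, 1.0),
        significant=p < alpha,
        alpha=alpha,
    )


@dataclass
class GeneTestResult:
    fit_null: FitResult
    fit_alt: FitResult
    lrt: LRTResult


def branch_site_lrt(
    caln: CodonAlignment,
    tree: LabeledTree,
    *,
    pi=None,
    omega2_starts: tuple[float, ...] = (0.5, 1.0, 2.0),
    alpha: float = 0.05,
    null_distribution: str = "chi2",
    engine: BranchSiteLikelihood | None = None,
) -> GeneTestResult:
    """Fit null and alternative branch-site models and test one gene.

    The alternative adds an extra start at the null solution (omega2 just
    above 1) so its maximized likelihood can never fall below the null's.
    """
    if pi is None:
        pi = estimate_codon_frequencies_f3x4(caln)
    if engine is None:
        engine = BranchSiteLikelihood(caln, tree, pi)
    fit_null_res = fit_branch_site(
        caln, tree, null=True, pi=pi, omega2_starts=omega2_starts, engine=engine
    )
    null_params = fit_null_res.params
    fit_alt_res = fit_branch_site(
        caln,
        tree,
        null=False,
        pi=pi,
        omega2_starts=omega2_starts,
        extra_starts=[
            BranchSiteParams(
                kappa=null_params.kappa,
                omega0=null_params.omega0,
                omega2=1.0 + 1e-5,
                p0=null_params.p0,
                p1=null_params.p1,
            )
        ],
        engine=engine,
    )
    lnl_alt = max(fit_alt_res.lnL, fit_null_res.lnL)
    lrt = likelihood_ratio_test(
        lnl_alt,
        fit_null_res.lnL,
        alpha=alpha,
        null_distribution=null_distribution,
    )
    return GeneTestResult(fit_null=fit_null_res, fit_alt=fit_alt_res, lrt=lrt)


# ---------------------------------------------------------------------------
# brute-force reference (used by the test-suite oracle; kept here so the
# enumeration logic is reviewable next to the pruning code it checks)


def brute_force_loglik(
    caln: CodonAlignment, tree: LabeledTree, params: BranchSiteParams, pi
) -> float:
    """Log-likelihood by explicit summation over internal-node codon states.

    Exponential in the number of internal nodes; only usable on toy trees.
    Independent of the pruning recursion: transition probabilities are read
    off scipy's expm and the joint probability of each full assignment is
    accumulated term by term.
    """
    pi_arr = _as_pi_array(pi)
    atree = ArrayTree.from_labeled(tree) if isinstance(tree, LabeledTree) else tree
    if atree.foreground_node < 0:
        raise ValueError("tree has no foreground branch label")
    scale = mixture_scale(params, pi_arr)
    bg = params.background_omegas
    fg = params.foreground_omegas
    P = {}
    for c in range(4):
        for v in range(atree.n_nodes):
            if v == atree.root:
                continue
            w = fg[c] if v == atree.foreground_node else bg[c]
            if (c, v) not in P:
                Q = build_rate_matrix(params.kappa, w, pi_arr)
                P[(c, v)] = transition_matrix(Q / scale, atree.lengths[v])
    internal = [
        v for v in range(atree.n_nodes) if atree.children[v]
    ]
    leaves = sorted(atree.leaf_names)
    leaf_vecs = {
        v: [
            codon_state_vector(caln.codon(atree.leaf_names[v], s))
            for s in range(caln.n_sites)
        ]
        for v in leaves
    }
    props = params.proportions
    total = 0.0
    states = [s for s in range(N_CODONS) if pi_arr[s] > 0]
    for site in range(caln.n_sites):
        site_lik = 0.0
        for c in range(4):
            for assignment in itertools.product(states, repeat=len(internal)):
                state_of = dict(zip(internal, assignment))
                term = pi_arr[state_of[atree.root]]
                for v in range(atree.n_nodes):
                    if v == atree.root:
                        continue
                    pv = state_of[atree.parent[v]]
                    if atree.children[v]:
                        term *= P[(c, v)][pv, state_of[v]]
                    else:
                        row = P[(c, v)][pv]
                        term *= float(row @ leaf_vecs[v][site])
                site_lik += props[c] * term
        total += np.log(site_lik)
    return float(total)
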