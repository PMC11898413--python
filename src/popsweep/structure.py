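"""Population-structure inference: IBS distances, neighbor joining and
a K-ancestral-population admixture model fitted by EM.

The admixture likelihood is the standard one: individual ``i``'s dosage
at site ``l`` is ``Binomial(2, x_il)`` with ``x_il = sum_k q_ik p_kl``,
where ``Q`` holds ancestry proportions (rows on the simplex) and ``P``
ancestral alt-allele frequencies.  It is maximized by plain EM — the
same fixed points as ADMIXTURE's block-relaxation, far easier to verify
at desk scale — with multiple random restarts, and K is chosen by
masked-genotype cross-validation error.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .matrix import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

EPS = 1e-6          # P is kept in [EPS, 1 - EPS]
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 2000


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

def ibs_distance(geno: GenotypeMatrix) -> DistanceMatrix:
    """Identity-by-state distance: mean |dosage_i - dosage_j| / 2 over
    sites where both samples are genotyped.  Lies in [0, 1]; errors if
    any pair shares no co-genotyped site."""
    D = geno.dosage.astype(np.float64)
    called = geno.dosage != MISSING
    Dz = np.where(called, D, 0.0)
    C = called.astype(np.float64)

    n = geno.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(Dz[i] - Dz)                      # (n, L)
        shared = C[i] * C                               # (n, L)
        num = (diff * shared).sum(axis=1)
        den = shared.sum(axis=1)
        if (den == 0).any():
            j = int(np.flatnonzero(den == 0)[0])
            raise ValueError(
                f"samples {geno.sample_ids[i]!r} and {geno.sample_ids[j]!r} "
                "share no co-genotyped site"
            )
        out[i] = num / den / 2.0
    np.fill_diagonal(out, 0.0)
    out = (out + out.T) / 2.0                           # exact symmetry
    return DistanceMatrix(out, ids=geno.sample_ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing the Q-criterion (ties broken
    by the lowest (row, column) index pair), computes branch lengths by
    the standard formulas, and finishes with a trifurcating root
    (unrooted convention).  Negative branch lengths are clamped to 0
    with a log note.  Exact on additive distance matrices.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.array(dm.data, dtype=np.float64)
    nodes: list[str] = [_leaf_newick(l) for l in labels]

    def clamp(x: float) -> float:
        if x < 0:
            log.info("nj_tree: clamped negative branch length %.6g to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        R = d.sum(axis=1)
        Qc = (m - 2.0) * d - R[:, None] - R[None, :]
        np.fill_diagonal(Qc, np.inf)
        # lowest (row, col) pair among minima
        i, j = np.unravel_index(int(np.argmin(Qc)), Qc.shape)
        if i > j:
            i, j = j, i
        li = d[i, j] / 2.0 + (R[i] - R[j]) / (2.0 * (m - 2.0))
        lj = d[i, j] - li
        li, lj = clamp(li), clamp(lj)
        merged = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        d_new = (d[i] + d[j] - d[i, j]) / 2.0
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], d_new[keep]])
        d = np.column_stack([d, np.append(d_new[keep], 0.0)])
        nodes = [nodes[k] for k in keep] + [merged]

    # resolve the final three around a trifurcating root
    (a, b, c) = range(3)
    la = clamp((d[a, b] + d[a, c] - d[b, c]) / 2.0)
    lb = clamp((d[a, b] + d[b, c] - d[a, c]) / 2.0)
    lc = clamp((d[a, c] + d[b, c] - d[a, b]) / 2.0)
    newick = (f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},"
              f"{nodes[c]}:{lc:.10g});")
    # convert_underscores=False: sample ids routinely contain "_"
    return TreeNode.read(io.StringIO(newick), convert_underscores=False)


def _leaf_newick(label: str) -> str:
    if any(ch in label for ch in "(),:;'\" \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# admixture model
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureFit:
    """One fitted admixture model."""

    K: int
    Q: np.ndarray           # samples x K, rows sum to 1
    P: np.ndarray           # K x variants, entries in [EPS, 1-EPS]
    loglik: float
    converged: bool
    n_iter: int
    n_restarts: int
    cv_error: float | None = None


class AdmixtureEM:
    """Admixture-model estimator with a scikit-learn-style interface.

    Parameters
    ----------
    n_components
        Number of ancestral populations K (>= 1).
    n_restarts
        Random restarts; the fit with the best log-likelihood is kept.
        K = 1 has a closed form and ignores restarts.
    max_iter, tol
        EM stops when the relative log-likelihood change drops below
        ``tol`` or after ``max_iter`` iterations.
    random_state
        Seed for the restart initializations.

    Attributes (after :meth:`fit`)
    ------------------------------
    Q_ : (n_samples, K) ancestry proportions, rows summing to 1.
    P_ : (K, n_variants) ancestral alt-allele frequencies.
    loglik_ : binomial log-likelihood at the solution (missing entries
        dropped from the sum; binomial coefficients omitted).
    converged_, n_iter_ : convergence diagnostics of the kept restart.
    """

    def __init__(self, n_components: int = 2, n_restarts: int = 3,
                 max_iter: int = DEFAULT_MAX_ITER, tol: float = DEFAULT_TOL,
                 random_state: int | None = None):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components, "n_restarts": self.n_restarts,
                "max_iter": self.max_iter, "tol": self.tol,
                "random_state": self.random_state}

    def set_params(self, **params) -> "AdmixtureEM":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- likelihood machinery -------------------------------------------
    @staticmethod
    def _loglik(G: np.ndarray, mask: np.ndarray, Q: np.ndarray,
                P: np.ndarray) -> float:
        X = np.clip(Q @ P, EPS / 2, 1 - EPS / 2)
        with np.errstate(invalid="ignore"):
            ll = np.where(mask, G * np.log(X) + (2.0 - G) * np.log1p(-X), 0.0)
        return float(ll.sum())

    def fit(self, dosage: np.ndarray) -> "AdmixtureEM":
        """Fit on a (samples x variants) dosage array with -1 for
        missing genotypes."""
        G = np.asarray(dosage, dtype=np.float64)
        mask = np.asarray(dosage) != MISSING
        G = np.where(mask, G, 0.0)
        if G.ndim != 2 or G.size == 0:
            raise ValueError("dosage must be a non-empty 2-D array")
        K = self.n_components
        if K < 1:
            raise ValueError("n_components must be >= 1")

        if K == 1:
            # closed form: pooled allele frequency per site
            copies = 2.0 * mask.sum(axis=0)
            alt = G.sum(axis=0)
            p = np.clip(np.divide(alt, copies, out=np.full(G.shape[1], 0.5),
                                  where=copies > 0), EPS, 1 - EPS)
            self.Q_ = np.ones((G.shape[0], 1))
            self.P_ = p[None, :]
            self.loglik_ = self._loglik(G, mask, self.Q_, self.P_)
            self.converged_, self.n_iter_ = True, 0
            return self

        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_restarts)):
            Q0 = rng.dirichlet(np.ones(K), size=G.shape[0])
            P0 = rng.uniform(EPS, 1 - EPS, size=(K, G.shape[1]))
            res = self._em(G, mask, Q0, P0)
            if best is None or res[2] > best[2]:
                best = res
        self.Q_, self.P_, self.loglik_, self.converged_, self.n_iter_ = best
        return self

    def _em(self, G, mask, Q, P):
        L_i = 2.0 * mask.sum(axis=1, keepdims=True)      # allele copies per sample
        if (L_i == 0).any():
            raise ValueError("a sample has no non-missing genotypes")
        G2 = np.where(mask, 2.0 - G, 0.0)
        prev = -np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            X = np.clip(Q @ P, EPS / 2, 1 - EPS / 2)
            R1 = np.where(mask, G / X, 0.0)               # alt-copy responsibilities
            R0 = np.where(mask, G2 / (1.0 - X), 0.0)
            A = P * (Q.T @ R1)                            # K x L expected alt copies
            B = (1.0 - P) * (Q.T @ R0)
            P = np.clip(A / np.maximum(A + B, 1e-300), EPS, 1 - EPS)
            Q = Q * (R1 @ P.T + R0 @ (1.0 - P).T) / L_i
            Q = Q / Q.sum(axis=1, keepdims=True)
            ll = self._loglik(G, mask, Q, P)
            # frequency clipping at EPS can perturb the objective by a
            # vanishing amount; only a material decrease is a bug
            if ll < prev - 1e-6 * max(1.0, abs(prev)):
                raise AssertionError(f"EM log-likelihood decreased: {prev} -> {ll}")
            if np.isfinite(prev) and abs(ll - prev) <= self.tol * abs(prev):
                converged = True
                prev = ll
                break
            prev = ll
        if not converged:
            log.warning("admixture EM did not converge after %d iterations", it)
        return Q, P, prev, converged, it

    def predict_dosage(self, Q: np.ndarray | None = None) -> np.ndarray:
        """Expected dosages 2 * Q P under the fitted model."""
        Q = self.Q_ if Q is None else Q
        return 2.0 * (Q @ self.P_)


def admixture_fit(geno: GenotypeMatrix, K: int, seed: int | None = None,
                  n_restarts: int = 3, max_iter: int = DEFAULT_MAX_ITER,
                  tol: float = DEFAULT_TOL) -> AdmixtureFit:
    """Fit the K-population admixture model on a cohort."""
    est = AdmixtureEM(n_components=K, n_restarts=n_restarts,
                      max_iter=max_iter, tol=tol, random_state=seed).fit(geno.dosage)
    return AdmixtureFit(K=K, Q=est.Q_, P=est.P_, loglik=est.loglik_,
                        converged=est.converged_, n_iter=est.n_iter_,
                        n_restarts=n_restarts)


# ---------------------------------------------------------------------------
# cross-validation over K
# ---------------------------------------------------------------------------

def cv_error(geno: GenotypeMatrix, K: int, folds: int = 5,
             seed: int | None = None, n_restarts: int = 1,
             max_iter: int = DEFAULT_MAX_ITER, tol: float = DEFAULT_TOL) -> float:
    """Masked-genotype cross-validation error for one K.

    Non-missing genotype entries are partitioned into ``folds`` random
    folds; each fold in turn is masked, the model refitted, and the
    masked dosages predicted as ``2 * Q P``.  Returns the RMS deviation
    over masked entries, averaged across folds.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    obs = np.argwhere(geno.dosage != MISSING)
    if len(obs) < folds:
        raise ValueError("fewer observed genotypes than folds")
    assignment = rng.integers(0, folds, size=len(obs))
    errors = []
    for f in range(folds):
        held = obs[assignment == f]
        if held.size == 0:
            raise ValueError(f"fold {f} holds no masked entries")
        masked = geno.dosage.copy()
        masked[held[:, 0], held[:, 1]] = MISSING
        est = AdmixtureEM(
            n_components=K, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(masked)
        pred = est.predict_dosage()
        truth = geno.dosage[held[:, 0], held[:, 1]].astype(np.float64)
        errors.append(np.sqrt(np.mean((pred[held[:, 0], held[:, 1]] - truth) ** 2)))
    return float(np.mean(errors))


def scan_K(geno: GenotypeMatrix, K_range=range(1, 7), repeats: int = 20,
           folds: int = 5, seed: int | None = None, n_restarts: int = 1,
           max_iter: int = DEFAULT_MAX_ITER, tol: float = DEFAULT_TOL
           ) -> pd.DataFrame:
    """CV-error scan across K.

    Each K is evaluated ``repeats`` times with distinct seeds and the
    minimum CV error per K is reported (columns ``K``, ``cv_error_min``,
    ``cv_error_mean``); the best K minimizes ``cv_error_min``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for K in K_range:
        vals = [cv_error(geno, K, folds, seed=int(rng.integers(0, 2**31 - 1)),
                         n_restarts=n_restarts, max_iter=max_iter, tol=tol)
                for _ in range(repeats)]
        rows.append({"K": K, "cv_error_min": min(vals),
                     "cv_error_mean": float(np.mean(vals)),
                     "n_repeats": repeats})
    return pd.DataFrame(rows)


def align_q_to_truth(Q_hat: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Resolve label switching: permute the columns of ``Q_hat`` to
    minimize the mean absolute error against ``Q_true``."""
    from itertools import permutations

    K = Q_true.shape[1]
    best_perm, best_err = None, np.inf
    for perm in permutations(range(K)):
        err = np.abs(Q_hat[:, perm] - Q_true).mean()
        if err < best_err:
            best_err, best_perm = err, perm
    return Q_hat[:, best_perm]
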