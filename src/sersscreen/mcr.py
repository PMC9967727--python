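"""Multivariate curve resolution by alternating least squares (MCR-ALS).

Factorizes a non-negative spectra matrix D (n_spectra x n_channels) as
D ~ C @ S with C >= 0 (per-sample component contributions) and S >= 0
(component spectra, rows max-normalized to 1), alternating exact
non-negative least-squares half-steps until the relative change in lack of
fit,  lof% = 100 * ||D - C S||_F / ||D||_F,  falls below tolerance.

Initialization seeds the leading rows of S with known reference spectra (a
soft prior: seeded rows are re-estimated every iteration); the remaining
rows start from background-dominated measured spectra (seeded fits) or by
SIMPLISMA-style pure-variable selection (unseeded fits), so that recovered
components can be assigned to analytes by cosine matching afterwards.

The NNLS half-steps use an active-set solver on the normal equations
(Bro & de Jong's fast NNLS); each half-step is an exact constrained
minimizer, which makes the lack of fit non-increasing by construction.
Rotational ambiguity is not explored beyond the constraints (non-negativity,
reference seeding, optional background smoothness): the row-max-1 convention
on S (scale folded into C) fixes scale, and a single solution is returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .spectra import SpectralDataset


@dataclass(frozen=True)
class MCRConfig:
    n_components: int = 6
    max_iter: int = 500
    tol: float = 1e-6            # relative lack-of-fit change for convergence
    init: str = "reference_plus_random"  # or "random"
    nonneg_C: bool = True
    nonneg_S: bool = True
    seed: int = 0
    # Background regularization for reference-seeded fits: after ALS, each
    # non-seeded component that is essentially broad (cosine to its own
    # Whittaker-smoothed version >= smooth_gate) is replaced by that smooth
    # version before the final contribution solve.  Autofluorescence and
    # substrate backgrounds are physically smooth; unconstrained ALS lets
    # them develop narrow dips at analyte channels (rotational overfitting)
    # that bleed background into the analyte's contributions.  Sharp
    # non-analyte bands fail the gate and are left untouched.  Set
    # smooth_background=None to disable.
    smooth_background: float | None = 1e5
    smooth_gate: float = 0.9

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.init not in ("reference_plus_random", "random"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class MCRResult:
    C: np.ndarray                 # n_spectra x k contributions (a.u.)
    S: np.ndarray                 # k x n_channels spectra, row max = 1
    lof_percent: list[float]      # per completed ALS iteration (non-increasing)
    n_iter: int
    converged: bool
    explained_variance: float
    lof_final: float = float("nan")  # lack of fit of the returned (C, S)
    seeded_analytes: tuple[str, ...] = ()
    ridge_fallback: bool = False  # a rank-deficient half-step was regularized

    @property
    def lof(self) -> float:
        """Lack of fit (%) of the returned factors; may sit marginally above
        the last ALS value when background smoothing is enabled."""
        if np.isfinite(self.lof_final):
            return self.lof_final
        return self.lof_percent[-1]

    def save(self, out_dir: str | Path, grid: np.ndarray | None = None) -> None:
        """S and C as CSV plus a JSON sidecar with the fit record."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = "" if grid is None else ",".join(f"{w:g}" for w in grid)
        np.savetxt(out_dir / "S.csv", self.S, delimiter=",", header=header, comments="")
        np.savetxt(out_dir / "C.csv", self.C, delimiter=",")
        sidecar = {
            "lof_percent": self.lof_percent,
            "lof_final": self.lof_final,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "explained_variance": self.explained_variance,
            "seeded_analytes": list(self.seeded_analytes),
            "ridge_fallback": self.ridge_fallback,
        }
        (out_dir / "mcr_result.json").write_text(json.dumps(sidecar, indent=2))


@dataclass
class ComponentAssignment:
    """Best-above-threshold mapping from MCR components to analytes."""

    assignments: dict            # analyte -> component index (assigned only)
    similarity: dict             # analyte -> cosine score of its best component
    similarity_matrix: np.ndarray  # k x n_references, cosine scores
    analytes: tuple[str, ...]
    threshold: float

    def component_for(self, analyte: str) -> int | None:
        return self.assignments.get(analyte)

    def is_assigned(self, analyte: str) -> bool:
        return analyte in self.assignments

    def components_matching(self, analyte: str, threshold: float = 0.9) -> list[int]:
        """All component indices whose cosine to the analyte's reference
        reaches ``threshold`` — the analyte subspace when splitting occurs."""
        j = self.analytes.index(analyte)
        return [int(i) for i in np.flatnonzero(self.similarity_matrix[:, j] >= threshold)]


# ---------------------------------------------------------------------------
# Non-negative least squares
# ---------------------------------------------------------------------------

def _solve_passive_groups(AtA: np.ndarray, AtB: np.ndarray, passive: np.ndarray,
                          eps_ridge: float) -> tuple[np.ndarray, bool]:
    """Solve the passive-set least-squares systems for many columns at once.

    Columns sharing the same passive-set pattern share one factorization
    (with k components there are at most 2^k patterns, so the grouping makes
    the many-right-hand-side case cheap).  Singular systems fall back to a
    small ridge term, flagged to the caller.
    """
    k, n = AtB.shape
    S = np.zeros((k, n))
    ridge = False
    keys = (passive.astype(np.int64) * (1 << np.arange(k, dtype=np.int64))[:, None]).sum(axis=0)
    for key in np.unique(keys):
        if key == 0:
            continue
        cols = np.flatnonzero(keys == key)
        P = passive[:, cols[0]]
        sub = AtA[np.ix_(P, P)]
        rhs = AtB[np.ix_(P, cols)]
        try:
            sol = np.linalg.solve(sub, rhs)
            if not np.all(np.isfinite(sol)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            ridge = True
            sol = np.linalg.solve(sub + eps_ridge * np.eye(int(P.sum())), rhs)
        S[np.ix_(P, cols)] = sol
    return S, ridge


def _nnls_multi(AtA: np.ndarray, AtB: np.ndarray, tol: float) -> tuple[np.ndarray, bool]:
    """Active-set NNLS on the normal equations (Lawson-Hanson / fast NNLS),
    vectorized over the columns of AtB."""
    k, N = AtB.shape
    X = np.zeros((k, N))
    passive = np.zeros((k, N), dtype=bool)
    done = np.zeros(N, dtype=bool)
    ridge = False
    eps_ridge = 1e-10 * max(float(np.max(np.diag(AtA))), 1.0)

    for _ in range(100 * k + 20):
        W = AtB - AtA @ X
        Wmask = np.where(passive | done[None, :], -np.inf, W)
        best = Wmask.max(axis=0)
        done |= best <= tol
        if done.all():
            break
        cols = np.flatnonzero(~done)
        jstar = np.argmax(Wmask[:, cols], axis=0)
        passive[jstar, cols] = True
        # inner feasibility loop: back off along x -> s until all passive
        # coefficients are positive, dropping those driven to zero
        work = cols
        for _ in range(30 * k + 10):
            S, r = _solve_passive_groups(AtA, AtB[:, work], passive[:, work], eps_ridge)
            ridge = ridge or r
            neg = passive[:, work] & (S <= 0.0)
            has_neg = neg.any(axis=0)
            X[:, work[~has_neg]] = np.maximum(S[:, ~has_neg], 0.0)
            if not has_neg.any():
                break
            wn = work[has_neg]
            Sn = S[:, has_neg]
            Xn = X[:, wn]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = np.where(neg[:, has_neg], Xn / (Xn - Sn), np.inf)
            ratios = np.nan_to_num(ratios, nan=0.0, posinf=np.inf)
            alpha = ratios.min(axis=0)
            Xn = Xn + alpha[None, :] * (Sn - Xn)
            keep = Xn > 1e-12
            passive[:, wn] &= keep
            Xn[~passive[:, wn]] = 0.0
            X[:, wn] = Xn
            work = wn
    return X, ridge


def nnls_solve(A: np.ndarray, B: np.ndarray, return_info: bool = False):
    """Column-wise non-negative least squares: X >= 0 minimizing ||A X - B||_F.

    B may be a vector or a matrix (one NNLS problem per column; columns are
    solved in a single vectorized active-set pass).  The residual never
    exceeds that of the zero solution; rank-deficient A is handled via a
    ridge fallback, flagged in ``info`` when requested.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    squeeze = B.ndim == 1
    if squeeze:
        B = B[:, None]
    if A.shape[0] != B.shape[0]:
        raise ValueError(f"shapes not conformable: A {A.shape}, B {B.shape}")
    AtA = A.T @ A
    AtB = A.T @ B
    tol = 1e-11 * max(float(np.max(np.abs(AtA))), 1.0)
    X, ridge = _nnls_multi(AtA, AtB, tol)
    if squeeze:
        X = X[:, 0]
    if return_info:
        return X, {"ridge_fallback": ridge}
    return X


def _ls_solve(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Unconstrained least squares (used when a non-negativity flag is off)."""
    return np.linalg.lstsq(A, B, rcond=None)[0]


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def pure_variables(D: np.ndarray, n: int, offset: float = 0.05) -> list[int]:
    """SIMPLISMA-style pure-variable (channel) selection.

    Purity of channel j is sigma_j / (mu_j + offset * max(mu)); subsequent
    picks are down-weighted by their squared correlation with already chosen
    channels so each pure variable tracks a distinct component.
    """
    mu = D.mean(axis=0)
    sigma = D.std(axis=0)
    purity = sigma / (mu + offset * max(float(mu.max()), 1e-12))
    weight = np.ones_like(purity)
    Dc = D - mu
    norms = np.linalg.norm(Dc, axis=0)
    chosen: list[int] = []
    for _ in range(n):
        masked = purity * weight
        masked[chosen] = -np.inf
        j = int(np.argmax(masked))
        chosen.append(j)
        if norms[j] > 0:
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = (Dc.T @ Dc[:, j]) / (norms * norms[j])
            corr = np.nan_to_num(corr)
            weight = weight * (1.0 - corr**2)
    return chosen


def _diverse_rows(D: np.ndarray, r: int, seeds: np.ndarray) -> np.ndarray | None:
    """Pick ``r`` measured spectra to seed the non-reference components.

    Rows are ranked greedily by residual norm after projecting out the
    seeded references and previously picked rows, weighted by the fraction
    of the row outside that span.  The weighting prefers rows dominated by
    background/matrix structure (blanks, high-fluorescence samples) over
    analyte-rich ones, and the picked row is used *as measured*: a real
    background spectrum carries no artificial dips at the analyte channels,
    which a projection residual would.
    """
    basis: list[np.ndarray] = []
    for s in np.atleast_2d(seeds):
        v = s.astype(float).copy()
        for b in basis:
            v -= (v @ b) * b
        nv = np.linalg.norm(v)
        if nv > 1e-12:
            basis.append(v / nv)
    R = D.astype(float).copy()
    for b in basis:
        R -= np.outer(R @ b, b)
    row_norms = np.maximum(np.linalg.norm(D, axis=1), 1e-12)
    picked = []
    for _ in range(r):
        res_norms = np.linalg.norm(R, axis=1)
        score = res_norms**2 / row_norms
        i = int(np.argmax(score))
        if res_norms[i] <= 1e-12:
            break
        picked.append(i)
        b = R[i] / res_norms[i]
        R = R - np.outer(R @ b, b)
    if not picked:
        return None
    return np.maximum(D[picked], 0.0)


def initialize(
    D: np.ndarray,
    refs: dict[str, np.ndarray] | None,
    config: MCRConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Build (C0, S0): leading S0 rows are the references, the rest come from
    pure-variable selection (or seeded random vectors); C0 is solved from S0."""
    D = np.asarray(D, dtype=float)
    n, m = D.shape
    k = config.n_components
    if k > min(n, m):
        raise ValueError(f"n_components={k} exceeds min(n_spectra, n_channels)={min(n, m)}")
    refs = refs or {}
    if len(refs) > k:
        raise ValueError(f"{len(refs)} references but only {k} components")
    rng = np.random.default_rng(config.seed)
    rows = []
    for name, spec in refs.items():
        spec = np.asarray(spec, dtype=float)
        if spec.shape != (m,):
            raise ValueError(f"reference {name!r} not on the data grid")
        rows.append(spec / max(spec.max(), 1e-12))
    r = k - len(rows)
    if r > 0:
        if config.init == "reference_plus_random":
            if rows:
                # seeded case: surplus components start as the measured
                # spectra most orthogonal to what is already seeded (greedy
                # residual-norm pick), so background/fluorescence rows — not
                # duplicates of the analyte — anchor the remaining components
                extra = _diverse_rows(D, r, np.vstack(rows))
            else:
                # unseeded case: classic SIMPLISMA — pure channels give the
                # initial contribution profiles, spectra follow by NNLS
                pure = pure_variables(D, r)
                Cp = D[:, pure]  # n x r pure-channel intensity profiles
                extra = nnls_solve(Cp, D) if np.any(Cp.max(axis=0) > 1e-12) else None
            if extra is None or np.atleast_2d(extra).shape[0] < r:
                extra = rng.uniform(0.1, 1.0, size=(r, m))
            for row in np.atleast_2d(extra)[:r]:
                rows.append(row / max(row.max(), 1e-12))
        else:
            for _ in range(r):
                row = rng.uniform(0.1, 1.0, size=m)
                rows.append(row / row.max())
    S0 = np.vstack(rows[:k])
    C0 = nnls_solve(S0.T, D.T).T if config.nonneg_C else _ls_solve(S0.T, D.T).T
    return C0, S0


# ---------------------------------------------------------------------------
# Fit
# ---------------------------------------------------------------------------

def _lof_percent(D: np.ndarray, C: np.ndarray, S: np.ndarray, normD: float) -> float:
    return 100.0 * float(np.linalg.norm(D - C @ S)) / normD


def fit(
    data: SpectralDataset | np.ndarray,
    refs: dict[str, np.ndarray] | None = None,
    config: MCRConfig = MCRConfig(),
) -> MCRResult:
    """Alternating least squares on D ~ C S until the lack of fit stalls.

    ``refs`` maps analyte names to baseline-free reference spectra on the
    data grid; seeded components keep their order, so component i of the
    result corresponds to the i-th reference at initialization (but is
    re-estimated freely during ALS — assignment should still go through
    :func:`match_components`).
    """
    D = data.matrix if isinstance(data, SpectralDataset) else np.asarray(data, dtype=float)
    if D.ndim != 2:
        raise ValueError("D must be a matrix")
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite values in D")
    if np.min(D) < -1e-9:
        raise ValueError("D must be non-negative (baseline-subtract and clip first)")
    D = np.maximum(D, 0.0)
    normD = max(float(np.linalg.norm(D)), 1e-300)

    C, S = initialize(D, refs, config)
    ridge = False
    lof_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        if config.nonneg_C:
            C, info = nnls_solve(S.T, D.T, return_info=True)
            C = C.T
            ridge = ridge or info["ridge_fallback"]
        else:
            C = _ls_solve(S.T, D.T).T
        if config.nonneg_S:
            S, info = nnls_solve(C, D, return_info=True)
            ridge = ridge or info["ridge_fallback"]
        else:
            S = _ls_solve(C, D)
        # revive dead components so k spectra always come back
        dead = S.max(axis=1) <= 1e-14
        if np.any(dead):
            rng = np.random.default_rng(config.seed + it)
            resid = np.maximum(D - C @ S, 0.0)
            for i in np.flatnonzero(dead):
                j = int(np.argmax(resid.sum(axis=0)))
                S[i] = resid.mean(axis=0) + 1e-12
                S[i, j] += 1e-9 * (1 + rng.random())
        lof = _lof_percent(D, C, S, normD)
        # fold scale into C so each S row has max 1 (product unchanged)
        scale = S.max(axis=1)
        pos = scale > 0
        S[pos] /= scale[pos, None]
        C[:, pos] *= scale[pos]
        lof_trace.append(lof)
        if len(lof_trace) >= 2:
            prev = lof_trace[-2]
            if abs(prev - lof) / max(lof, 1e-12) < config.tol or lof < 1e-9:
                converged = True
                break
        elif lof < 1e-9:
            converged = True
            break
    # regularize broad non-seeded components (see MCRConfig), then solve the
    # final contributions against the returned spectra
    n_seeded = len(refs) if refs else 0
    if n_seeded and config.smooth_background is not None and D.shape[1] >= 10:
        from .spectra import whittaker_smooth

        for i in range(n_seeded, config.n_components):
            smooth = np.maximum(whittaker_smooth(S[i], config.smooth_background), 0.0)
            if cosine_similarity(S[i], smooth) >= config.smooth_gate:
                S[i] = smooth / max(smooth.max(), 1e-12)
    if config.nonneg_C:
        C, info = nnls_solve(S.T, D.T, return_info=True)
        C = C.T
        ridge = ridge or info["ridge_fallback"]
    else:
        C = _ls_solve(S.T, D.T).T
    lof_final = _lof_percent(D, C, S, normD)
    ev = 1.0 - (lof_final / 100.0) ** 2
    return MCRResult(
        C=C,
        S=S,
        lof_percent=lof_trace,
        n_iter=it,
        converged=converged,
        explained_variance=ev,
        lof_final=lof_final,
        seeded_analytes=tuple(refs.keys()) if refs else (),
        ridge_fallback=ridge,
    )


# ---------------------------------------------------------------------------
# Component assignment
# ---------------------------------------------------------------------------

def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def match_components(
    S: np.ndarray,
    references: dict[str, np.ndarray],
    threshold: float = 0.7,
) -> ComponentAssignment:
    """Assign each analyte its best-matching component by cosine similarity.

    At most one component per analyte; assigned only when the best score
    reaches ``threshold``; ties broken toward the lower component index.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    names = tuple(references.keys())
    sim = np.zeros((S.shape[0], len(names)))
    for j, name in enumerate(names):
        ref = np.asarray(references[name], dtype=float)
        if ref.shape != (S.shape[1],):
            raise ValueError(f"reference {name!r} not on the component grid")
        for i in range(S.shape[0]):
            sim[i, j] = cosine_similarity(S[i], ref)
    assignments: dict[str, int] = {}
    similarity: dict[str, float] = {}
    for j, name in enumerate(names):
        best = int(np.argmax(sim[:, j]))  # argmax takes the first (lowest) index on ties
        similarity[name] = float(sim[best, j])
        if sim[best, j] >= threshold:
            assignments[name] = best
    return ComponentAssignment(
        assignments=assignments,
        similarity=similarity,
        similarity_matrix=sim,
        analytes=names,
        threshold=threshold,
    )


def suggest_n_components(D: np.ndarray, k_max: int = 10, config: MCRConfig | None = None) -> list[float]:
    """Lack-of-fit elbow helper: lof% for k = 1..k_max (never auto-applied)."""
    base = config or MCRConfig()
    out = []
    for k in range(1, k_max + 1):
        cfg = MCRConfig(n_components=k, max_iter=100, tol=base.tol, init="random", seed=base.seed)
        out.append(fit(D, refs=None, config=cfg).lof)
    return out
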