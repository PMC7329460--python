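"""Average-information REML for dense multi-component mixed models.

The model is ``y = X b + sum_k Z_k u_k + e`` with ``u_k ~ N(0, K_k s2_k)``
(``K_k`` either an explicit covariance such as the genomic relationship
matrix, or the identity) and ``e ~ N(0, I s2_e)``, all terms mutually
independent. Estimation works on the phenotype covariance

    V = sum_k s2_k Z_k K_k Z_k' + s2_e I

with average-information (AI) updates and EM-REML fallback steps whenever
an AI step would leave the parameter space or decrease the restricted
likelihood. Problem sizes here are at most a couple of thousand records,
so everything is dense.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "RandomBlock",
    "ModelBundle",
    "MixedModelFit",
    "RemlError",
    "reml_loglik",
    "reml_loglik_mme",
    "reml_fit",
    "blup_solve",
    "blup_solve_mme",
    "vc_standard_errors",
    "delta_method_se",
]

RESIDUAL = "e"


class RemlError(RuntimeError):
    pass


@dataclass
class RandomBlock:
    """One random term: incidence ``Z`` and covariance structure.

    ``K is None`` tags an identity (i.i.d.) structure; otherwise ``K`` is
    the level covariance (e.g. G). ``level_ids`` names the columns of
    ``Z`` and may include levels with no records (their BLUPs are still
    predicted through ``K``).
    """

    label: str
    Z: np.ndarray
    K: np.ndarray | None = None
    level_ids: list | None = None

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        if self.level_ids is None:
            self.level_ids = list(range(self.Z.shape[1]))
        if self.K is not None:
            self.K = np.asarray(self.K, dtype=float)
            if self.K.shape != (self.Z.shape[1],) * 2:
                raise ValueError(f"block {self.label!r}: K shape {self.K.shape} "
                                 f"does not match {self.Z.shape[1]} incidence columns")

    @property
    def structure(self) -> str:
        return "I" if self.K is None else "K"

    @property
    def n_levels(self) -> int:
        return self.Z.shape[1]

    def cov_contribution(self) -> np.ndarray:
        """Z K Z' (the derivative of V w.r.t. this term's variance)."""
        if self.K is None:
            return self.Z @ self.Z.T
        return self.Z @ self.K @ self.Z.T


@dataclass
class ModelBundle:
    """Response, fixed design and random blocks for one model fit."""

    y: np.ndarray
    X: np.ndarray
    blocks: list
    meta: "object | None" = None  # per-record metadata (DataFrame)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        n = self.y.size
        if self.X.shape[0] != n:
            raise ValueError("X row count does not match y")
        for b in self.blocks:
            if b.Z.shape[0] != n:
                raise ValueError(f"block {b.label!r} has {b.Z.shape[0]} rows for {n} records")
        labels = [b.label for b in self.blocks]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate random-term labels: {labels}")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed design X is rank deficient")

    @property
    def n_records(self) -> int:
        return self.y.size

    @property
    def labels(self) -> list:
        return [b.label for b in self.blocks]

    def subset(self, mask) -> "ModelBundle":
        """Row subset keeping all random-effect columns (levels)."""
        mask = np.asarray(mask)
        blocks = [RandomBlock(b.label, b.Z[mask], b.K, b.level_ids) for b in self.blocks]
        meta = None
        if self.meta is not None:
            try:
                meta = self.meta.loc[mask].reset_index(drop=True)
            except AttributeError:
                meta = None
        return ModelBundle(self.y[mask], self.X[mask], blocks, meta)


@dataclass
class MixedModelFit:
    """REML estimates: variance components, BLUEs, BLUPs, diagnostics."""

    vcs: dict
    blues: np.ndarray
    blups: dict
    loglik: float
    ai_matrix: np.ndarray
    ai_labels: list
    iterations: int
    converged: bool
    trajectory: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    boundary: list = field(default_factory=list)


def _theta_to_vcs(labels, theta):
    return {lab: float(v) for lab, v in zip(labels + [RESIDUAL], theta)}


def _cov_derivatives(bundle: ModelBundle):
    """[Z_k K_k Z_k' for each block] + [I] (residual)."""
    mats = [b.cov_contribution() for b in bundle.blocks]
    mats.append(np.eye(bundle.n_records))
    return mats


def _build_v(mats, theta):
    V = theta[-1] * mats[-1].copy()
    for s2, M in zip(theta[:-1], mats[:-1]):
        if s2 != 0.0:
            V += s2 * M
    return V


def _projection(bundle, V):
    """Return (P, Py, loglik) for covariance V.

    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1 and
    loglik = -0.5 [log|V| + log|X'V^-1X| + y' P y] (constant dropped).
    """
    n = bundle.n_records
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError as err:
        raise RemlError(f"V is not positive definite (cond ~ {np.linalg.cond(V):.3g})") from err
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    VinvX = Vinv @ bundle.X
    XtVinvX = bundle.X.T @ VinvX
    sign, logdet_x = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise RemlError("X'V^-1X is singular")
    P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
    P = 0.5 * (P + P.T)
    Py = P @ bundle.y
    quad = float(bundle.y @ Py)
    ll = -0.5 * (logdet_v + logdet_x + quad)
    return P, Py, ll


def reml_loglik(bundle: ModelBundle, vcs: dict) -> float:
    """Restricted log-likelihood (additive constant dropped), V route."""
    labels = bundle.labels
    theta = np.array([vcs[lab] for lab in labels] + [vcs[RESIDUAL]], dtype=float)
    mats = _cov_derivatives(bundle)
    _, _, ll = _projection(bundle, _build_v(mats, theta))
    return ll


def _inv_spd(K, label):
    """Inverse and log-determinant of a covariance; singular K is an error.

    The V-based primary routes tolerate singular K (e.g. VanRaden G built
    from sample frequencies has a zero eigenvalue); the MME routes need
    K^-1 and direct the user to a ridge instead of silently degrading.
    """
    try:
        c, low = linalg.cho_factor(K, lower=True, check_finite=False)
    except linalg.LinAlgError:
        raise RemlError(f"K of {label!r} is singular; add a ridge "
                        "(e.g. vanraden_g(..., ridge=1e-6))") from None
    diag = np.diag(c)
    if np.min(diag) < 1e-8 * np.max(diag):
        raise RemlError(f"K of {label!r} is numerically singular; add a ridge "
                        "(e.g. vanraden_g(..., ridge=1e-6))")
    ld = 2.0 * float(np.sum(np.log(diag)))
    return linalg.cho_solve((c, low), np.eye(K.shape[0]), check_finite=False), ld


def reml_loglik_mme(bundle: ModelBundle, vcs: dict) -> float:
    """Restricted log-likelihood via the mixed-model equations.

    Uses |V| = |s2_e I| |D| |C_uu| and |X'V^-1 X| = |C| / |C_uu| where C
    is the full MME coefficient matrix and D the random-effect prior
    covariance. Independent of :func:`reml_loglik`; used as a dual route
    in tests.
    """
    s2e = vcs[RESIDUAL]
    y, X = bundle.y, bundle.X
    Zs = [b.Z for b in bundle.blocks]
    Z = np.hstack(Zs) if Zs else np.zeros((y.size, 0))
    q = Z.shape[1]
    # D^-1 and log|D|
    Dinv_blocks, logdet_d = [], 0.0
    for b in bundle.blocks:
        s2 = vcs[b.label]
        if s2 <= 0:
            raise RemlError(f"component {b.label!r} must be > 0 for the MME route")
        if b.K is None:
            Dinv_blocks.append(np.eye(b.n_levels) / s2)
            logdet_d += b.n_levels * np.log(s2)
        else:
            Kinv, ld = _inv_spd(b.K, b.label)
            Dinv_blocks.append(Kinv / s2)
            logdet_d += b.n_levels * np.log(s2) + ld
    Dinv = linalg.block_diag(*Dinv_blocks) if Dinv_blocks else np.zeros((0, 0))
    W = np.hstack([X, Z])
    C = W.T @ W / s2e
    C[X.shape[1]:, X.shape[1]:] += Dinv
    Cuu = Z.T @ Z / s2e + Dinv
    sol = np.linalg.solve(C, W.T @ y / s2e)
    b_hat, u_hat = sol[: X.shape[1]], sol[X.shape[1]:]
    sign_c, logdet_c = np.linalg.slogdet(C)
    sign_u, logdet_cuu = np.linalg.slogdet(Cuu) if q else (1.0, 0.0)
    if sign_c <= 0 or sign_u <= 0:
        raise RemlError("MME coefficient matrix not positive definite")
    n = y.size
    resid = y - X @ b_hat - Z @ u_hat
    ypy = float(y @ resid) / s2e
    logdet_v = n * np.log(s2e) + logdet_d + logdet_cuu
    logdet_x = logdet_c - logdet_cuu
    return -0.5 * (logdet_v + logdet_x + ypy)


def _em_step(theta, mats, P, Py, n_levels):
    """EM-REML update; always stays in the parameter space."""
    new = theta.copy()
    n = Py.size
    for k, M in enumerate(mats):
        q = n_levels[k] if k < len(n_levels) else n
        s2 = theta[k]
        MPy = M @ Py
        quad = float(Py @ MPy)
        tr = float(np.sum(P * M))
        new[k] = s2 + (s2 * s2) * (quad - tr) / q
    return np.maximum(new, 0.0)


def _scores_ai(theta, mats, P, Py, free):
    """Score vector and average-information matrix over free parameters."""
    MPys = [mats[k] @ Py for k in free]
    scores = np.array([
        -0.5 * (float(np.sum(P * mats[k])) - float(Py @ mats[k] @ Py)) for k in free
    ])
    nf = len(free)
    AI = np.empty((nf, nf))
    PMPys = [P @ v for v in MPys]
    for a in range(nf):
        for b in range(a, nf):
            AI[a, b] = AI[b, a] = 0.5 * float(MPys[a] @ PMPys[b])
    return scores, AI


def _flag_confounded(bundle):
    msgs = []
    for i, bi in enumerate(bundle.blocks):
        for bj in bundle.blocks[i + 1:]:
            if bi.Z.shape != bj.Z.shape or not np.array_equal(bi.Z, bj.Z):
                continue
            Ki = np.eye(bi.n_levels) if bi.K is None else bi.K
            Kj = np.eye(bj.n_levels) if bj.K is None else bj.K
            if np.allclose(Ki, Kj, atol=1e-10):
                msgs.append(
                    f"terms {bi.label!r} and {bj.label!r} share incidence and covariance "
                    "structure: only their sum is identified"
                )
    return msgs


def reml_fit(bundle: ModelBundle, init: dict | None = None, max_iter: int = 100,
             tol: float = 1e-8, boundary_eps: float = 1e-8,
             verbose: bool = False) -> MixedModelFit:
    """AI-REML with EM fallback and boundary pinning.

    Parameters
    ----------
    init : dict or None
        Starting variance components by term label (+ ``"e"``). Default:
        var(y) split equally across all components.
    boundary_eps : float
        Components are pinned at ``boundary_eps * var(y)`` when an update
        drives them to the boundary, and re-released if the score later
        points back inside.
    """
    labels = bundle.labels
    n_par = len(labels) + 1
    if bundle.n_records <= bundle.X.shape[1]:
        raise RemlError("more fixed-effect columns than records")
    vy = float(np.var(bundle.y, ddof=1)) if bundle.n_records > 1 else 1.0
    if vy <= 0:
        vy = 1.0  # constant response: variances collapse to the boundary
    floor = boundary_eps * vy
    if init is None:
        theta = np.full(n_par, max(vy / n_par, floor))
    else:
        theta = np.array([init[lab] for lab in labels] + [init[RESIDUAL]], dtype=float)
        theta = np.maximum(theta, floor)
    mats = _cov_derivatives(bundle)
    n_levels = [b.n_levels for b in bundle.blocks]

    warn = _flag_confounded(bundle)
    pinned = np.zeros(n_par, dtype=bool)
    P, Py, ll = _projection(bundle, _build_v(mats, theta))
    traj = [(theta.copy(), ll)]
    converged = False
    it = 0
    AI_free = np.eye(1)
    free_idx = list(range(n_par))
    for it in range(1, max_iter + 1):
        # release pinned components whose score points inward
        scores_all, _ = _scores_ai(theta, mats, P, Py, list(range(n_par)))
        for k in range(n_par):
            if pinned[k] and scores_all[k] > 0:
                pinned[k] = False
        pinned[-1] = False  # residual variance never pinned
        free_idx = [k for k in range(n_par) if not pinned[k]]
        scores, AI = _scores_ai(theta, mats, P, Py, free_idx)
        AI_free = AI
        try:
            delta = np.linalg.solve(AI + 1e-12 * np.eye(len(free_idx)), scores)
        except np.linalg.LinAlgError:
            delta = None

        accepted = False
        if delta is not None:
            step = 1.0
            for _ in range(12):
                cand = theta.copy()
                cand[free_idx] = theta[free_idx] + step * delta
                if cand[-1] <= 0:
                    step *= 0.5
                    continue
                # project components that left the space onto the boundary
                cand[cand < floor] = floor
                try:
                    P_c, Py_c, ll_c = _projection(bundle, _build_v(mats, cand))
                except RemlError:
                    step *= 0.5
                    continue
                if ll_c >= ll - 1e-12:
                    accepted = True
                    break
                step *= 0.5
        if not accepted:
            # EM fallback: guaranteed ascent, stays in the space
            cand = _em_step(theta, mats, P, Py, n_levels)
            cand[pinned] = theta[pinned]
            cand[cand < floor] = floor
            P_c, Py_c, ll_c = _projection(bundle, _build_v(mats, cand))
        # pin components that collapsed
        newly_pinned = (cand <= floor * (1 + 1e-12))
        newly_pinned[-1] = False
        pinned |= newly_pinned
        d_theta = np.max(np.abs(cand - theta) / (theta + 1.0))
        d_ll = ll_c - ll
        theta, P, Py, ll = cand, P_c, Py_c, ll_c
        traj.append((theta.copy(), ll))
        if verbose:
            print(f"iter {it}: loglik {ll:.8f} dll {d_ll:.2e} dtheta {d_theta:.2e}")
        if abs(d_ll) < tol and d_theta < 1e-6:
            converged = True
            break
    if not converged:
        warn.append(f"REML did not converge in {max_iter} iterations")

    vcs = _theta_to_vcs(labels, theta)
    blues, blups = blup_solve(bundle, vcs)
    # AI over all parameters at the optimum (free ones; pinned reported too)
    scores, AI_all = _scores_ai(theta, mats, P, Py, list(range(n_par)))
    fit = MixedModelFit(
        vcs=vcs, blues=blues, blups=blups, loglik=ll,
        ai_matrix=AI_all, ai_labels=labels + [RESIDUAL],
        iterations=it, converged=converged, trajectory=traj,
        warnings=warn, boundary=[lab for lab, p in zip(labels + [RESIDUAL], pinned) if p],
    )
    return fit


def blup_solve(bundle: ModelBundle, vcs: dict):
    """BLUEs and BLUPs at fixed variance components (closed form via V).

    ``b_hat = (X'V^-1X)^-1 X'V^-1 y`` and for each term
    ``u_hat_k = s2_k K_k Z_k' P y`` — levels with zero incidence are
    predicted through ``K_k`` (zero for identity structures).
    """
    labels = bundle.labels
    theta = np.array([vcs[lab] for lab in labels] + [vcs[RESIDUAL]], dtype=float)
    mats = _cov_derivatives(bundle)
    V = _build_v(mats, theta)
    n = bundle.n_records
    c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    VinvX = Vinv @ bundle.X
    XtVinvX = bundle.X.T @ VinvX
    blues = np.linalg.solve(XtVinvX, VinvX.T @ bundle.y)
    Py = Vinv @ (bundle.y - bundle.X @ blues)
    blups = {}
    for b, s2 in zip(bundle.blocks, theta[:-1]):
        ZtPy = b.Z.T @ Py
        blups[b.label] = s2 * (ZtPy if b.K is None else b.K @ ZtPy)
    return blues, blups


def blup_solve_mme(bundle: ModelBundle, vcs: dict):
    """Henderson mixed-model-equation solve (dual route to blup_solve)."""
    s2e = vcs[RESIDUAL]
    X = bundle.X
    Zs = [b.Z for b in bundle.blocks]
    Z = np.hstack(Zs) if Zs else np.zeros((bundle.n_records, 0))
    Dinv_blocks = []
    for b in bundle.blocks:
        s2 = vcs[b.label]
        if b.K is None:
            Dinv_blocks.append(np.eye(b.n_levels) / s2)
        else:
            Dinv_blocks.append(_inv_spd(b.K, b.label)[0] / s2)
    Dinv = linalg.block_diag(*Dinv_blocks) if Dinv_blocks else np.zeros((0, 0))
    W = np.hstack([X, Z])
    C = W.T @ W / s2e
    C[X.shape[1]:, X.shape[1]:] += Dinv
    try:
        sol = np.linalg.solve(C, W.T @ bundle.y / s2e)
    except np.linalg.LinAlgError as err:
        raise RemlError("singular MME coefficient matrix; consider a G ridge") from err
    blues = sol[: X.shape[1]]
    blups, at = {}, X.shape[1]
    for b in bundle.blocks:
        blups[b.label] = sol[at: at + b.n_levels]
        at += b.n_levels
    return blues, blups


def vc_standard_errors(fit: MixedModelFit) -> dict:
    """Asymptotic SEs from the inverse AI matrix (None when undefined)."""
    ses = {lab: None for lab in fit.ai_labels}
    try:
        cov = np.linalg.inv(fit.ai_matrix)
    except np.linalg.LinAlgError:
        warnings.warn("AI matrix not invertible; SEs undefined")
        return ses
    d = np.diag(cov)
    for lab, v in zip(fit.ai_labels, d):
        ses[lab] = float(np.sqrt(v)) if v > 0 else None
    return ses


def delta_method_se(fit: MixedModelFit, func, rel_step: float = 1e-6):
    """SE of a smooth scalar function of the variance components.

    ``func`` maps a dict of components to a scalar; the gradient is taken
    by central differences with relative step ``rel_step``.
    """
    theta = np.array([fit.vcs[lab] for lab in fit.ai_labels])
    try:
        cov = np.linalg.inv(fit.ai_matrix)
    except np.linalg.LinAlgError:
        return None
    grad = np.zeros_like(theta)
    for k in range(theta.size):
        h = rel_step * (abs(theta[k]) + rel_step)
        up, dn = theta.copy(), theta.copy()
        up[k] += h
        dn[k] -= h
        grad[k] = (func(_theta_to_vcs(fit.ai_labels[:-1], up))
                   - func(_theta_to_vcs(fit.ai_labels[:-1], dn))) / (2 * h)
    var = float(grad @ cov @ grad)
    return float(np.sqrt(var)) if var > 0 else None
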