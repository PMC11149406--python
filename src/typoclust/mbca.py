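"""Model-based cluster analysis: Gaussian mixtures with eigen-decomposition
covariance families.

Each component covariance is parameterized as ``Sigma_c = lambda_c * D_c *
A_c * D_c'`` — volume (lambda), shape (A, diagonal with unit determinant)
and orientation (D, orthogonal).  Each of the three elements may be Equal
across clusters, Variable, or (for shape/orientation) the Identity, giving
the standard 14 model names EII ... VVV.  Models are fitted by EM with
model-constrained M-steps (Celeux & Govaert closed forms; the
orientation-coupled families VEE/EVE/VVE use inner iterative updates, the
shared-orientation ones via a majorize-minimise step over the orthogonal
group).  Model selection maximizes BIC = 2*loglik - m*log(n) or ICL = BIC
minus twice the classification entropy.

Covariance collapse (a component shrinking onto few points) is handled the
way practitioners expect from mixture software: the cell is marked
non-converged and excluded from model selection instead of raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import solve_triangular

from .core import DataMatrix, Partition

__all__ = [
    "MODELS",
    "MixtureModel",
    "ModelGrid",
    "count_params",
    "em_fit",
    "model_search",
    "classify",
]

MODELS = (
    "EII", "VII", "EEI", "VEI", "EVI", "VVI",
    "EEE", "VEE", "EVE", "VVE", "EEV", "VEV", "EVV", "VVV",
)

_LOG2PI = np.log(2 * np.pi)


def count_params(model_name: str, k: int, p: int) -> int:
    """Free parameters m = (k-1) + k*p + m_cov entering the BIC penalty."""
    if model_name not in MODELS:
        raise ValueError(f"unknown model {model_name!r}")
    vol, shape, orient = model_name
    ori_full = p * (p - 1) // 2
    m_vol = k if vol == "V" else 1
    if shape == "I":
        m_shape = 0
    elif shape == "E":
        m_shape = p - 1
    else:
        m_shape = k * (p - 1)
    if orient == "I":
        m_orient = 0
    elif orient == "E":
        m_orient = ori_full
    else:
        m_orient = k * ori_full
    return (k - 1) + k * p + m_vol + m_shape + m_orient


@dataclass
class MixtureModel:
    """A fitted Gaussian mixture under one covariance parameterization."""

    model_name: str
    k: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray  # k x p x p
    loglik: float
    n_params: int
    bic: float | None
    icl: float | None
    posterior: np.ndarray
    converged: bool
    n_iter: int = 0
    loglik_trace: list = field(default_factory=list)

    @property
    def volumes(self) -> np.ndarray:
        p = self.means.shape[1]
        return np.array([np.linalg.det(S) ** (1 / p) for S in self.covariances])

    def decompose(self, c: int):
        """(lambda, A, D) of component c: volume, unit-det diagonal shape,
        orthogonal orientation (eigenvalues descending)."""
        S = self.covariances[c]
        p = S.shape[0]
        w, V = np.linalg.eigh(S)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        lam = float(np.prod(w) ** (1 / p))
        return lam, np.diag(w / lam), V


@dataclass
class ModelGrid:
    k_range: tuple
    models: tuple
    bic: pd.DataFrame
    icl: pd.DataFrame
    fits: dict = field(default_factory=dict)  # (model, k) -> MixtureModel

    def best(self, criterion: str = "bic"):
        tab = self.bic if criterion == "bic" else self.icl
        if tab.isna().all().all():
            raise ValueError("no converged cell in the model grid")
        idx = tab.stack().idxmax()
        k, model = idx
        return self.fits[(model, int(k))]


# ------------------------------------------------------------- M-steps


def _detnorm_diag(d: np.ndarray) -> tuple:
    """Split a positive diagonal into (det^(1/p), unit-det diagonal)."""
    p = d.size
    g = float(np.prod(d) ** (1 / p))
    return g, d / g


def _mm_orientation(Ws, Ainvs, D0, tol=1e-8, max_iter=100):
    """Shared-orientation update: minimize sum_c tr(D' W_c D Ainv_c) over
    orthogonal D by majorize-minimise (each step solves a Procrustes
    problem)."""
    D = D0
    prev = np.inf
    for _ in range(max_iter):
        G = np.zeros_like(D)
        for W, Ai in zip(Ws, Ainvs):
            om = np.linalg.eigvalsh(W)[-1]
            G += 2.0 * ((W - om * np.eye(W.shape[0])) @ D) * Ai[None, :]
        U, _, Vt = np.linalg.svd(G)
        D = -U @ Vt
        f = sum(float(np.sum((D.T @ W @ D) * np.diag(Ai))) for W, Ai in zip(Ws, Ainvs))
        if abs(prev - f) < tol * (1 + abs(f)):
            break
        prev = f
    return D


def _mstep_cov(model: str, W: list, nc: np.ndarray, p: int, state: dict):
    """Component covariances for one model family.

    ``W`` holds the k weighted scatter matrices, ``nc`` the soft counts.
    ``state`` carries warm-start quantities (shared orientation, volumes)
    across EM iterations for the inner-iterative families.
    """
    k = len(W)
    n = nc.sum()
    eye = np.eye(p)
    Wsum = np.sum(W, axis=0)

    if model == "EII":
        lam = np.trace(Wsum) / (n * p)
        return np.array([lam * eye] * k)
    if model == "VII":
        return np.array([(np.trace(W[c]) / (nc[c] * p)) * eye for c in range(k)])
    if model == "EEI":
        d = np.diag(Wsum) / n
        return np.array([np.diag(d)] * k)
    if model == "VVI":
        return np.array([np.diag(np.diag(W[c]) / nc[c]) for c in range(k)])
    if model == "EVI":
        covs = []
        lam = 0.0
        Bs = []
        for c in range(k):
            g, B = _detnorm_diag(np.maximum(np.diag(W[c]), 1e-300))
            Bs.append(B)
            lam += g
        lam /= n
        return np.array([np.diag(lam * B) for B in Bs])
    if model == "VEI":
        lam = state.setdefault("lam", np.array([np.trace(W[c]) / (nc[c] * p) for c in range(k)]))
        for _ in range(20):
            d = np.sum([np.diag(W[c]) / lam[c] for c in range(k)], axis=0)
            _, B = _detnorm_diag(np.maximum(d, 1e-300))
            new_lam = np.array(
                [np.sum(np.diag(W[c]) / B) / (p * nc[c]) for c in range(k)]
            )
            if np.allclose(new_lam, lam, rtol=1e-8):
                lam = new_lam
                break
            lam = new_lam
        state["lam"] = lam
        return np.array([np.diag(lam[c] * B) for c in range(k)])
    if model == "EEE":
        return np.array([Wsum / n] * k)
    if model == "VVV":
        return np.array([W[c] / nc[c] for c in range(k)])
    if model == "EVV":
        lam = 0.0
        Cs = []
        for c in range(k):
            det = max(np.linalg.det(W[c]), 1e-300)
            g = det ** (1 / p)
            Cs.append(W[c] / g)
            lam += g
        lam /= n
        return np.array([lam * C for C in Cs])
    if model == "VEE":
        lam = state.setdefault("lam", np.array([np.trace(W[c]) / (nc[c] * p) for c in range(k)]))
        C = Wsum / max(np.linalg.det(Wsum), 1e-300) ** (1 / p)
        for _ in range(20):
            M = np.sum([W[c] / lam[c] for c in range(k)], axis=0)
            C = M / max(np.linalg.det(M), 1e-300) ** (1 / p)
            Cinv = np.linalg.inv(C)
            new_lam = np.array([np.sum(W[c] * Cinv.T) / (p * nc[c]) for c in range(k)])
            if np.allclose(new_lam, lam, rtol=1e-8):
                lam = new_lam
                break
            lam = new_lam
        state["lam"] = lam
        return np.array([lam[c] * C for c in range(k)])
    if model in ("EEV", "VEV"):
        eigs, vecs = [], []
        for c in range(k):
            w, V = np.linalg.eigh(W[c])
            order = np.argsort(w)[::-1]
            eigs.append(np.maximum(w[order], 1e-300))
            vecs.append(V[:, order])
        eigs = np.array(eigs)
        if model == "EEV":
            Om = eigs.sum(axis=0)
            g, A = _detnorm_diag(Om)
            lam = g / n
            return np.array([lam * (vecs[c] * A[None, :]) @ vecs[c].T for c in range(k)])
        lam = state.setdefault("lam", np.array([eigs[c].sum() / (nc[c] * p) for c in range(k)]))
        for _ in range(20):
            Om = np.sum(eigs / lam[:, None], axis=0)
            _, A = _detnorm_diag(Om)
            new_lam = (eigs / A[None, :]).sum(axis=1) / (p * nc)
            if np.allclose(new_lam, lam, rtol=1e-8):
                lam = new_lam
                break
            lam = new_lam
        state["lam"] = lam
        return np.array(
            [lam[c] * (vecs[c] * A[None, :]) @ vecs[c].T for c in range(k)]
        )
    if model in ("EVE", "VVE"):
        # shared orthogonal orientation D, per-cluster diagonal shape
        _, D = np.linalg.eigh(Wsum)
        D = state.setdefault("D", D[:, ::-1])
        lam = state.setdefault(
            "lam", np.array([np.trace(W[c]) / (nc[c] * p) for c in range(k)])
        )
        for _ in range(10):
            diag = np.array([np.diag(D.T @ W[c] @ D) for c in range(k)])
            diag = np.maximum(diag, 1e-300)
            gs = np.prod(diag, axis=1) ** (1 / p)
            As = diag / gs[:, None]
            if model == "EVE":
                lam_shared = gs.sum() / n
                lam = np.full(k, lam_shared)
            else:
                lam = gs / nc
            Ainvs = 1.0 / (As * lam[:, None])
            D_new = _mm_orientation(W, Ainvs, D)
            if np.abs(D_new - D).max() < 1e-8:
                D = D_new
                break
            D = D_new
        state["D"], state["lam"] = D, lam
        diag = np.array([np.diag(D.T @ W[c] @ D) for c in range(k)])
        diag = np.maximum(diag, 1e-300)
        gs = np.prod(diag, axis=1) ** (1 / p)
        As = diag / gs[:, None]
        if model == "EVE":
            lam = np.full(k, gs.sum() / n)
        else:
            lam = gs / nc
        return np.array([(D * (lam[c] * As[c])[None, :]) @ D.T for c in range(k)])
    raise ValueError(f"unknown model {model!r}")  # pragma: no cover


# ------------------------------------------------------------- EM


class _Collapse(Exception):
    pass


def _log_gauss(X: np.ndarray, mu: np.ndarray, S: np.ndarray) -> np.ndarray:
    p = X.shape[1]
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        raise _Collapse
    z = solve_triangular(L, (X - mu).T, lower=True)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (p * _LOG2PI + logdet + (z**2).sum(axis=0))


def _ward_init(X: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(X, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def _as_posterior(init, X, k) -> np.ndarray:
    n = X.shape[0]
    if init is None:
        labels = _ward_init(X, k)
    elif isinstance(init, Partition):
        labels = init.labels
    else:
        z = np.asarray(init, float)
        if z.shape == (n, k):
            return z
        labels = np.asarray(init, int)
    z = np.zeros((n, k))
    z[np.arange(n), np.asarray(labels, int) - labels.min()] = 1.0
    return z


def em_fit(
    data,
    model_name: str,
    k: int,
    init=None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureModel:
    """Fit one (model, k) cell by EM.

    ``init`` may be None (deterministic Ward-linkage hard start), a
    Partition, a label vector, or an n x k posterior matrix.  The loglik is
    nondecreasing across iterations; convergence is declared when its
    relative change drops below ``tol``.  Covariance collapse marks the fit
    non-converged (BIC/ICL set to None) rather than raising.
    """
    if model_name not in MODELS:
        raise ValueError(f"unknown model {model_name!r}")
    X = data.values if isinstance(data, DataMatrix) else np.asarray(data, float)
    n, p = X.shape
    m = count_params(model_name, k, p)
    if n <= m:
        warnings.warn(
            f"{model_name} k={k}: more parameters ({m}) than cases ({n})",
            stacklevel=2,
        )
    scale = float(np.var(X, axis=0).mean())
    floor = 1e-10 * scale
    z = _as_posterior(init, X, k)
    state: dict = {}
    loglik = -np.inf
    converged = False
    weights = means = covs = None
    it = 0
    trace = []
    try:
        for it in range(1, max_iter + 1):
            # M-step
            nc = z.sum(axis=0)
            if np.any(nc < 1e-8):
                raise _Collapse
            weights = nc / n
            means = (z.T @ X) / nc[:, None]
            W = []
            for c in range(k):
                dev = X - means[c]
                W.append((dev * z[:, c : c + 1]).T @ dev)
            covs = _mstep_cov(model_name, W, nc, p, state)
            for S in covs:
                if np.linalg.eigvalsh(S)[0] < floor:
                    raise _Collapse
            # E-step
            logdens = np.stack(
                [np.log(weights[c]) + _log_gauss(X, means[c], covs[c]) for c in range(k)],
                axis=1,
            )
            mx = logdens.max(axis=1, keepdims=True)
            lse = mx[:, 0] + np.log(np.exp(logdens - mx).sum(axis=1))
            new_loglik = float(lse.sum())
            trace.append(new_loglik)
            z = np.exp(logdens - lse[:, None])
            if np.isfinite(loglik) and abs(new_loglik - loglik) < tol * (1 + abs(new_loglik)):
                loglik = new_loglik
                converged = True
                break
            loglik = new_loglik
    except _Collapse:
        return MixtureModel(
            model_name=model_name, k=k, weights=weights, means=means,
            covariances=covs, loglik=loglik, n_params=m, bic=None, icl=None,
            posterior=z, converged=False, n_iter=it, loglik_trace=trace,
        )
    bic = 2.0 * loglik - m * np.log(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = float(-np.nansum(z * np.log(np.where(z > 0, z, 1.0))))
    icl = bic - 2.0 * ent
    return MixtureModel(
        model_name=model_name, k=k, weights=weights, means=means,
        covariances=covs, loglik=loglik, n_params=m, bic=float(bic),
        icl=float(icl), posterior=z, converged=converged, n_iter=it,
        loglik_trace=trace,
    )


def model_search(
    data,
    k_range=range(2, 10),
    models=MODELS,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ModelGrid:
    """Fit every (model, k) cell from the shared Ward initialization.

    Returns the grid with BIC and ICL tables (non-converged cells NaN);
    ``grid.best('bic')`` / ``grid.best('icl')`` select the winning fits.
    Duplicate model names are deduplicated, order preserved.
    """
    models = tuple(dict.fromkeys(models))
    ks = tuple(k_range)
    if not ks or not models:
        raise ValueError("empty model grid")
    X = data.values if isinstance(data, DataMatrix) else np.asarray(data, float)
    bic = pd.DataFrame(np.nan, index=list(ks), columns=list(models))
    icl = pd.DataFrame(np.nan, index=list(ks), columns=list(models))
    fits = {}
    for k in ks:
        labels = _ward_init(X, k)
        for model in models:
            fit = em_fit(X, model, k, init=labels, tol=tol, max_iter=max_iter)
            fits[(model, k)] = fit
            if fit.converged and fit.bic is not None:
                bic.loc[k, model] = fit.bic
                icl.loc[k, model] = fit.icl
    grid = ModelGrid(k_range=ks, models=models, bic=bic, icl=icl, fits=fits)
    if bic.isna().all().all():
        raise ValueError("no model converged anywhere on the grid")
    return grid


def classify(model: MixtureModel):
    """MAP labels and per-case uncertainty 1 - max_c z_ic.

    Ties go to the lowest cluster index (argmax convention).
    """
    if not model.converged:
        raise ValueError("cannot classify from a non-converged model")
    labels = np.argmax(model.posterior, axis=1) + 1
    uncertainty = 1.0 - model.posterior.max(axis=1)
    k = model.k
    # keep k from the model even if some component got no MAP assignments
    present = np.unique(labels)
    if len(present) != k:
        remap = {c: i + 1 for i, c in enumerate(present)}
        labels = np.array([remap[c] for c in labels])
        k = len(present)
    return Partition(labels, k=k), uncertainty
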