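"""Joint deep semi-NMF with PPI and graph-Laplacian priors.

The model factorizes three expression matrices ``X_i`` (samples x features,
shared samples) as ``X_i ~ U H_i^0`` with one common sample latent matrix
``U`` (n x k0, unconstrained sign) and per-omics coefficient hierarchies

    H_i^0 = s(Z_i^1 s(Z_i^2 ... s(Z_i^N H_i^N))),   s(x) = 1/(1+e^-x),

so every derived layer ``H_i^0 .. H_i^{N-1}`` is elementwise in (0,1) and
hence nonnegative by construction; only the junction matrices ``Z_i^n``
and the deepest layer ``H_i^N`` are free-sign parameters. The objective is

    sum_i ||X_i - U H_i^0||_F^2
        + lambda1 * sum_S ||S||_F^2                      (S = U, all Z, all H^N)
        + lambda2 * Tr(H_ppi^0 M H_ppi^0^T)              (PPI prior on one omics)
        + lambda3 * sum_i Tr(H_i^0 B_i H_i^0^T)          (graph smoothness)

where ``B_i`` is the Laplacian of the omics-i feature connectivity graph
and ``M`` is either the Laplacian of the PPI adjacency (default, so the
penalty drives interacting proteins toward similar loadings) or the raw
adjacency ("literal" mode).

Optimization is full-batch first-order descent with adaptive moment
estimates and a monotone backtracking safeguard; gradients are analytic
(reverse-mode through the sigmoid chain).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .graphs import FeatureGraph, graph_from_prior, laplacian_from_adjacency
from .io import OmicsMatrix, PriorNetwork

__all__ = [
    "sigmoid",
    "logit",
    "LayerDims",
    "PenaltyWeights",
    "DeepFactorModel",
    "FitResult",
    "forward",
    "objective",
    "gradients",
    "svd_init",
    "nmf_init",
    "fit",
    "reconstruction_correlation",
    "PDJDSNMF",
    "PDJDSNMFResults",
]

_EPS = 1e-4  # margin used when squeezing initial layers into (0,1)


def sigmoid(x):
    """Numerically stable logistic function, elementwise."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def logit(y):
    y = np.asarray(y, dtype=float)
    return np.log(y) - np.log1p(-y)


@dataclass(frozen=True)
class LayerDims:
    """Latent dimensions per depth, ``[k0, k1, ..., kN]``.

    ``k0`` is the number of factors (and of co-expression modules); the
    default profile decreases with depth, e.g. ``[30, 25, 20, 15]`` for a
    four-layer network.
    """

    k: tuple[int, ...]

    def __init__(self, k: Sequence[int]):
        k = tuple(int(v) for v in k)
        if not k or any(v < 1 for v in k):
            raise ValueError("layer dims must be positive integers")
        object.__setattr__(self, "k", k)

    @property
    def k0(self) -> int:
        return self.k[0]

    @property
    def n_sublayers(self) -> int:
        return len(self.k) - 1

    def validate_against(self, n_samples: int, p: Sequence[int]) -> None:
        bound = min(n_samples, min(p))
        if self.k0 > bound:
            raise ValueError(
                f"k0={self.k0} exceeds min(n_samples, min p_i)={bound}; "
                "k must be smaller than both the sample count and every feature count"
            )


@dataclass(frozen=True)
class PenaltyWeights:
    """Penalty strengths: lambda1 (parameter norms), lambda2 (PPI prior), lambda3 (Laplacians)."""

    lambda1: float = 0.001
    lambda2: float = 0.1
    lambda3: float = 0.01

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "lambda3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class DeepFactorModel:
    """Parameter container: shared ``U`` plus per-omics ``Z`` chains and deep layers.

    ``Z[i]`` is the list ``[Z_i^1, ..., Z_i^N]`` (shapes ``k_{n-1} x k_n``)
    and ``Hdeep[i]`` is ``H_i^N`` (``k_N x p_i``). When ``linear`` is True
    the model degenerates to single-layer joint NMF: ``H_i^0 = Hdeep[i]``
    with no activation (used by the "jnmf" ablation, where nonnegativity is
    kept by projection instead of by the sigmoid).
    """

    U: np.ndarray
    Z: list[list[np.ndarray]]
    Hdeep: list[np.ndarray]
    dims: LayerDims
    linear: bool = False

    @property
    def n_omics(self) -> int:
        return len(self.Hdeep)

    def parameters(self) -> list[np.ndarray]:
        out = [self.U]
        for i in range(self.n_omics):
            out.extend(self.Z[i])
            out.append(self.Hdeep[i])
        return out

    def copy(self) -> "DeepFactorModel":
        return DeepFactorModel(
            U=self.U.copy(),
            Z=[[z.copy() for z in zs] for zs in self.Z],
            Hdeep=[h.copy() for h in self.Hdeep],
            dims=self.dims,
            linear=self.linear,
        )


def forward(model: DeepFactorModel, omics_index: int):
    """Derived layers for one omics: returns ``(H0, Xhat)``.

    ``H0`` is computed by the nested sigmoid compositions from the deepest
    layer upward, so its entries are strictly inside (0,1); ``Xhat = U H0``.
    """
    H0 = _layers(model, omics_index)[0]
    return H0, model.U @ H0


def _layers(model: DeepFactorModel, i: int) -> list[np.ndarray]:
    """All layers ``[H^0, H^1, ..., H^N]`` for omics ``i`` (H^N = Hdeep)."""
    H = model.Hdeep[i]
    if model.linear:
        return [H]
    k = model.dims.k
    if H.shape[0] != k[-1]:
        raise ValueError(f"omics {i}: deepest layer has {H.shape[0]} rows, expected k_N={k[-1]}")
    layers = [H]
    for n in range(len(model.Z[i]), 0, -1):
        Zn = model.Z[i][n - 1]
        if Zn.shape != (k[n - 1], k[n]):
            raise ValueError(f"omics {i}: Z^{n} has shape {Zn.shape}, expected {(k[n - 1], k[n])}")
        if Zn.shape[1] != layers[0].shape[0]:
            raise ValueError(f"omics {i}: shape mismatch at layer {n}")
        layers.insert(0, sigmoid(Zn @ layers[0]))
    return layers


def _check_alignment(model: DeepFactorModel, X: Sequence[OmicsMatrix], P, graphs, ppi_omics: int):
    if P is not None:
        pi = X[ppi_omics].n_features
        if P.adjacency.shape[0] != pi:
            raise ValueError(
                f"PPI prior has {P.adjacency.shape[0]} features but omics {ppi_omics} has {pi}"
            )
    if graphs is not None:
        for i, (g, x) in enumerate(zip(graphs, X)):
            if g is not None and g.n_features != x.n_features:
                raise ValueError(f"graph {i} has {g.n_features} features but omics {i} has {x.n_features}")


def objective(
    model: DeepFactorModel,
    X: Sequence[OmicsMatrix],
    P: PriorNetwork | None,
    graphs: Sequence[FeatureGraph] | None,
    w: PenaltyWeights,
    ppi_mode: str = "laplacian",
    ppi_omics: int = 0,
):
    """Objective value and its four terms ``(residual, norm, ppi, laplacian)``.

    The returned total is ``residual + l1*norm + l2*ppi + l3*laplacian``;
    the terms are reported unweighted.
    """
    total, terms, _ = _objective_and_grads(
        model, X, P, graphs, w, ppi_mode, ppi_omics, want_grads=False
    )
    return total, terms


def gradients(model, X, P, graphs, w, ppi_mode="laplacian", ppi_omics=0):
    """Analytic gradients of the objective w.r.t. every parameter matrix."""
    _, _, grads = _objective_and_grads(model, X, P, graphs, w, ppi_mode, ppi_omics, want_grads=True)
    return grads


def _ppi_matrix(P: PriorNetwork, ppi_mode: str) -> np.ndarray:
    if ppi_mode == "laplacian":
        return graph_from_prior(P).laplacian
    if ppi_mode == "literal":
        return P.adjacency
    raise ValueError(f"unknown ppi_mode {ppi_mode!r}")


def _objective_and_grads(model, X, P, graphs, w, ppi_mode, ppi_omics, want_grads):
    if ppi_mode not in ("laplacian", "literal"):
        raise ValueError(f"unknown ppi_mode {ppi_mode!r}")
    _check_alignment(model, X, P, graphs, ppi_omics)
    U = model.U
    M = _ppi_matrix(P, ppi_mode) if (P is not None and w.lambda2 > 0) else None

    residual = 0.0
    ppi_term = 0.0
    lap_term = 0.0
    norm_term = float(np.sum(U * U))
    for i in range(model.n_omics):
        for Zn in model.Z[i]:
            norm_term += float(np.sum(Zn * Zn))
        norm_term += float(np.sum(model.Hdeep[i] ** 2))

    gU = 2.0 * w.lambda1 * U if want_grads else None
    gZ: list[list[np.ndarray]] = []
    gH: list[np.ndarray] = []

    for i in range(model.n_omics):
        layers = _layers(model, i)
        H0 = layers[0]
        R = U @ H0 - X[i].values
        residual += float(np.sum(R * R))

        Bi = graphs[i].laplacian if (graphs is not None and graphs[i] is not None) else None
        if Bi is not None:
            lap_term += float(np.sum((H0 @ Bi) * H0))
        if M is not None and i == ppi_omics:
            ppi_term += float(np.sum((H0 @ M) * H0))

        if not want_grads:
            continue

        # dJ/dH0, then reverse through the sigmoid chain
        G = 2.0 * (U.T @ R)
        if Bi is not None and w.lambda3 > 0:
            G = G + 2.0 * w.lambda3 * (H0 @ Bi)
        if M is not None and i == ppi_omics:
            G = G + 2.0 * w.lambda2 * (H0 @ M)
        gU = gU + 2.0 * (R @ H0.T)

        if model.linear:
            gZ.append([])
            gH.append(G + 2.0 * w.lambda1 * model.Hdeep[i])
            continue

        gZi = [None] * len(model.Z[i])
        for n in range(1, len(model.Z[i]) + 1):
            Hprev = layers[n - 1]  # = s(Z^n H^n)
            Gpre = G * Hprev * (1.0 - Hprev)
            gZi[n - 1] = Gpre @ layers[n].T + 2.0 * w.lambda1 * model.Z[i][n - 1]
            G = model.Z[i][n - 1].T @ Gpre
        gZ.append(gZi)
        gH.append(G + 2.0 * w.lambda1 * model.Hdeep[i])

    total = residual + w.lambda1 * norm_term + w.lambda2 * ppi_term + w.lambda3 * lap_term
    terms = (residual, norm_term, ppi_term, lap_term)
    if not want_grads:
        return total, terms, None
    grads = DeepFactorModel(U=gU, Z=gZ, Hdeep=gH, dims=model.dims, linear=model.linear)
    return total, terms, grads


def _squeeze_unit(V: np.ndarray, eps: float = _EPS):
    """Affine map of V into (eps, 1-eps); returns (mapped, scale a, shift b)
    with mapped = a*V + b."""
    lo, hi = V.min(), V.max()
    if hi - lo < 1e-12:
        return np.full_like(V, 0.5), 1.0, 0.5 - lo
    a = (1.0 - 2.0 * eps) / (hi - lo)
    b = eps - a * lo
    return a * V + b, a, b


def _fix_signs(Ufac: np.ndarray, Vt: np.ndarray):
    # deterministic sign convention: dominant entry of each right vector positive
    for r in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[r])))
        if Vt[r, j] < 0:
            Vt[r] *= -1.0
            Ufac[:, r] *= -1.0
    return Ufac, Vt


def svd_init(X: Sequence[OmicsMatrix], dims: LayerDims, seed: int = 0, linear: bool = False) -> DeepFactorModel:
    """Deterministic SVD-based initialization.

    ``U`` and the first-layer coefficients come from a rank-``k0``
    truncated SVD of the column-concatenated data; the per-omics blocks of
    the right factor are squeezed into ``(eps, 1-eps)`` (with the scale
    absorbed into ``U``) so the sigmoid hierarchy can represent them.
    Deeper layers are initialized recursively: logit-transform the current
    layer, truncate its SVD at the next dimension, repeat. ``seed`` is
    recorded for provenance; the procedure itself is deterministic (signs
    are disambiguated by a fixed convention).
    """
    n = X[0].n_samples
    p = [x.n_features for x in X]
    dims.validate_against(n, p)
    Xc = np.concatenate([x.values for x in X], axis=1)
    k0 = dims.k0

    # rank-(k0-1) truncated SVD plus one constant offset factor: the right
    # factor must be squeezed into (0,1) by an affine map, and the offset
    # factor absorbs the map's shift exactly, so the initialization loses
    # only the k0-th singular component instead of a rank-1 shift error.
    r = k0 - 1
    if r > 0:
        Us, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        Us, s, Vt = Us[:, :r], s[:r], Vt[:r]
        Ufac = Us * s
        Ufac, Vt = _fix_signs(Ufac, Vt)
        H0all, a, b = _squeeze_unit(Vt)
        U = Ufac / a
        offset_col = 2.0 * (Xc.mean(axis=1) - U @ H0all.mean(axis=1))
    else:
        H0all = np.empty((0, Xc.shape[1]))
        U = np.empty((n, 0))
        offset_col = 2.0 * Xc.mean(axis=1)
    H0all = np.vstack([H0all, np.full((1, Xc.shape[1]), 0.5)])
    U = np.column_stack([U, offset_col])

    offs = np.cumsum([0] + p)
    blocks = [H0all[:, offs[i]:offs[i + 1]] for i in range(len(X))]
    if linear or dims.n_sublayers == 0:
        return DeepFactorModel(U=U, Z=[[] for _ in X], Hdeep=blocks, dims=dims, linear=True)
    Z, Hdeep = _chain_from_blocks(blocks, dims)
    for i in range(len(X)):
        _refine_chain(Z[i], Hdeep[i], blocks[i], dims)
    return DeepFactorModel(U=U, Z=Z, Hdeep=Hdeep, dims=dims, linear=False)


def _chain_from_blocks(blocks, dims: LayerDims):
    """Recursive logit/truncated-SVD construction of the deep layers from
    per-omics first-layer blocks in (0,1)."""
    Z: list[list[np.ndarray]] = [[] for _ in blocks]
    Hdeep: list[np.ndarray] = []
    for i, block in enumerate(blocks):
        Hcur = block
        for depth in range(1, dims.n_sublayers + 1):
            kn = dims.k[depth]
            A = logit(np.clip(Hcur, _EPS, 1.0 - _EPS))
            Ua, sa, Va = np.linalg.svd(A, full_matrices=False)
            r = min(kn, len(sa))
            Zi = Ua[:, :r] * sa[:r]
            Vr = Va[:r]
            Zi, Vr = _fix_signs(Zi, Vr)
            if r < kn:  # rank-deficient layer: pad with zeros
                Zi = np.pad(Zi, ((0, 0), (0, kn - r)))
                Vr = np.pad(Vr, ((0, kn - r), (0, 0)))
            if depth < dims.n_sublayers:
                Hcur, a, _ = _squeeze_unit(Vr)
                Zi = Zi / a
            else:
                Hdeep.append(Vr)
            Z[i].append(Zi)
    return Z, Hdeep


def _refine_chain(Zi: list[np.ndarray], Hd: np.ndarray, target: np.ndarray, dims: LayerDims,
                  max_iter: int = 3000):
    """Polish one omics' chain so ``s(Z^1 s(... s(Z^N H^N)))`` reproduces a
    target first layer.

    The logit/truncated-SVD recursion is only a crude chain inverse — the
    rank truncation happens in logit space and can distort the layer it is
    meant to reproduce. A short quasi-Newton run on
    ``||chain(Z, H^N) - target||_F^2`` fixes that; deterministic.
    """
    from scipy.optimize import minimize

    params = Zi + [Hd]
    sizes = [p.size for p in params]

    def unpack(v):
        o = 0
        for p, s in zip(params, sizes):
            p[...] = v[o : o + s].reshape(p.shape)
            o += s

    def fun(v):
        unpack(v)
        layers = [params[-1]]
        for d in range(len(Zi), 0, -1):
            layers.insert(0, sigmoid(params[d - 1] @ layers[0]))
        diff = layers[0] - target
        G = 2.0 * diff
        grads = [None] * len(params)
        for d in range(1, len(Zi) + 1):
            Hprev = layers[d - 1]
            Gpre = G * Hprev * (1.0 - Hprev)
            grads[d - 1] = Gpre @ layers[d].T
            G = params[d - 1].T @ Gpre
        grads[-1] = G
        return float(np.sum(diff * diff)), np.concatenate([g.ravel() for g in grads])

    x0 = np.concatenate([p.ravel() for p in params])
    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-12})
    unpack(res.x)


def nmf_init(X: Sequence[OmicsMatrix], dims: LayerDims, seed: int = 0, linear: bool = False) -> DeepFactorModel:
    """Parts-based initialization from a rank-``k0`` NMF of the concatenated data.

    Requires nonnegative input (guaranteed when per-feature min-max
    scaling is on). An NNDSVD-initialized coordinate-descent NMF gives a
    sparse, parts-based first layer whose factors align with co-expression
    blocks far better than raw singular vectors, which mix them; the deep
    chain is then built by the same logit/truncated-SVD recursion the SVD
    initializer uses. Recommended when the goal is module discovery rather
    than pure reconstruction.
    """
    from sklearn.decomposition import NMF

    n = X[0].n_samples
    p = [x.n_features for x in X]
    dims.validate_against(n, p)
    Xc = np.concatenate([x.values for x in X], axis=1)
    if Xc.min() < 0:
        raise ValueError("nmf initialization requires nonnegative data (enable scaling)")
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        nmf = NMF(n_components=dims.k0, init="nndsvd", max_iter=600, tol=1e-6, random_state=seed)
        W = nmf.fit_transform(Xc)
        H = nmf.components_
    margin = 0.01  # keep logits of the squeezed layer within a mild range
    a = (1.0 - 2.0 * margin) / max(H.max(), 1e-12)
    H0 = a * H + margin
    U = W / a
    offs = np.cumsum([0] + p)
    blocks = [H0[:, offs[i]:offs[i + 1]] for i in range(len(X))]
    if linear or dims.n_sublayers == 0:
        return DeepFactorModel(U=U, Z=[[] for _ in X], Hdeep=blocks, dims=dims, linear=True)
    Z, Hdeep = _chain_from_blocks(blocks, dims)
    for i in range(len(X)):
        _refine_chain(Z[i], Hdeep[i], blocks[i], dims)
    return DeepFactorModel(U=U, Z=Z, Hdeep=Hdeep, dims=dims, linear=False)


def reconstruction_correlation(X: OmicsMatrix | np.ndarray, Xhat: np.ndarray) -> float:
    """Pearson correlation between a matrix and its reconstruction, flattened."""
    x = (X.values if isinstance(X, OmicsMatrix) else np.asarray(X, float)).ravel()
    y = np.asarray(Xhat, float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class FitResult:
    """Raw optimizer output: fitted parameters plus traces and diagnostics."""

    model: DeepFactorModel
    objective_trace: np.ndarray
    term_trace: np.ndarray  # iterations x 4: residual, norm, ppi, laplacian
    recon_corr: dict
    converged: bool
    iterations: int
    seed: int


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def reset(self):
        for m in self.m:
            m[...] = 0.0
        for v in self.v:
            v[...] = 0.0
        self.t = 0

    def steps(self, grads):
        self.t += 1
        out = []
        for j, g in enumerate(grads):
            self.m[j] = self.b1 * self.m[j] + (1 - self.b1) * g
            self.v[j] = self.b2 * self.v[j] + (1 - self.b2) * g * g
            mhat = self.m[j] / (1 - self.b1 ** self.t)
            vhat = self.v[j] / (1 - self.b2 ** self.t)
            out.append(self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def fit(
    X: Sequence[OmicsMatrix],
    P: PriorNetwork | None,
    graphs: Sequence[FeatureGraph] | None,
    dims: LayerDims,
    w: PenaltyWeights,
    max_iter: int = 2000,
    tol: float = 1e-5,
    learning_rate: float = 1e-2,
    ppi_mode: str = "laplacian",
    ppi_omics: int = 0,
    seed: int = 0,
    linear: bool = False,
    init: DeepFactorModel | None = None,
    method: str = "adam",
    init_method: str = "svd",
) -> FitResult:
    """Minimize the objective from an SVD start.

    With ``method="adam"`` (default) descent directions come from adaptive
    moment estimates; each step is backtracked (halved, up to 30 times)
    until the objective does not increase, so the recorded trace is
    monotone non-increasing up to a 1e-12 relative slack. Stops when the
    relative objective change falls below ``tol`` or after ``max_iter``
    iterations. ``method="lbfgs"`` hands the same objective and analytic
    gradients to a limited-memory quasi-Newton solver, which reaches tight
    optima in far fewer iterations on small problems. The "jnmf" ablation
    uses ``linear=True``: a single identity-activation layer with ``U`` and
    ``H`` kept nonnegative (projection under "adam", box bounds under
    "lbfgs").
    """
    if method not in ("adam", "lbfgs"):
        raise ValueError(f"unknown method {method!r}")
    if init_method not in ("svd", "nmf"):
        raise ValueError(f"unknown init_method {init_method!r}")
    if init is not None:
        model = init.copy()
    elif init_method == "nmf":
        model = nmf_init(X, dims, seed=seed, linear=linear)
    else:
        model = svd_init(X, dims, seed=seed, linear=linear)
    if linear:
        model.U = np.maximum(model.U, 0.0)
        model.Hdeep = [np.maximum(h, 0.0) for h in model.Hdeep]
    if method == "lbfgs":
        return _fit_lbfgs(model, X, P, graphs, w, max_iter, tol, ppi_mode, ppi_omics, seed, linear)

    def pack(m):
        return m.parameters()

    def obj(m):
        return _objective_and_grads(m, X, P, graphs, w, ppi_mode, ppi_omics, want_grads=False)[0]

    opt = _Adam(pack(model), lr=learning_rate)
    total, terms, grads = _objective_and_grads(model, X, P, graphs, w, ppi_mode, ppi_omics, True)
    if not np.isfinite(total):
        raise FloatingPointError("objective is non-finite at initialization")

    obj_trace = []
    term_trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        steps = opt.steps(pack(grads))
        params = pack(model)
        base = [p.copy() for p in params]
        scale = 1.0
        accepted = False
        new_total = np.inf
        for _ in range(30):
            for pcur, p0, st in zip(params, base, steps):
                pcur[...] = p0 - scale * st
            if linear:
                model.U[...] = np.maximum(model.U, 0.0)
                for h in model.Hdeep:
                    h[...] = np.maximum(h, 0.0)
            new_total = obj(model)
            if np.isfinite(new_total) and new_total <= total * (1.0 + 1e-12):
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            # direction not admissible at any scale: restore, flush stale
            # moments (the usual culprit), damp, retry
            for pcur, p0 in zip(params, base):
                pcur[...] = p0
            opt.reset()
            opt.lr *= 0.5
            obj_trace.append(total)
            term_trace.append(terms)
            if opt.lr < 1e-14:
                converged = True
                break
            continue
        if not np.isfinite(new_total):
            raise FloatingPointError(
                "objective diverged (NaN/Inf); try a smaller learning_rate"
            )
        new_total, terms, grads = _objective_and_grads(
            model, X, P, graphs, w, ppi_mode, ppi_omics, True
        )
        obj_trace.append(new_total)
        term_trace.append(terms)
        rel = abs(total - new_total) / max(abs(total), 1e-12)
        total = new_total
        if rel < tol:
            converged = True
            break

    return FitResult(
        model=model,
        objective_trace=np.asarray(obj_trace),
        term_trace=np.asarray(term_trace),
        recon_corr=_recon_corrs(model, X),
        converged=converged,
        iterations=it,
        seed=seed,
    )


def _recon_corrs(model, X):
    recon = {}
    vals = []
    for i, x in enumerate(X):
        _, Xhat = forward(model, i)
        r = reconstruction_correlation(x, Xhat)
        recon[x.omics_name] = r
        vals.append(r)
    recon["mean"] = float(np.mean(vals))
    return recon


def _fit_lbfgs(model, X, P, graphs, w, max_iter, tol, ppi_mode, ppi_omics, seed, linear):
    from scipy.optimize import minimize

    params = model.parameters()
    sizes = [p.size for p in params]

    def unpack(v):
        o = 0
        for p, s in zip(params, sizes):
            p[...] = v[o : o + s].reshape(p.shape)
            o += s

    def fun(v):
        unpack(v)
        total, _, g = _objective_and_grads(model, X, P, graphs, w, ppi_mode, ppi_omics, True)
        return total, np.concatenate([x.ravel() for x in g.parameters()])

    bounds = None
    if linear:  # U and H stay in the nonnegative orthant via box bounds
        bounds = [(0.0, None)] * sum(sizes)

    obj_trace, term_trace = [], []

    def callback(v):
        unpack(v)
        total, terms, _ = _objective_and_grads(model, X, P, graphs, w, ppi_mode, ppi_omics, False)
        obj_trace.append(total)
        term_trace.append(terms)

    x0 = np.concatenate([p.ravel() for p in params])
    res = minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        callback=callback,
        options={"maxiter": max_iter, "ftol": tol * 1e-2, "gtol": 1e-10},
    )
    if not np.isfinite(res.fun):
        raise FloatingPointError("objective diverged (NaN/Inf)")
    unpack(res.x)
    return FitResult(
        model=model,
        objective_trace=np.asarray(obj_trace),
        term_trace=np.asarray(term_trace),
        recon_corr=_recon_corrs(model, X),
        converged=bool(res.success) or res.nit < max_iter,
        iterations=int(res.nit),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# statsmodels-style front end


class PDJDSNMF:
    """Prior-knowledge-driven joint deep semi-NMF model.

    Parameters
    ----------
    X : sequence of OmicsMatrix
        Expression matrices over identical samples (same ids, same order).
    ppi : PriorNetwork or None
        Binary PPI adjacency aligned to one omics' features.
    dims : LayerDims or sequence of int
        Latent dimensions per depth, e.g. ``[30, 25, 20, 15]``.
    penalties : PenaltyWeights
        lambda1/2/3 strengths; zero disables a term.
    graphs : sequence of FeatureGraph, optional
        Per-omics connectivity Laplacians; built from feature correlations
        (``graph_method``, ``tau``) when omitted and lambda3 > 0.
    ppi_mode : {"laplacian", "literal"}
        Whether the PPI penalty uses the Laplacian of the adjacency
        (default) or the raw adjacency.
    ppi_omics : int, optional
        Index of the omics carrying the PPI prior; default is the omics
        whose feature ids overlap the PPI node set most.
    scale : bool
        Min-max scale each feature to [0, 1] before fitting (default).

    Examples
    --------
    >>> model = PDJDSNMF([mrna, lncrna, mirna], ppi, dims=[30, 25, 20, 15])
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    """

    def __init__(
        self,
        X: Sequence[OmicsMatrix],
        ppi: PriorNetwork | None,
        dims,
        penalties: PenaltyWeights = PenaltyWeights(),
        graphs: Sequence[FeatureGraph] | None = None,
        graph_method: str = "corr_threshold",
        tau: float = 0.8,
        ppi_mode: str = "laplacian",
        ppi_omics: int | None = None,
        scale: bool = True,
    ):
        if len(X) < 1:
            raise ValueError("need at least one omics matrix")
        sids = X[0].sample_ids
        for x in X[1:]:
            if x.sample_ids != sids:
                raise ValueError(
                    f"sample ids of omics '{x.omics_name}' differ from '{X[0].omics_name}'"
                )
        self.dims = dims if isinstance(dims, LayerDims) else LayerDims(dims)
        self.dims.validate_against(X[0].n_samples, [x.n_features for x in X])
        self.penalties = penalties
        self.ppi_mode = ppi_mode
        self.scaled = scale
        self._raw = list(X)
        if scale:
            self.X = [_minmax_scale(x) for x in X]
        else:
            self.X = list(X)
        self.ppi = ppi
        if ppi is not None:
            if ppi_omics is None:
                overlaps = [len(set(x.feature_ids) & set(ppi.feature_ids)) for x in X]
                ppi_omics = int(np.argmax(overlaps))
            if X[ppi_omics].feature_ids != ppi.feature_ids:
                raise ValueError(
                    f"PPI prior is not aligned to omics '{X[ppi_omics].omics_name}' "
                    "(feature ids must match in order)"
                )
        self.ppi_omics = int(ppi_omics) if ppi_omics is not None else 0
        if graphs is None and penalties.lambda3 > 0:
            from .graphs import build_feature_graph

            graphs = [build_feature_graph(x, method=graph_method, tau=tau) for x in self.X]
        self.graphs = graphs

    @classmethod
    def from_dataframes(cls, frames: dict, ppi_edges=None, **kwargs) -> "PDJDSNMF":
        """Build from ``{omics_name: DataFrame}`` plus an optional edge list.

        ``ppi_edges`` is an iterable of (source, target) feature-id pairs
        attached to the omics chosen by ``ppi_omics`` (default: largest
        overlap with the edge list's node set).
        """
        X = [OmicsMatrix.from_dataframe(df, name) for name, df in frames.items()]
        ppi = None
        if ppi_edges is not None:
            nodes = {str(a) for a, b in ppi_edges} | {str(b) for a, b in ppi_edges}
            overlaps = [len(set(x.feature_ids) & nodes) for x in X]
            target = X[int(np.argmax(overlaps))]
            idx = {f: i for i, f in enumerate(target.feature_ids)}
            A = np.zeros((target.n_features, target.n_features))
            for a, b in ppi_edges:
                a, b = str(a), str(b)
                if a != b and a in idx and b in idx:
                    A[idx[a], idx[b]] = A[idx[b], idx[a]] = 1.0
            ppi = PriorNetwork(A, target.feature_ids)
        return cls(X, ppi, **kwargs)

    def objective(self, model: DeepFactorModel):
        return objective(
            model, self.X, self.ppi, self.graphs, self.penalties, self.ppi_mode, self.ppi_omics
        )

    def fit(
        self,
        max_iter: int = 2000,
        tol: float = 1e-5,
        learning_rate: float = 1e-2,
        seed: int = 0,
        linear: bool = False,
        init: DeepFactorModel | None = None,
        method: str = "adam",
        init_method: str = "svd",
    ) -> "PDJDSNMFResults":
        res = fit(
            self.X,
            self.ppi,
            self.graphs,
            self.dims,
            self.penalties,
            max_iter=max_iter,
            tol=tol,
            learning_rate=learning_rate,
            ppi_mode=self.ppi_mode,
            ppi_omics=self.ppi_omics,
            seed=seed,
            linear=linear,
            init=init,
            method=method,
            init_method=init_method,
        )
        return PDJDSNMFResults(self, res)


def _minmax_scale(x: OmicsMatrix) -> OmicsMatrix:
    V = x.values
    lo = V.min(axis=0)
    rng = V.max(axis=0) - lo
    out = np.zeros_like(V)
    nz = rng > 0
    out[:, nz] = (V[:, nz] - lo[nz]) / rng[nz]
    return OmicsMatrix(out, x.sample_ids, x.feature_ids, x.omics_name)


class PDJDSNMFResults:
    """Results of a PD-JDSNMF fit.

    Attributes
    ----------
    params : DeepFactorModel
        Fitted parameter matrices (``U``, junction matrices, deep layers).
    objective_trace, term_trace : ndarray
        Objective value and its four unweighted terms per iteration.
    recon_corr : dict
        Per-omics reconstruction Pearson correlation plus ``"mean"``.
    converged, iterations, seed
        Convergence flag, iteration count and the seed used.
    """

    def __init__(self, model: PDJDSNMF, raw: FitResult):
        self.model = model
        self.params = raw.model
        self.objective_trace = raw.objective_trace
        self.term_trace = raw.term_trace
        self.recon_corr = raw.recon_corr
        self.converged = raw.converged
        self.iterations = raw.iterations
        self.seed = raw.seed

    def coefficient_matrix(self, omics_index: int) -> np.ndarray:
        """First-layer coefficients ``H_i^0`` (k0 x p_i), each entry in (0,1)."""
        return _layers(self.params, omics_index)[0]

    def reconstruction(self, omics_index: int) -> np.ndarray:
        """``U H_i^0`` on the (scaled, if scaling is on) data scale."""
        return forward(self.params, omics_index)[1]

    def extract_modules(self, zscore_threshold: float = 1.96, two_sided: bool = False):
        from .modules import extract_modules

        return extract_modules(self, zscore_threshold=zscore_threshold, two_sided=two_sided)

    def summary(self) -> str:
        lines = ["PD-JDSNMF fit summary", "=" * 42]
        d = self.model.dims
        w = self.model.penalties
        lines.append(f"layers (k): {list(d.k)}   sublayers: {d.n_sublayers}")
        lines.append(
            f"lambda1={w.lambda1:g}  lambda2={w.lambda2:g}  lambda3={w.lambda3:g}  "
            f"ppi_mode={self.model.ppi_mode}"
        )
        lines.append(
            f"iterations: {self.iterations}   converged: {self.converged}   seed: {self.seed}"
        )
        if len(self.objective_trace):
            lines.append(f"final objective: {self.objective_trace[-1]:.6g}")
        lines.append("-" * 42)
        lines.append("reconstruction Pearson correlation")
        for name, r in self.recon_corr.items():
            lines.append(f"  {name:<12s} {r:8.4f}")
        return "\n".join(lines)

    # -- checkpointing -----------------------------------------------------

    def save(self, directory) -> None:
        """Write a checkpoint: TSV parameter matrices plus a JSON manifest."""
        import pandas as pd

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.params.U).to_csv(d / "U.tsv", sep="\t", index=False)
        names = [x.omics_name for x in self.model.X]
        for i, name in enumerate(names):
            for n, Zn in enumerate(self.params.Z[i], start=1):
                pd.DataFrame(Zn).to_csv(d / f"Z_{name}_{n}.tsv", sep="\t", index=False)
            pd.DataFrame(self.params.Hdeep[i]).to_csv(d / f"Hdeep_{name}.tsv", sep="\t", index=False)
            pd.DataFrame(self.coefficient_matrix(i), columns=self.model.X[i].feature_ids).to_csv(
                d / f"H0_{name}.tsv", sep="\t", index=False
            )
        manifest = {
            "dims": list(self.model.dims.k),
            "lambda1": self.model.penalties.lambda1,
            "lambda2": self.model.penalties.lambda2,
            "lambda3": self.model.penalties.lambda3,
            "ppi_mode": self.model.ppi_mode,
            "ppi_omics": self.model.ppi_omics,
            "scaled": self.model.scaled,
            "seed": self.seed,
            "iterations": self.iterations,
            "converged": self.converged,
            "linear": self.params.linear,
            "omics": names,
            "recon_corr": self.recon_corr,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
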