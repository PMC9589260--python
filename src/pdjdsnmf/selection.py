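"""Model selection: penalty grid search, layer-dimension sweep, ablations.

Both procedures score candidates by the reconstruction Pearson
correlation between each original matrix and its reconstruction, the
standard selection criterion in this model family. All candidates share
one seed and one SVD start so differences reflect the candidate settings,
not initialization noise.
"""

from __future__ import annotations

import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .graphs import FeatureGraph, build_feature_graph
from .io import OmicsMatrix, PriorNetwork
from .model import LayerDims, PDJDSNMF, PDJDSNMFResults, PenaltyWeights, _minmax_scale

logger = logging.getLogger("pdjdsnmf")

__all__ = ["lambda_grid_search", "dims_sweep", "select_dims", "ablation_fit"]


def _prepare(X, graphs, graph_method, tau, need_graphs):
    # graphs are correlation-based, hence identical on raw and scaled data
    if graphs is None and need_graphs:
        graphs = [build_feature_graph(_minmax_scale(x), method=graph_method, tau=tau) for x in X]
    return graphs


def lambda_grid_search(
    X: Sequence[OmicsMatrix],
    ppi: PriorNetwork | None,
    dims,
    grid: Sequence[float] = (0.001, 0.01, 0.1),
    graphs: Sequence[FeatureGraph] | None = None,
    graph_method: str = "corr_threshold",
    tau: float = 0.8,
    ppi_mode: str = "laplacian",
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit every (lambda1, lambda2, lambda3) in ``grid``^3 with a shared seed.

    The default grid {0.001, 0.01, 0.1} yields 27 combinations, enumerated
    with lambda1 slowest and lambda3 fastest (``combination`` is 1-based).
    Returns one row per combination with per-omics and mean reconstruction
    correlations; a diverging fit is recorded as missing, not fatal. The
    best combination is the argmax of the mean correlation.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")
    graphs = _prepare(X, graphs, graph_method, tau, need_graphs=any(g > 0 for g in grid))
    names = [x.omics_name for x in X]
    rows = []
    for idx, (l1, l2, l3) in enumerate(itertools.product(grid, grid, grid), start=1):
        row = {"combination": idx, "lambda1": l1, "lambda2": l2, "lambda3": l3}
        try:
            model = PDJDSNMF(
                X, ppi, dims=dims, penalties=PenaltyWeights(l1, l2, l3),
                graphs=graphs, ppi_mode=ppi_mode,
            )
            res = model.fit(seed=seed, **fit_kwargs)
            for name in names:
                row[f"corr_{name}"] = res.recon_corr[name]
            row["corr_mean"] = res.recon_corr["mean"]
        except FloatingPointError as exc:
            logger.warning("grid point %s diverged: %s", (l1, l2, l3), exc)
            for name in names:
                row[f"corr_{name}"] = np.nan
            row["corr_mean"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def dims_sweep(
    X: Sequence[OmicsMatrix],
    ppi: PriorNetwork | None,
    candidates: Sequence,
    penalties: PenaltyWeights = PenaltyWeights(),
    graphs: Sequence[FeatureGraph] | None = None,
    graph_method: str = "corr_threshold",
    tau: float = 0.8,
    ppi_mode: str = "laplacian",
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """One fit per candidate layer profile, shared seed, input order preserved.

    Output columns mirror the published sweep table: the layer sizes, one
    reconstruction correlation per omics, their mean, and the standard
    deviation across the three correlations. Both std conventions are
    reported: ``corr_std`` is the population (/3) std — the convention
    that reproduces the published table — and ``corr_std_sample`` the /2
    one. Selection maximizes the mean and breaks ties by smallest
    population std (see :func:`select_dims`).
    """
    graphs = _prepare(X, graphs, graph_method, tau, penalties.lambda3 > 0)
    names = [x.omics_name for x in X]
    cands = [c if isinstance(c, LayerDims) else LayerDims(c) for c in candidates]
    depth = max(len(c.k) for c in cands)
    rows = []
    for c in cands:
        row = {f"k{d}": (c.k[d] if d < len(c.k) else np.nan) for d in range(depth)}
        try:
            model = PDJDSNMF(X, ppi, dims=c, penalties=penalties, graphs=graphs, ppi_mode=ppi_mode)
            res = model.fit(seed=seed, **fit_kwargs)
            corrs = np.array([res.recon_corr[name] for name in names])
            for name, r in zip(names, corrs):
                row[f"corr_{name}"] = r
            row["corr_mean"] = float(corrs.mean())
            row["corr_std"] = float(corrs.std(ddof=0))
            row["corr_std_sample"] = float(corrs.std(ddof=1))
        except FloatingPointError as exc:
            logger.warning("candidate %s diverged: %s", c.k, exc)
            for name in names:
                row[f"corr_{name}"] = np.nan
            row["corr_mean"] = row["corr_std"] = row["corr_std_sample"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def select_dims(sweep: pd.DataFrame) -> int:
    """Index of the best sweep row: max mean correlation, ties broken by
    smallest population std."""
    ok = sweep.dropna(subset=["corr_mean"])
    if ok.empty:
        raise ValueError("no successful sweep rows")
    best_mean = ok["corr_mean"].max()
    near = ok[np.isclose(ok["corr_mean"], best_mean, rtol=0, atol=1e-12)]
    return int(near["corr_std"].idxmin())


def ablation_fit(
    X: Sequence[OmicsMatrix],
    ppi: PriorNetwork | None,
    graphs: Sequence[FeatureGraph] | None,
    dims,
    penalties: PenaltyWeights,
    variant: str = "pdjdsnmf",
    ppi_mode: str = "laplacian",
    seed: int = 0,
    **fit_kwargs,
) -> PDJDSNMFResults:
    """Fit one of the nested model variants.

    - ``"pdjdsnmf"``: the full model (all penalties as given).
    - ``"jdsnmf"``: the deep nonlinear model without priors
      (lambda2 = lambda3 = 0).
    - ``"jnmf"``: single-layer linear joint NMF; both the shared basis and
      the coefficients are kept nonnegative by projection after each step.
    """
    if variant not in ("pdjdsnmf", "jdsnmf", "jnmf"):
        raise ValueError(f"unknown variant {variant!r}")
    w = penalties
    linear = False
    if variant in ("jdsnmf", "jnmf"):
        w = PenaltyWeights(penalties.lambda1, 0.0, 0.0)
        ppi = None
        graphs = None
    if variant == "jnmf":
        linear = True
    model = PDJDSNMF(X, ppi, dims=dims, penalties=w, graphs=graphs, ppi_mode=ppi_mode)
    return model.fit(seed=seed, linear=linear, **fit_kwargs)
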