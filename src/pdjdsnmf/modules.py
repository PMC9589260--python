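"""Co-expression module extraction from a fitted factorization.

A module is one latent factor: for each omics, the factor's row of the
first-layer coefficient matrix ``H_i^0`` is standardized across features,
and features whose z-score clears a threshold are the module's members.
Each module is scored by the Pearson correlation between the original and
reconstructed data restricted to its member features, pooled across omics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("pdjdsnmf")

__all__ = ["Module", "ModuleSet", "extract_modules", "module_correlation", "module_summary"]


@dataclass
class Module:
    """Members of one factor across omics, with their z-scores."""

    factor_index: int
    members: dict  # omics_name -> {feature_id: zscore}
    correlation: float | None = None

    def member_ids(self, omics_name: str) -> list[str]:
        return list(self.members.get(omics_name, {}))

    def size(self, omics_name: str | None = None) -> int:
        if omics_name is not None:
            return len(self.members.get(omics_name, {}))
        return sum(len(m) for m in self.members.values())


@dataclass
class ModuleSet:
    modules: list[Module]
    omics_names: list[str]
    zscore_threshold: float = 1.96

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def __getitem__(self, i: int) -> Module:
        return self.modules[i]

    def to_json(self, path=None) -> str:
        payload = {
            "zscore_threshold": self.zscore_threshold,
            "omics": self.omics_names,
            "modules": [
                {
                    "factor_index": m.factor_index,
                    "correlation": m.correlation,
                    "members": {o: dict(d) for o, d in m.members.items()},
                }
                for m in self.modules
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_tsv(self, path=None) -> pd.DataFrame:
        rows = [
            {"module": m.factor_index, "omics": o, "feature": f, "z": z}
            for m in self.modules
            for o, d in m.members.items()
            for f, z in d.items()
        ]
        df = pd.DataFrame(rows, columns=["module", "omics", "feature", "z"])
        if path is not None:
            df.to_csv(path, sep="\t", index=False)
        return df


def extract_modules(results, zscore_threshold: float = 1.96, two_sided: bool = False) -> ModuleSet:
    """Threshold per-factor coefficient z-scores into a ModuleSet.

    For omics ``i`` and factor row ``r`` of ``H_i^0``, feature ``j`` is a
    member of module ``r`` iff ``z = (H[r,j] - mean_j) / std_j`` is at
    least ``zscore_threshold`` (``|z|`` with ``two_sided=True``). A
    constant row contributes no members. Exactly ``k0`` modules are
    returned, one per factor; a feature may belong to several.
    """
    if zscore_threshold <= 0:
        raise ValueError("zscore_threshold must be positive")
    model = results.model
    k0 = model.dims.k0
    names = [x.omics_name for x in model.X]
    modules = [Module(factor_index=r, members={o: {} for o in names}) for r in range(k0)]
    for i, name in enumerate(names):
        H0 = results.coefficient_matrix(i)
        mu = H0.mean(axis=1, keepdims=True)
        sd = H0.std(axis=1, ddof=1, keepdims=True)  # sample std across features
        for r in range(k0):
            if sd[r, 0] == 0:
                logger.info("factor %d: constant row for omics %s, no members", r, name)
                continue
            z = (H0[r] - mu[r, 0]) / sd[r, 0]
            hit = np.abs(z) >= zscore_threshold if two_sided else z >= zscore_threshold
            modules[r].members[name] = {
                model.X[i].feature_ids[j]: float(z[j]) for j in np.nonzero(hit)[0]
            }
    for m in modules:
        m.correlation = module_correlation(m, results)
    return ModuleSet(modules=modules, omics_names=names, zscore_threshold=zscore_threshold)


def module_correlation(module: Module, results) -> float | None:
    """Member-restricted reconstruction correlation, pooled across omics.

    Concatenates the member columns of every omics' (scaled) data matrix
    and of the corresponding reconstruction ``U H_i^0``, then takes one
    Pearson correlation. Returns None for an empty module.
    """
    model = results.model
    xs, ys = [], []
    for i, x in enumerate(model.X):
        ids = module.members.get(x.omics_name, {})
        if not ids:
            continue
        pos = [x.feature_ids.index(f) for f in ids]
        Xhat = results.reconstruction(i)
        xs.append(x.values[:, pos].ravel())
        ys.append(Xhat[:, pos].ravel())
    if not xs:
        return None
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def module_summary(ms: ModuleSet) -> pd.DataFrame:
    """Per-module member counts per omics plus correlation, ranked by correlation.

    A final ``mean`` row gives the average member count per omics across
    modules (the shape of the published per-module membership statistics).
    """
    cols = ["module"] + [f"n_{o}" for o in ms.omics_names] + ["correlation"]
    if not ms.modules:
        return pd.DataFrame(columns=cols)
    rows = []
    for m in ms.modules:
        row = {"module": m.factor_index}
        for o in ms.omics_names:
            row[f"n_{o}"] = m.size(o)
        row["correlation"] = m.correlation
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    df = df.sort_values("correlation", ascending=False, na_position="last").reset_index(drop=True)
    mean_row = {"module": "mean"}
    for o in ms.omics_names:
        mean_row[f"n_{o}"] = df[f"n_{o}"].mean()
    mean_row["correlation"] = df["correlation"].dropna().mean() if df["correlation"].notna().any() else None
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
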