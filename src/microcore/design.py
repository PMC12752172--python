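"""Design-matrix construction from sample metadata.

Categorical covariates get treatment (dummy) coding against a declared
reference level; continuous covariates are standardised to mean 0, SD 1.
Column labels are traceable: ``term[level]`` for dummies, the bare name
for continuous terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import SampleMetadata

__all__ = ["build_design"]


def build_design(
    meta: SampleMetadata,
    covariates: list[str],
    references: dict[str, str] | None = None,
    standardize: bool = True,
    add_intercept: bool = False,
) -> pd.DataFrame:
    """Build a model matrix for the named covariates.

    Parameters
    ----------
    meta
        Sample metadata; row order is preserved.
    covariates
        Metadata columns to encode, in order.
    references
        Reference level per categorical covariate; defaults to the
        declared reference (first declared level, else the alphabetically
        first observed level).
    standardize
        Standardise continuous columns to mean 0, SD 1.
    add_intercept
        Prepend a constant column named ``"(Intercept)"``.
    """
    references = references or {}
    cols: dict[str, np.ndarray] = {}
    if add_intercept:
        cols["(Intercept)"] = np.ones(len(meta.data))
    for cov in covariates:
        if cov not in meta.data.columns:
            raise ValueError(f"covariate {cov!r} not in metadata")
        series = meta.data[cov]
        if np.issubdtype(series.dtype, np.number) and cov not in meta.levels:
            vals = series.to_numpy(dtype=float)
            if standardize:
                sd = vals.std()
                if sd == 0:
                    raise ValueError(f"continuous covariate {cov!r} is constant")
                vals = (vals - vals.mean()) / sd
            cols[cov] = vals
        else:
            values = series.astype(str)
            declared = meta.levels.get(cov)
            observed = list(pd.unique(values))
            level_order = [l for l in declared if l in set(observed)] if declared else sorted(observed)
            ref = references.get(cov, meta.reference_level(cov))
            if ref not in level_order:
                # declared reference unobserved among retained samples: fall back
                ref = level_order[0]
            if len(level_order) < 2:
                raise ValueError(f"categorical covariate {cov!r} has a single level")
            unseen = set(values) - set(level_order)
            if unseen:
                raise ValueError(f"unseen level(s) {sorted(unseen)} for covariate {cov!r}")
            for level in level_order:
                if level == ref:
                    continue
                cols[f"{cov}[{level}]"] = (values == level).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=meta.data.index)
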