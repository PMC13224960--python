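"""Normalization ("trans") and prevalence filtering for omics tables.

Methods
-------
cpm
    counts per million: value / column sum * 1e6 (per sample).
acpm
    asinh(cpm); tames the heavy right tail of count data.
pa
    presence/absence: 1 where value > 0.
log
    log2(value + 1), the common transcriptomics convention.
log1
    natural log1p, the common MS proteomics/metabolomics convention.
"""

from __future__ import annotations

import numpy as np

from .model import OmicsTable

__all__ = ["trans", "filter_prevalence", "TRANS_METHODS"]

TRANS_METHODS = ("cpm", "acpm", "pa", "log", "log1")


def trans(table: OmicsTable, method: str) -> OmicsTable:
    """Return a normalized copy of ``table``; the transform name is appended
    to ``norm_history``.

    ``cpm``, ``acpm`` and ``pa`` require non-negative values; ``cpm`` and
    ``acpm`` additionally reject all-zero sample columns (undefined scaling).
    """
    if method not in TRANS_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {TRANS_METHODS}")
    v = table.values
    arr = v.to_numpy(dtype=float)
    if method in ("cpm", "acpm", "pa") and (arr < 0).any():
        raise ValueError(f"negative values are not allowed under {method!r}")
    if method in ("cpm", "acpm"):
        colsum = arr.sum(axis=0)
        if (colsum == 0).any():
            bad = v.columns[np.flatnonzero(colsum == 0)[0]]
            raise ValueError(f"all-zero sample column {bad!r} cannot be scaled")
        out = arr / colsum * 1e6
        if method == "acpm":
            out = np.arcsinh(out)
    elif method == "pa":
        out = (arr > 0).astype(float)
    elif method == "log":
        out = np.log2(arr + 1.0)
    else:  # log1
        out = np.log1p(arr)
    return table.copy_with(v.__class__(out, index=v.index, columns=v.columns), transform=method)


def filter_prevalence(table: OmicsTable, min_prev: float) -> tuple[OmicsTable, dict]:
    """Keep features present (value > 0) in strictly more than ``min_prev``
    of samples.  Returns the filtered table and a report dict."""
    if not 0 <= min_prev < 1:
        raise ValueError("min_prev must be in [0, 1)")
    prev = (table.values.to_numpy(dtype=float) > 0).mean(axis=1)
    keep = prev > min_prev
    out = table.copy_with(table.values.loc[keep])
    report = {
        "n_in": table.n_features,
        "n_kept": int(keep.sum()),
        "n_dropped": int((~keep).sum()),
        "min_prev": min_prev,
    }
    return out, report
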