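"""All-pairs correlation with analytic p-values and multiple-testing correction.

Correlations are computed by vectorized matrix products (optionally tiled
into row blocks to bound memory); two-sided p-values come from the exact
Student-t relation

    t = r * sqrt((n - 2) / (1 - r^2)),   df = n - 2,

so no permutation loop is needed.  Spearman is Pearson on midranks
(ties get the average rank).  Adjustment covers exactly the tests a
correlation screen performs: the strict upper triangle in intra mode,
the full rows x cols rectangle in inter mode.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .model import OmicsTable

__all__ = ["CorrelationResult", "c_net_calculate", "adjust_p"]

ADJUST_METHODS = ("BH", "bonferroni", "holm", "none")
_EXACT_ONE = 1.0 - 1e-12   # |r| beyond this is treated as exact +-1
_CLIP = 1.0 - 1e-15


@dataclass
class CorrelationResult:
    """Paired r / p / p_adj matrices with provenance.

    ``mode`` is ``"intra"`` (one table; symmetric matrices with unit
    diagonal) or ``"inter"`` (two tables; rectangular).  NaN entries mark
    zero-variance features and are NaN in all three matrices.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    n: int
    method: str
    adjust: str
    mode: str
    row_layer: str = ""
    col_layer: str = ""

    @property
    def row_ids(self) -> list[str]:
        return [str(i) for i in self.r.index]

    @property
    def col_ids(self) -> list[str]:
        return [str(c) for c in self.r.columns]

    def to_long(self) -> pd.DataFrame:
        """Long-format table (row, col, r, p, p_adj); intra mode emits the
        strict upper triangle only."""
        rows = []
        rv, pv, av = self.r.to_numpy(), self.p.to_numpy(), self.p_adj.to_numpy()
        ridx, cidx = list(self.r.index), list(self.r.columns)
        for i in range(rv.shape[0]):
            j0 = i + 1 if self.mode == "intra" else 0
            for j in range(j0, rv.shape[1]):
                rows.append((ridx[i], cidx[j], rv[i, j], pv[i, j], av[i, j]))
        return pd.DataFrame(rows, columns=["row", "col", "r", "p", "p_adj"])

    def save(self, path) -> None:
        """Portable archive: one ``.npz`` with the three matrices, the id
        vectors, and a JSON metadata string (documented layout)."""
        meta = {"n": int(self.n), "method": self.method, "adjust": self.adjust,
                "mode": self.mode, "row_layer": self.row_layer, "col_layer": self.col_layer}
        np.savez(
            path,
            r=self.r.to_numpy(), p=self.p.to_numpy(), p_adj=self.p_adj.to_numpy(),
            row_ids=np.array(self.row_ids, dtype=object),
            col_ids=np.array(self.col_ids, dtype=object),
            meta=np.array(json.dumps(meta)),
        )

    @classmethod
    def load(cls, path) -> "CorrelationResult":
        with np.load(path, allow_pickle=True) as z:
            meta = json.loads(str(z["meta"]))
            rows = [str(x) for x in z["row_ids"]]
            cols = [str(x) for x in z["col_ids"]]
            return cls(
                r=pd.DataFrame(z["r"], index=rows, columns=cols),
                p=pd.DataFrame(z["p"], index=rows, columns=cols),
                p_adj=pd.DataFrame(z["p_adj"], index=rows, columns=cols),
                n=meta["n"], method=meta["method"], adjust=meta["adjust"],
                mode=meta["mode"], row_layer=meta.get("row_layer", ""),
                col_layer=meta.get("col_layer", ""),
            )


def adjust_p(p_values, method: str = "BH", m: int | None = None) -> np.ndarray:
    """Multiple-testing adjustment of a 1-D p-value collection.

    NaN entries are passed through and excluded from the test count unless
    ``m`` is given explicitly.  BH is the step-up procedure with running
    minimum; Holm the step-down with running maximum; Bonferroni the plain
    ``min(1, m*p)``.
    """
    if method not in ADJUST_METHODS:
        raise ValueError(f"unknown adjust method {method!r}; choose from {ADJUST_METHODS}")
    p = np.asarray(p_values, dtype=float).ravel()
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    q = p[finite]
    k = q.size
    if k == 0:
        return out
    m_eff = k if m is None else int(m)
    if method == "none":
        out[finite] = q
        return out
    if method == "bonferroni":
        out[finite] = np.minimum(1.0, q * m_eff)
        return out
    order = np.argsort(q, kind="stable")
    sorted_q = q[order]
    if method == "BH":
        ranks = np.arange(1, k + 1)
        adj = sorted_q * m_eff / ranks
        adj = np.minimum.accumulate(adj[::-1])[::-1]
    else:  # holm
        mult = m_eff - np.arange(k)
        adj = np.maximum.accumulate(np.clip(mult, 1, None) * sorted_q)
    adj = np.minimum(adj, 1.0)
    restored = np.empty(k)
    restored[order] = adj
    out[finite] = restored
    return out


def _as_matrix(table) -> tuple[np.ndarray, list, list, str]:
    if isinstance(table, OmicsTable):
        df = table.values
        layer = table.layer
    elif isinstance(table, pd.DataFrame):
        df, layer = table, ""
    else:
        raise TypeError("expected OmicsTable or DataFrame (features x samples)")
    return df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns.astype(str)), layer


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=1, method="average")


def _p_from_r(r: np.ndarray, n) -> np.ndarray:
    """Two-sided p from the exact t relation; |r| ~ 1 maps to p = 0."""
    df = np.asarray(n, dtype=float) - 2.0
    exact = np.abs(r) >= _EXACT_ONE
    rc = np.clip(r, -_CLIP, _CLIP)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rc * np.sqrt(df / (1.0 - rc * rc))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(exact, 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    return p


def _pearson_block(a: np.ndarray, b: np.ndarray, block_size: int) -> np.ndarray:
    """Row-standardize and multiply, tiled over row blocks of ``a``."""
    def standardize(x):
        xc = x - x.mean(axis=1, keepdims=True)
        ss = np.sqrt((xc * xc).sum(axis=1))
        zero = ss == 0
        ss_safe = np.where(zero, 1.0, ss)
        z = xc / ss_safe[:, None]
        z[zero] = np.nan
        return z

    za, zb = standardize(a), standardize(b)
    out = np.empty((za.shape[0], zb.shape[0]))
    for start in range(0, za.shape[0], block_size):
        stop = min(start + block_size, za.shape[0])
        out[start:stop] = za[start:stop] @ zb.T
    return out


def _pairwise_pearson(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson r and per-pair n via masked matrix algebra."""
    ma, mb = np.isfinite(a), np.isfinite(b)
    a0, b0 = np.where(ma, a, 0.0), np.where(mb, b, 0.0)
    ma_f, mb_f = ma.astype(float), mb.astype(float)
    n = ma_f @ mb_f.T
    sx = a0 @ mb_f.T
    sy = ma_f @ b0.T
    sxx = (a0 * a0) @ mb_f.T
    syy = ma_f @ (b0 * b0).T
    sxy = a0 @ b0.T
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r = cov / np.sqrt(vx * vy)
    r[(n < 3) | ~np.isfinite(r)] = np.nan
    return r, n


def c_net_calculate(
    table_a,
    table_b=None,
    method: str = "spearman",
    adjust: str = "BH",
    missing: str = "complete",
    block_size: int = 1024,
) -> CorrelationResult:
    """All-pairs correlation of one table (intra) or two tables (inter).

    Tables must share sample ids; with two tables the sample intersection
    is used (aligned by id) and must contain at least 3 samples.  Features
    with zero variance get NaN rows/columns.  ``missing="pairwise"``
    switches to pairwise-complete observations with per-pair df in the
    t formula; the default drops samples with any missing value.

    Raises ``NotImplementedError`` for ``method="bray"`` (dissimilarity
    screens are out of scope for the analytic p-value route).
    """
    if method == "bray":
        raise NotImplementedError(
            "Bray-Curtis mode is not implemented; use pearson or spearman")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}; choose pearson or spearman")
    if missing not in ("complete", "pairwise"):
        raise ValueError("missing must be 'complete' or 'pairwise'")

    a, row_ids, samples_a, layer_a = _as_matrix(table_a)
    mode = "intra" if table_b is None else "inter"
    if table_b is None:
        b, col_ids, samples_b, layer_b = a, row_ids, samples_a, layer_a
    else:
        b, col_ids, samples_b, layer_b = _as_matrix(table_b)

    shared = [s for s in samples_a if s in set(samples_b)]
    if len(shared) < 3:
        raise ValueError(
            f"need at least 3 shared samples, found {len(shared)}")
    ia = [samples_a.index(s) for s in shared]
    ib = [samples_b.index(s) for s in shared]
    a = a[:, ia]
    b = b[:, ib]

    if missing == "complete":
        ok = np.isfinite(a).all(axis=0) & np.isfinite(b).all(axis=0)
        a, b = a[:, ok], b[:, ok]

    n = a.shape[1]
    if n < 3:
        raise ValueError(f"need n >= 3 complete samples, found {n}")
    if n == 3:
        warnings.warn("n = 3 gives df = 1: p-values have very heavy tails",
                      stacklevel=2)

    if missing == "complete":
        if method == "spearman":
            a_use, b_use = _rank_rows(a), (_rank_rows(b) if table_b is not None else None)
            if b_use is None:
                b_use = a_use
        else:
            a_use, b_use = a, b
        r = _pearson_block(a_use, b_use, block_size)
        n_eff: np.ndarray | int = n
    else:
        r, n_eff = _pairwise_missing(a, b, method, intra=table_b is None)

    if mode == "intra":
        r = (r + r.T) / 2.0
        np.fill_diagonal(r, np.where(np.isnan(np.diag(r)), np.nan, 1.0))
    r = np.where(np.abs(r) >= _EXACT_ONE, np.sign(r), r)

    p = _p_from_r(r, n_eff)
    if mode == "intra":
        np.fill_diagonal(p, np.where(np.isnan(np.diag(r)), np.nan, 0.0))

    p_adj = _adjust_matrix(p, adjust, mode)

    return CorrelationResult(
        r=pd.DataFrame(r, index=row_ids, columns=col_ids),
        p=pd.DataFrame(p, index=row_ids, columns=col_ids),
        p_adj=pd.DataFrame(p_adj, index=row_ids, columns=col_ids),
        n=int(np.min(n_eff)) if np.ndim(n_eff) else int(n_eff),
        method=method, adjust=adjust, mode=mode,
        row_layer=layer_a, col_layer=layer_b,
    )


def _pairwise_missing(a, b, method, intra):
    if method == "pearson":
        return _pairwise_pearson(a, b)
    # per-pair re-ranking cannot be expressed as one matrix product
    r = np.full((a.shape[0], b.shape[0]), np.nan)
    n = np.zeros_like(r)
    for i in range(a.shape[0]):
        for j in range(b.shape[0]):
            ok = np.isfinite(a[i]) & np.isfinite(b[j])
            if ok.sum() < 3:
                continue
            x = stats.rankdata(a[i, ok])
            y = stats.rankdata(b[j, ok])
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r[i, j] = np.corrcoef(x, y)[0, 1]
            n[i, j] = ok.sum()
    return r, n


def _adjust_matrix(p: np.ndarray, adjust: str, mode: str) -> np.ndarray:
    """Adjust over the strict upper triangle (intra, mirrored back) or the
    full rectangle (inter); the unit diagonal never enters the universe."""
    if adjust == "none":
        return p.copy()
    out = np.full(p.shape, np.nan)
    if mode == "intra":
        iu = np.triu_indices(p.shape[0], k=1)
        out[iu] = adjust_p(p[iu], adjust)
        out.T[iu] = out[iu]
        np.fill_diagonal(out, np.where(np.isnan(np.diag(p)), np.nan, 0.0))
    else:
        out = adjust_p(p.ravel(), adjust).reshape(p.shape)
    return out
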