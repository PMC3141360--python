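"""Spearman rank correlation matrix across the per-zone layers.

Spearman's rho is computed as the Pearson correlation of average-ranked
values (average ranks for ties), which is the standard tie-corrected
formulation. Two-sided significance uses the t approximation

    t = rho * sqrt((n - 2) / (1 - rho^2)),  df = n - 2,

appropriate for the several-hundred-zone regime this analysis targets; a
seed-controlled permutation test is available for small n. Because ranks
are invariant to the positive scaling used in standardization, the
matrix is computed on the raw (unstandardized) layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedCorrelationError, ValidationError

MATRIX_ORDER = ["density", "flats", "ill", "old", "uhi"]
RAW_COLUMN = {
    "density": "density_raw",
    "flats": "flats_raw",
    "ill": "ill_raw",
    "old": "old_raw",
    "uhi": "uhi_raw",
}


def spearman_rho(x, y) -> float:
    """Spearman's rho: Pearson correlation of average-ranked values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("vectors differ in length")
    if x.size < 3:
        raise ValidationError("need n >= 3 for a rank correlation")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation with a constant vector")
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman_p(rho: float, n: int) -> float:
    """Two-sided p for rho via the t approximation with n-2 df.

    |rho| = 1 is reported as p = 0 (the t statistic diverges).
    """
    if n < 4:
        raise ValidationError("need n >= 4 for a p-value")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def spearman_p_permutation(x, y, n_perm: int = 9999, seed: int = 0) -> float:
    """Permutation two-sided p for small samples (seed-controlled)."""
    rng = np.random.default_rng(seed)
    obs = abs(spearman_rho(x, y))
    y = np.asarray(y, dtype=float)
    hits = 0
    for _ in range(n_perm):
        try:
            r = spearman_rho(x, rng.permutation(y))
        except UndefinedCorrelationError:  # pragma: no cover - constant input
            continue
        if abs(r) >= obs - 1e-15:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def significance_flag(p: float) -> str:
    """'**' for p < 0.01, '*' for p < 0.05, '' otherwise."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationMatrix:
    """Lower-triangular Spearman matrix with significance flags."""

    names: list[str]
    rho: pd.DataFrame  # NaN above the diagonal and on it
    p: pd.DataFrame
    flags: pd.DataFrame
    n: int

    def to_frame(self) -> pd.DataFrame:
        """Printable lower-triangular layout with flag suffixes."""
        out = pd.DataFrame("-", index=self.names, columns=self.names)
        for i, a in enumerate(self.names):
            for j in range(i):
                b = self.names[j]
                r = self.rho.loc[a, b]
                if np.isnan(r):
                    out.loc[a, b] = "n/a"
                else:
                    out.loc[a, b] = f"{r:.3f}{self.flags.loc[a, b]}"
        return out


def correlation_matrix(
    table: pd.DataFrame, order: list[str] | None = None
) -> CorrelationMatrix:
    """All pairwise Spearman correlations between raw layers.

    ``table`` is a layer table with the *_raw columns; a pair involving a
    constant layer is reported as NaN while the other pairs proceed.
    """
    names = order or MATRIX_ORDER
    cols = {}
    for name in names:
        col = RAW_COLUMN.get(name, name)
        if col not in table.columns:
            raise ValidationError(f"layer table missing column {col!r}")
        cols[name] = table[col].to_numpy(dtype=float)
    n = len(table)
    rho = pd.DataFrame(np.nan, index=names, columns=names)
    p = pd.DataFrame(np.nan, index=names, columns=names)
    flags = pd.DataFrame("", index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i):
            b = names[j]
            try:
                r = spearman_rho(cols[a], cols[b])
            except UndefinedCorrelationError:
                continue
            rho.loc[a, b] = r
            if n >= 4:
                pv = spearman_p(r, n)
                p.loc[a, b] = pv
                flags.loc[a, b] = significance_flag(pv)
    return CorrelationMatrix(names=names, rho=rho, p=p, flags=flags, n=n)


def write_correlation_csv(matrix: CorrelationMatrix, path) -> None:
    matrix.to_frame().to_csv(path, index_label=f"n={matrix.n}")
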