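"""Spatial screening of digital expression: Moran's I and co-expression.

Regionalized genes concentrate expression in contiguous territories, so
neighboring voxels carry similar values; spatially dispersed
(salt-and-pepper) or noise-dominated genes do not. Moran's I over a 26-voxel
neighborhood (the 3x3x3 cube around each in-mask voxel) quantifies this:

    I = (N / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with N in-mask voxels and W the sum of weights. Under spatial randomness
E[I] = -1/(N-1); inference uses either the Cliff-Ord randomization variance
(normal approximation, one-sided upper tail) or a permutation test.

Co-expression is screened with plain Pearson correlation between the digital
expressions of gene pairs over in-mask voxels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .reconstruction import DigitalExpressionModel, VolumeMask

#: The 13 lexicographically positive offsets of the 3x3x3 cube; with their
#: negations they enumerate all 26 neighbors.
_HALF_OFFSETS = [
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if (di, dj, dk) > (0, 0, 0)
]


class ConstantFieldError(ValueError):
    """Moran's I is undefined for a field constant over the mask."""


@dataclass
class NeighborWeights:
    """Sparse spatial weights over in-mask voxels (3x3x3 cube contiguity)."""

    mask: VolumeMask
    matrix: sparse.csr_matrix
    style: str

    def __post_init__(self) -> None:
        self._moments: tuple[float, float, float] | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        """Sum of all weights (W)."""
        return float(self.matrix.sum())

    @property
    def neighbor_counts(self) -> np.ndarray:
        return np.asarray((self.matrix != 0).sum(axis=1)).ravel()

    @property
    def isolated(self) -> np.ndarray:
        """In-mask voxels with no in-mask neighbor."""
        return self.neighbor_counts == 0

    def moments(self) -> tuple[float, float, float]:
        """(S0, S1, S2) of the Cliff-Ord variance formula."""
        if self._moments is None:
            w = self.matrix
            s0 = self.s0
            sym = w + w.T
            s1 = 0.5 * float(sym.multiply(sym).sum())
            row = np.asarray(w.sum(axis=1)).ravel()
            col = np.asarray(w.sum(axis=0)).ravel()
            s2 = float(((row + col) ** 2).sum())
            self._moments = (s0, s1, s2)
        return self._moments

    def values(self, field: np.ndarray) -> np.ndarray:
        """Flatten a 3D field to the weights' in-mask voxel order."""
        field = np.asarray(field, dtype=float)
        if field.shape != self.mask.shape:
            raise ValueError(
                f"field shape {field.shape} does not match mask {self.mask.shape}"
            )
        return field[self.mask.in_mask]


def build_weights(mask: VolumeMask, style: str = "binary") -> NeighborWeights:
    """Binary (or row-standardized) 26-connectivity weights within the mask.

    Two in-mask voxels are neighbors when one lies in the 3x3x3 cube centered
    on the other (Chebyshev distance 1); out-of-mask voxels never contribute.
    """
    if style not in ("binary", "row_standardized"):
        raise ValueError(f"unknown weight style {style!r}")
    grid = mask.in_mask
    if mask.n_voxels < 4:
        raise ValueError("mask must contain at least 4 voxels")
    index = -np.ones(grid.shape, dtype=np.int64)
    index[grid] = np.arange(mask.n_voxels)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for off in _HALF_OFFSETS:
        src = [slice(max(0, -o), grid.shape[a] - max(0, o)) for a, o in enumerate(off)]
        dst = [slice(max(0, o), grid.shape[a] + min(0, o)) for a, o in enumerate(off)]
        a = index[tuple(src)].ravel()
        b = index[tuple(dst)].ravel()
        keep = (a >= 0) & (b >= 0)
        rows.append(a[keep])
        cols.append(b[keep])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    n = mask.n_voxels
    w = sparse.coo_matrix(
        (np.ones(2 * r.size), (np.concatenate([r, c]), np.concatenate([c, r]))),
        shape=(n, n),
    ).tocsr()
    if style == "row_standardized":
        counts = np.asarray(w.sum(axis=1)).ravel()
        inv = np.divide(1.0, counts, out=np.zeros_like(counts), where=counts > 0)
        w = sparse.diags(inv) @ w
    return NeighborWeights(mask=mask, matrix=w.tocsr(), style=style)


def _centered(field: np.ndarray, weights: NeighborWeights) -> tuple[np.ndarray, float]:
    x = weights.values(field)
    # ptp (not den == 0): the mean of N identical floats can differ from them
    # by rounding, leaving a spurious tiny variance.
    if np.ptp(x) == 0:
        raise ConstantFieldError("undefined index: field is constant over the mask")
    z = x - x.mean()
    den = float(z @ z)
    return z, den


def morans_i(field: np.ndarray, weights: NeighborWeights) -> float:
    """Moran's spatial autocorrelation index of a 3D field over the mask."""
    z, den = _centered(field, weights)
    num = float(z @ (weights.matrix @ z))
    return (weights.n / weights.s0) * num / den


@dataclass
class MoranResult:
    """Moran's I for one gene with its null moments and one-sided p-value.

    ``neg_log_p`` is -ln(p), infinite when p underflows to exactly zero (the
    strongest possible support at double precision).
    """

    gene_id: str
    I: float
    expected: float
    variance: float
    z: float
    p_value: float
    neg_log_p: float
    method: str
    n_voxels: int
    total_digital_expression: float = math.nan
    low_expression: bool = False

    @property
    def p_underflowed(self) -> bool:
        return self.p_value == 0.0


def _analytic_moments(z: np.ndarray, den: float, weights: NeighborWeights) -> tuple[float, float]:
    """E[I] and the Cliff-Ord randomization variance for the observed values."""
    n = weights.n
    if n < 4:
        raise ValueError("randomization variance requires at least 4 voxels")
    s0, s1, s2 = weights.moments()
    b2 = n * float((z**4).sum()) / den**2
    e_i = -1.0 / (n - 1)
    num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0) - b2 * (
        (n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0
    )
    var = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i * e_i
    return e_i, var


def morans_test(
    field: np.ndarray,
    weights: NeighborWeights,
    method: str = "analytic",
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
    gene_id: str = "",
    total_digital_expression: float | None = None,
) -> MoranResult:
    """Moran's I with a one-sided (positive autocorrelation) significance test.

    ``analytic``: normal approximation with the randomization variance.
    ``permutation``: p = (1 + #{I_perm >= I_obs}) / (1 + n_perm) over random
    relabelings of the in-mask values; the analytic moments are still
    reported for reference.
    """
    z, den = _centered(field, weights)
    n = weights.n
    i_obs = (n / weights.s0) * float(z @ (weights.matrix @ z)) / den
    e_i, var = _analytic_moments(z, den, weights)
    zscore = (i_obs - e_i) / math.sqrt(var) if var > 0 else math.inf

    if method == "analytic":
        p = float(stats.norm.sf(zscore))
    elif method == "permutation":
        if n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        rng = np.random.default_rng(seed)
        perms = np.empty((n_perm, n))
        for k in range(n_perm):
            perms[k] = rng.permutation(z)
        num = np.einsum("pi,pi->p", perms @ weights.matrix.T, perms)
        i_perm = (n / weights.s0) * num / den
        p = float((1 + int((i_perm >= i_obs - 1e-12).sum())) / (1 + n_perm))
    else:
        raise ValueError(f"unknown method {method!r}")

    total = math.nan if total_digital_expression is None else float(total_digital_expression)
    return MoranResult(
        gene_id=gene_id,
        I=i_obs,
        expected=e_i,
        variance=var,
        z=zscore,
        p_value=p,
        neg_log_p=math.inf if p == 0 else -math.log(p),
        method=method,
        n_voxels=n,
        total_digital_expression=total,
        low_expression=(not math.isnan(total)) and total < 100,
    )


def sector_classify(I: float, neg_log_p: float) -> int | None:
    """Classify a gene into the five (index, p-value) sectors of the screen.

    Sectors 1-3 are index bands alone (0.01<I<0.02, 0.06<I<0.07, 0.09<I<0.1);
    sectors 4 and 5 additionally require the p-value to have underflowed to
    zero (0.1<I<0.2 and 0.6<I<0.7 respectively). Values outside every band
    return ``None``.
    """
    if not math.isfinite(I):
        raise ValueError("sector classification requires a finite index")
    if 0.01 < I < 0.02:
        return 1
    if 0.06 < I < 0.07:
        return 2
    if 0.09 < I < 0.1:
        return 3
    if math.isinf(neg_log_p):
        if 0.1 < I < 0.2:
            return 4
        if 0.6 < I < 0.7:
            return 5
    return None


def moran_screen_table(
    model: DigitalExpressionModel,
    weights: NeighborWeights,
    method: str = "analytic",
    n_perm: int = 9999,
    seed: int | None = None,
    i_min: float = 0.1,
    p_max: float = 0.0,
    p_adjust: str = "none",
) -> pd.DataFrame:
    """Moran screen over every gene of a model, as a tidy table.

    Constant (including all-zero) volumes cannot be screened; they appear
    with ``unscreenable=True`` and NaN statistics rather than being dropped.
    ``passes`` marks genes with I > i_min whose p-value underflowed to zero
    (or p <= p_max when p_max > 0). ``low_expression`` flags genes whose
    total digital expression is below 100, where the index is unreliable.
    The screen uses raw p-values by default; ``p_adjust="bh"`` adds a
    Benjamini-Hochberg ``p_adjusted`` column and applies the pass rule to it.
    """
    if p_adjust not in ("none", "bh"):
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    rows = []
    rng = np.random.default_rng(seed)
    for gene in model.genes:
        total = float(model.volumes[gene].sum())
        try:
            res = morans_test(
                model.volumes[gene], weights, method=method, n_perm=n_perm,
                seed=rng, gene_id=gene, total_digital_expression=total,
            )
        except ConstantFieldError:
            rows.append(
                dict(gene=gene, I=math.nan, expected=math.nan, variance=math.nan,
                     z=math.nan, p_value=math.nan, neg_log_p=math.nan,
                     total_digital_expression=total,
                     low_expression=total < 100, unscreenable=True,
                     passes=False, sector=None)
            )
            continue
        rows.append(
            dict(gene=gene, I=res.I, expected=res.expected, variance=res.variance,
                 z=res.z, p_value=res.p_value, neg_log_p=res.neg_log_p,
                 total_digital_expression=total, low_expression=res.low_expression,
                 unscreenable=False, passes=False,
                 sector=sector_classify(res.I, res.neg_log_p))
        )
    table = pd.DataFrame(rows).set_index("gene")
    p_col = "p_value"
    if p_adjust == "bh":
        screened = ~table["unscreenable"]
        adjusted = np.full(len(table), np.nan)
        if screened.any():
            adjusted[screened.to_numpy()] = stats.false_discovery_control(
                table.loc[screened, "p_value"].to_numpy(), method="bh"
            )
        table["p_adjusted"] = adjusted
        p_col = "p_adjusted"
    crit = (
        table[p_col] == 0.0 if p_max == 0.0 else table[p_col] <= p_max
    )
    table["passes"] = (~table["unscreenable"]) & (table["I"] > i_min) & crit
    return table


def screen_regionalized(
    model: DigitalExpressionModel,
    weights: NeighborWeights,
    i_min: float = 0.1,
    p_max: float = 0.0,
    method: str = "analytic",
    n_perm: int = 9999,
    seed: int | None = None,
) -> list[MoranResult]:
    """Genes passing the regionalization cut (I > i_min, p-value underflow).

    The default cut (I > 0.1 with p = 0) targets strongly supported positive
    autocorrelation, i.e. genes expressed in contiguous territories.
    """
    table = moran_screen_table(
        model, weights, method=method, n_perm=n_perm, seed=seed,
        i_min=i_min, p_max=p_max,
    )
    out = []
    for gene, row in table[table["passes"]].iterrows():
        out.append(
            MoranResult(
                gene_id=str(gene), I=row["I"], expected=row["expected"],
                variance=row["variance"], z=row["z"], p_value=row["p_value"],
                neg_log_p=row["neg_log_p"], method=method, n_voxels=weights.n,
                total_digital_expression=row["total_digital_expression"],
                low_expression=bool(row["low_expression"]),
            )
        )
    return out


def _stacked_values(
    model: DigitalExpressionModel, genes: Sequence[str]
) -> np.ndarray:
    grid = model.mask.in_mask
    return np.stack([np.asarray(model.volumes[g], dtype=float)[grid] for g in genes])


def pairwise_correlation(
    model: DigitalExpressionModel, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """All-pairs Pearson correlation of digital expressions over in-mask voxels.

    Out-of-mask voxels are structurally zero for every gene and are excluded
    (they would inflate every correlation). Pairs involving a constant gene
    are undefined and reported as NaN; the diagonal is 1 for non-constant
    genes.
    """
    if genes is None:
        genes = model.genes
    if len(genes) < 2:
        raise ValueError("pairwise correlation requires at least 2 genes")
    mat = _stacked_values(model, genes)
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    zmat = centered / safe[:, None]
    cor = zmat @ zmat.T
    np.clip(cor, -1.0, 1.0, out=cor)
    cor[constant, :] = np.nan
    cor[:, constant] = np.nan
    np.fill_diagonal(cor, np.where(constant, np.nan, 1.0))
    return pd.DataFrame(cor, index=list(genes), columns=list(genes))


@dataclass
class CorrelationRanking:
    """Genes ranked by decreasing Pearson correlation to a reference gene."""

    reference: str
    entries: list[tuple[str, float]]
    cor_min: float
    top_k: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.entries) + 1),
                "gene": [g for g, _ in self.entries],
                "Cor": [c for _, c in self.entries],
            }
        ).set_index("rank")


def coexpression_ranking(
    model: DigitalExpressionModel,
    reference: str,
    cor_min: float = 0.4,
    top_k: int | None = None,
) -> CorrelationRanking:
    """Rank every other gene by Pearson correlation to ``reference``.

    Keeps genes with Cor >= cor_min (the co-expression screen's threshold),
    optionally truncated to the ``top_k`` strongest. Constant genes are
    unrankable and omitted; a constant reference is an error.
    """
    if reference not in model.volumes:
        raise KeyError(f"unknown reference gene {reference!r}")
    genes = [g for g in model.genes]
    mat = _stacked_values(model, genes)
    ref_idx = genes.index(reference)
    ref = mat[ref_idx] - mat[ref_idx].mean()
    ref_norm = math.sqrt(float(ref @ ref))
    if ref_norm == 0:
        raise ConstantFieldError("reference field is constant over the mask")
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    entries = []
    for g, row, nrm in zip(genes, centered, norms):
        if g == reference or nrm == 0:
            continue
        cor = float(row @ ref) / (nrm * ref_norm)
        if cor >= cor_min:
            entries.append((g, cor))
    entries.sort(key=lambda e: (-e[1], e[0]))
    if top_k is not None:
        entries = entries[:top_k]
    return CorrelationRanking(reference=reference, entries=entries, cor_min=cor_min, top_k=top_k)


def write_moran_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t")
    return path


def write_ranking(ranking: CorrelationRanking, path: str | Path) -> Path:
    path = Path(path)
    ranking.to_frame().to_csv(path, sep="\t")
    return path
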