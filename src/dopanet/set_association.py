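"""Tercile-discretized gene-set association ("Super Gene Set" style).

Expression values are discretized by absolute magnitude into terciles
(+1 high, 0 middle, −1 low). Two genes are concordant when their
discretized profiles agree — directly (positive) or after negation
(negative) — in at least a ``min_agree`` fraction of samples. The
association between two gene sets is then the hypergeometric upper tail
of the concordant pair count: population = all (a, b) pairs with a in
set A and b in the background outside A, draws = the pairs with b in set
B, successes = concordant pairs. The reported sign is whichever
concordance direction dominates among the drawn pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .enrichment import hypergeom_upper_tail
from .io_model import ExpressionExperiment, normalize_symbols

__all__ = [
    "DiscretizedMatrix",
    "SetAssociationResult",
    "discretize",
    "gene_concordance",
    "associate_sets",
]


@dataclass
class DiscretizedMatrix:
    """Genes × samples matrix with entries in {−1, 0, +1}."""

    values: pd.DataFrame
    band_counts: dict[int, int]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class SetAssociationResult:
    set_a: str
    set_b: str
    n_concordant_pairs: int
    n_possible_pairs: int
    p: float
    sign: str  # "positive" | "negative"
    n_positive_pairs: int = 0
    n_negative_pairs: int = 0
    population_pairs: int = 0
    population_concordant: int = 0

    def to_dict(self) -> dict:
        return {
            "set_a": self.set_a,
            "set_b": self.set_b,
            "k": self.n_concordant_pairs,
            "n_pairs": self.n_possible_pairs,
            "p": float(self.p),
            "sign": self.sign,
        }


def _tercile_codes(flat_abs: np.ndarray) -> np.ndarray:
    """Stable-ranked tercile codes for a flat vector of magnitudes."""
    T = flat_abs.size
    t = T // 3
    codes = np.zeros(T, dtype=np.int8)
    if t:
        order = np.argsort(flat_abs, kind="stable")
        codes[order[:t]] = -1
        codes[order[T - t :]] = 1
    return codes


def discretize(e: ExpressionExperiment, scope: str = "global") -> DiscretizedMatrix:
    """Tercile discretization of absolute expression.

    ``global`` ranks all matrix entries together; ``per_sample`` ranks
    within each sample. Exactly ⌊T/3⌋ entries land in the +1 and −1 bands
    (T = entries in scope); the remainder of the integer division stays in
    the 0 band. Ties break by stable (gene, sample) order, so the band
    counts are exact even for constant input.
    """
    if scope not in ("global", "per_sample"):
        raise ValueError("scope must be 'global' or 'per_sample'")
    X = np.abs(e.values.to_numpy(dtype=float))
    if X.size == 0:
        raise ValueError("empty expression matrix")
    if scope == "global":
        codes = _tercile_codes(X.ravel(order="C")).reshape(X.shape)
    else:
        codes = np.column_stack([_tercile_codes(X[:, j]) for j in range(X.shape[1])])
    values = pd.DataFrame(codes, index=e.values.index, columns=e.values.columns)
    band_counts = {
        -1: int(np.count_nonzero(codes == -1)),
        0: int(np.count_nonzero(codes == 0)),
        1: int(np.count_nonzero(codes == 1)),
    }
    return DiscretizedMatrix(values, band_counts)


def gene_concordance(
    d: DiscretizedMatrix, gene_i: str, gene_j: str, min_agree: float = 2 / 3
) -> str:
    """Pairwise profile concordance: 'positive', 'negative' or 'none'.

    Positive when the two discretized profiles agree in >= min_agree of
    samples; negative when profile i equals the negation of profile j as
    often; positive takes precedence on an exact tie (all-zero profiles
    agree both ways and are reported positive).
    """
    xi = d.values.loc[normalize_symbol_or_raise(d, gene_i)].to_numpy()
    xj = d.values.loc[normalize_symbol_or_raise(d, gene_j)].to_numpy()
    eq = float(np.mean(xi == xj))
    neg = float(np.mean(xi == -xj))
    tol = 1e-12
    if eq >= min_agree - tol and eq >= neg:
        return "positive"
    if neg >= min_agree - tol:
        return "negative"
    return "none"


def normalize_symbol_or_raise(d: DiscretizedMatrix, gene: str) -> str:
    from .io_model import normalize_symbol

    g = normalize_symbol(gene)
    if g not in d.values.index:
        raise KeyError(f"gene {g} not in discretized matrix")
    return g


def associate_sets(
    d: DiscretizedMatrix,
    set_a: Iterable[str],
    set_b: Iterable[str],
    background: Optional[Iterable[str]] = None,
    min_agree: float = 2 / 3,
    name_a: str = "set_a",
    name_b: str = "set_b",
) -> SetAssociationResult:
    """Hypergeometric set–set association on discretized profiles.

    Shared genes are excluded from set B (and B is restricted to the
    background); the background defaults to every gene in the matrix.
    """
    genes = set(d.values.index)
    A = sorted(normalize_symbols(set_a) & genes)
    bg = normalize_symbols(background) & genes if background is not None else genes
    pop_b = sorted((bg - set(A)))
    B = normalize_symbols(set_b) & set(pop_b)
    if not A or not B:
        raise ValueError("gene sets are empty after intersecting with the matrix")

    X = d.values.loc[A].to_numpy()  # a × s
    Y = d.values.loc[pop_b].to_numpy()  # b × s
    eq = (X[:, None, :] == Y[None, :, :]).mean(axis=2)
    neg = (X[:, None, :] == -Y[None, :, :]).mean(axis=2)
    tol = 1e-12
    pos_mask = (eq >= min_agree - tol) & (eq >= neg)
    neg_mask = (neg >= min_agree - tol) & ~pos_mask
    conc = pos_mask | neg_mask

    in_b = np.array([g in B for g in pop_b])
    N = conc.size
    m = int(conc.sum())
    n = int(len(A) * in_b.sum())
    k = int(conc[:, in_b].sum())
    pos_k = int(pos_mask[:, in_b].sum())
    neg_k = int(neg_mask[:, in_b].sum())
    p = hypergeom_upper_tail(N, m, n, k)
    sign = "positive" if pos_k >= neg_k else "negative"
    return SetAssociationResult(
        set_a=name_a,
        set_b=name_b,
        n_concordant_pairs=k,
        n_possible_pairs=n,
        p=p,
        sign=sign,
        n_positive_pairs=pos_k,
        n_negative_pairs=neg_k,
        population_pairs=N,
        population_concordant=m,
    )
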