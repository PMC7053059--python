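"""Expression preprocessing and rotation gene-set tests.

Preprocessing mirrors two common microarray pipelines: a detection-p
filter (beadarray-style platforms reporting per-cell detection p-values)
and a signal-floor filter (keep probes whose log2 signal reaches a floor
in at least one sample), plus quantile normalization.

The set-level test is a rotation test in the spirit of ROAST: the design
is reduced by orthogonal projection to one effect coordinate (the
two-group contrast) plus the residual space; random rotations draw a
uniform unit vector over the combined effect+residual space and recompute
per-gene moderated t statistics, so sample-level exchangeability is not
required and gene–gene correlation is preserved (the same rotation is
applied to every gene). The default "mixed" set statistic is the mean of
squared moderated t over the set, which ignores effect direction and so
detects sets whose members move both up and down.

Per-gene moderation follows the empirical-Bayes variance shrinkage of
limma-style linear models: each gene's residual variance is shrunk toward
a global prior estimated by moment matching on the log residual variances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import brentq
from scipy.special import digamma, polygamma

from .io_model import ExpressionExperiment, normalize_symbols

__all__ = [
    "PreprocessReport",
    "RotationResult",
    "filter_by_detection",
    "filter_by_signal",
    "quantile_normalize",
    "moderated_t",
    "rotation_set_test",
]


@dataclass
class PreprocessReport:
    n_probes_in: int
    n_probes_kept: int
    filter_rule: str
    normalized: bool = False


@dataclass
class RotationResult:
    set_name: str
    n_genes_in_set: int
    set_statistic_observed: float
    p_mixed: float
    n_rotations: int
    per_gene_stats: list[float]
    statistic: str = "msq"

    def to_dict(self) -> dict:
        return {
            "set_name": self.set_name,
            "n_genes_in_set": self.n_genes_in_set,
            "set_statistic_observed": float(self.set_statistic_observed),
            "p_mixed": float(self.p_mixed),
            "n_rotations": self.n_rotations,
            "statistic": self.statistic,
            "per_gene_stats": [float(t) for t in self.per_gene_stats],
        }


# ---------------------------------------------------------------------------
# Filters and normalization
# ---------------------------------------------------------------------------


def filter_by_detection(
    e: ExpressionExperiment, p_cut: float = 0.01
) -> tuple[ExpressionExperiment, PreprocessReport]:
    """Keep genes detected (detection_p < p_cut) in at least one sample."""
    if e.detection_p is None:
        raise ValueError(
            "experiment carries no detection p-values; use filter_by_signal instead"
        )
    keep = (e.detection_p.to_numpy() < p_cut).any(axis=1)
    kept = e.values.index[keep]
    out = ExpressionExperiment(
        e.values.loc[kept], e.groups, e.detection_p.loc[kept]
    )
    report = PreprocessReport(
        n_probes_in=len(e.values),
        n_probes_kept=len(kept),
        filter_rule=f"detection_p < {p_cut} in >=1 sample",
    )
    return out, report


def filter_by_signal(
    e: ExpressionExperiment, floor: float = 6.0
) -> tuple[ExpressionExperiment, PreprocessReport]:
    """Keep genes whose log2 signal reaches ``floor`` in at least one sample."""
    keep = (e.values.to_numpy() >= floor).any(axis=1)
    kept = e.values.index[keep]
    dp = e.detection_p.loc[kept] if e.detection_p is not None else None
    out = ExpressionExperiment(e.values.loc[kept], e.groups, dp)
    report = PreprocessReport(
        n_probes_in=len(e.values),
        n_probes_kept=len(kept),
        filter_rule=f"log2 signal >= {floor} in >=1 sample",
    )
    return out, report


def quantile_normalize(e: ExpressionExperiment) -> ExpressionExperiment:
    """Force every sample onto the common (mean-of-sorted) distribution.

    Ties within a sample receive the mean of the reference values assigned
    to the tied ranks, so a constant sample maps to the reference mean.
    """
    X = e.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    order = np.argsort(X, axis=0, kind="stable")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        idx = order[:, j]
        sorted_col = col[idx]
        assigned = reference.copy()
        # average reference values over runs of tied observations
        start = 0
        for end in range(1, n_genes + 1):
            if end == n_genes or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    assigned[start:end] = reference[start:end].mean()
                start = end
        out[idx, j] = assigned
    values = pd.DataFrame(out, index=e.values.index, columns=e.values.columns)
    return ExpressionExperiment(values, e.groups, e.detection_p)


# ---------------------------------------------------------------------------
# Moderated t and the rotation machinery
# ---------------------------------------------------------------------------


def _contrast_basis(groups: pd.Series) -> tuple[np.ndarray, np.ndarray, int]:
    """Orthonormal contrast direction, residual-space basis, residual df."""
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, found {levels}")
    g = (groups == levels[1]).to_numpy(dtype=float)
    n = g.size
    for lev in levels:
        if (groups == lev).sum() < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 samples")
    u_c = g - g.mean()
    u_c /= np.linalg.norm(u_c)
    design = np.column_stack([np.ones(n) / np.sqrt(n), u_c])
    U_res = null_space(design.T)  # n × (n-2), orthonormal
    d = n - 2
    return u_c, U_res, d


def _decompose(e: ExpressionExperiment) -> tuple[np.ndarray, int]:
    """Reduce genes × samples to genes × (1 + residual df) coordinates.

    Column 0 is the contrast (effect) coordinate scaled so its null
    variance equals the residual variance; the rest are residual-space
    coordinates. Squared row norms split into effect² + d·s².
    """
    u_c, U_res, d = _contrast_basis(e.groups)
    Y = e.values.to_numpy(dtype=float)
    Z = Y @ np.column_stack([u_c, U_res])
    return Z, d


def _fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Estimate (d0, s0²) of the scaled inverse-chi² variance prior.

    Moment matching on log s²: the excess variance of log s² beyond the
    sampling component trigamma(d/2) identifies the prior df d0; the mean
    identifies s0². Infinite d0 (no excess spread) collapses the
    moderated variance to the common value.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise ValueError("all residual variances are zero; data is degenerate")
    # With no excess spread beyond the chi^2 sampling noise the prior is a
    # point mass; the arithmetic mean keeps the equal-variance limit equal
    # to the ordinary pooled statistic.
    if pos.size < 2:
        return np.inf, float(np.mean(pos))
    z = np.log(pos)
    e_z = z - digamma(d / 2) + np.log(d / 2)
    excess = z.var(ddof=1) - float(polygamma(1, d / 2))
    if excess <= 1e-12:
        return np.inf, float(np.mean(pos))

    def f(log_d0: float) -> float:
        return float(polygamma(1, np.exp(log_d0) / 2)) - excess

    lo, hi = np.log(1e-3), np.log(1e8)
    if f(lo) < 0:  # excess larger than any trigamma in range
        d0 = 1e-3
    elif f(hi) > 0:
        d0 = np.inf
    else:
        d0 = float(np.exp(brentq(f, lo, hi, xtol=1e-12)))
    if np.isinf(d0):
        s0_sq = float(np.mean(pos))
    else:
        s0_sq = float(np.exp(e_z.mean() + digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_sq


def _moderated_from_coords(
    effect: np.ndarray, s2: np.ndarray, d: int, d0: float, s0_sq: float
) -> np.ndarray:
    if np.isinf(d0):
        s_tilde = np.full_like(s2, s0_sq)
    else:
        s_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(s_tilde)
    return np.where(s_tilde > 0, t, 0.0)


def moderated_t(e: ExpressionExperiment) -> np.ndarray:
    """Per-gene two-sample t with empirical-Bayes shrunken variance.

    Equals the ordinary pooled two-sample t when all genes share the same
    residual variance (shrinkage becomes a no-op).
    """
    Z, d = _decompose(e)
    effect = Z[:, 0]
    s2 = (Z[:, 1:] ** 2).sum(axis=1) / d
    d0, s0_sq = _fit_variance_prior(s2, d)
    return _moderated_from_coords(effect, s2, d, d0, s0_sq)


def rotation_set_test(
    e: ExpressionExperiment,
    gene_set: Iterable[str],
    n_rotations: int = 9999,
    seed: Optional[int] = None,
    statistic: str = "msq",
    set_name: str = "",
) -> RotationResult:
    """Rotation gene-set test for a two-group design.

    ``statistic`` selects the set summary of per-gene moderated t:
    ``"msq"`` (mean squared, the direction-agnostic "mixed" alternative,
    default), ``"mean_abs"`` (mean absolute, also direction-agnostic), or
    ``"mean"`` (signed mean, directional, tested two-sided).

    The null is built from ``n_rotations`` uniform random unit vectors in
    the effect+residual coordinate space; each rotation is shared across
    genes, preserving inter-gene correlation. The variance prior (d0, s0²)
    is estimated once from the observed data and held fixed across
    rotations. p = (b + 1) / (n_rotations + 1).
    """
    if statistic not in ("msq", "mean_abs", "mean"):
        raise ValueError("statistic must be 'msq', 'mean_abs' or 'mean'")
    wanted = normalize_symbols(gene_set)
    present = [g for g in e.values.index if g in wanted]
    missing = sorted(wanted - set(present))
    if not present:
        raise ValueError(f"gene set shares no genes with the matrix; missing: {missing}")

    Z, d = _decompose(e)
    if d < 1:
        raise ValueError("no residual degrees of freedom (need > 2 samples)")
    effect = Z[:, 0]
    s2 = (Z[:, 1:] ** 2).sum(axis=1) / d
    scale = max(1.0, float(np.abs(e.values.to_numpy()).max()))
    if float((Z**2).sum()) <= (1e-10 * scale) ** 2 * Z.size:
        raise ValueError("constant expression matrix: zero residual variance")
    # The prior is fit on rotation-invariant per-gene energies (effect +
    # residual, d+1 df) rather than on residual variances alone, so every
    # rotated statistic is the same function of Z·r as the observed one
    # and the rotation null is exactly exchangeable with the observation.
    d0, s0_sq = _fit_variance_prior((Z**2).sum(axis=1) / (d + 1), d + 1)

    idx = [e.values.index.get_loc(g) for g in present]
    t_obs = _moderated_from_coords(effect[idx], s2[idx], d, d0, s0_sq)

    def summarize(t: np.ndarray) -> np.ndarray:
        if statistic == "msq":
            return np.mean(t**2, axis=0)
        if statistic == "mean_abs":
            return np.mean(np.abs(t), axis=0)
        return np.mean(t, axis=0)

    observed = float(summarize(t_obs[:, None])[0])

    Zs = Z[idx]  # set genes × (d+1)
    norms2 = (Zs**2).sum(axis=1)
    rng = np.random.default_rng(seed)
    R = rng.standard_normal((n_rotations, d + 1))
    R /= np.linalg.norm(R, axis=1, keepdims=True)
    eff_rot = Zs @ R.T  # set genes × rotations
    s2_rot = np.clip((norms2[:, None] - eff_rot**2) / d, 0.0, None)
    t_rot = _moderated_from_coords(eff_rot, s2_rot, d, d0, s0_sq)
    null = summarize(t_rot)

    if statistic == "mean":
        b = int(np.count_nonzero(np.abs(null) >= abs(observed)))
    else:
        b = int(np.count_nonzero(null >= observed))
    p = (b + 1) / (n_rotations + 1)
    return RotationResult(
        set_name=set_name,
        n_genes_in_set=len(present),
        set_statistic_observed=observed,
        p_mixed=p,
        n_rotations=n_rotations,
        per_gene_stats=[float(t) for t in t_obs],
        statistic=statistic,
    )
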