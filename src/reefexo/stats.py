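"""Statistical machinery shared by every analysis stage.

All procedures here are implemented from first principles on top of numpy
and the univariate reference distributions in :mod:`scipy.stats`:

* one-way ANOVA and Dunnett's many-to-one comparison (shared-control
  multivariate-*t* family adjustment, evaluated by deterministic Gauss
  quadrature),
* Tukey's HSD with a compact-letter display,
* Benjamini–Hochberg step-up FDR,
* the angular (arcsine-square-root) + z-score transform used before
  ordination,
* principal coordinates analysis (Gower double-centering),
* two-factor sequential (Type I) PERMANOVA in the style of vegan's
  ``adonis``,
* ordinary least squares, and
* a G²-based categorical congruency coefficient (Theil's uncertainty
  coefficient).

Every routine returns plain dataclasses or numpy arrays so results can be
serialized as tidy TSV by the pipeline layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache as _lru_cache

import networkx as nx
import numpy as np
from scipy import special, stats as sps

__all__ = [
    "AnovaResult",
    "DunnettResult",
    "TukeyResult",
    "PermanovaResult",
    "PcoaResult",
    "LinearFit",
    "CongruencyResult",
    "one_way_anova",
    "dunnett_many_to_one",
    "dunnett_sf",
    "tukey_hsd",
    "bh_fdr",
    "angular_zscore_transform",
    "pcoa",
    "permanova",
    "pairwise_permanova",
    "linear_fit",
    "congruency_r2",
]


# --------------------------------------------------------------------------
# one-way ANOVA
# --------------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: float
    p: float
    mse: float
    df_between: int
    df_within: int
    degenerate: bool = False


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Parameters
    ----------
    groups:
        Sequence of 1-D arrays, one per group; each must hold >= 2
        observations.

    A table with zero total variance is degenerate (no signal to test);
    by convention it returns ``p = 1`` with ``degenerate=True``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    n = np.array([g.size for g in groups])
    N = int(n.sum())
    k = len(groups)
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_between = float((n * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_b, df_w = k - 1, N - k
    if ss_between + ss_within <= 0.0:
        return AnovaResult(0.0, 1.0, 0.0, df_b, df_w, degenerate=True)
    mse = ss_within / df_w
    if mse == 0.0:
        # all within-group variance is zero but groups differ: F -> inf
        return AnovaResult(np.inf, 0.0, 0.0, df_b, df_w)
    F = (ss_between / df_b) / mse
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), p, float(mse), df_b, df_w)


# --------------------------------------------------------------------------
# Dunnett many-to-one
# --------------------------------------------------------------------------

@dataclass
class DunnettResult:
    mean_diffs: np.ndarray       # treatment mean minus control mean
    tstats: np.ndarray
    pvalues: np.ndarray          # family-adjusted
    df: int
    mse: float
    sided: str


def _quad_nodes(df: int, n_u: int = 48, n_z: int = 64):
    """Quadrature nodes/weights for E over (s/sigma, Z0).

    s²/σ² ~ chi²_df/df is handled with generalized Gauss–Laguerre
    (alpha = df/2 − 1 after the substitution q = 2x); for small df, where
    the chi tail makes Laguerre converge slowly, with Gauss–Legendre in
    chi-probability space instead.  The standard-normal control term uses
    Gauss–Hermite.
    """
    if df >= 8:
        x, wu = special.roots_genlaguerre(n_u, df / 2.0 - 1.0)
        u = np.sqrt(2.0 * x / df)                   # values of s/sigma
        wu = wu / special.gamma(df / 2.0)
    else:
        q, wu = np.polynomial.legendre.leggauss(max(n_u, 160))
        q = (q + 1.0) / 2.0
        wu = wu / 2.0
        u = sps.chi.ppf(q, df) / np.sqrt(df)
    y, wz = special.roots_hermite(n_z)
    z = np.sqrt(2.0) * y
    wz = wz / np.sqrt(np.pi)
    return u, wu, z, wz


def _max_t_cdf(t: np.ndarray, b: np.ndarray, df: int, sided: str) -> np.ndarray:
    """P(max_i T_i <= t) (greater) or P(max_i |T_i| <= t) (two-sided).

    T is the Dunnett statistic vector under H0 with shared-control loading
    ``b_i = sqrt(n_i/(n_i+n_0))``; correlation rho_ij = b_i b_j.  The joint
    probability factorizes conditional on the control z-score and the
    pooled-SD scale, leaving a smooth 2-D integral evaluated exactly
    (to ~1e-9) by product Gauss quadrature.  Deterministic: no RNG.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    b = np.asarray(b, dtype=float)
    c = np.sqrt(1.0 - b**2)
    u, wu, z, wz = _quad_nodes(df)
    tu = t[:, None, None] * u[None, :, None]        # (nt, nu, 1)
    bz = b[:, None, None, None] * z[None, None, None, :]  # (k, 1, 1, nz)
    # product over comparisons; collapse identical b for speed
    if np.allclose(b, b[0]):
        arg = (tu[None, ...] - bz[:1]) / c[0]
        if sided == "two-sided":
            inner = special.ndtr(arg) - special.ndtr((-tu[None, ...] - bz[:1]) / c[0])
        else:
            inner = special.ndtr(arg)
        prod = np.clip(inner[0], 0.0, 1.0) ** len(b)
    else:
        prod = np.ones((t.size, u.size, z.size))
        for bi, ci in zip(b, c):
            arg = (tu - bi * z[None, None, :]) / ci
            if sided == "two-sided":
                term = special.ndtr(arg) - special.ndtr((-tu - bi * z[None, None, :]) / ci)
            else:
                term = special.ndtr(arg)
            prod *= np.clip(term, 0.0, 1.0)
    out = np.einsum("iuz,u,z->i", prod, wu, wz)
    return np.clip(out, 0.0, 1.0)


def dunnett_sf(tstats, n_treat, n_control, df, sided="greater",
               interpolate_above: int = 512) -> np.ndarray:
    """Family-adjusted Dunnett p-values for observed t statistics.

    ``n_treat`` is a scalar (balanced) or one size per comparison; all
    observed statistics must share the same design.  For large batches the
    smooth monotone map ``t -> p`` is evaluated on a dense grid and
    linearly interpolated (error far below the 1e-4 contract).
    """
    tstats = np.atleast_1d(np.asarray(tstats, dtype=float))
    shape = tstats.shape
    n_treat = np.atleast_1d(np.asarray(n_treat, dtype=float))
    if n_treat.size == 1:
        # one comparison: the family adjustment is void and the statistic
        # is an ordinary pooled t — use the exact reduction
        if sided == "two-sided":
            return (2.0 * sps.t.sf(np.abs(tstats), df)).reshape(shape)
        return sps.t.sf(tstats, df).reshape(shape)
    b = np.sqrt(n_treat / (n_treat + float(n_control)))
    tq = (np.abs(tstats) if sided == "two-sided" else tstats).ravel()
    finite = np.isfinite(tq)
    p = np.where(tq > 0, 0.0, 1.0)      # placeholder for +-inf statistics
    if finite.any():
        tf = tq[finite]
        in_grid = (tf >= -12.0) & (tf <= 12.0)
        if tf.size > interpolate_above and in_grid.all():
            grid, cdf = _cached_max_t_grid(tuple(np.round(b, 12)), df, sided)
            p[finite] = 1.0 - np.interp(tf, grid, cdf)
        else:
            p[finite] = 1.0 - _max_t_cdf(tf, b, df, sided)
    return np.clip(p, 0.0, 1.0).reshape(shape)


@_lru_cache(maxsize=64)
def _cached_max_t_grid(b_key: tuple, df: int, sided: str):
    grid = np.linspace(-12.0, 12.0, 4096)
    cdf = _max_t_cdf(grid, np.array(b_key), df, sided)
    return grid, cdf


def dunnett_many_to_one(control, treatments, sided: str = "greater") -> DunnettResult:
    """Dunnett's many-to-one comparison of k treatment groups vs one control.

    Pooled-variance model: ``t_i = (mean_i - mean_0) / sqrt(MSE (1/n_i + 1/n_0))``
    with MSE pooled over all k+1 groups.  Adjusted p-values come from the
    multivariate t with the shared-control correlation structure; with a
    single treatment the adjustment is void and the result equals an
    ordinary pooled two-sample t test.
    """
    if sided not in ("greater", "two-sided"):
        raise ValueError("sided must be 'greater' or 'two-sided'")
    control = np.asarray(control, dtype=float)
    treatments = [np.asarray(g, dtype=float) for g in treatments]
    if control.size < 2 or any(g.size < 2 for g in treatments):
        raise ValueError("every group needs at least two observations")
    groups = [control] + treatments
    n = np.array([g.size for g in groups], dtype=float)
    df = int(n.sum()) - len(groups)
    means = np.array([g.mean() for g in groups])
    ss_within = sum(((g - m) ** 2).sum() for g, m in zip(groups, means))
    mse = ss_within / df
    diffs = means[1:] - means[0]
    se = np.sqrt(mse * (1.0 / n[1:] + 1.0 / n[0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diffs / se, np.where(diffs != 0, np.inf * np.sign(diffs), 0.0))
    if mse == 0.0:
        # degenerate: no residual variance; p is 0/1 by sign convention
        p = np.where(t > 0, 0.0, 1.0) if sided == "greater" else np.where(t != 0, 0.0, 1.0)
        return DunnettResult(diffs, t, p, df, 0.0, sided)
    p = dunnett_sf(t, n[1:], n[0], df, sided=sided)
    return DunnettResult(diffs, t, p, df, float(mse), sided)


# --------------------------------------------------------------------------
# Tukey HSD with compact letter display
# --------------------------------------------------------------------------

@dataclass
class TukeyResult:
    pvalues: np.ndarray      # k x k symmetric matrix of adjusted p
    letters: list[str]       # compact letter display, one string per group
    df: int
    mse: float


def tukey_hsd(groups: list[np.ndarray]) -> TukeyResult:
    """Tukey's honestly-significant-difference test over all group pairs.

    Adjusted p from the studentized range; Tukey–Kramer standard error for
    unbalanced pairs.  The compact letter display assigns one letter per
    maximal clique of the non-significance graph (alpha = 0.05), so two
    groups share a letter iff they are not significantly different.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    a = one_way_anova(groups)
    k = len(groups)
    n = np.array([g.size for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if a.mse == 0.0:
                pij = 1.0 if means[i] == means[j] else 0.0
            else:
                se = np.sqrt(a.mse / 2.0 * (1.0 / n[i] + 1.0 / n[j]))
                q = abs(means[i] - means[j]) / se
                pij = float(sps.studentized_range.sf(q, k, a.df_within))
            p[i, j] = p[j, i] = pij
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if p[i, j] >= 0.05:
                g.add_edge(i, j)
    cliques = sorted(nx.find_cliques(g), key=lambda c: (min(-means[i] for i in c)))
    letters = ["" for _ in range(k)]
    for letter_idx, clique in enumerate(cliques):
        ch = chr(ord("a") + letter_idx)
        for i in clique:
            letters[i] += ch
    letters = ["".join(sorted(s)) for s in letters]
    return TukeyResult(p, letters, a.df_within, a.mse)


# --------------------------------------------------------------------------
# Benjamini–Hochberg
# --------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


# --------------------------------------------------------------------------
# transforms
# --------------------------------------------------------------------------

def angular_zscore_transform(matrix) -> np.ndarray:
    """Arcsine-square-root transform then per-row (feature) z-score.

    Input rows are features, columns samples, values in [0, 1].  Constant
    rows (zero SD) cannot be standardized and map to all-zero with a
    warning.
    """
    x = np.asarray(matrix, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("relative abundances must lie in [0, 1]")
    y = np.arcsin(np.sqrt(x))
    mu = y.mean(axis=-1, keepdims=True)
    sd = y.std(axis=-1, ddof=1, keepdims=True)
    const = (sd == 0) | ~np.isfinite(sd)
    if np.any(const):
        warnings.warn(f"{int(const.sum())} constant feature(s) mapped to zero rows")
    sd = np.where(const, 1.0, sd)
    z = (y - mu) / sd
    if z.ndim == 2:
        z[const[:, 0], :] = 0.0
    return z


# --------------------------------------------------------------------------
# PCoA
# --------------------------------------------------------------------------

@dataclass
class PcoaResult:
    coordinates: np.ndarray   # n x n_pos, axes ordered by eigenvalue
    eigenvalues: np.ndarray   # all eigenvalues, descending (negatives kept)


def pcoa(distance) -> PcoaResult:
    """Principal coordinates analysis (classical MDS, Gower centering).

    Negative eigenvalues of non-Euclidean distances are reported as-is and
    excluded from the coordinate embedding; no Lingoes/Cailliez correction
    is applied.
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    a = -0.5 * d**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ a @ J
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    idx = np.argsort(vals)[::-1]
    vals, vecs = vals[idx], vecs[:, idx]
    pos = vals > max(vals.max(), 0) * 1e-10
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    return PcoaResult(coords, vals)


# --------------------------------------------------------------------------
# PERMANOVA (two-factor, sequential SS, adonis-style)
# --------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    terms: list[str]
    df: np.ndarray
    ss: np.ndarray
    r2: np.ndarray            # per term; residual appended via residual_r2
    pseudo_f: np.ndarray
    p: np.ndarray
    residual_df: int
    residual_ss: float

    @property
    def residual_r2(self) -> float:
        return float(self.residual_ss / (self.ss.sum() + self.residual_ss))


def _dummy(labels: np.ndarray) -> np.ndarray:
    levels = np.unique(labels)
    return (labels[:, None] == levels[None, :]).astype(float)


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def permanova(distance, treatment, diel=None, *, n_perm: int = 999,
              seed: int = 0, interaction: bool = True) -> PermanovaResult:
    """Permutational MANOVA on a distance matrix, sequential (Type I) SS.

    With ``diel`` given, the model is ``treatment + diel (+ interaction)``
    in that fixed order, matching the adonis default.  P-values come from
    free permutation of sample labels (rows/columns of the Gower-centered
    matrix) with a seeded generator.
    """
    d = np.asarray(distance, dtype=float)
    n = d.shape[0]
    treatment = np.asarray(treatment)
    if np.unique(treatment).size < 2:
        raise ValueError("factor 'treatment' needs at least two levels")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    a = -0.5 * d**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ a @ J
    ss_total = float(np.trace(G))

    ones = np.ones((n, 1))
    blocks = [("treatment", _dummy(treatment))]
    if diel is not None:
        diel = np.asarray(diel)
        if np.unique(diel).size < 2:
            raise ValueError("factor 'diel' needs at least two levels")
        blocks.append(("diel", _dummy(diel)))
        if interaction:
            inter = np.asarray([f"{t}\x00{d_}" for t, d_ in zip(treatment, diel)])
            blocks.append(("treatment:diel", _dummy(inter)))

    names, dfs, hats = [], [], []
    X = ones
    H_prev = _hat(X)
    rank_prev = int(round(np.trace(H_prev)))
    for name, B in blocks:
        X = np.hstack([X, B])
        H = _hat(X)
        rank = int(round(np.trace(H)))
        names.append(name)
        dfs.append(rank - rank_prev)
        hats.append((H, H_prev))
        H_prev, rank_prev = H, rank

    H_full = H_prev
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    R = np.eye(n) - H_full

    def term_ss(Gm):
        return np.array([float(np.trace((H - Hp) @ Gm)) for H, Hp in hats])

    ss = term_ss(G)
    ss_res = float(np.trace(R @ G))
    dfs = np.array(dfs)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss / dfs) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ssp = term_ss(Gp)
        ssp_res = ss_total - ssp.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            fp = (ssp / dfs) / (ssp_res / df_res)
        exceed += fp >= f_obs - 1e-12
    p = (exceed + 1.0) / (n_perm + 1.0)
    r2 = ss / ss_total
    return PermanovaResult(names, dfs, ss, r2, f_obs, p, df_res, ss_res)


def pairwise_permanova(distance, labels, *, n_perm: int = 999, seed: int = 0):
    """One-way PERMANOVA for every pair of factor levels.

    Returns a list of dicts with raw and BH-adjusted permutation p-values
    (the correction method for the a-posteriori contrasts is unspecified in
    the field convention, so both are reported).
    """
    d = np.asarray(distance, dtype=float)
    labels = np.asarray(labels)
    levels = list(np.unique(labels))
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            mask = (labels == levels[i]) | (labels == levels[j])
            idx = np.where(mask)[0]
            sub = permanova(d[np.ix_(idx, idx)], labels[idx],
                            n_perm=n_perm, seed=seed)
            rows.append({"a": levels[i], "b": levels[j],
                         "r2": float(sub.r2[0]), "pseudo_f": float(sub.pseudo_f[0]),
                         "p": float(sub.p[0])})
    padj = bh_fdr([r["p"] for r in rows])
    for r, pa in zip(rows, padj):
        r["p_adjusted"] = float(pa)
    return rows


# --------------------------------------------------------------------------
# OLS
# --------------------------------------------------------------------------

@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float
    p: float        # two-sided p for the slope
    n: int


def linear_fit(x, y) -> LinearFit:
    """Simple ordinary-least-squares regression of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched x/y with n >= 3")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("zero variance in x")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sse = float((resid**2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sst == 0.0 else 1.0 - sse / sst
    df = x.size - 2
    se = np.sqrt(sse / df / sxx) if df > 0 else np.nan
    if se == 0.0:
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / se
        p = float(2.0 * sps.t.sf(abs(t), df))
    return LinearFit(float(slope), intercept, float(r2), p, int(x.size))


# --------------------------------------------------------------------------
# categorical congruency (Theil's U via G²)
# --------------------------------------------------------------------------

@dataclass
class CongruencyResult:
    r2: float          # uncertainty coefficient U(category | class)
    g2: float          # likelihood-ratio statistic
    p: float           # chi2 p of the LR statistic
    dof: int
    n: int
    cramers_v: float   # alternative effect size


def congruency_r2(category_labels, class_labels) -> CongruencyResult:
    """Congruency of two categorical labelings.

    ``r2`` is Theil's uncertainty coefficient U(category | class) =
    G² / (2 N H(category)) with H the natural-log entropy of the category
    margin — the "RSquare (U)" of common contingency-analysis software.
    It is 1 when the class labels fully determine the categories and 0
    under independence.  Cramér's V is reported as an alternative.
    """
    cat = np.asarray(category_labels)
    cls = np.asarray(class_labels)
    if cat.size != cls.size or cat.size == 0:
        raise ValueError("label vectors must be non-empty and matched")
    cat_levels, cat_idx = np.unique(cat, return_inverse=True)
    cls_levels, cls_idx = np.unique(cls, return_inverse=True)
    if cat_levels.size < 2 or cls_levels.size < 2:
        raise ValueError("each label vector needs at least two levels")
    n = cat.size
    table = np.zeros((cat_levels.size, cls_levels.size))
    np.add.at(table, (cat_idx, cls_idx), 1.0)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / n
    nz = table > 0
    g2 = float(2.0 * (table[nz] * np.log(table[nz] / expected[nz])).sum())
    h_cat = float(-(row / n * np.log(row / n)).sum())
    r2 = g2 / (2.0 * n * h_cat) if h_cat > 0 else np.nan
    dof = (cat_levels.size - 1) * (cls_levels.size - 1)
    p = float(sps.chi2.sf(g2, dof))
    chi2 = float(((table - expected) ** 2 / np.where(expected > 0, expected, 1)).sum())
    v = np.sqrt(chi2 / (n * (min(table.shape) - 1)))
    return CongruencyResult(float(np.clip(r2, 0.0, 1.0)), g2, p, dof, n, float(v))
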