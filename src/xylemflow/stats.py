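"""Comparative inference on trait tables.

The analysis unit depends on the question: raw samples are averaged per
tree × organ (avoiding pseudo-replication), species means are the mean of
tree means, and leaf-habit / organ contrasts run on species means — the
printed degrees of freedom (11 for 13 angiosperm species in a two-habit
model, 24 or 23 for the organ model) confirm that convention.

Contrasts come from one-factor linear models, which for two groups reduce
exactly to the pooled-variance two-sample computation implemented here
(an invariant the test suite checks against an independent OLS fit).
Post-hoc all-pairs comparisons use Tukey–Kramer p-values on the
studentized-range distribution with the one-way pooled MSE, summarised as
a compact letter display (insert–absorb algorithm).  Root-to-branch ratios
are means of per-pair ratios (the figure statistic — deliberately not the
ratio of group means).  The tree-height analysis is a random-intercept
(species) model with the intercept variance profiled out of the Gaussian
likelihood; the slope p-value is a likelihood-ratio test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "ContrastResult",
    "LetterDisplay",
    "aggregate_tree_means",
    "species_means",
    "two_group_contrast",
    "habit_contrast",
    "organ_contrast",
    "tukey_pairwise",
    "compact_letters",
    "tukey_letters",
    "pearson_matrix",
    "rb_ratio",
    "height_model",
    "LOG10_TRAITS",
]

log = logging.getLogger(__name__)

#: traits analysed on the log10 scale in parametric tests
LOG10_TRAITS = ("KS_hydr", "KS_pot", "K_L")


@dataclass(frozen=True)
class ContrastResult:
    """A marginal-mean contrast: estimate, SE, df, t and two-sided p."""

    contrast: float
    SE: float
    df: int
    t_ratio: float
    p_value: float


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display: groups sharing no letter differ at alpha."""

    letters: Dict[str, str]
    p_matrix: pd.DataFrame
    alpha: float

    def __getitem__(self, group: str) -> str:
        return self.letters[group]


# ---------------------------------------------------------------------------
# aggregation

def aggregate_tree_means(samples: pd.DataFrame) -> pd.DataFrame:
    """Average raw samples per (species, tree, organ, trait).

    Expects long format with columns
    ``species, tree_id, organ, trait, value`` (extra metadata columns such
    as ``leaf_habit`` are carried through).  Returns one row per
    tree × organ × trait.
    """
    keys = ["species", "tree_id", "organ", "trait"]
    meta = [c for c in samples.columns if c not in keys + ["value", "sample_id"]]
    agg = {"value": "mean", **{c: "first" for c in meta}}
    out = samples.groupby(keys, as_index=False, sort=True).agg(agg)
    return out


def species_means(tree_means: pd.DataFrame) -> pd.DataFrame:
    """Species means = mean of tree means, per organ × trait."""
    keys = ["species", "organ", "trait"]
    meta = [c for c in tree_means.columns if c not in keys + ["value", "tree_id"]]
    agg = {"value": "mean", **{c: "first" for c in meta}}
    return tree_means.groupby(keys, as_index=False, sort=True).agg(agg)


# ---------------------------------------------------------------------------
# contrasts

def two_group_contrast(a: Sequence[float], b: Sequence[float]) -> ContrastResult:
    """mean(a) − mean(b) from a one-factor linear model (pooled variance).

    df = n_a + n_b − 2 (observations minus the two model parameters).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    diff = a.mean() - b.mean()
    df = a.size + b.size - 2
    sp2 = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    sp2 /= df
    se = math.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    if se == 0.0:
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        t = diff / se
        p = float(2.0 * sps.t.sf(abs(t), df))
    return ContrastResult(float(diff), float(se), int(df), float(t), min(max(p, 0.0), 1.0))


def habit_contrast(
    values: Mapping[str, float] | pd.Series,
    habits: Mapping[str, str],
) -> ContrastResult:
    """Deciduous − evergreen contrast on angiosperm species means.

    ``values`` maps species → species-mean trait value; ``habits`` maps
    species → leaf habit.  Gymnosperms are excluded.
    """
    dec = [v for s, v in dict(values).items() if habits.get(s) == "deciduous"]
    eve = [v for s, v in dict(values).items() if habits.get(s) == "evergreen"]
    if len(dec) < 2 or len(eve) < 2:
        raise ValueError("need at least two species per leaf habit")
    return two_group_contrast(dec, eve)


def organ_contrast(
    root_values: Sequence[float], branch_values: Sequence[float]
) -> ContrastResult:
    """Root − branch contrast on species means (missing cells simply absent;
    df adjusts to the observation count)."""
    root = [v for v in root_values if np.isfinite(v)]
    branch = [v for v in branch_values if np.isfinite(v)]
    if not root or not branch:
        raise ValueError("an organ is entirely missing")
    return two_group_contrast(root, branch)


# ---------------------------------------------------------------------------
# Tukey all-pairs + compact letter display

def tukey_pairwise(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """All-pairs Tukey(-Kramer) adjusted p-values.

    One-way pooled MSE; q = |m_i − m_j| / sqrt(MSE/2 · (1/n_i + 1/n_j)),
    compared against the studentized-range distribution with k groups and
    N − k error df.
    """
    names = list(groups)
    data = {g: np.asarray(groups[g], float) for g in names}
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for g, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} needs at least two values")
    k = len(names)
    n_tot = sum(v.size for v in data.values())
    df_e = n_tot - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in data.values()) / df_e
    if mse <= 0:
        raise ValueError("zero within-group variance; Tukey comparison degenerate")
    p = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i, j in itertools.combinations(range(k), 2):
        vi, vj = data[names[i]], data[names[j]]
        se = math.sqrt(mse / 2.0 * (1.0 / vi.size + 1.0 / vj.size))
        q = abs(vi.mean() - vj.mean()) / se
        pij = float(sps.studentized_range.sf(q, k, df_e))
        p.iloc[i, j] = p.iloc[j, i] = min(max(pij, 0.0), 1.0)
    return p


def compact_letters(
    p_matrix: pd.DataFrame, means: Mapping[str, float], alpha: float = 0.05
) -> Dict[str, str]:
    """Insert–absorb compact letter display from a pairwise p-value matrix.

    Two groups share at least one letter iff their adjusted p ≥ alpha.
    Letters are assigned in descending order of group mean so that 'a'
    labels the highest-mean homogeneous set.
    """
    names = list(p_matrix.index)
    columns = [set(names)]
    for i, j in itertools.combinations(names, 2):
        if p_matrix.loc[i, j] < alpha:
            new_cols = []
            for col in columns:
                if i in col and j in col:
                    new_cols.extend([col - {i}, col - {j}])
                else:
                    new_cols.append(col)
            # absorb: drop columns contained in another
            columns = [
                c
                for idx, c in enumerate(new_cols)
                if c and not any(c < other or (c == other and idx2 < idx)
                                 for idx2, other in enumerate(new_cols) if idx2 != idx)
            ]
    order = sorted(names, key=lambda g: -means[g])
    # sort columns by the highest-mean member they contain
    def col_rank(col):
        return min(order.index(g) for g in col)

    columns.sort(key=col_rank)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in names}
    for letter, col in zip(alphabet, columns):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in names}


def tukey_letters(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> LetterDisplay:
    """Tukey all-pairs test plus compact letter display."""
    p = tukey_pairwise(groups)
    means = {g: float(np.mean(groups[g])) for g in groups}
    return LetterDisplay(compact_letters(p, means, alpha), p, alpha)


# ---------------------------------------------------------------------------
# correlations

def pearson_matrix(
    table: pd.DataFrame, traits: Sequence[str] | None = None, min_pairs: int = 3
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between trait columns.

    ``table``: one row per species, one column per trait (species-wise
    means).  Returns a long DataFrame with r, two-sided p, n and
    significance flags ('*' p<0.05, '(*)' p<0.1) mirroring the usual
    correlation-matrix display.  Cells with fewer than ``min_pairs``
    complete pairs are flagged unavailable (NaN).
    """
    cols = list(traits) if traits is not None else list(table.columns)
    rows = []
    for t1, t2 in itertools.combinations(cols, 2):
        sub = table[[t1, t2]].dropna()
        n = len(sub)
        if n < min_pairs:
            rows.append((t1, t2, np.nan, np.nan, n, "n.a."))
            continue
        r, p = sps.pearsonr(sub[t1], sub[t2])
        flag = "*" if p < 0.05 else "(*)" if p < 0.1 else ""
        rows.append((t1, t2, float(r), float(p), n, flag))
    return pd.DataFrame(rows, columns=["trait_1", "trait_2", "r", "p", "n", "signif"])


# ---------------------------------------------------------------------------
# root-to-branch ratios

def rb_ratio(
    root: Mapping[str, float], branch: Mapping[str, float]
) -> Tuple[pd.Series, float]:
    """Per-pair root/branch ratios and their mean.

    Pairing is by key (tree id or species, depending on the chosen level).
    The summary is the mean of ratios — the figure statistic — which is
    generally larger than the ratio of group means under heterogeneity.
    Pairs with a zero/absent branch value are dropped with a warning.
    """
    ratios = {}
    for key, r in root.items():
        b = branch.get(key)
        if b is None or not np.isfinite(b) or not np.isfinite(r):
            continue
        if b == 0:
            log.warning("R:B pair %s dropped: zero branch value", key)
            continue
        ratios[key] = r / b
    if not ratios:
        raise ValueError("no complete root/branch pairs")
    s = pd.Series(ratios, name="rb_ratio")
    return s, float(s.mean())


# ---------------------------------------------------------------------------
# random-intercept height model

def _ri_profile_loglik(
    psi: float, y: np.ndarray, X: np.ndarray, group_sizes: np.ndarray,
    group_idx: np.ndarray,
) -> Tuple[float, np.ndarray, float]:
    """Profile Gaussian log-likelihood of y = Xβ + u_group + e at variance
    ratio psi = σ_u²/σ_e².  Returns (loglik, beta, sigma_e²)."""
    # V_i^{-1} = I − psi/(1+n_i psi) J within each group
    w = psi / (1.0 + group_sizes * psi)  # per group
    # weighted cross-products via group sums
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    yty = y @ y
    # subtract rank-one group corrections
    for g, ng in enumerate(group_sizes):
        sel = group_idx == g
        Xs = X[sel].sum(axis=0)
        ys = y[sel].sum()
        XtX -= w[g] * np.outer(Xs, Xs)
        Xty -= w[g] * Xs * ys
        yty -= w[g] * ys * ys
    beta = np.linalg.solve(XtX, Xty)
    rss = yty - beta @ Xty
    rss = max(rss, 1e-300)
    sigma2 = rss / n
    logdet = np.sum(np.log1p(group_sizes * psi))
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + n + logdet)
    return ll, beta, sigma2


def _fit_random_intercept(
    y: np.ndarray, X: np.ndarray, groups: Sequence
) -> Tuple[float, np.ndarray, float, float]:
    """ML fit over psi ≥ 0; returns (loglik, beta, sigma_e², psi)."""
    codes, _ = pd.factorize(np.asarray(groups))
    sizes = np.bincount(codes).astype(float)

    def nll(log_psi: float) -> float:
        return -_ri_profile_loglik(math.exp(log_psi), y, X, sizes, codes)[0]

    ll0 = _ri_profile_loglik(0.0, y, X, sizes, codes)[0]
    res = optimize.minimize_scalar(nll, bounds=(-10.0, 6.0), method="bounded")
    psi = math.exp(res.x)
    ll, beta, s2 = _ri_profile_loglik(psi, y, X, sizes, codes)
    if ll0 >= ll:  # boundary solution: no between-group variance
        ll, beta, s2 = _ri_profile_loglik(0.0, y, X, sizes, codes)
        psi = 0.0
    return ll, beta, s2, psi


@dataclass(frozen=True)
class HeightModelResult:
    slope: float
    slope_p: float
    psi: float  # variance ratio σ_species² / σ_residual²
    loglik: float
    pooled_fallback: bool = False


def height_model(
    values: Sequence[float], heights: Sequence[float], species: Sequence
) -> HeightModelResult:
    """Trait ~ height with a species random intercept (ML).

    The species-intercept variance is profiled out of the likelihood on a
    1-D grid over the variance ratio; the fixed height slope's p-value is a
    likelihood-ratio test against the intercept-only random-intercept
    model (χ²₁).  A singular fit falls back to pooled least squares.
    """
    y = np.asarray(values, float)
    h = np.asarray(heights, float)
    sp_arr = np.asarray(species)
    ok = np.isfinite(y) & np.isfinite(h)
    y, h, sp_arr = y[ok], h[ok], sp_arr[ok]
    if len(np.unique(sp_arr)) < 2:
        raise ValueError("need at least two species")
    if y.size < 4:
        raise ValueError("too few observations")
    X1 = np.column_stack([np.ones_like(h), h])
    X0 = np.ones((y.size, 1))
    try:
        ll1, beta1, _, psi = _fit_random_intercept(y, X1, sp_arr)
        ll0, _, _, _ = _fit_random_intercept(y, X0, sp_arr)
    except np.linalg.LinAlgError:
        log.warning("singular random-intercept fit; falling back to pooled regression")
        slope, intercept, r, p, se = sps.linregress(h, y)
        return HeightModelResult(float(slope), float(p), 0.0, math.nan, True)
    lr = max(0.0, 2.0 * (ll1 - ll0))
    p = float(sps.chi2.sf(lr, 1))
    return HeightModelResult(float(beta1[1]), p, float(psi), float(ll1))
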