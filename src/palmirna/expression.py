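"""Count normalisation and fixed-dispersion differential expression.

Normalisation follows the median-of-ratios construction: library *j*'s size
factor is

    s_j = median_i [ c_ij / (prod_k c_ik)^(1/m) ]

over rows *i* with all counts positive, where the denominator is the per-row
geometric mean across the *m* libraries (a pseudo-reference sample).

With one library per condition no dispersion can be estimated, so testing
uses a negative-binomial *exact* conditional test at a supplied dispersion
phi = BCV^2 (default BCV 0.2, phi 0.04): counts are scaled to pseudo-counts
by their size factors, and the two-sided p-value sums, over all splits of
the pseudo-count total between the two groups under equal NB means, the
probabilities no larger than that of the observed split.  P-values are
Benjamini-Hochberg adjusted; a contrast is significant when both p < 0.05
and FDR < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

DEFAULT_BCV = 0.2
ALPHA = 0.05


@dataclass
class NormalizationModel:
    size_factors: pd.Series  # s_j > 0 per library
    pseudo_reference: pd.Series  # per-row geometric mean over samples


@dataclass
class DEResult:
    mirna_id: str
    contrast: tuple[str, str]  # (control, treated)
    log2_fold_change: float
    p_value: float
    fdr: float
    significant: bool
    dispersion: float


def drop_all_zero_rows(counts: pd.DataFrame) -> pd.DataFrame:
    """Remove rows with no reads in any library (pre-DE filter)."""
    return counts.loc[counts.sum(axis=1) > 0]


def size_factors(counts: pd.DataFrame) -> NormalizationModel:
    """Median-of-ratios size factors; rows containing any zero count are
    excluded from the median (but stay in the matrix)."""
    c = counts.to_numpy(dtype=float)
    positive = (c > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no row with all counts positive; cannot normalise")
    geo = np.exp(np.log(c[positive]).mean(axis=1))
    ratios = c[positive] / geo[:, None]
    s = np.median(ratios, axis=0)
    # per-row geometric mean (0 for rows containing a zero)
    with np.errstate(divide="ignore"):
        logc = np.log(c)
    pseudo = pd.Series(
        np.exp(logc.mean(axis=1)), index=counts.index, name="pseudo_reference"
    )
    return NormalizationModel(
        pd.Series(s, index=counts.columns, name="size_factor"), pseudo
    )


def normalize(counts: pd.DataFrame, model: NormalizationModel) -> pd.DataFrame:
    """n_ij = c_ij / s_j."""
    return counts / model.size_factors


def _nb_logpmf(k: np.ndarray, mu: float, phi: float) -> np.ndarray:
    if phi == 0:
        return stats.poisson.logpmf(k, mu)
    r = 1.0 / phi
    p = r / (r + mu)
    return stats.nbinom.logpmf(k, r, p)


def nb_exact_test(
    count_a: int,
    count_b: int,
    s_a: float = 1.0,
    s_b: float = 1.0,
    dispersion: float = DEFAULT_BCV**2,
) -> tuple[float, float]:
    """Two-sided NB exact conditional test for one library per group.

    Counts are scaled to pseudo-counts (count / s, rounded half-up).  Under
    the null both pseudo-counts are NB with equal mean mu = n/2 (n = their
    sum) and variance mu + phi mu^2; the p-value sums P(Y_a = k, Y_b = n-k |
    sum = n) over all k whose probability does not exceed the observed
    one.  Returns (log2 fold change treated/control, p-value); the fold
    change uses a +0.5 stabiliser on the normalised counts.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if count_a < 0 or count_b < 0 or (count_a == 0 and count_b == 0):
        raise ValueError("counts must be >= 0 and not both zero")
    ya = math.floor(count_a / s_a + 0.5)
    yb = math.floor(count_b / s_b + 0.5)
    log2fc = math.log2((count_b / s_b + 0.5) / (count_a / s_a + 0.5))
    n = ya + yb
    if n == 0:
        return log2fc, 1.0
    mu = n / 2.0
    k = np.arange(n + 1)
    logp = _nb_logpmf(k, mu, dispersion) + _nb_logpmf(n - k, mu, dispersion)
    logp -= logsumexp(logp)
    obs = logp[ya]
    p = float(np.exp(logsumexp(logp[logp <= obs + 1e-12])))
    return log2fc, min(1.0, p)


def bh_adjust(p_values: "np.ndarray | list[float]") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    counts: pd.DataFrame,
    contrasts: list[tuple[str, str]],
    bcv: float = DEFAULT_BCV,
    alpha: float = ALPHA,
    fdr_alpha: float = ALPHA,
) -> pd.DataFrame:
    """Run the exact test for every row and contrast; BH-adjust within each
    contrast.  ``contrasts`` lists (control, treated) library pairs."""
    counts = drop_all_zero_rows(counts)
    model = size_factors(counts)
    phi = bcv**2
    rows = []
    for control, treated in contrasts:
        s_a = float(model.size_factors[control])
        s_b = float(model.size_factors[treated])
        stats_rows = []
        for mirna_id, row in counts.iterrows():
            ca, cb = int(row[control]), int(row[treated])
            if ca == 0 and cb == 0:
                continue
            lfc, p = nb_exact_test(ca, cb, s_a, s_b, phi)
            stats_rows.append((mirna_id, lfc, p))
        if not stats_rows:
            continue
        fdr = bh_adjust([r[2] for r in stats_rows])
        for (mirna_id, lfc, p), q in zip(stats_rows, fdr):
            rows.append(
                {
                    "mirna_id": mirna_id,
                    "contrast": f"{treated}_vs_{control}",
                    "log2_fold_change": lfc,
                    "p_value": p,
                    "fdr": q,
                    "significant": bool(p < alpha and q < fdr_alpha),
                    "dispersion": phi,
                }
            )
    return pd.DataFrame(rows)


def complete_linkage_order(
    normalized: pd.DataFrame, axis: str = "rows"
) -> tuple[list[int], list[tuple[int, int, float]]]:
    """Agglomerative complete-linkage clustering on log2(n + 1) Euclidean
    distances, with deterministic tie-breaks (smallest member index first).

    Returns the leaf order for heatmap rendering and the merge sequence as
    (cluster_a, cluster_b, distance) over current cluster labels (original
    leaves keep their row index; merged clusters get new labels n, n+1...).
    """
    x = np.log2(normalized.to_numpy(dtype=float) + 1.0)
    if axis == "columns":
        x = x.T
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two rows to cluster")
    # complete linkage with Lance-Williams max-updates on cluster distances
    d0 = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    dist: dict[int, dict[int, float]] = {
        i: {j: float(d0[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    smallest = {i: i for i in range(n)}  # smallest original index per cluster
    trees: dict[int, object] = {i: i for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_label = n
    while len(dist) > 1:
        best = None
        for a in sorted(dist):
            for b, dd in sorted(dist[a].items()):
                if b <= a:
                    continue
                key = (dd, min(smallest[a], smallest[b]), a, b)
                if best is None or key < best:
                    best = key
        dd, _, a, b = best
        merges.append((a, b, float(dd)))
        new = {
            k: max(dist[a][k], dist[b][k])
            for k in dist
            if k not in (a, b)
        }
        for k in list(dist):
            dist[k].pop(a, None)
            dist[k].pop(b, None)
        del dist[a], dist[b]
        for k, v in new.items():
            dist[k][next_label] = v
        dist[next_label] = new
        smallest[next_label] = min(smallest[a], smallest[b])
        trees[next_label] = (trees.pop(a), trees.pop(b))
        next_label += 1

    def leaves(t) -> list[int]:
        if isinstance(t, int):
            return [t]
        return leaves(t[0]) + leaves(t[1])

    order = leaves(trees[next_label - 1])
    return order, merges


def ddct_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """2^-ddCt relative quantification (fold of control)."""
    ddct = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return 2.0 ** (-ddct)
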