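"""Two-group differential expression on counts, plus small exact-test utilities.

The test is a negative-binomial exact test in the classic count-based DE
style: samples are normalized by median-of-ratios size factors, a per-gene
dispersion is estimated by the method of moments and stabilised against a
mean-dispersion trend, and the total count of one group, conditioned on the
two-group total, is compared against its null NB distribution by summing
the probabilities of outcomes less likely than the observed one plus half
the observed atom (a mid-p rule, which keeps null p-values approximately
uniform despite the discreteness of counts).
Genes are called differentially expressed by a dual threshold:
Benjamini-Hochberg FDR below a cutoff AND |log2 fold change| above a cutoff
(defaults FDR < 0.001, |log2FC| > 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import CountMatrix

logger = logging.getLogger(__name__)

_DISPERSION_FLOOR = 1e-8
_TREND_BINS = 20
# above this two-group total the exact sum is replaced by a tail-doubling
# approximation (the NB is effectively continuous there)
_EXACT_MAX_TOTAL = 20_000


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios library size factors.

    Each sample's factor is the median over genes of count / geometric
    mean across samples, using only genes with nonzero counts in every
    sample. If no such gene exists, falls back to total-count ratios
    (each total divided by the geometric mean of totals) with a warning.
    """
    mat = counts.counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        sub = mat[all_nonzero]
        geo = np.exp(np.log(sub).mean(axis=1, keepdims=True))
        factors = np.median(sub / geo, axis=0)
    else:
        logger.warning(
            "no gene has nonzero counts in every sample; "
            "falling back to total-count size factors"
        )
        totals = mat.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (minimum-likelihood rule).

    The p-value is the sum of hypergeometric probabilities, margins fixed,
    of all tables at most as probable as the observed one.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValueError("table cells must be finite and non-negative")
    if t.sum() == 0:
        raise ValueError("table has no observations")
    return float(stats.fisher_exact(t.astype(int), alternative="two-sided")[1])


def ddct_relative_expression(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_calib: float,
    ct_ref_calib: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) in the test sample minus the same
    difference in the calibrator sample; the fold change is 2**(-ddCt).
    """
    vals = (ct_target_test, ct_ref_test, ct_target_calib, ct_ref_calib)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_calib - ct_ref_calib)
    return 2.0 ** (-ddct)


def _moment_dispersions(norm: np.ndarray, cols_by_group, inv_sf: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments dispersion pooled over the two groups.

    For normalized counts, Var(K/s) = q * E[1/s] + alpha * q^2, so
    alpha = (sample var - mean * mean(1/s)) / mean^2 per group; the two
    group estimates are pooled with df weights.
    """
    num = np.zeros(norm.shape[0])
    den = 0.0
    for cols in cols_by_group:
        sub = norm[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        z = inv_sf[cols].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m * z) / np.maximum(m, 1e-300) ** 2, 0.0)
        df = len(cols) - 1
        num += df * a
        den += df
    return np.maximum(num / den, _DISPERSION_FLOOR)


def _dispersion_trend(means: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Mean-dispersion trend over mean-ranked bins.

    Bin-level means of the moment estimates (their sampling distribution
    is right-skewed, so the mean tracks the expected dispersion where a
    median would sit below it and let light-tailed genes through) are
    smoothed by a running median over neighbouring bins.
    """
    n = len(means)
    order = np.argsort(means, kind="stable")
    bins = np.array_split(order, min(_TREND_BINS, max(n, 1)))
    trend = np.empty(n)
    level = [np.mean(alphas[b]) for b in bins if len(b)]
    for i, b in enumerate(bins):
        lo, hi = max(0, i - 1), min(len(level), i + 2)
        trend[b] = np.median(level[lo:hi])
    return trend


def _nb_params(mu: float, var: float) -> tuple[float, float]:
    """scipy nbinom (n, p) for a given mean/variance; Poisson-like if var<=mu."""
    var = max(var, mu * (1 + 1e-8))
    n = mu * mu / (var - mu)
    p = mu / var
    return n, p


def _exact_pvalue(k_a: int, k_total: int, mu_a, var_a, mu_b, var_b) -> float:
    """Two-sided conditional exact p-value for the group-A total.

    Sums P(a, k_total - a) over all splits whose joint NB probability is
    at most that of the observed split, normalised by the total over all
    splits. Above _EXACT_MAX_TOTAL falls back to doubling the smaller
    conditional tail.
    """
    if k_total == 0:
        return 1.0
    na, pa = _nb_params(mu_a, var_a)
    nb, pb = _nb_params(mu_b, var_b)
    if k_total <= _EXACT_MAX_TOTAL:
        a = np.arange(k_total + 1)
        logp = stats.nbinom.logpmf(a, na, pa) + stats.nbinom.logpmf(k_total - a, nb, pb)
        logp -= logp.max()
        p_obs = logp[k_a]
        w = np.exp(logp)
        total = w.sum()
        # mid-p rule: outcomes strictly less probable than the observed one
        # plus half the mass of equally probable outcomes; removes the
        # conservativeness of the discrete atom while keeping the test exact
        less = w[logp < p_obs - 1e-8].sum()
        equal = w[np.abs(logp - p_obs) <= 1e-8].sum()
        return float(min((less + 0.5 * equal) / total, 1.0))
    # large totals: the conditional law of K_A is effectively continuous;
    # approximate it as normal (conditioning two normals on their sum) and
    # double the smaller tail, with continuity correction
    m = k_total * mu_a / (mu_a + mu_b)
    v = var_a * var_b / (var_a + var_b)
    z_left = (k_a + 0.5 - m) / math.sqrt(v)
    z_right = (k_a - 0.5 - m) / math.sqrt(v)
    left = stats.norm.cdf(z_left)
    right = stats.norm.sf(z_right)
    return float(min(1.0, 2.0 * min(left, right)))


class NBDiffExpression:
    """Negative-binomial exact test between two groups of a count matrix.

    Parameters
    ----------
    counts : CountMatrix
        Raw counts with group labels.
    group_a, group_b : str
        The two groups to contrast. log2 fold changes are reported as
        A relative to B (positive = higher in ``group_a``).
    dispersion : float or array, optional
        Known per-gene dispersion(s); when given, moment estimation and
        trend smoothing are skipped (useful for simulated data with known
        overdispersion).
    """

    def __init__(self, counts: CountMatrix, group_a: str, group_b: str,
                 dispersion=None):
        self.counts = counts
        self.group_a = group_a
        self.group_b = group_b
        self.samples_a = counts.samples_of(group_a)
        self.samples_b = counts.samples_of(group_b)
        if len(self.samples_a) < 2 or len(self.samples_b) < 2:
            raise ValueError("need at least two replicates per group")
        self.dispersion = dispersion

    def fit(self, fdr_cutoff: float = 0.001, lfc_cutoff: float = 1.0
            ) -> "NBDiffExpressionResults":
        cm = self.counts
        cols = self.samples_a + self.samples_b
        sub = CountMatrix(cm.counts[cols], cm.lengths, cm.groups.loc[cols])
        sf = size_factors(sub).to_numpy()
        mat = sub.counts.to_numpy(dtype=float)
        norm = mat / sf
        ia = np.arange(len(self.samples_a))
        ib = np.arange(len(self.samples_a), len(cols))

        mean_a = norm[:, ia].mean(axis=1)
        mean_b = norm[:, ib].mean(axis=1)
        q0 = norm.mean(axis=1)  # pooled null mean per gene

        if self.dispersion is not None:
            alpha = np.broadcast_to(
                np.asarray(self.dispersion, dtype=float), (mat.shape[0],)
            ).copy()
        else:
            raw = _moment_dispersions(norm, [ia, ib], 1.0 / sf)
            trend = _dispersion_trend(q0, raw)
            alpha = np.maximum(raw, trend)

        S_a, S_b = sf[ia].sum(), sf[ib].sum()
        Q_a, Q_b = (sf[ia] ** 2).sum(), (sf[ib] ** 2).sum()
        k_a = mat[:, ia].sum(axis=1).astype(int)
        k_b = mat[:, ib].sum(axis=1).astype(int)

        pvals = np.ones(mat.shape[0])
        for g in range(mat.shape[0]):
            mu_a = q0[g] * S_a
            mu_b = q0[g] * S_b
            if mu_a <= 0 or mu_b <= 0:
                continue
            var_a = mu_a + alpha[g] * q0[g] ** 2 * Q_a
            var_b = mu_b + alpha[g] * q0[g] ** 2 * Q_b
            pvals[g] = _exact_pvalue(k_a[g], k_a[g] + k_b[g], mu_a, var_a, mu_b, var_b)

        fdr = bh_fdr(pvals)
        log2fc = np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)
        sign = np.where(
            (fdr < fdr_cutoff) & (np.abs(log2fc) > lfc_cutoff),
            np.sign(log2fc).astype(int),
            0,
        ).astype(int)

        frame = pd.DataFrame(
            {
                "baseMeanA": mean_a,
                "baseMeanB": mean_b,
                "log2fc": log2fc,
                "pvalue": pvals,
                "fdr": fdr,
                "sign": sign,
            },
            index=cm.gene_ids,
        )
        return NBDiffExpressionResults(
            frame, self.group_a, self.group_b, fdr_cutoff, lfc_cutoff, alpha
        )


@dataclass
class NBDiffExpressionResults:
    """Per-gene differential expression calls for one two-group contrast."""

    frame: pd.DataFrame
    group_a: str
    group_b: str
    fdr_cutoff: float
    lfc_cutoff: float
    dispersions: np.ndarray

    @property
    def sign(self) -> pd.Series:
        """Signed call per gene: +1 up in A, -1 down in A, 0 no call."""
        return self.frame["sign"]

    def n_up(self) -> int:
        return int((self.frame["sign"] == 1).sum())

    def n_down(self) -> int:
        return int((self.frame["sign"] == -1).sum())

    def summary(self) -> str:
        f = self.frame
        lines = [
            f"NB exact test: {self.group_a} vs {self.group_b}",
            f"  genes tested        : {len(f)}",
            f"  thresholds          : FDR < {self.fdr_cutoff}, |log2FC| > {self.lfc_cutoff}",
            f"  up in {self.group_a:<6}       : {self.n_up()}",
            f"  down in {self.group_a:<6}     : {self.n_down()}",
            f"  median dispersion   : {np.median(self.dispersions):.4g}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def nb_test(
    counts: CountMatrix,
    group_a: str,
    group_b: str,
    fdr_cutoff: float = 0.001,
    lfc_cutoff: float = 1.0,
    dispersion=None,
) -> NBDiffExpressionResults:
    """Functional wrapper: fit the two-group NB exact test in one call."""
    return NBDiffExpression(counts, group_a, group_b, dispersion=dispersion).fit(
        fdr_cutoff=fdr_cutoff, lfc_cutoff=lfc_cutoff
    )
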