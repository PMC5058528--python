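"""Two-locus gametic disequilibrium from dominant phenotype counts.

Dominant markers hide genotypes: at each locus only band presence/absence is
seen, so a pair of loci yields a 2x2 phenotype table (present/absent at A x
present/absent at B).  Under Hardy-Weinberg random union of gametes the four
phenotype class probabilities are functions of the four haplotype frequencies
``h11, h10, h01, h00`` (presence alleles written first):

    P(absent, absent)   = h00**2
    P(absent, present)  = (h00 + h01)**2 - h00**2
    P(present, absent)  = (h00 + h10)**2 - h00**2
    P(present, present) = 1 - the rest

The maximum-likelihood haplotype frequencies are found by EM over the ten
unordered haplotype pairs, multi-started because the dominant-data likelihood
can be flat or multimodal at small n.  Disequilibrium is
``D = h11 - (h11 + h10)(h11 + h01)`` and significance comes from the
likelihood-ratio statistic referred to chi-square with one degree of freedom
(an approximation retained even for boundary MLEs).  Multiple testing is
handled by FDR step-up corrections.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MarkerMatrix

EM_TOL = 1e-10
EM_MAX_ITER = 10_000


@dataclass
class PhenotypeTable2x2:
    """Counts of individuals by band phenotype at two dominant loci."""

    n_pp: int
    n_pa: int
    n_ap: int
    n_aa: int

    def __post_init__(self):
        if min(self.n_pp, self.n_pa, self.n_ap, self.n_aa) < 0:
            raise ValueError("negative phenotype count")
        if self.n < 2:
            raise ValueError("need at least 2 individuals")

    @property
    def n(self) -> int:
        return self.n_pp + self.n_pa + self.n_ap + self.n_aa

    def as_array(self) -> np.ndarray:
        return np.array([self.n_pp, self.n_pa, self.n_ap, self.n_aa], dtype=float)


@dataclass
class LDResult:
    h11: float
    h10: float
    h01: float
    h00: float
    lnl: float
    lnl0: float
    converged: bool
    n: int

    @property
    def D(self) -> float:
        return self.h11 - (self.h11 + self.h10) * (self.h11 + self.h01)

    @property
    def lr(self) -> float:
        return 2.0 * (self.lnl - self.lnl0)


def _class_probs(h):
    """Phenotype class probabilities (pp, pa, ap, aa) for h = (h11,h10,h01,h00).

    Accepts stacked arrays with haplotype axis first.
    """
    h11, h10, h01, h00 = h
    p_aa = h00 ** 2
    p_ap = (h00 + h01) ** 2 - p_aa
    p_pa = (h00 + h10) ** 2 - p_aa
    p_pp = 1.0 - p_aa - p_ap - p_pa
    return np.stack([p_pp, p_pa, p_ap, p_aa])


def _log_likelihood(counts, h):
    p = np.clip(_class_probs(h), 1e-300, None)
    return np.sum(counts * np.log(p), axis=0)


def _em_update(counts, h):
    """One EM step; vectorized over trailing axes of ``h``.

    E-step sums expected haplotype counts over the unordered pairs compatible
    with each phenotype class; M-step renormalizes.
    """
    h11, h10, h01, h00 = h
    n_pp, n_pa, n_ap, n_aa = counts
    tiny = 1e-300

    # class (absent, absent): pair (ab, ab)
    e00 = 2.0 * n_aa

    # class (absent, present): pairs (aB,aB), (aB,ab)
    p_ap = h01 ** 2 + 2.0 * h01 * h00
    w = n_ap / np.clip(p_ap, tiny, None)
    e01 = w * (2.0 * h01 ** 2 + 2.0 * h01 * h00)
    e00 = e00 + w * (2.0 * h01 * h00)

    # class (present, absent): pairs (Ab,Ab), (Ab,ab)
    p_pa = h10 ** 2 + 2.0 * h10 * h00
    w = n_pa / np.clip(p_pa, tiny, None)
    e10 = w * (2.0 * h10 ** 2 + 2.0 * h10 * h00)
    e00 = e00 + w * (2.0 * h10 * h00)

    # class (present, present): pairs (AB,AB), (AB,Ab), (AB,aB), (AB,ab), (Ab,aB)
    p_pp = h11 ** 2 + 2.0 * h11 * (h10 + h01 + h00) + 2.0 * h10 * h01
    w = n_pp / np.clip(p_pp, tiny, None)
    e11 = w * (2.0 * h11 ** 2 + 2.0 * h11 * (h10 + h01 + h00))
    e10 = e10 + w * (2.0 * h11 * h10 + 2.0 * h10 * h01)
    e01 = e01 + w * (2.0 * h11 * h01 + 2.0 * h10 * h01)
    e00 = e00 + w * (2.0 * h11 * h00)

    total = e11 + e10 + e01 + e00
    return np.stack([e11, e10, e01, e00]) / np.clip(total, tiny, None)


def _null_fit(counts):
    """Closed-form independence (D = 0) fit: marginal square-root MLEs."""
    n_pp, n_pa, n_ap, n_aa = counts
    n = counts.sum(axis=0)
    qa = np.sqrt((n_ap + n_aa) / n)   # absence-allele freq at locus A
    qb = np.sqrt((n_pa + n_aa) / n)
    pa_, pb_ = 1.0 - qa, 1.0 - qb
    h0 = np.stack([pa_ * pb_, pa_ * qb, qa * pb_, qa * qb])
    return h0, _log_likelihood(counts, h0)


def _starts(counts, n_starts=5):
    """Independence start plus four corner-biased starts."""
    h0, _ = _null_fit(counts)
    starts = [h0]
    for corner in range(min(n_starts - 1, 4)):
        biased = 0.2 * h0 + 0.8 * 0.05
        biased = np.array(biased, copy=True)
        biased[corner] = biased[corner] + 0.8 * 0.85
        starts.append(biased / biased.sum(axis=0, keepdims=True))
    return starts[:n_starts]


def _polish(counts, h, lnl):
    """Simplex-search refinement of an EM solution.

    Near boundary MLEs the EM step sizes collapse before the optimum is
    reached; a short Nelder-Mead ascent on softmax-parametrized frequencies
    closes the residual gap.  Returns the better of the two solutions.
    """
    from scipy.optimize import minimize

    def neg_lnl(z):
        e = np.exp(z - z.max())
        return -_log_likelihood(counts, e / e.sum())

    z0 = np.log(np.clip(h, 1e-12, None))
    res = minimize(neg_lnl, z0, method="Nelder-Mead",
                   options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-12})
    if -res.fun > lnl:
        e = np.exp(res.x - res.x.max())
        return e / e.sum(), float(-res.fun)
    return h, lnl


def em_haplotype_freqs_dominant(table: PhenotypeTable2x2, tol: float = EM_TOL,
                                max_iter: int = EM_MAX_ITER,
                                starts: int = 5) -> LDResult:
    """MLE of two-locus haplotype frequencies from a dominant phenotype table.

    Runs ``starts`` EM chains (independence start + corner-biased starts),
    keeps the best likelihood and refines it with a short simplex ascent.
    The EM likelihood is monotone non-decreasing; chains stop when the
    absolute log-likelihood change falls below ``tol``.
    """
    counts = table.as_array()
    best_h, best_lnl, converged = None, -np.inf, False
    for h in _starts(counts, starts):
        h = np.asarray(h, dtype=float)
        lnl = _log_likelihood(counts, h)
        ok = False
        for _ in range(max_iter):
            h = _em_update(counts, h)
            new = _log_likelihood(counts, h)
            if new < lnl - 1e-8:
                raise RuntimeError("EM likelihood decreased")
            if abs(new - lnl) < tol:
                lnl = new
                ok = True
                break
            lnl = new
        if lnl > best_lnl:
            best_h, best_lnl, converged = h, lnl, ok
    best_h, best_lnl = _polish(counts, best_h, best_lnl)
    _, lnl0 = _null_fit(counts)
    return LDResult(*map(float, best_h), lnl=float(best_lnl), lnl0=float(lnl0),
                    converged=bool(converged), n=table.n)


def ld_test(result: LDResult):
    """Likelihood-ratio test of D = 0, chi-square with 1 df."""
    lr = result.lr
    if lr < -1e-8:
        raise ValueError(f"negative likelihood-ratio statistic ({lr}); ascent failure")
    lr = max(lr, 0.0)
    return lr, float(stats.chi2.sf(lr, df=1))


def fdr_adjust(pvals, method: str = "bh"):
    """Step-up FDR-adjusted q-values.

    ``bh`` is the Benjamini-Hochberg step-up; ``pike_robust`` is the sharpened
    two-stage step-up that estimates the fraction of true nulls first.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value list")
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    key = {"bh": "fdr_bh", "pike_robust": "fdr_tsbky"}[method]
    return multipletests(pvals, method=key)[1]


# ---------------------------------------------------------------------------
# vectorized scan over many locus pairs
# ---------------------------------------------------------------------------

def _pair_counts(calls: np.ndarray, pairs: np.ndarray):
    """Phenotype-class counts (pp, pa, ap, aa) for each requested locus pair."""
    A = calls[:, pairs[:, 0]].astype(float)
    B = calls[:, pairs[:, 1]].astype(float)
    n = calls.shape[0]
    n_pp = (A * B).sum(axis=0)
    n_pa = (A * (1 - B)).sum(axis=0)
    n_ap = ((1 - A) * B).sum(axis=0)
    n_aa = n - n_pp - n_pa - n_ap
    return np.stack([n_pp, n_pa, n_ap, n_aa])


def _em_batch(counts, tol=EM_TOL, max_iter=30_000, n_starts=5):
    """Run the multi-start EM for every column of a 4 x m count array."""
    m = counts.shape[1]
    start_list = _starts(counts, n_starts)
    # stack starts: (4, n_starts * m)
    h = np.concatenate(start_list, axis=1)
    big = np.tile(counts, (1, len(start_list)))
    lnl = _log_likelihood(big, h)
    active = np.ones(h.shape[1], dtype=bool)
    done_iter = np.zeros(h.shape[1], dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        h_act = _em_update(big[:, active], h[:, active])
        new = _log_likelihood(big[:, active], h_act)
        conv = np.abs(new - lnl[active]) < tol
        h[:, active] = h_act
        lnl[active] = new
        idx = np.flatnonzero(active)
        done_iter[idx[conv]] = True
        active[idx[conv]] = False
    per_start_lnl = lnl.reshape(len(start_list), m)
    per_start_conv = done_iter.reshape(len(start_list), m)
    best = per_start_lnl.argmax(axis=0)
    cols = best * m + np.arange(m)
    h_best = h[:, cols]
    return h_best, per_start_lnl.max(axis=0), per_start_conv[best, np.arange(m)]


def ld_scan(matrix: MarkerMatrix, pairs: str = "all", fdr_method: str = "bh",
            tol: float = EM_TOL, max_iter: int = 30_000) -> pd.DataFrame:
    """LD statistics for locus pairs of a marker matrix.

    ``pairs='all'`` scans every pair; ``pairs='same_size_cross_primer'``
    restricts to pairs with identical fragment sizes from different primer
    pairs (the duplicated-marker candidates used by the QC dedup rule).
    Returns columns ``locusA, locusB, D, LR, p, q, converged``; non-converged
    fits keep their statistics but carry ``converged=False`` and are excluded
    from the FDR adjustment (q = NaN).
    """
    primary = matrix.primary()
    loci = list(primary.calls.columns)
    if pairs == "all":
        idx_pairs = list(itertools.combinations(range(len(loci)), 2))
    elif pairs == "same_size_cross_primer":
        info = primary.locus_info
        idx_pairs = [
            (i, j) for i, j in itertools.combinations(range(len(loci)), 2)
            if info["size_bp"].iloc[i] == info["size_bp"].iloc[j]
            and info["primer"].iloc[i] != info["primer"].iloc[j]
        ]
    else:
        raise ValueError(f"unknown pair selection {pairs!r}")
    if not idx_pairs:
        return pd.DataFrame(columns=["locusA", "locusB", "D", "LR", "p", "q",
                                     "converged"])

    pair_arr = np.array(idx_pairs)
    counts = _pair_counts(primary.calls.to_numpy(), pair_arr)
    h, lnl, conv = _em_batch(counts, tol=tol, max_iter=max_iter)
    _, lnl0 = _null_fit(counts)
    D = h[0] - (h[0] + h[1]) * (h[0] + h[2])
    lr = np.maximum(2.0 * (lnl - lnl0), 0.0)
    p = stats.chi2.sf(lr, df=1)

    out = pd.DataFrame({
        "locusA": [loci[i] for i, _ in idx_pairs],
        "locusB": [loci[j] for _, j in idx_pairs],
        "D": D, "LR": lr, "p": p, "q": np.nan, "converged": conv,
    })
    if conv.any():
        out.loc[conv, "q"] = fdr_adjust(out.loc[conv, "p"].to_numpy(), fdr_method)
    return out
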