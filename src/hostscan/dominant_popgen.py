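"""Allele frequencies, gene diversity and FST from dominant markers.

Dominant markers only reveal band presence, so the absence-allele frequency q
is inferred from the frequency of band-absent (recessive homozygote)
individuals under Hardy-Weinberg proportions.  Three estimators are offered:

* ``sqrt``: q = sqrt(x) where x is the absence phenotype frequency;
* ``lynch_milligan``: the Taylor-corrected square root, which removes the
  leading-order downward bias of sqrt(x);
* ``zhivotovsky`` (default): the Bayesian posterior mean of q given
  ``n_absent ~ Binomial(n, q**2)`` with a uniform prior on q, evaluated in
  closed form via beta functions.  This never returns q = 0 in finite samples
  and is well behaved at monomorphic loci.

Differentiation uses Weir-Cockerham-style variance components on the
estimated per-population frequencies.  Dominant data carry far less
information about q than codominant allele counts, and plug-in square-root
estimators respond sublinearly to q at weakly informative loci, which
attenuates between-population components.  Both effects are handled by a
moment calibration (:func:`calibrated_freqs`): the raw estimate is pushed
through the inverse of the estimator's exact mean response, and each
population enters the components with an effective allele-copy count
``m = q(1-q)/Var(q-hat)`` where the sampling variance is evaluated exactly
(binomial sums) at the pooled frequency -- the same role the Lynch-Milligan
delta-method variance ``(1 - q**2)/(4n)`` plays asymptotically.
Significance comes from permuting individuals among groups.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import betaln

_METHODS = ("sqrt", "lynch_milligan", "zhivotovsky")


def estimate_allele_freq(n_absent, n, method: str = "zhivotovsky"):
    """Absence-allele frequency estimate(s); accepts scalars or arrays."""
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
    n_absent = np.asarray(n_absent, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("sample size must be at least 1")
    if np.any((n_absent < 0) | (n_absent > n)):
        raise ValueError("n_absent outside [0, n]")
    x = n_absent / n
    if method == "sqrt":
        q = np.sqrt(x)
    elif method == "lynch_milligan":
        with np.errstate(divide="ignore", invalid="ignore"):
            var = x * (1.0 - x) / n
            corr = np.where(x > 0, var / (8.0 * x ** 2), 0.0)
        # the Taylor correction is unreliable at very low phenotype counts
        corr = np.minimum(corr, 0.25)
        q = np.where(x > 0, np.sqrt(x) / (1.0 - corr), 0.0)
    else:  # zhivotovsky, uniform prior on q
        q = np.exp(betaln(n_absent + 1.0, n - n_absent + 1.0)
                   - betaln(n_absent + 0.5, n - n_absent + 1.0))
    q = np.clip(q, 0.0, 1.0)
    return q.item() if q.ndim == 0 else q


def _lm_variance(q, n):
    """Delta-method sampling variance of q-hat for dominant data."""
    return (1.0 - q ** 2) / (4.0 * n)


@lru_cache(maxsize=64)
def _response_curves(n: int, method: str):
    """Exact response of a dominant-data estimator as a function of true q.

    For ``n`` individuals and absence counts ``k ~ Binomial(n, q**2)`` the
    estimator takes values ``e(k)``; its mean response ``g(q) = E[e(k) | q]``
    and sampling variance are evaluated exactly on a q grid by binomial sums.
    ``g`` is strictly increasing, so it can be inverted by interpolation; the
    inverted estimator has unit slope in q, which removes the response
    attenuation that otherwise biases between-population variance components
    downward at weakly informative (low-q) loci.
    """
    from scipy import stats as _st
    k = np.arange(n + 1)
    est = np.asarray(estimate_allele_freq(k, n, method), dtype=float)
    qgrid = np.linspace(0.0, 1.0, 1201)
    pm = _st.binom.pmf(k[:, None], n, (qgrid ** 2)[None, :])
    g = (pm * est[:, None]).sum(axis=0)
    var = (pm * (est[:, None] - g[None, :]) ** 2).sum(axis=0)
    gprime = np.gradient(g, qgrid)
    # enforce strict monotonicity for the interpolation-based inverse
    g = np.maximum.accumulate(g)
    return qgrid, g, var, gprime


def calibrated_freqs(counts, sizes, method: str = "zhivotovsky"):
    """Moment-calibrated per-population q and effective allele-copy counts.

    ``counts``: r x L band-absence counts, ``sizes``: length-r sample sizes.
    Per population the raw estimate is pushed through the inverse of the
    estimator's exact mean response.  The sampling variance is evaluated at
    the pooled absence frequency (per-population plug-ins are degenerate at
    boundary counts) and converted to the effective copy count
    ``m = q(1-q)/Var`` used by the variance-component machinery.

    Returns ``(q_tilde, m, q_pool)``.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    sizes = np.asarray(sizes, dtype=float).reshape(-1)
    r = counts.shape[0]
    n_total = int(sizes.sum())
    grid_p, g_p, var_p, gprime_p = _response_curves(n_total, method)
    q_pool = np.interp(
        np.asarray(estimate_allele_freq(counts.sum(axis=0), n_total, method)),
        g_p, grid_p)
    q_tilde = np.empty_like(counts)
    m = np.empty_like(counts)
    for i in range(r):
        n_i = int(sizes[i])
        grid, g, var, gprime = _response_curves(n_i, method)
        raw = np.asarray(estimate_allele_freq(counts[i], n_i, method))
        q_tilde[i] = np.interp(raw, g, grid)
        v = np.interp(q_pool, grid, var) \
            / np.clip(np.interp(q_pool, grid, gprime), 0.02, None) ** 2
        m[i] = np.maximum(q_pool * (1.0 - q_pool) / np.maximum(v, 1e-12), 2.0)
    return q_tilde, m, q_pool


def _wc_components(q, m):
    """Weir-Cockerham haploid-style (T1, T2) per locus.

    ``q``: r x L matrix of per-population frequencies; ``m``: r x L effective
    copy counts.  Returns per-locus numerator and denominator components whose
    ratio-of-sums is the multilocus theta.
    """
    r = q.shape[0]
    m_sum = m.sum(axis=0)
    m_bar = m_sum / r
    n_c = (m_sum - (m ** 2).sum(axis=0) / m_sum) / (r - 1)
    q_bar = (m * q).sum(axis=0) / m_sum
    s2 = (m * (q - q_bar) ** 2).sum(axis=0) / ((r - 1) * m_bar)
    pq = q_bar * (1.0 - q_bar)
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = s2 - (pq - s2 * (r - 1) / r) / (m_bar - 1.0)
        t2 = ((n_c - 1.0) / (m_bar - 1.0)) * pq \
            + (1.0 + (r - 1.0) * (m_bar - n_c) / (m_bar - 1.0)) * s2 / r
    return t1, t2


@dataclass
class DiversityReport:
    """Nei's gene diversity (HJ, pooled) and mean within-population diversity (HS)."""

    hj: float
    hs: float
    n_polymorphic: int
    n_loci: int
    n_samples: int

    def as_dict(self):
        return asdict(self)


def _group_absence_counts(matrix, grouping):
    """Per-group (band-absent count, group size) arrays for each locus."""
    primary = matrix.primary()
    if isinstance(grouping, str):
        labels = primary.metadata[grouping]
    else:
        labels = pd.Series(grouping).reindex(primary.calls.index)
    if labels.isna().any():
        raise ValueError("grouping undefined for some samples")
    groups = sorted(labels.unique())
    calls = primary.calls.to_numpy()
    absent = 1 - calls
    counts = np.array([absent[(labels == g).to_numpy()].sum(axis=0) for g in groups],
                      dtype=float)
    sizes = np.array([(labels == g).sum() for g in groups], dtype=float)
    return groups, counts, sizes, primary


def gene_diversity(matrix, grouping, method: str = "zhivotovsky") -> DiversityReport:
    """HJ (total gene diversity) and HS (mean within-population diversity).

    HJ uses the sample-size-weighted mean of the per-population allele
    frequencies (so populations fixed for alternative alleles contribute the
    full 0.5 to HJ while contributing 0 to HS); HS averages per-population
    expected heterozygosities over populations, then over loci.
    """
    groups, counts, sizes, primary = _group_absence_counts(matrix, grouping)
    if len(groups) < 1 or np.any(sizes < 2):
        raise ValueError("each population needs at least 2 samples")
    q_pop = estimate_allele_freq(counts, sizes[:, None], method)
    q_pool = (sizes[:, None] * q_pop).sum(axis=0) / sizes.sum()
    he_pop = 2.0 * q_pop * (1.0 - q_pop)
    hj = float(np.mean(2.0 * q_pool * (1.0 - q_pool)))
    hs = float(np.mean(he_pop))
    band_freq = primary.calls.mean(axis=0).to_numpy()
    n_poly = int(np.sum((band_freq > 0) & (band_freq < 1)))
    return DiversityReport(hj=hj, hs=hs, n_polymorphic=n_poly,
                           n_loci=primary.n_loci, n_samples=primary.n_samples)


def _theta_from_counts(counts, sizes, method):
    q, m, _ = calibrated_freqs(counts, sizes, method)
    t1, t2 = _wc_components(q, m)
    valid = t2 > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(valid, t1 / t2, np.nan)
    global_theta = t1[valid].sum() / t2[valid].sum() if valid.any() else np.nan
    return global_theta, per_locus


def fst_dominant(matrix, grouping, n_perm: int = 5000, seed: int = 0,
                 method: str = "zhivotovsky"):
    """Global and per-locus dominant-marker FST with a permutation test.

    The permutation unit is the individual: group labels are reassigned at
    random with group sizes preserved, which keeps LD structure across loci
    intact.  ``p = (#{perm >= observed} + 1) / (n_perm + 1)``.

    Returns ``(global_fst, per_locus_fst: Series, p_value)``.
    """
    import warnings
    groups, counts, sizes, primary = _group_absence_counts(matrix, grouping)
    if len(groups) < 2:
        raise ValueError("FST needs at least two groups")
    if np.any(sizes < 2):
        raise ValueError("each group needs at least 2 samples")
    if n_perm and n_perm < 100:
        warnings.warn("fewer than 100 permutations; p-value resolution is poor")

    observed, per_locus = _theta_from_counts(counts, sizes, method)

    p_value = np.nan
    if n_perm:
        rng = np.random.default_rng(seed)
        if isinstance(grouping, str):
            labels = primary.metadata[grouping]
        else:
            labels = pd.Series(grouping).reindex(primary.calls.index)
        absent = (1 - primary.calls.to_numpy()).astype(float)
        label_arr = labels.to_numpy()
        group_list = sorted(pd.unique(label_arr))
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(label_arr)
            c = np.array([absent[perm == g].sum(axis=0) for g in group_list])
            theta, _ = _theta_from_counts(c, sizes, method)
            if theta >= observed - 1e-12:
                hits += 1
        p_value = (hits + 1) / (n_perm + 1)

    return float(observed), pd.Series(per_locus, index=primary.calls.columns,
                                      name="fst"), float(p_value)


def locus_stats(matrix, grouping, method: str = "zhivotovsky") -> pd.DataFrame:
    """Per-locus table: per-group q, pooled expected heterozygosity He, FST."""
    groups, counts, sizes, primary = _group_absence_counts(matrix, grouping)
    q_pop = estimate_allele_freq(counts, sizes[:, None], method)
    _, _, q_pool = calibrated_freqs(counts, sizes, method)
    _, per_locus = _theta_from_counts(counts, sizes, method)
    out = pd.DataFrame(index=primary.calls.columns.rename("locus"))
    for g, qg in zip(groups, q_pop):
        out[f"q_{g}"] = qg
    out["He"] = 2.0 * q_pool * (1.0 - q_pool)
    out["fst"] = per_locus
    return out


def trimmed_mean_fst(per_locus_fst, trim: float = 0.30) -> float:
    """Mean of the central mass of locus FST values after symmetric trimming.

    NaN entries (monomorphic loci) are dropped first; negative estimates are
    kept, since the trimming itself handles the tails.
    """
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    values = np.asarray(pd.Series(per_locus_fst).dropna(), dtype=float)
    if values.size * (1.0 - 2.0 * trim) < 4:
        raise ValueError("too few loci for the requested trim")
    values = np.sort(values, kind="stable")
    k = int(np.floor(trim * values.size))
    central = values[k: values.size - k] if k else values
    return float(central.mean())
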