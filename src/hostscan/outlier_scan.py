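"""FDist-style outlier scan for dominant markers.

A neutral (He, FST) cloud is simulated under the Balding-Nichols island
parameterization at a target FST (normally the trimmed mean of the empirical
locus FST distribution, so that true outliers do not inflate the null), using
the same dominant-data estimators as the empirical analysis.  The cloud is
reduced to conditional quantile envelopes on a heterozygosity grid: loci whose
empirical FST exceed the 95%/99% quantile of their He bin are labelled
outliers.  Loci flagged at the 95% level in two or more independent
comparisons form the consensus (robust) set.

The beta sampling scheme replaces a coalescent island simulation: for the
purpose of conditional-quantile envelopes the stationary distribution of
island-model allele frequencies is the same one-parameter beta family, which
is far simpler and fully seedable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dominant_popgen import _wc_components, calibrated_freqs


@dataclass
class NeutralEnvelope:
    """Conditional FST quantile curves on a binned He grid."""

    target_fst: float             # seed statistic (trimmed-mean locus FST)
    sample_sizes: tuple
    n_sim_loci: int
    n_demes: int
    seed: int
    bins: pd.DataFrame            # he_lo, he_hi, q50, q95, q99
    bn_f: float = np.nan          # calibrated Balding-Nichols parameter
    cloud: pd.DataFrame | None = None

    def lookup(self, he):
        """Row index of the He bin for each value (nearest bin outside range)."""
        he = np.atleast_1d(np.asarray(he, dtype=float))
        lo = self.bins["he_lo"].to_numpy()
        hi = self.bins["he_hi"].to_numpy()
        idx = np.searchsorted(hi, he, side="left")
        idx = np.clip(idx, 0, len(self.bins) - 1)
        below = he < lo[0]
        idx[below] = 0
        return idx

    def to_tsv(self, path):
        self.bins.to_csv(path, sep="\t", index=False)
        return path


def _simulate_cloud(rng, bn_f, sizes, n_loci, method):
    """(He, locus FST) for ``n_loci`` neutral loci at Balding-Nichols F."""
    r = sizes.size
    p0 = rng.uniform(0.01, 0.99, size=n_loci)
    a = p0 * (1.0 - bn_f) / bn_f
    b = (1.0 - p0) * (1.0 - bn_f) / bn_f
    p = rng.beta(a, b, size=(r, n_loci))             # presence-allele freq per deme
    absent = rng.binomial(sizes[:, None].astype(int), (1.0 - p) ** 2)
    q, m, q_pool = calibrated_freqs(absent, sizes, method)
    t1, t2 = _wc_components(q, m)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(t2 > 0, t1 / t2, np.nan)
    he = 2.0 * q_pool * (1.0 - q_pool)
    return he, fst


def _trimmed_mean(values, trim):
    values = np.sort(values[np.isfinite(values)], kind="stable")
    k = int(np.floor(trim * values.size))
    return float(values[k: values.size - k].mean()) if values.size else np.nan


def calibrate_bn_f(target_fst: float, sizes, trim: float, seed: int,
                   method: str, n_pilot: int = 4000, n_iter: int = 18) -> float:
    """Balding-Nichols F whose simulated trimmed-mean locus FST hits the seed.

    The seed statistic of the scan is a trimmed mean of noisy per-locus
    estimates, which sits well below the generating F (the locus FST
    distribution is right-skewed); matching the statistic rather than the
    parameter is what keeps the neutral false-positive rate at its nominal
    level.  Bisection with common random numbers per iteration.
    """
    lo, hi = 1e-4, 0.95
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        rng = np.random.default_rng(seed)     # common draws across iterations
        _, fst = _simulate_cloud(rng, mid, sizes, n_pilot, method)
        if _trimmed_mean(fst, trim) < target_fst:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_neutral_envelope(target_fst: float, sample_sizes, n_sim_loci: int = 50_000,
                              n_demes: int = 100, seed: int = 0,
                              method: str = "zhivotovsky", n_bins: int | None = None,
                              min_per_bin: int = 50, keep_cloud: bool = False,
                              trim: float = 0.30) -> NeutralEnvelope:
    """Simulate the neutral (He, FST) cloud and reduce it to quantile envelopes.

    ``target_fst`` is the seed statistic: the ``trim``-trimmed mean of locus
    FST values that the simulated cloud must reproduce (``trim=0`` targets the
    plain mean).  The generating Balding-Nichols F is calibrated internally by
    :func:`calibrate_bn_f`.  Per simulated locus: ancestral frequency ~
    Uniform(0.01, 0.99), sampled demes receive Balding-Nichols frequencies,
    dominant phenotypes are drawn at the empirical sample sizes, and (He, FST)
    are computed with the same estimators as the empirical scan.  Bins are
    equal-occupancy over He with at least ``min_per_bin`` points each.
    """
    if not 0.0 < target_fst < 1.0:
        raise ValueError("target_fst must be in (0, 1)")
    sizes = np.asarray(sample_sizes, dtype=float)
    if sizes.size < 2 or np.any(sizes < 2):
        raise ValueError("need >= 2 samples in each of >= 2 groups")
    if n_bins is None:
        n_bins = max(20, min(60, n_sim_loci // (4 * min_per_bin)))
    if n_sim_loci < n_bins * min_per_bin:
        raise ValueError(
            f"{n_sim_loci} simulated loci cannot fill {n_bins} bins at "
            f">={min_per_bin} points per bin")

    bn_f = calibrate_bn_f(target_fst, sizes, trim, seed, method)
    rng = np.random.default_rng(seed + 1)
    he, fst = _simulate_cloud(rng, bn_f, sizes, n_sim_loci, method)

    ok = np.isfinite(fst)
    he, fst = he[ok], fst[ok]
    order = np.argsort(he, kind="stable")
    he, fst = he[order], fst[order]
    edges = np.linspace(0, he.size, n_bins + 1).astype(int)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        f = fst[lo:hi]
        rows.append({
            "he_lo": he[lo], "he_hi": he[hi - 1],
            "q50": np.quantile(f, 0.50), "q95": np.quantile(f, 0.95),
            "q99": np.quantile(f, 0.99), "n": hi - lo,
        })
    bins = pd.DataFrame(rows)
    cloud = pd.DataFrame({"He": he, "fst": fst}) if keep_cloud else None
    return NeutralEnvelope(target_fst=float(target_fst),
                           sample_sizes=tuple(int(s) for s in sizes),
                           n_sim_loci=n_sim_loci, n_demes=n_demes, seed=seed,
                           bins=bins, bn_f=float(bn_f), cloud=cloud)


def classify_outliers(locus_stats: pd.DataFrame, envelope: NeutralEnvelope,
                      comparison: str = "combined") -> pd.DataFrame:
    """Assign an outlier level (none/95/99) to each empirical locus.

    ``locus_stats`` needs columns ``He`` and ``fst`` indexed by locus (as
    produced by :func:`hostscan.dominant_popgen.locus_stats`).
    """
    if locus_stats.empty:
        raise ValueError("empty locus stats")
    he = locus_stats["He"].to_numpy(dtype=float)
    fst = locus_stats["fst"].to_numpy(dtype=float)
    idx = envelope.lookup(he)
    q95 = envelope.bins["q95"].to_numpy()[idx]
    q99 = envelope.bins["q99"].to_numpy()[idx]
    level = np.where(fst > q99, 99, np.where(fst > q95, 95, 0))
    level[~np.isfinite(fst)] = 0
    return pd.DataFrame({
        "locus": locus_stats.index, "comparison": comparison,
        "He": he, "fst": fst, "level": level,
    }).set_index(["locus", "comparison"]).reset_index()


def consensus_outliers(calls: pd.DataFrame, min_comparisons: int = 2) -> set:
    """Loci flagged at >= 95% level in at least ``min_comparisons`` comparisons."""
    if calls["comparison"].nunique() < 2:
        raise ValueError("consensus needs calls from at least two comparisons")
    flagged = calls[calls["level"] >= 95]
    counts = flagged.groupby("locus")["comparison"].nunique()
    return set(counts[counts >= min_comparisons].index)


def nested_outlier_counts(calls: pd.DataFrame, combined_id: str = "combined") -> dict:
    """The four nested headline counts of an outlier report.

    * ``flagged_anywhere``: loci at >= 95% in at least one comparison;
    * ``flagged_multiple``: loci at >= 95% in more than one comparison;
    * ``flagged_combined``: loci at >= 95% in the pooled (combined) comparison;
    * ``robust``: combined outliers that are also flagged in multiple
      comparisons.
    """
    flagged = calls[calls["level"] >= 95]
    per_locus = flagged.groupby("locus")["comparison"].nunique()
    anywhere = set(per_locus.index)
    multiple = set(per_locus[per_locus >= 2].index)
    combined = set(flagged.loc[flagged["comparison"] == combined_id, "locus"])
    return {
        "flagged_anywhere": len(anywhere),
        "flagged_multiple": len(multiple),
        "flagged_combined": len(combined),
        "robust": len(combined & multiple),
    }
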