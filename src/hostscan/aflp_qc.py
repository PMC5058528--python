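"""Replicate-based genotyping QC and marker filtering.

Error estimation follows the replicate-scoring convention for anonymous
dominant markers: the error rate is the ratio of call mismatches among
replicate genotypings to the total number of replicated calls.  Filtering
applies four rules in a fixed order:

1. drop loci with any replicate discordance (strict: a single mismatched pair
   removes the locus, since mismatch-prone loci are not representative of the
   average error rate);
2. drop loci whose fragment size matches a negative-control peak;
3. collapse same-size loci amplified by different primer pairs that are in
   significant LD (non-specific primer binding produces duplicated markers);
   one member of each linked cluster is retained, chosen as the
   lexicographically first locus id;
4. drop singleton loci, where only one individual carries the rarer
   phenotype.

Every rule logs ``initial/removed/retained`` counts so the provenance log
always reconstructs the initial locus count.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import MarkerMatrix, QCError
from .ld_dominant import ld_scan


@dataclass
class QCReport:
    error_rate: float
    removed_by_rule: dict
    size_freq_r: float
    size_freq_p: float

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path


def estimate_error_rate(matrix: MarkerMatrix) -> float:
    """Mismatched calls over compared calls across all replicate pairs."""
    pairs = matrix.replicate_pairs()
    if not pairs:
        raise QCError("no replicate pairs in the matrix; error rate undefined")
    calls = matrix.calls
    mismatches = compared = 0
    for orig, rep in pairs:
        a = calls.loc[orig].to_numpy()
        b = calls.loc[rep].to_numpy()
        mismatches += int((a != b).sum())
        compared += a.size
    return mismatches / compared


def _replicate_discordant_loci(matrix: MarkerMatrix) -> list:
    pairs = matrix.replicate_pairs()
    if not pairs:
        return []
    calls = matrix.calls
    bad = np.zeros(matrix.n_loci, dtype=bool)
    for orig, rep in pairs:
        bad |= (calls.loc[orig].to_numpy() != calls.loc[rep].to_numpy())
    return list(calls.columns[bad])


def filter_markers(matrix: MarkerMatrix, negative_control_sizes=(),
                   ld_fdr_alpha: float = 0.05) -> MarkerMatrix:
    """Apply the four filtering rules in order; idempotent.

    Rule 3 tests LD only among same-size cross-primer candidate pairs, with
    FDR control restricted to those candidates.
    """
    # rule 1: replicate mismatches
    m = matrix.drop_loci(_replicate_discordant_loci(matrix), "replicate_mismatch")

    # rule 2: negative-control peak sizes
    control = set(int(s) for s in negative_control_sizes)
    rule2 = [l for l in m.calls.columns if int(m.sizes[l]) in control]
    m = m.drop_loci(rule2, "negative_control_size")

    # rule 3: same-size cross-primer duplicates in significant LD
    scan = ld_scan(m, pairs="same_size_cross_primer")
    linked = scan[(scan["converged"]) & (scan["q"] <= ld_fdr_alpha)]
    g = nx.Graph()
    g.add_edges_from(zip(linked["locusA"], linked["locusB"]))
    drop = set()
    for comp in nx.connected_components(g):
        drop |= comp - {min(comp)}
    m = m.drop_loci(sorted(drop), "linked_duplicate")

    # rule 4: singletons (rarer phenotype in exactly one individual)
    primary = m.primary()
    ones = primary.calls.sum(axis=0)
    minority = np.minimum(ones, primary.n_samples - ones)
    rule4 = list(primary.calls.columns[minority == 1])
    m = m.drop_loci(rule4, "singleton")

    if m.n_loci == 0:
        raise QCError("all loci removed by filtering")
    return m


def size_frequency_correlation(matrix: MarkerMatrix):
    """Pearson correlation of per-locus band frequency vs fragment size.

    A significant negative correlation indicates size homoplasy; near-zero
    correlation (e.g. |r| small with p > 0.05) is the no-homoplasy criterion.
    """
    primary = matrix.primary()
    if primary.n_loci < 3:
        raise QCError("need at least 3 loci for the size-frequency correlation")
    freq = primary.calls.mean(axis=0).to_numpy(dtype=float)
    size = primary.sizes.to_numpy(dtype=float)
    if np.ptp(freq) == 0 or np.ptp(size) == 0:
        raise QCError("zero variance in band frequency or fragment size; "
                      "correlation undefined")
    r, p = stats.pearsonr(freq, size)
    return float(r), float(p)


def qc_report(matrix: MarkerMatrix, negative_control_sizes=(),
              ld_fdr_alpha: float = 0.05):
    """Run the full QC stage; returns ``(filtered_matrix, QCReport)``."""
    err = estimate_error_rate(matrix)
    filtered = filter_markers(matrix, negative_control_sizes, ld_fdr_alpha)
    r, p = size_frequency_correlation(filtered)
    removed = {e["rule"]: e["removed"] for e in filtered.log}
    return filtered, QCReport(error_rate=err, removed_by_rule=removed,
                              size_freq_r=r, size_freq_p=p)


def write_qc_log(matrix: MarkerMatrix, path) -> Path:
    path = Path(path)
    matrix.log_frame().to_csv(path, sep="\t", index=False)
    return path
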