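"""Sequence-locus analyses: SNP calling, EM phasing, diversity, F84, PhiST.

The nuclear locus arrives as aligned diploid consensus sequences in which
heterozygous sites carry two-base IUPAC codes.  SNPs are called per column
(ambiguity codes count as both alleles; columns containing N or gaps are
excluded).  Gametic phase is resolved by an EM algorithm over haplotype
frequencies under random pairing (the classic frequency-EM for multi-site
genotypes); individuals whose best pair has posterior probability below a
confidence threshold are left unphased, the single-program analogue of
requiring consensus among several phasing programs.

Diversity statistics per group: number of haplotypes H, polymorphic sites p,
singleton haplotypes Sn, haplotype diversity Hd = n/(n-1) (1 - sum p_i**2),
nucleotide diversity pi (mean pairwise difference per site), and the
four-gamete minimum number of recombination events Rm.  Distances between
haplotypes use the F84 substitution model (closed-form ML distance from base
frequencies, transitions and transversions); PhiST comes from a two-level
AMOVA on squared distances with individual-level permutation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .containers import HET_TO_ALLELES, DiploidAlignment, HaplotypeSet

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


# ---------------------------------------------------------------------------
# SNP calling
# ---------------------------------------------------------------------------

def call_snps(alignment: DiploidAlignment) -> pd.DataFrame:
    """Per-column variant table from a diploid IUPAC alignment.

    Allele counts treat each individual as two gene copies (a heterozygous
    code contributes one copy of each base).  Columns containing N or gaps are
    excluded; columns with more than two alleles are flagged rather than
    dropped.  ``codon_pos`` is 1-3 relative to the alignment's frame offset
    (0 for columns before the first complete codon).
    """
    seqs = list(alignment.sequences)
    length = alignment.length
    rows = []
    for col in range(length):
        column = [s[col] for s in seqs]
        if any(ch in ("N", "-") for ch in column):
            continue
        counts: dict = {}
        for ch in column:
            for base in HET_TO_ALLELES.get(ch, (ch, ch)):
                counts[base] = counts.get(base, 0) + 1
        if len(counts) < 2:
            continue
        alleles = sorted(counts, key=lambda b: (-counts[b], b))
        codon_pos = 0
        if col >= alignment.frame_offset:
            codon_pos = (col - alignment.frame_offset) % 3 + 1
        rows.append({
            "position": col + 1,
            "alleles": "/".join(alleles),
            "counts": "/".join(str(counts[a]) for a in alleles),
            "n_alleles": len(alleles),
            "codon_pos": codon_pos,
            "multiallelic_flag": len(counts) > 2,
        })
    return pd.DataFrame(rows, columns=["position", "alleles", "counts", "n_alleles",
                                       "codon_pos", "multiallelic_flag"])


# ---------------------------------------------------------------------------
# EM phasing
# ---------------------------------------------------------------------------

def _genotype_vectors(alignment: DiploidAlignment, variants: pd.DataFrame):
    """Biallelic site positions plus per-individual genotypes (0/1/2 = het)."""
    sites = variants[~variants["multiallelic_flag"]]
    positions = sites["position"].to_numpy() - 1
    alleles = [tuple(a.split("/")) for a in sites["alleles"]]
    genos = {}
    for sid, seq in alignment.sequences.items():
        g = []
        for (pos, (a0, a1)) in zip(positions, alleles):
            ch = seq[pos]
            if ch == a0:
                g.append(0)
            elif ch == a1:
                g.append(1)
            else:
                pair = HET_TO_ALLELES.get(ch)
                if pair is None or set(pair) != {a0, a1}:
                    raise ValueError(
                        f"{sid} position {pos + 1}: state {ch!r} incompatible "
                        f"with alleles {a0}/{a1}")
                g.append(2)
        genos[sid] = tuple(g)
    return positions, alleles, genos


def _compatible_pairs(geno):
    """All unordered haplotype pairs consistent with a multi-site genotype."""
    het_idx = [i for i, g in enumerate(geno) if g == 2]
    base = [g if g != 2 else 0 for g in geno]
    if not het_idx:
        h = tuple(base)
        return [(h, h)]
    pairs = []
    first = het_idx[0]
    for assignment in itertools.product((0, 1), repeat=len(het_idx) - 1):
        a = list(base)
        b = list(base)
        a[first], b[first] = 0, 1
        for i, bit in zip(het_idx[1:], assignment):
            a[i], b[i] = bit, 1 - bit
        pairs.append((tuple(a), tuple(b)))
    return pairs


def em_phase(alignment: DiploidAlignment, tol: float = 1e-8, max_iter: int = 1000,
             seed: int = 0, confidence_threshold: float = 0.9,
             max_het_sites: int = 15) -> HaplotypeSet:
    """Phase diploid sequences by EM over haplotype frequencies.

    The likelihood is the product over individuals of
    ``sum over compatible pairs (2 - delta_ab) f_a f_b``; the EM iterates
    expected pair counts.  Each phased individual receives its most probable
    pair; ``confidence`` is that pair's posterior probability.  Individuals
    with more than ``max_het_sites`` heterozygous sites (pair enumeration grows
    as 2**(h-1)) or confidence below the threshold stay unphased.
    """
    if alignment.n_samples < 2:
        raise ValueError("phasing needs at least 2 individuals")
    variants = call_snps(alignment)
    if variants.empty:
        haps = {}
        pairs, conf = {}, {}
        backbone = next(iter(alignment.sequences))
        hap_id = "hap_001"
        haps[hap_id] = backbone
        for sid in alignment.sequences.index:
            pairs[sid] = (hap_id, hap_id)
            conf[sid] = 1.0
        return HaplotypeSet(haps, pairs, conf, alignment.metadata, unphased=[])

    positions, alleles, genos = _genotype_vectors(alignment, variants)

    sample_pairs = {}
    unphased = []
    for sid, g in genos.items():
        n_het = sum(1 for x in g if x == 2)
        if n_het > max_het_sites:
            unphased.append(sid)
        else:
            sample_pairs[sid] = _compatible_pairs(g)

    hap_index: dict = {}
    for plist in sample_pairs.values():
        for a, b in plist:
            for h in (a, b):
                hap_index.setdefault(h, len(hap_index))
    n_h = len(hap_index)

    # expected counts from uniform pair weights as the starting frequency
    freq = np.zeros(n_h)
    for plist in sample_pairs.values():
        w = 1.0 / len(plist)
        for a, b in plist:
            freq[hap_index[a]] += w
            freq[hap_index[b]] += w
    freq /= freq.sum()

    pair_idx = {
        sid: (np.array([hap_index[a] for a, _ in plist]),
              np.array([hap_index[b] for _, b in plist]),
              np.array([1.0 if a == b else 2.0 for a, b in plist]))
        for sid, plist in sample_pairs.items()
    }

    lnl_old = -np.inf
    for _ in range(max_iter):
        new = np.zeros(n_h)
        lnl = 0.0
        for sid, (ia, ib, mult) in pair_idx.items():
            w = mult * freq[ia] * freq[ib]
            tot = w.sum()
            if tot <= 0:
                w = np.ones_like(w)
                tot = w.sum()
            lnl += math.log(max(tot, 1e-300))
            w = w / tot
            np.add.at(new, ia, w)
            np.add.at(new, ib, w)
        freq = new / new.sum()
        if abs(lnl - lnl_old) < tol:
            break
        lnl_old = lnl

    # most probable pair per individual
    backbone = list(next(iter(alignment.sequences)))
    inv_index = {v: k for k, v in hap_index.items()}

    def hap_seq(state):
        s = list(backbone)
        for (pos, (a0, a1), bit) in zip(positions, alleles, state):
            s[pos] = a1 if bit else a0
        return "".join(s)

    chosen: dict = {}
    confidence: dict = {}
    hap_ids: dict = {}
    hap_seqs: dict = {}

    def register(state):
        if state not in hap_ids:
            hap_ids[state] = f"hap_{len(hap_ids) + 1:03d}"
            hap_seqs[hap_ids[state]] = hap_seq(state)
        return hap_ids[state]

    for sid, (ia, ib, mult) in pair_idx.items():
        w = mult * freq[ia] * freq[ib]
        tot = w.sum()
        if tot <= 0:
            post = np.ones_like(w) / w.size
        else:
            post = w / tot
        k = int(post.argmax())
        conf = float(post[k]) if len(post) > 1 else 1.0
        if conf < confidence_threshold:
            unphased.append(sid)
            continue
        a, b = inv_index[int(ia[k])], inv_index[int(ib[k])]
        chosen[sid] = tuple(sorted((a, b)))
        confidence[sid] = conf

    pairs_out = {sid: (register(a), register(b)) for sid, (a, b) in chosen.items()}
    return HaplotypeSet(hap_seqs, pairs_out, confidence, alignment.metadata,
                        unphased=sorted(unphased))


# ---------------------------------------------------------------------------
# haplotype summary statistics
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def minimum_recombination_events(seq_list) -> int:
    """Hudson-Kaplan lower bound on recombination events (four-gamete test).

    Site pairs exhibiting all four gametes define open intervals; Rm is the
    size of a maximal set of pairwise disjoint such intervals, after removing
    intervals that contain another.
    """
    if not seq_list:
        return 0
    length = len(seq_list[0])
    var_cols = []
    for col in range(length):
        states = {s[col] for s in seq_list}
        if len(states) == 2:
            var_cols.append(col)
    intervals = []
    for i, j in itertools.combinations(var_cols, 2):
        gametes = {(s[i], s[j]) for s in seq_list}
        if len(gametes) == 4:
            intervals.append((i, j))
    # keep only minimal intervals
    minimal = [iv for iv in intervals
               if not any(o != iv and iv[0] <= o[0] and o[1] <= iv[1]
                          for o in intervals)]
    minimal.sort(key=lambda iv: iv[1])
    rm, last_end = 0, -1
    for a, b in minimal:
        if a >= last_end:      # open intervals (a, b): disjoint if next starts at/after end
            rm += 1
            last_end = b
    return rm


@dataclass
class SeqSummary:
    group: str
    n: int            # phased individuals
    h: int            # distinct haplotypes
    p: int            # polymorphic sites
    sn: int           # singleton haplotypes
    hd: float
    pi: float
    rm: int


def haplotype_summary(haps: HaplotypeSet, group_by: str = "host",
                      include_total: bool = True) -> pd.DataFrame:
    """Per-group diversity table (one row per group, optional pooled total)."""
    groups = haps.copies(group_by)
    order = sorted(groups)
    if include_total:
        groups = dict(groups)
        groups["total"] = [h for g in order for h in groups[g]]
        order = order + ["total"]
    rows = []
    for g in order:
        copies = groups[g]
        if len(copies) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 haplotype copies")
        seqs = [haps.haplotypes[h] for h in copies]
        counts = pd.Series(copies).value_counts()
        n_copies = len(copies)
        freqs = counts / n_copies
        hd = n_copies / (n_copies - 1) * (1.0 - float((freqs ** 2).sum()))
        length = len(seqs[0])
        total_diff = sum(_hamming(a, b) for a, b in itertools.combinations(seqs, 2))
        n_pairs = n_copies * (n_copies - 1) // 2
        pi = total_diff / n_pairs / length if n_pairs else 0.0
        poly = sum(1 for col in range(length) if len({s[col] for s in seqs}) > 1)
        rows.append(SeqSummary(
            group=g, n=len(copies) // 2, h=int(counts.size), p=int(poly),
            sn=int((counts == 1).sum()), hd=float(hd), pi=float(pi),
            rm=minimum_recombination_events(sorted(set(seqs)))))
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("group")


# ---------------------------------------------------------------------------
# F84 distance
# ---------------------------------------------------------------------------

def f84_distance(seq1: str, seq2: str) -> float:
    """Closed-form F84 maximum-likelihood distance between two sequences.

    Gapped/ambiguous positions are pairwise-deleted.  Base frequencies are
    empirical means of the two sequences.  Saturated pairs (logarithm of a
    non-positive argument) return ``inf``.
    """
    pairs = [(a, b) for a, b in zip(seq1.upper(), seq2.upper())
             if a in "ACGT" and b in "ACGT"]
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    if not pairs:
        raise ValueError("no comparable (ungapped A/C/G/T) positions")
    L = len(pairs)
    counts = {b: 0.0 for b in "ACGT"}
    transitions = transversions = 0
    for a, b in pairs:
        counts[a] += 0.5
        counts[b] += 0.5
        if a != b:
            if {a, b} <= PURINES or {a, b} <= PYRIMIDINES:
                transitions += 1
            else:
                transversions += 1
    if transitions == 0 and transversions == 0:
        return 0.0
    freq = {b: counts[b] / L for b in "ACGT"}
    pi_r = freq["A"] + freq["G"]
    pi_y = freq["C"] + freq["T"]
    P = transitions / L
    Q = transversions / L
    if pi_r <= 0 or pi_y <= 0:
        # degenerate composition: transversion classes undefined; fall back to
        # the Jukes-Cantor-style log correction on total differences
        D = (transitions + transversions) / L
        arg = 1.0 - 4.0 * D / 3.0
        return math.inf if arg <= 0 else -0.75 * math.log(arg)
    A = (freq["T"] * freq["C"] / pi_y) + (freq["A"] * freq["G"] / pi_r)
    B = freq["T"] * freq["C"] + freq["A"] * freq["G"]
    C = pi_r * pi_y
    arg1 = 1.0 - P / (2.0 * A) - (A - B) * Q / (2.0 * A * C)
    arg2 = 1.0 - Q / (2.0 * C)
    if arg1 <= 0 or arg2 <= 0:
        return math.inf
    return -2.0 * A * math.log(arg1) + 2.0 * (A - B - C) * math.log(arg2)


# ---------------------------------------------------------------------------
# AMOVA PhiST
# ---------------------------------------------------------------------------

def _distance_matrix(haps: HaplotypeSet, distance: str):
    hap_ids = sorted(haps.haplotypes)
    seqs = [haps.haplotypes[h] for h in hap_ids]
    k = len(hap_ids)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if distance == "f84":
                dij = f84_distance(seqs[i], seqs[j])
            elif distance == "hamming":
                dij = float(_hamming(seqs[i], seqs[j]))
            else:
                raise ValueError(f"unknown distance {distance!r}")
            d[i, j] = d[j, i] = dij
    return {h: i for i, h in enumerate(hap_ids)}, d


def _amova_phi(d2, group_sizes, group_slices):
    """Two-level AMOVA variance-component ratio from squared distances.

    ``group_slices`` hold, per group, the row indices of that group's gene
    copies into ``d2`` (indices repeat when copies share a haplotype).
    """
    n = int(sum(group_sizes))
    G = len(group_sizes)
    all_idx = np.concatenate(group_slices)
    ssd_total = d2[np.ix_(all_idx, all_idx)].sum() / (2.0 * n)
    ssd_within = 0.0
    for sl, ng in zip(group_slices, group_sizes):
        block = d2[np.ix_(sl, sl)]
        ssd_within += block.sum() / (2.0 * ng)
    ssd_among = ssd_total - ssd_within
    df_a, df_w = G - 1, n - G
    sigma_w = ssd_within / df_w if df_w else 0.0
    n_bar = (n - sum(g * g for g in group_sizes) / n) / df_a
    sigma_a = (ssd_among / df_a - sigma_w) / n_bar
    denom = sigma_a + sigma_w
    if denom == 0:
        return 0.0, True
    return sigma_a / denom, False


def phi_st(haps: HaplotypeSet, group_by: str = "host", n_perm: int = 1000,
           seed: int = 0, distance: str = "f84"):
    """AMOVA PhiST between groups of phased individuals, with permutation p.

    Individuals are the permutation unit: each individual's two haplotype
    copies move together when group labels are reshuffled.  Degenerate
    all-identical data yields PhiST = 0 with p = 1.
    """
    ids = list(haps.pairs)
    labels = [haps.metadata.at[sid, group_by] for sid in ids]
    groups = sorted(set(labels))
    if len(groups) != 2 and len(groups) < 2:
        raise ValueError("PhiST needs at least two groups")
    index, d = _distance_matrix(haps, distance)
    if not np.isfinite(d).all():
        raise ValueError("saturated (infinite) distances; PhiST undefined")
    copy_idx = np.array([[index[a], index[b]] for a, b in
                         (haps.pairs[sid] for sid in ids)])
    d2 = d ** 2

    def phi_for(label_order):
        slices, sizes = [], []
        for g in groups:
            rows = [i for i, lab in enumerate(label_order) if lab == g]
            copies = copy_idx[rows].ravel()
            if copies.size < 2:
                raise ValueError(f"group {g!r} has fewer than 2 copies")
            slices.append(copies)
            sizes.append(copies.size)
        return _amova_phi(d2, sizes, slices)

    observed, degenerate = phi_for(labels)
    if degenerate:
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    labels_arr = np.array(labels)
    hits = 0
    for _ in range(n_perm):
        perm, _ = phi_for(rng.permutation(labels_arr))
        if perm >= observed - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return float(observed), float(p)


# ---------------------------------------------------------------------------
# codon effects
# ---------------------------------------------------------------------------

def annotate_codon_effect(variants: pd.DataFrame, reference: str,
                          frame_offset: int = 0) -> pd.DataFrame:
    """Classify each biallelic SNP as synonymous or nonsynonymous.

    Both alleles are substituted into the reference codon and translated with
    the standard genetic code.  SNPs falling in an incomplete codon at the
    alignment edge are flagged and left unclassified.
    """
    rows = []
    for _, v in variants.iterrows():
        if v.get("multiallelic_flag", False):
            rows.append({"position": v["position"], "effect": "ambiguous",
                         "aa_change": ""})
            continue
        col = v["position"] - 1
        codon_index = (col - frame_offset) // 3
        start = frame_offset + 3 * codon_index
        if col < frame_offset or start + 3 > len(reference):
            rows.append({"position": v["position"], "effect": "incomplete_codon",
                         "aa_change": ""})
            continue
        offset = col - start
        a0, a1 = v["alleles"].split("/")
        codon = list(reference[start:start + 3].upper())
        aas = []
        for allele in (a0, a1):
            c = list(codon)
            c[offset] = allele
            aas.append(str(Seq("".join(c)).translate()))
        effect = "synonymous" if aas[0] == aas[1] else "nonsynonymous"
        rows.append({"position": v["position"], "effect": effect,
                     "aa_change": f"{aas[0]}->{aas[1]}"})
    return pd.DataFrame(rows, columns=["position", "effect", "aa_change"])
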