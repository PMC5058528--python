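"""Truth-known synthetic data emulating the two-host study design.

The generator produces the two inputs every downstream stage needs:

* a dominant (presence/absence) marker matrix for two host-associated fly
  populations sampled at several locations, with a small planted set of
  high-divergence outlier loci, optional sex-associated loci, and replicate
  re-genotypings with a known per-call miscall rate; and
* a diploid nuclear-locus alignment (IUPAC ambiguity codes for heterozygotes)
  drawn from host-specific haplotype pools with one near-fixed host-diagnostic
  SNP and host-asymmetric haplotype richness.

Population divergence follows the Balding-Nichols beta parameterization: a
locus with ancestral presence-allele frequency ``p0`` gives each population a
frequency ``p ~ Beta(p0(1-F)/F, (1-p0)(1-F)/F)``, so ``F`` is the expected
fixation index between populations.  This gives one-parameter control of FST
with closed-form expectations; no demography or forward selection is modelled
(outliers are simply loci with a larger between-host ``F``).

All randomness flows from ``SimConfig.seed`` through spawned NumPy generators,
so the same seed always yields byte-identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .containers import (
    IUPAC_HET,
    DiploidAlignment,
    MarkerMatrix,
    read_diploid_fasta,
    read_marker_tsv,
    write_diploid_fasta,
    write_marker_tsv,
)

_PRIMER_TAGS = ("P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8")


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the study conditions: 265 retained markers of which 15 are
    host-associated outliers, between-host fixation index 0.057 for neutral
    loci and 0.49 for outliers, a 5.5% per-call miscall rate estimated from six
    replicate pairs, and a 910-bp nuclear locus with 22 third-codon-position
    SNPs whose diagnostic site is nearly fixed between hosts (derived-allele
    frequency 0.007 in the ancestral-host flies, 0.8755 in the novel-host
    flies).  Haplotype pool sizes (36, 15) give the ancestral host roughly
    twice the haplotype richness of the novel host.
    """

    seed: int = 0
    n_locations: int = 3
    hosts: tuple = ("glabra", "coriacea")
    location_names: tuple | None = None
    n_per_group_per_location: int = 30
    n_neutral_loci: int = 250
    n_outlier_loci: int = 15
    n_sex_loci: int = 0
    background_fst: float = 0.057
    outlier_fst: float = 0.49
    sex_fst: float = 0.20
    location_fst: float = 0.02
    miscall_rate: float = 0.055
    n_replicate_pairs: int = 6
    seq_length: int = 910
    n_seq_snps: int = 22
    host_snp_freqs: tuple = (0.007, 0.8755)
    frame_offset: int = 0
    haplotype_pool_sizes: tuple = (36, 15)
    n_shared_haplotypes: int = 5
    size_range: tuple = (78, 792)

    def __post_init__(self):
        if len(self.hosts) != 2:
            raise ValueError("exactly two host groups are required")
        for name in ("background_fst", "outlier_fst", "sex_fst", "location_fst",
                     "miscall_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for f in self.host_snp_freqs:
            if not 0.0 <= f <= 1.0:
                raise ValueError("host_snp_freqs outside [0, 1]")
        if self.n_per_group_per_location < 2:
            raise ValueError("need at least 2 individuals per group per location "
                             "(FST undefined otherwise)")
        if self.n_outlier_loci > self.n_neutral_loci + self.n_outlier_loci:
            raise ValueError("n_outlier_loci exceeds total locus count")
        if self.n_seq_snps > self.seq_length // 3:
            raise ValueError("more SNPs requested than third-codon positions available")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        if self.location_names is None:
            base = ("NC", "SC", "eFL", "wFL", "GA", "VA", "DE", "NJ", "NY", "MD", "DEx")
            if self.n_locations > len(base):
                object.__setattr__(self, "location_names", tuple(
                    f"LOC{i}" for i in range(self.n_locations)))
            else:
                self.location_names = tuple(base[: self.n_locations])

    @property
    def n_loci(self) -> int:
        return self.n_neutral_loci + self.n_outlier_loci + self.n_sex_loci


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a synthetic fixture."""

    locus_class: dict = field(default_factory=dict)       # locus -> neutral|outlier|sex
    allele_freqs: dict = field(default_factory=dict)      # locus -> {pop_label: p_presence}
    miscall_rate: float = 0.0
    true_phases: dict = field(default_factory=dict)       # sample -> [seq_a, seq_b]
    haplotype_pools: dict = field(default_factory=dict)   # host -> {seq: freq}
    snp_positions: list = field(default_factory=list)     # pool-level, 1-based
    realized_snp_positions: list = field(default_factory=list)  # segregating in sample
    diagnostic_position: int | None = None                # 1-based
    diag_freqs: dict = field(default_factory=dict)        # host -> derived-allele freq

    def outlier_loci(self):
        return [l for l, c in self.locus_class.items() if c == "outlier"]

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _spawn(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(key + 1)[key])


def _balding_nichols(rng, p0, F, size):
    """Draw population frequencies around p0 with fixation index F."""
    if F <= 0.0:
        return np.broadcast_to(p0, size).copy()
    a = p0 * (1.0 - F) / F
    b = (1.0 - p0) * (1.0 - F) / F
    return rng.beta(a, b, size=size)


def _planted_outlier_freqs(rng, p0, F):
    """Frequency pair whose realized two-population fixation index equals F.

    Outliers are planted, not forward-simulated: an independent
    Balding-Nichols pair at high F often fails to realize any divergence, so
    instead the pair is constructed directly around a mid-range mean
    frequency with the separation that makes the two-population
    variance-component fixation index equal F:
    ``(p1-p2)^2/2 = F * pbar*(1-pbar) / (1 - F/2)``.  Which host gets the
    higher frequency is random.
    """
    if F <= 0.0:
        return np.array([p0, p0])
    pbar = float(p0)
    for _ in range(60):
        delta = np.sqrt(2.0 * F * pbar * (1.0 - pbar) / (1.0 - F / 2.0))
        lo, hi = pbar - delta / 2.0, pbar + delta / 2.0
        if lo >= 0.01 and hi <= 0.99:
            break
        pbar = np.clip(pbar, 0.02 + delta / 2.0, 0.98 - delta / 2.0)
    pair = np.array([pbar - delta / 2.0, pbar + delta / 2.0])
    if rng.random() < 0.5:
        pair = pair[::-1]
    return np.clip(pair, 0.005, 0.995)


def _sample_ids(config: SimConfig) -> pd.DataFrame:
    rows = []
    for host in config.hosts:
        for loc in config.location_names:
            for i in range(config.n_per_group_per_location):
                rows.append({"sample_id": f"{host[:3]}_{loc}_{i:03d}",
                             "host": host, "location": loc})
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_dominant_markers(config: SimConfig):
    """Simulate the marker matrix; returns ``(MarkerMatrix, TruthRecord)``.

    Band presence is sampled with probability ``1 - (1 - p)**2`` (presence
    allele dominant, absence homozygote silent, HWE within populations).
    Within-host location structure is drawn hierarchically at
    ``config.location_fst`` around each host-level frequency.
    """
    rng = _spawn(config.seed, 0)
    meta = _sample_ids(config)
    n_samples = len(meta)

    classes = (["neutral"] * config.n_neutral_loci
               + ["outlier"] * config.n_outlier_loci
               + ["sex"] * config.n_sex_loci)
    sizes = rng.integers(config.size_range[0], config.size_range[1] + 1,
                         size=config.n_loci)
    loci = [f"L{sizes[i]}_{i:03d}" for i in range(config.n_loci)]
    primers = [_PRIMER_TAGS[i % len(_PRIMER_TAGS)] for i in range(config.n_loci)]

    sex = rng.choice(["F", "M"], size=n_samples)
    year = rng.choice([2006, 2007], size=n_samples)

    truth = TruthRecord(miscall_rate=config.miscall_rate)
    calls = np.zeros((n_samples, config.n_loci), dtype=np.int8)

    host_idx = {h: (meta["host"] == h).to_numpy() for h in config.hosts}
    cell_idx = {(h, l): (host_idx[h] & (meta["location"] == l).to_numpy())
                for h in config.hosts for l in config.location_names}
    sex_idx = {s: (sex == s) for s in ("F", "M")}

    p0s = rng.uniform(0.05, 0.95, size=config.n_loci)
    for j, (locus, cls) in enumerate(zip(loci, classes)):
        p0 = p0s[j]
        truth.locus_class[locus] = cls
        freqs = {}
        if cls == "sex":
            # frequency differs by sex, not by host/location
            p_sex = _balding_nichols(rng, p0, config.sex_fst, 2)
            for s, p in zip(("F", "M"), p_sex):
                band_p = 1.0 - (1.0 - p) ** 2
                calls[sex_idx[s], j] = rng.random(sex_idx[s].sum()) < band_p
                freqs[f"sex:{s}"] = float(p)
        else:
            if cls == "outlier":
                p_host = _planted_outlier_freqs(rng, p0, config.outlier_fst)
            else:
                p_host = _balding_nichols(rng, p0, config.background_fst, 2)
            for h, ph in zip(config.hosts, p_host):
                p_loc = _balding_nichols(rng, np.clip(ph, 1e-9, 1 - 1e-9),
                                         config.location_fst, config.n_locations)
                for l, pl in zip(config.location_names, p_loc):
                    band_p = 1.0 - (1.0 - pl) ** 2
                    mask = cell_idx[(h, l)]
                    calls[mask, j] = rng.random(mask.sum()) < band_p
                    freqs[f"{h}:{l}"] = float(pl)
                freqs[h] = float(ph)
        truth.allele_freqs[locus] = freqs

    # replicate re-genotypings: same individual, each call flipped with miscall_rate
    rep_sources = rng.choice(meta.index.to_numpy(), size=config.n_replicate_pairs,
                             replace=False)
    rep_rows, rep_meta = [], []
    for sid in rep_sources:
        i = meta.index.get_loc(sid)
        flips = rng.random(config.n_loci) < config.miscall_rate
        rep_rows.append(np.where(flips, 1 - calls[i], calls[i]))
        rep_meta.append({"sample_id": f"{sid}_rep", "host": meta.at[sid, "host"],
                         "location": meta.at[sid, "location"], "replicate_of": sid})
    # primary calls get the same per-call miscall noise applied once
    noise = rng.random(calls.shape) < config.miscall_rate
    calls = np.where(noise, 1 - calls, calls).astype(np.int8)

    index = meta.index.append(pd.Index([r["sample_id"] for r in rep_meta]))
    all_calls = np.vstack([calls, np.array(rep_rows, dtype=np.int8).reshape(
        len(rep_rows), config.n_loci)]) if rep_rows else calls
    metadata = pd.DataFrame({
        "host": list(meta["host"]) + [r["host"] for r in rep_meta],
        "location": list(meta["location"]) + [r["location"] for r in rep_meta],
        "sex": list(sex) + [""] * len(rep_meta),
        "year": list(year) + [0] * len(rep_meta),
        "replicate_of": [""] * n_samples + [r["replicate_of"] for r in rep_meta],
    }, index=pd.Index(index, name="sample_id"))

    locus_info = pd.DataFrame({"size_bp": sizes, "primer": primers},
                              index=pd.Index(loci, name="locus"))
    matrix = MarkerMatrix(
        pd.DataFrame(all_calls, index=metadata.index, columns=loci),
        metadata, locus_info)
    return matrix, truth


# ---------------------------------------------------------------------------
# sequence locus
# ---------------------------------------------------------------------------

def _third_codon_positions(length: int, frame_offset: int) -> np.ndarray:
    """0-based columns that are third codon positions for complete codons."""
    pos = np.arange(frame_offset + 2, length, 3)
    return pos


def _grow_pool(rng, k, site_count, seed_haps):
    """Grow k distinct binary haplotypes by single/double-site toggles."""
    pool = [tuple(h) for h in seed_haps]
    seen = set(pool)
    guard = 0
    while len(pool) < k:
        guard += 1
        if guard > 10000:
            raise RuntimeError("could not grow a distinct haplotype pool")
        parent = list(pool[rng.integers(len(pool))])
        for s in rng.choice(site_count, size=int(rng.integers(1, 3)), replace=False):
            parent[s] ^= 1
        t = tuple(parent)
        if t not in seen:
            pool.append(t)
            seen.add(t)
    return pool


def _skewed_weights(k, top_mass, ratio=0.87):
    """One dominant haplotype at ~top_mass, a gentle geometric tail after it.

    The tail decays slowly enough that most pool members are realized in a
    few hundred sampled gene copies, so the observed haplotype count
    approaches the pool size at large n.
    """
    if k == 1:
        return np.ones(1)
    tail = ratio ** np.arange(k - 1)
    w = np.concatenate([[top_mass], (1.0 - top_mass) * tail / tail.sum()])
    return w / w.sum()


def _assign_diagnostic(pool_A, pool_B, w_A, w_B, targets):
    """Greedily pick which haplotypes carry the derived diagnostic allele.

    Minimizes the squared error between realized per-host derived-allele
    frequencies and the requested targets; shared haplotypes contribute to
    both hosts at once.  Deterministic.
    """
    haps = sorted(set(pool_A) | set(pool_B))
    wA = {h: 0.0 for h in haps}
    wB = {h: 0.0 for h in haps}
    for h, w in zip(pool_A, w_A):
        wA[h] += w
    for h, w in zip(pool_B, w_B):
        wB[h] += w
    derived = set()
    cur = np.zeros(2)
    tgt = np.asarray(targets, dtype=float)
    improved = True
    while improved:
        improved = False
        best, best_err = None, float(np.sum((cur - tgt) ** 2))
        for h in haps:
            if h in derived:
                continue
            trial = cur + np.array([wA[h], wB[h]])
            err = float(np.sum((trial - tgt) ** 2))
            if err < best_err - 1e-15:
                best, best_err = h, err
        if best is not None:
            derived.add(best)
            cur += np.array([wA[best], wB[best]])
            improved = True
    return derived


def simulate_sequences(config: SimConfig):
    """Simulate the diploid sequence locus; returns ``(DiploidAlignment, TruthRecord)``.

    Haplotypes are built on a tree-free mutation model: binary states at
    ``n_seq_snps`` third-codon-position sites grown by stepwise toggles from a
    root haplotype, one diagnostic site assigned derived/ancestral states so
    per-host derived-allele frequencies approximate ``host_snp_freqs``.  Each
    individual receives two haplotypes drawn i.i.d. from its host's pool and
    is emitted as an IUPAC-coded diploid consensus.
    """
    rng = _spawn(config.seed, 1)
    meta = _sample_ids(config)[["host", "location"]]

    third = _third_codon_positions(config.seq_length, config.frame_offset)
    snp_pos = np.sort(rng.choice(third, size=config.n_seq_snps, replace=False))
    diag_idx = int(rng.integers(config.n_seq_snps))

    backbone = rng.choice(list("ACGT"), size=config.seq_length)
    bases = "ACGT"
    derived_base = []
    for p in snp_pos:
        alt = [b for b in bases if b != backbone[p]]
        derived_base.append(alt[rng.integers(3)])

    kA, kB = config.haplotype_pool_sizes
    non_diag = [i for i in range(config.n_seq_snps) if i != diag_idx]
    root = tuple([0] * config.n_seq_snps)
    pool_A = _grow_pool(rng, kA, config.n_seq_snps, [root])
    # diag column will be overwritten below; grow B from shared A members
    n_shared = min(config.n_shared_haplotypes, kA, kB)
    shared = [pool_A[i] for i in range(n_shared)]
    seedB = shared if shared else [root]
    pool_B = _grow_pool(rng, kB, config.n_seq_snps, seedB)

    # strip the diagnostic site from the grown states, reassign it greedily
    def strip(h):
        h = list(h)
        h[diag_idx] = 0
        return tuple(h)
    pool_A = [strip(h) for h in pool_A]
    pool_B = [strip(h) for h in pool_B]
    # stripping can create duplicates; deduplicate preserving order
    def dedup(pool):
        seen, out = set(), []
        for h in pool:
            if h not in seen:
                seen.add(h)
                out.append(h)
        return out
    pool_A, pool_B = dedup(pool_A), dedup(pool_B)
    pool_A = _grow_pool(rng, kA, config.n_seq_snps, pool_A) if len(pool_A) < kA else pool_A
    pool_B = _grow_pool(rng, kB, config.n_seq_snps, pool_B) if len(pool_B) < kB else pool_B
    # re-strip in case regrowth touched the diagnostic site
    pool_A, pool_B = dedup([strip(h) for h in pool_A]), dedup([strip(h) for h in pool_B])

    # the novel host's common haplotypes are host-specific (the derived
    # cluster); shared (ancestral) haplotypes sit in its frequency tail
    shared_set = set(pool_A)
    pool_B = ([h for h in pool_B if h not in shared_set]
              + [h for h in pool_B if h in shared_set])

    # top-haplotype masses chosen so realized haplotype diversities sit near
    # the ancestral-host ~0.79 / novel-host ~0.49 asymmetry
    w_A = _skewed_weights(len(pool_A), top_mass=0.25)
    w_B = _skewed_weights(len(pool_B), top_mass=0.65)

    derived = _assign_diagnostic(pool_A, pool_B, w_A, w_B, config.host_snp_freqs)

    def finalize(h):
        h = list(h)
        h[diag_idx] = 1 if tuple(strip(h)) in derived else 0
        return tuple(h)
    pool_A = [finalize(h) for h in pool_A]
    pool_B = [finalize(h) for h in pool_B]

    def to_seq(state):
        s = backbone.copy()
        for i, (p, st) in enumerate(zip(snp_pos, state)):
            if st:
                s[p] = derived_base[i]
        return "".join(s)

    pools = {config.hosts[0]: (pool_A, w_A), config.hosts[1]: (pool_B, w_B)}
    truth = TruthRecord(miscall_rate=config.miscall_rate)
    truth.snp_positions = [int(p) + 1 for p in snp_pos]
    truth.diagnostic_position = int(snp_pos[diag_idx]) + 1
    for host, (pool, w) in pools.items():
        truth.haplotype_pools[host] = {to_seq(h): float(wi) for h, wi in zip(pool, w)}
        truth.diag_freqs[host] = float(sum(
            wi for h, wi in zip(pool, w) if h[diag_idx] == 1))

    seqs = {}
    sampled_states = []
    for sid, row in meta.iterrows():
        pool, w = pools[row["host"]]
        i, j = rng.choice(len(pool), size=2, p=w)
        sampled_states.extend([pool[i], pool[j]])
        a, b = to_seq(pool[i]), to_seq(pool[j])
        truth.true_phases[sid] = sorted([a, b])
        cons = [x if x == y else IUPAC_HET[frozenset((x, y))] for x, y in zip(a, b)]
        seqs[sid] = "".join(cons)
    states = np.array(sampled_states)
    truth.realized_snp_positions = [int(snp_pos[s]) + 1
                                    for s in range(config.n_seq_snps)
                                    if len(set(states[:, s])) > 1]

    aln = DiploidAlignment(pd.Series(seqs, index=meta.index), meta,
                           frame_offset=config.frame_offset)
    return aln, truth


def write_fixture_set(matrix: MarkerMatrix, alignment: DiploidAlignment,
                      truth: TruthRecord, directory) -> dict:
    """Write marker TSV, diploid FASTA and truth JSON; returns the paths.

    The files round-trip losslessly through :func:`read_marker_tsv` and
    :func:`read_diploid_fasta`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "markers": write_marker_tsv(matrix, directory / "markers.tsv"),
        "sequences": write_diploid_fasta(alignment, directory / "sequences.fasta"),
        "truth": truth.to_json(directory / "truth.json"),
    }
    return paths


def read_fixture_set(directory, frame_offset: int = 0) -> tuple:
    directory = Path(directory)
    return (read_marker_tsv(directory / "markers.tsv"),
            read_diploid_fasta(directory / "sequences.fasta", frame_offset=frame_offset),
            TruthRecord.from_json(directory / "truth.json"))
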