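"""Shared data containers and plain-text I/O.

The pipeline passes three kinds of data between stages:

* :class:`MarkerMatrix` -- individuals x dominant (presence/absence) loci with
  per-sample metadata and per-locus fragment sizes, plus a provenance log of
  filtering events.
* :class:`DiploidAlignment` -- aligned diploid consensus sequences of a single
  nuclear locus, heterozygous sites coded with two-base IUPAC ambiguity codes.
* :class:`HaplotypeSet` -- phased haplotypes with per-individual pairs and
  per-group counts.

File dialects are deliberately plain: the marker matrix is a TSV with metadata
columns followed by one 0/1 column per locus named ``L<size_bp>_<serial>``;
sequences are FASTA with headers ``<sample_id>|<host>|<location>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

METADATA_COLUMNS = ["host", "location", "sex", "year", "replicate_of"]

#: Scoring window for fragment sizes (bp); enforced when reading marker TSVs.
SIZE_WINDOW = (76, 800)

_LOCUS_RE = re.compile(r"^L(\d+)_(\S+)$")

IUPAC_HET = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
HET_TO_ALLELES = {code: tuple(sorted(pair)) for pair, code in IUPAC_HET.items()}
VALID_NUCLEOTIDES = set("ACGT") | set(HET_TO_ALLELES) | {"N", "-"}


class QCError(ValueError):
    """Raised when a QC step would produce a degenerate result."""


def parse_locus_id(locus_id: str) -> int:
    """Return the fragment size (bp) encoded in a ``L<size>_<serial>`` id."""
    m = _LOCUS_RE.match(locus_id)
    if m is None:
        raise ValueError(f"malformed locus id {locus_id!r}; expected 'L<size>_<serial>'")
    return int(m.group(1))


@dataclass
class MarkerMatrix:
    """Presence/absence calls for dominant markers plus sample metadata.

    Parameters
    ----------
    calls : DataFrame
        0/1 integers, index = sample ids, columns = locus ids.
    metadata : DataFrame
        One row per sample (same index as ``calls``) with columns
        ``host, location, sex, year, replicate_of``; ``replicate_of`` is the
        id of the original sample for re-genotyped replicates, else "".
    locus_info : DataFrame
        One row per locus with columns ``size_bp`` and ``primer``.
    log : list of dict
        Ordered filter events ``{rule, removed, retained}``.
    """

    calls: pd.DataFrame
    metadata: pd.DataFrame
    locus_info: pd.DataFrame
    log: list = field(default_factory=list)

    def __post_init__(self):
        if not self.calls.index.equals(self.metadata.index):
            raise ValueError("calls and metadata indexes differ")
        if not self.calls.columns.equals(self.locus_info.index):
            raise ValueError("calls columns and locus_info index differ")
        vals = self.calls.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("marker calls must be 0/1")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")

    # -- basic views ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def sizes(self) -> pd.Series:
        return self.locus_info["size_bp"]

    def is_replicate(self) -> pd.Series:
        rep = self.metadata["replicate_of"].fillna("")
        return rep.astype(str) != ""

    def primary(self) -> "MarkerMatrix":
        """Matrix restricted to non-replicate samples (analysis view)."""
        keep = ~self.is_replicate()
        return MarkerMatrix(self.calls.loc[keep], self.metadata.loc[keep],
                            self.locus_info, list(self.log))

    def replicate_pairs(self) -> list:
        """(original_id, replicate_id) links declared in the metadata."""
        pairs = []
        rep = self.metadata["replicate_of"].fillna("").astype(str)
        for rid, orig in rep.items():
            if orig:
                if orig not in self.calls.index:
                    raise ValueError(f"replicate {rid} points at unknown sample {orig}")
                pairs.append((orig, rid))
        return pairs

    def drop_loci(self, loci, rule: str) -> "MarkerMatrix":
        loci = [l for l in loci if l in self.calls.columns]
        keep = [c for c in self.calls.columns if c not in set(loci)]
        new_log = list(self.log) + [
            {"rule": rule, "initial": self.n_loci, "removed": len(loci),
             "retained": len(keep)}
        ]
        return MarkerMatrix(self.calls[keep], self.metadata,
                            self.locus_info.loc[keep], new_log)

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.log, columns=["rule", "initial", "removed", "retained"])


def write_marker_tsv(matrix: MarkerMatrix, path) -> Path:
    """Write the marker TSV dialect (plus a ``.loci.tsv`` primer sidecar)."""
    path = Path(path)
    out = pd.concat([matrix.metadata[METADATA_COLUMNS], matrix.calls], axis=1)
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False)
    side = matrix.locus_info.copy()
    side.insert(0, "locus", side.index)
    side.to_csv(path.with_suffix(path.suffix + ".loci.tsv"), sep="\t", index=False)
    return path


def read_marker_tsv(path, size_window=SIZE_WINDOW) -> MarkerMatrix:
    """Read a marker TSV, enforcing the fragment-size scoring window."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "replicate_of": str,
                                            "host": str, "location": str, "sex": str})
    missing = [c for c in ["sample_id", *METADATA_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"marker TSV {path} missing metadata column(s): {missing}")
    df = df.set_index("sample_id")
    meta = df[METADATA_COLUMNS].copy()
    meta["replicate_of"] = meta["replicate_of"].fillna("")
    locus_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    calls = df[locus_cols].astype(np.int8)

    sizes = {c: parse_locus_id(c) for c in locus_cols}
    side_path = path.with_suffix(path.suffix + ".loci.tsv")
    primer = {}
    if side_path.exists():
        side = pd.read_csv(side_path, sep="\t").set_index("locus")
        primer = side["primer"].to_dict()
    locus_info = pd.DataFrame({
        "size_bp": [sizes[c] for c in locus_cols],
        "primer": [primer.get(c, "P0") for c in locus_cols],
    }, index=pd.Index(locus_cols, name="locus"))

    lo, hi = size_window
    keep = [c for c in locus_cols if lo <= sizes[c] <= hi]
    m = MarkerMatrix(calls[keep], meta, locus_info.loc[keep])
    if len(keep) < len(locus_cols):
        m.log.append({"rule": "size_window", "initial": len(locus_cols),
                      "removed": len(locus_cols) - len(keep), "retained": len(keep)})
    return m


@dataclass
class DiploidAlignment:
    """Aligned IUPAC-coded diploid consensus sequences with sample metadata."""

    sequences: pd.Series          # sample_id -> str (uniform length)
    metadata: pd.DataFrame        # sample_id -> host, location
    frame_offset: int = 0         # 0-based alignment column where a codon starts

    def __post_init__(self):
        lens = {len(s) for s in self.sequences}
        if len(lens) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lens)}")
        if not self.sequences.index.equals(self.metadata.index):
            raise ValueError("sequence ids and metadata ids differ")
        for sid, seq in self.sequences.items():
            bad = [(i + 1, ch) for i, ch in enumerate(seq) if ch not in VALID_NUCLEOTIDES]
            if bad:
                pos, ch = bad[0]
                raise ValueError(f"non-IUPAC character {ch!r} at position {pos} in {sid}")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences)))

    @property
    def n_samples(self) -> int:
        return len(self.sequences)


def write_diploid_fasta(aln: DiploidAlignment, path) -> Path:
    path = Path(path)
    records = []
    for sid, seq in aln.sequences.items():
        host = aln.metadata.at[sid, "host"]
        loc = aln.metadata.at[sid, "location"]
        records.append(SeqRecord(Seq(seq), id=f"{sid}|{host}|{loc}", description=""))
    SeqIO.write(records, str(path), "fasta")
    return path


def read_diploid_fasta(path, frame_offset: int = 0) -> DiploidAlignment:
    seqs, hosts, locs, ids = [], [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"FASTA header {rec.id!r} not of the form '<sample_id>|<host>|<location>'")
        ids.append(parts[0]); hosts.append(parts[1]); locs.append(parts[2])
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise ValueError(f"no sequences in {path}")
    idx = pd.Index(ids, name="sample_id")
    return DiploidAlignment(
        pd.Series(seqs, index=idx),
        pd.DataFrame({"host": hosts, "location": locs}, index=idx),
        frame_offset=frame_offset,
    )


@dataclass
class HaplotypeSet:
    """Phased haplotypes for a diploid alignment.

    ``pairs`` maps each phased individual to an ordered pair of haplotype ids;
    individuals that failed the phasing-confidence threshold are absent from
    ``pairs`` and listed in ``unphased``.
    """

    haplotypes: dict              # hap_id -> full-length sequence (A/C/G/T)
    pairs: dict                   # sample_id -> (hap_id, hap_id)
    confidence: dict              # sample_id -> posterior prob of chosen pair
    metadata: pd.DataFrame        # all individuals (host, location)
    unphased: list = field(default_factory=list)

    def copies(self, group_by: str | None = None):
        """Haplotype ids of all phased gene copies, optionally per group."""
        if group_by is None:
            return [h for pair in self.pairs.values() for h in pair]
        out = {}
        for sid, pair in self.pairs.items():
            out.setdefault(self.metadata.at[sid, group_by], []).extend(pair)
        return out

    def group_counts(self, group_by: str = "host") -> pd.DataFrame:
        groups = self.copies(group_by)
        counts = {g: pd.Series(hs).value_counts() for g, hs in groups.items()}
        df = pd.DataFrame(counts).reindex(sorted(self.haplotypes)).fillna(0).astype(int)
        return df

    def consensus_of(self, sample_id: str) -> str:
        """IUPAC consensus implied by the individual's haplotype pair."""
        a, b = (self.haplotypes[h] for h in self.pairs[sample_id])
        out = []
        for x, y in zip(a, b):
            out.append(x if x == y else IUPAC_HET[frozenset((x, y))])
        return "".join(out)


def write_haplotype_fasta(haps: HaplotypeSet, path) -> Path:
    """Two records per phased individual, suffixed ``_a``/``_b``."""
    path = Path(path)
    records = []
    for sid, (h1, h2) in haps.pairs.items():
        host = haps.metadata.at[sid, "host"]
        loc = haps.metadata.at[sid, "location"]
        for suffix, h in (("_a", h1), ("_b", h2)):
            records.append(SeqRecord(Seq(haps.haplotypes[h]),
                                     id=f"{sid}{suffix}|{host}|{loc}",
                                     description=h))
    SeqIO.write(records, str(path), "fasta")
    return path
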