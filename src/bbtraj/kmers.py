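"""Annotation-free sample comparison via canonical k-mer profiles.

Each read set is reduced to counts of canonical k-mers (the
lexicographically smaller of a k-mer and its reverse complement), windows
containing non-ACGT symbols are skipped, and k-mers seen fewer than
``min_abundance`` times are dropped at finalization.  Sample pairs are then
compared with an abundance-weighted Bray-Curtis dissimilarity over the
union of their k-mer keys, after optionally equalizing read counts by
reservoir subsampling.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .composition import DistanceMatrix

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerProfile:
    k: int
    counts: dict[str, int] = field(default_factory=dict)
    n_reads_used: int = 0
    sample_id: str = ""

    def total(self) -> int:
        return sum(self.counts.values())


def _sniff_format(path: str) -> tuple[str, bool]:
    p = str(path)
    gz = p.endswith(".gz")
    stem = p[:-3] if gz else p
    if stem.endswith((".fq", ".fastq")):
        return "fastq", gz
    if stem.endswith((".fa", ".fasta", ".fna")):
        return "fasta", gz
    raise ValueError(f"cannot infer FASTA/FASTQ format from {path!r}")


def iter_reads(path) -> "list[str]":
    """Sequences (uppercased strings) from a FASTA/FASTQ file, .gz allowed."""
    fmt, gz = _sniff_format(path)
    opener = gzip.open if gz else open
    if not Path(path).exists():
        raise FileNotFoundError(path)
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield str(rec.seq).upper()


def count_canonical_kmers(reads, k: int = 21, min_abundance: int = 2,
                          sample_id: str = "") -> KmerProfile:
    """Canonical k-mer counts of a read set (path or iterable of strings)."""
    if k < 1 or k > 31:
        raise ValueError("k must lie in 1..31")
    if k % 2 == 0:
        logger.warning("even k=%d; odd k is the conventional choice", k)
    if isinstance(reads, (str, Path)):
        if not sample_id:
            sample_id = Path(str(reads)).name.split(".")[0]
        reads = iter_reads(reads)
    counts: dict[str, int] = {}
    n_reads = 0
    any_window = False
    for seq in reads:
        n_reads += 1
        for i in range(len(seq) - k + 1):
            window = seq[i:i + k]
            if not _VALID.issuperset(window):
                continue
            any_window = True
            key = canonical(window)
            counts[key] = counts.get(key, 0) + 1
    if n_reads == 0:
        raise ValueError("empty read set")
    if not any_window:
        logger.warning("no k-mer window of length %d found in %d reads",
                       k, n_reads)
    counts = {km: c for km, c in counts.items() if c >= min_abundance}
    return KmerProfile(k=k, counts=counts, n_reads_used=n_reads,
                       sample_id=sample_id)


def subsample_reads(reads, n_reads: int, seed: int | None = None) -> list[str]:
    """Uniform without-replacement reservoir sample of exactly ``n_reads``
    sequences (all of them if the set is smaller); seed-reproducible."""
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    if isinstance(reads, (str, Path)):
        reads = iter_reads(reads)
    rng = np.random.default_rng(seed)
    reservoir: list[str] = []
    for i, seq in enumerate(reads):
        if i < n_reads:
            reservoir.append(seq)
        else:
            j = int(rng.integers(0, i + 1))
            if j < n_reads:
                reservoir[j] = seq
    return reservoir


def kmer_bray_curtis(profiles: list[KmerProfile]) -> DistanceMatrix:
    """Abundance-weighted Bray-Curtis over the union key set of the
    profiles; identical profiles give 0, disjoint ones 1."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    ks = {p.k for p in profiles}
    if len(ks) > 1:
        raise ValueError(f"profiles mix k values {sorted(ks)}")
    ids = [p.sample_id or f"sample{i}" for i, p in enumerate(profiles)]
    if len(set(ids)) != len(ids):
        ids = [f"{s}_{i}" for i, s in enumerate(ids)]
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = profiles[i].counts, profiles[j].counts
            keys = set(a) | set(b)
            num = sum(abs(a.get(kk, 0) - b.get(kk, 0)) for kk in keys)
            den = sum(a.get(kk, 0) + b.get(kk, 0) for kk in keys)
            d[i, j] = d[j, i] = 0.0 if den == 0 else num / den
    return DistanceMatrix(d, ids=ids, metric="kmer-braycurtis")


def profile_to_tsv(profile: KmerProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("kmer\tcount\n")
        for km in sorted(profile.counts):
            fh.write(f"{km}\t{profile.counts[km]}\n")


def kmer_distance_pipeline(paths, k: int = 21, min_abundance: int = 2,
                           max_reads: int | None = None,
                           seed: int | None = None) -> DistanceMatrix:
    """Simka-style end-to-end run: equalize read counts across samples
    (default: the smallest sample's count), count canonical k-mers with the
    abundance filter, and return the Bray-Curtis matrix."""
    paths = list(paths)
    read_sets = [list(iter_reads(p)) for p in paths]
    if max_reads is None:
        max_reads = min(len(r) for r in read_sets)
    profiles = []
    for i, (p, rs) in enumerate(zip(paths, read_sets)):
        sub = subsample_reads(rs, max_reads,
                              seed=None if seed is None else seed + i)
        profiles.append(count_canonical_kmers(
            sub, k=k, min_abundance=min_abundance,
            sample_id=Path(str(p)).name.split(".")[0]))
    return kmer_bray_curtis(profiles)
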