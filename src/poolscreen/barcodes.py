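"""Design of chromosomal DNA barcodes and their padlock probes.

Barcodes are short DNA k-mers (30 nt by default) inserted next to each
library member's open reading frame and detected in situ via padlock
probes.  Candidate sequences are drawn uniformly at random and then
filtered on composition (GC content, homopolymer runs, terminal bases)
and on mutual dissimilarity: a barcode is retained only if its Hamming
distance to every *other* candidate in the dataset exceeds a floor,
which suppresses spurious cross-detection.

A padlock probe against a barcode is built by reverse-complementing the
target and splitting it in half: the two halves are the 5' and 3'
hybridisation arms, joined by a scaffold carrying the readout barcode
and RCA primer site.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DesignParams",
    "BarcodeSeq",
    "Padlock",
    "gc_fraction",
    "max_homopolymer_run",
    "hamming",
    "generate_candidates",
    "passes_composition",
    "select_barcodes",
    "design_padlock",
    "read_fasta",
    "write_fasta",
]

BASES = "ACGT"
_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class DesignParams:
    """Parameters of barcode generation and selection.

    ``min_pairwise_hamming`` is the smallest *allowed* distance, i.e. a
    strict "distance > 7" rule is expressed as ``min_pairwise_hamming=8``.
    ``allowed_end_bases`` constrains both the 5' and the 3' terminal base;
    the default {G, C} can be narrowed to {G} for stricter picks.
    """

    n_candidates: int = 10_000
    k: int = 30
    gc_min: float = 0.40
    gc_max: float = 0.60
    max_homopolymer: int = 3
    allowed_end_bases: frozenset[str] = frozenset({"G", "C"})
    min_pairwise_hamming: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise ValueError(f"need 0 <= gc_min <= gc_max <= 1, got ({self.gc_min}, {self.gc_max})")
        if not (1 <= self.max_homopolymer <= self.k):
            raise ValueError("max_homopolymer must be in [1, k]")
        if self.min_pairwise_hamming > self.k:
            raise ValueError("min_pairwise_hamming cannot exceed k")
        if self.n_candidates < 0 or self.k <= 0:
            raise ValueError("n_candidates must be >= 0 and k > 0")
        bad = set(self.allowed_end_bases) - set(BASES)
        if bad:
            raise ValueError(f"allowed_end_bases outside ACGT: {bad}")
        # frozen dataclass: normalise via object.__setattr__
        object.__setattr__(self, "allowed_end_bases", frozenset(self.allowed_end_bases))


@dataclass(frozen=True)
class BarcodeSeq:
    """A named DNA barcode sequence (uppercase, ACGT only)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        _check_acgt(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Padlock:
    """A padlock probe: 5' arm + scaffold + 3' arm, all 5'->3'."""

    target_id: str
    arm5: str
    scaffold: str
    arm3: str

    @property
    def seq(self) -> str:
        return self.arm5 + self.scaffold + self.arm3


def _check_acgt(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set(BASES):
        raise ValueError(f"sequence contains non-ACGT characters: {set(seq) - set(BASES)}")


def gc_fraction(seq: str) -> float:
    """Fraction of G+C bases. Rejects ambiguity codes."""
    _check_acgt(seq)
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-base run."""
    if not seq:
        raise ValueError("empty sequence")
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        if run > best:
            best = run
    return best


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def generate_candidates(params: DesignParams) -> list[BarcodeSeq]:
    """Draw ``n_candidates`` i.i.d. uniform-base k-mers (seeded)."""
    rng = np.random.default_rng(params.seed)
    idx = rng.integers(0, 4, size=(params.n_candidates, params.k))
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    seqs = lut[idx].tobytes().decode()
    return [
        BarcodeSeq(id=f"bc{i:05d}", seq=seqs[i * params.k : (i + 1) * params.k])
        for i in range(params.n_candidates)
    ]


def passes_composition(seq: str, params: DesignParams) -> bool:
    """Composition predicates: GC window, homopolymer cap, end bases."""
    return (
        params.gc_min <= gc_fraction(seq) <= params.gc_max
        and max_homopolymer_run(seq) <= params.max_homopolymer
        and seq[0] in params.allowed_end_bases
        and seq[-1] in params.allowed_end_bases
    )


def _encode(seqs: Sequence[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


def select_barcodes(
    candidates: Sequence[BarcodeSeq], params: DesignParams
) -> list[BarcodeSeq]:
    """Filter candidates on composition and all-against-all distance.

    The distance criterion is evaluated against every *other* sequence in
    the input dataset (not merely within the returned set): a candidate
    survives only if ``hamming >= min_pairwise_hamming`` to all others.
    Consequently two identical candidates eliminate each other, and the
    filter is idempotent on its own output.
    """
    if not candidates:
        return []
    k = len(candidates[0])
    if any(len(c) != k for c in candidates):
        raise ValueError("candidates must all have equal length")
    enc = _encode([c.seq for c in candidates])
    n = len(candidates)
    ok_dist = np.ones(n, dtype=bool)
    # chunked all-pairs Hamming; O(n^2 k) bytes handled in stripes
    chunk = max(1, 64_000_000 // (n * k))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d = (enc[lo:hi, None, :] != enc[None, :, :]).sum(axis=2)
        d[np.arange(lo, hi) - lo, np.arange(lo, hi)] = params.k  # self
        ok_dist[lo:hi] &= d.min(axis=1) >= params.min_pairwise_hamming
    return [
        c
        for c, ok in zip(candidates, ok_dist)
        if ok and passes_composition(c.seq, params)
    ]


def design_padlock(target: BarcodeSeq, scaffold: str = "") -> Padlock:
    """Build a padlock probe for ``target``.

    The target is reverse-complemented and split in half; the first half
    of the reverse complement is taken as the 5' arm, the second half as
    the 3' arm (a documented convention). Concatenating the two arms
    reconstructs the full reverse complement of the target.
    """
    if len(target) % 2 != 0:
        raise ValueError(f"target length must be even, got {len(target)}")
    if scaffold:
        _check_acgt(scaffold)
    rc = str(Seq(target.seq).reverse_complement())
    half = len(rc) // 2
    return Padlock(target_id=target.id, arm5=rc[:half], scaffold=scaffold, arm3=rc[half:])


def read_fasta(path: str | Path) -> list[BarcodeSeq]:
    return [BarcodeSeq(id=rec.id, seq=str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[BarcodeSeq | Padlock], path: str | Path) -> None:
    records = []
    for s in seqs:
        if isinstance(s, Padlock):
            desc = f"arm5=1..{len(s.arm5)} scaffold={len(s.arm5)+1}..{len(s.arm5)+len(s.scaffold)} arm3={len(s.arm5)+len(s.scaffold)+1}..{len(s.seq)}"
            records.append(SeqRecord(Seq(s.seq), id=f"plp_{s.target_id}", description=desc))
        else:
            records.append(SeqRecord(Seq(s.seq), id=s.id, description=""))
    SeqIO.write(records, str(path), "fasta")
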