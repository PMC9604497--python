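"""Quality filtering and bisulfite-aware alignment to the amplicon.

Bisulfite conversion collapses the alphabet asymmetrically: reads from the
original-top (OT) strand space show unmethylated C as T, reads from the
original-bottom (OB) space show the mirrored G-to-A change when projected on
the plus strand.  Alignment therefore happens in a *collapsed* alphabet —
both read and reference have C collapsed to T (OT) or G collapsed to A (OB)
— so that conversion events never count as mismatches, while the original
read bases are preserved for methylation and SNP calling.

Two alignment engines are exposed behind one interface: ``edlib`` (default;
fast edit-distance path, appropriate for substitution-dominated amplicon
reads) and ``affine`` (Biopython global aligner with configurable
match/mismatch/gap scores, default +1/-1/-3/-1, where a gap of length L
scores open + (L-1)*extend).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .reference import AmpliconReference

__all__ = [
    "FastqRead",
    "AlignScores",
    "AlignedRead",
    "read_fastq",
    "write_fastq",
    "quality_filter",
    "collapse",
    "classify_strand_space",
    "align_read",
    "align_reads",
]

PHRED_OFFSET = 33


@dataclass
class FastqRead:
    id: str
    seq: str
    quals: np.ndarray  # Phred scores per base

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.quals)) if len(self.quals) else 0.0


def read_fastq(path) -> list[FastqRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            FastqRead(
                id=rec.id,
                seq=str(rec.seq),
                quals=np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16),
            )
        )
    return reads


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(int(q) + PHRED_OFFSET) for q in r.quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


@dataclass
class FilterStats:
    retained: int
    discarded: int


def quality_filter(reads, min_q: float = 30.0):
    """Retain reads whose mean Phred quality is >= ``min_q``.

    Returns (kept_reads, FilterStats).
    """
    if not reads:
        warnings.warn("quality_filter: empty input")
        return [], FilterStats(0, 0)
    kept = [r for r in reads if r.mean_quality >= min_q]
    return kept, FilterStats(len(kept), len(reads) - len(kept))


def collapse(seq: str, space: str) -> str:
    """Collapse the bisulfite-ambiguous base for the given strand space."""
    if space == "OT":
        return seq.replace("C", "T")
    if space == "OB":
        return seq.replace("G", "A")
    raise ValueError(f"unknown strand space {space!r}")


def classify_strand_space(read: FastqRead, reference: AmpliconReference,
                          identity_floor: float = 0.8):
    """Label a read OT or OB by reduced-alphabet mismatch count.

    Returns (space, identity); space is None (unalignable) on a tie or when
    the best identity falls below ``identity_floor``.
    """
    dists = {}
    for space in ("OT", "OB"):
        res = edlib.align(collapse(read.seq, space), collapse(reference.seq, space),
                          mode="NW", task="distance")
        dists[space] = res["editDistance"]
    best = min(dists, key=dists.get)
    identity = 1.0 - dists[best] / max(len(read.seq), reference.length)
    if dists["OT"] == dists["OB"] or identity < identity_floor:
        return None, identity
    return best, identity


@dataclass
class AlignScores:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -3.0
    gap_extend: float = -1.0


@dataclass
class AlignedRead:
    read_id: str
    strand_space: str
    seq: str  # original (uncollapsed) read sequence
    ref_to_read: np.ndarray  # amplicon offset -> read index, -1 where unaligned
    mismatches: list = field(default_factory=list)  # (coord, ref base, read base), collapsed space
    mean_quality: float = 0.0
    identity: float = 0.0
    score: float = 0.0

    def read_base(self, coord: int, start: int) -> str | None:
        """Original read base aligned to a 1-based genomic coordinate."""
        idx = self.ref_to_read[coord - start]
        return self.seq[idx] if idx >= 0 else None


class AlignmentRejected(Exception):
    def __init__(self, read_id, reason):
        self.read_id, self.reason = read_id, reason
        super().__init__(f"{read_id}: {reason}")


def _cigar_to_map(cigar: str, ref_len: int, read_len: int):
    """Build ref->read index map and aligned column list from an edlib
    extended CIGAR (query = read, target = reference)."""
    ref_to_read = np.full(ref_len, -1, dtype=np.int64)
    ri = ti = 0
    num = ""
    cols = []  # (ref_idx, read_idx) aligned columns
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        L = int(num)
        num = ""
        if ch in "=X M":
            for _ in range(L):
                ref_to_read[ti] = ri
                cols.append((ti, ri))
                ti += 1
                ri += 1
        elif ch == "I":  # insertion in read
            ri += L
        elif ch == "D":  # deletion from reference
            ti += L
    return ref_to_read, cols


def _edlib_align(read_c: str, ref_c: str):
    res = edlib.align(read_c, ref_c, mode="NW", task="path")
    ref_to_read, cols = _cigar_to_map(res["cigar"], len(ref_c), len(read_c))
    return ref_to_read, cols, -float(res["editDistance"])


def _affine_align(read_c: str, ref_c: str, scores: AlignScores):
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scores.match
    aligner.mismatch_score = scores.mismatch
    aligner.open_gap_score = scores.gap_open
    aligner.extend_gap_score = scores.gap_extend
    aln = aligner.align(ref_c, read_c)[0]
    ref_to_read = np.full(len(ref_c), -1, dtype=np.int64)
    cols = []
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            ref_to_read[t0 + k] = q0 + k
            cols.append((t0 + k, q0 + k))
    return ref_to_read, cols, float(aln.score)


def align_read(
    read: FastqRead,
    reference: AmpliconReference,
    strand_space: str,
    engine: str = "edlib",
    scores: AlignScores | None = None,
    identity_floor: float = 0.8,
    min_length_frac: float = 0.5,
) -> AlignedRead:
    """Global alignment of one read in the collapsed alphabet of its space.

    Raises :class:`AlignmentRejected` for reads shorter than
    ``min_length_frac`` of the amplicon or below the identity floor.
    """
    if len(read.seq) < min_length_frac * reference.length:
        raise AlignmentRejected(read.id, "read shorter than half the amplicon")
    ref_c = collapse(reference.seq, strand_space)
    read_c = collapse(read.seq, strand_space)
    if engine == "edlib":
        ref_to_read, cols, score = _edlib_align(read_c, ref_c)
    elif engine == "affine":
        ref_to_read, cols, score = _affine_align(read_c, ref_c, scores or AlignScores())
    else:
        raise ValueError(f"unknown engine {engine!r}")
    mismatches = []
    matches = 0
    for ti, ri in cols:
        if ref_c[ti] == read_c[ri]:
            matches += 1
        else:
            mismatches.append((reference.start + ti, ref_c[ti], read_c[ri]))
    # normalise by the longer sequence so gaps also depress identity
    identity = matches / max(len(read_c), len(ref_c))
    if identity < identity_floor:
        raise AlignmentRejected(read.id, f"identity {identity:.3f} below floor")
    return AlignedRead(
        read_id=read.id,
        strand_space=strand_space,
        seq=read.seq,
        ref_to_read=ref_to_read,
        mismatches=mismatches,
        mean_quality=read.mean_quality,
        identity=identity,
        score=score,
    )


def align_reads(reads, reference: AmpliconReference, engine: str = "edlib",
                identity_floor: float = 0.8, **kwargs):
    """Classify and align a batch; returns (aligned list, rejection list)."""
    aligned, rejected = [], []
    for r in reads:
        space, ident = classify_strand_space(r, reference, identity_floor)
        if space is None:
            rejected.append((r.id, f"unalignable (identity {ident:.3f} or tie)"))
            continue
        try:
            aligned.append(
                align_read(r, reference, space, engine=engine,
                           identity_floor=identity_floor, **kwargs)
            )
        except AlignmentRejected as e:
            rejected.append((e.read_id, e.reason))
    return aligned, rejected
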