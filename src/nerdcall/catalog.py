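"""Indel normalization and ID-83 catalog construction.

A VCF indel record can represent the same physical event many ways
(different anchor placements within a repeat tract).  Every indel is
therefore brought into a canonical form first — anchor bases stripped,
then left-aligned by repeated unit shifting — and only then classified
into one of the 83 channels.  Context counting (homopolymer run length,
tandem repeat copies, microhomology) always scans rightward from the
left-aligned start, which together with left-alignment makes the
classification representation-independent.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .channels import (
    DELETION,
    ID83_LABELS,
    INSERTION,
    MICROHOMOLOGY,
    PYRIMIDINE,
    REPEAT,
    ChannelId,
)
from .errors import DataError, UnclassifiableIndelError
from .variants import VariantRecord


class ReferenceGenome:
    """0-based, half-open access to reference contigs.

    Accepts either a path to an indexed FASTA (random access via pyfaidx)
    or an in-memory mapping ``{contig: sequence}`` as produced by the
    simulator.  An unknown contig is a :class:`DataError`: silently
    skipping variants on missing contigs would corrupt catalogs.
    """

    def __init__(self, source: str | Path | Mapping[str, str]):
        if isinstance(source, (str, Path)):
            import pyfaidx

            self._fasta = pyfaidx.Fasta(
                str(source), as_raw=True, sequence_always_upper=True
            )
            self._mem: Mapping[str, str] | None = None
            self._lengths = {name: len(rec) for name, rec in self._fasta.items()}
        elif isinstance(source, Mapping):
            self._fasta = None
            self._mem = {name: seq.upper() for name, seq in source.items()}
            self._lengths = {name: len(seq) for name, seq in self._mem.items()}
        else:
            raise TypeError("source must be a FASTA path or a contig mapping")

    @property
    def contigs(self) -> tuple[str, ...]:
        return tuple(self._lengths)

    def length(self, chrom: str) -> int:
        self._check(chrom)
        return self._lengths[chrom]

    def _check(self, chrom: str) -> None:
        if chrom not in self._lengths:
            raise DataError(f"contig {chrom!r} absent from the reference")

    def seq(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``[start, end)``, clipped to the contig bounds."""
        self._check(chrom)
        start = max(start, 0)
        end = min(end, self._lengths[chrom])
        if end <= start:
            return ""
        if self._mem is not None:
            return self._mem[chrom][start:end]
        return str(self._fasta[chrom][start:end])

    def base(self, chrom: str, pos: int) -> str:
        """Single base at 0-based ``pos``; empty string out of range."""
        return self.seq(chrom, pos, pos + 1)


@dataclass(frozen=True)
class NormalizedIndel:
    """A pure insertion or deletion in canonical (left-aligned) form.

    ``start`` is the 0-based position of the first inserted/deleted base;
    ``seq`` the inserted or deleted bases, uppercase.
    """

    chrom: str
    start: int
    seq: str
    kind: str  # "insertion" | "deletion"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("indel sequence must be nonempty")
        if self.start < 0:
            raise ValueError("indel start must be >= 0")
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"unknown indel kind {self.kind!r}")


def normalize_indel(v: VariantRecord, ref_genome: ReferenceGenome) -> NormalizedIndel:
    """Canonicalize a VCF indel: strip anchors, verify the reference, left-align.

    Raises
    ------
    DataError
        If the record's REF allele disagrees with the reference genome.
    UnclassifiableIndelError
        For complex substitutions (both alleles nonempty after anchor
        stripping) — these fit no ID-83 channel.
    """
    ref = v.ref.upper()
    alt = v.alt.upper()
    if len(ref) == len(alt):
        raise UnclassifiableIndelError(
            f"{v.chrom}:{v.pos} {ref}>{alt} is not a length-changing variant"
        )
    pos0 = v.pos - 1
    genome_ref = ref_genome.seq(v.chrom, pos0, pos0 + len(ref))
    if genome_ref != ref:
        raise DataError(
            f"REF mismatch at {v.chrom}:{v.pos}: VCF has {ref!r}, "
            f"reference has {genome_ref!r}"
        )
    # strip shared prefix (anchor), then shared suffix
    p = 0
    while p < min(len(ref), len(alt)) and ref[p] == alt[p]:
        p += 1
    ref_t, alt_t = ref[p:], alt[p:]
    s = 0
    while s < min(len(ref_t), len(alt_t)) and ref_t[len(ref_t) - 1 - s] == alt_t[len(alt_t) - 1 - s]:
        s += 1
    if s:
        ref_t, alt_t = ref_t[: len(ref_t) - s], alt_t[: len(alt_t) - s]
    if ref_t and alt_t:
        raise UnclassifiableIndelError(
            f"{v.chrom}:{v.pos} {ref}>{alt} is a complex substitution"
        )
    start = pos0 + p
    if ref_t:
        kind, seq = "deletion", ref_t
    else:
        kind, seq = "insertion", alt_t
    # left-align: shift by one base while the base before the locus equals
    # the last indel base (standard unit rotation)
    while start > 0:
        prev = ref_genome.base(v.chrom, start - 1)
        if prev != seq[-1]:
            break
        seq = prev + seq[:-1]
        start -= 1
    return NormalizedIndel(v.chrom, start, seq, kind)


def homopolymer_length(n: NormalizedIndel, ref_genome: ReferenceGenome) -> int:
    """Homopolymer run length at a 1 bp indel locus.

    Deletions: run length of the deleted base in the reference, including
    the deleted base itself.  Insertions: run length of the inserted base
    in the reference adjacent to (rightward of) the insertion point, not
    counting the inserted base.  The locus is left-aligned, so the run
    extends only rightward.
    """
    if len(n.seq) != 1:
        raise ValueError("homopolymer context is defined for 1 bp indels only")
    base = n.seq
    run = 0
    pos = n.start
    while ref_genome.base(n.chrom, pos) == base:
        run += 1
        pos += 1
    return run


def repeat_unit_count(n: NormalizedIndel, ref_genome: ReferenceGenome) -> int:
    """Number of exact tandem copies of the indel sequence at the locus.

    Copies are counted contiguously rightward from the left-aligned
    start.  For deletions the deleted copy itself is included (count is
    >= 1); for insertions only pre-existing copies count (may be 0).
    """
    if len(n.seq) < 2:
        raise ValueError("repeat context is defined for >=2 bp indels only")
    unit = n.seq
    size = len(unit)
    count = 0
    pos = n.start
    while ref_genome.seq(n.chrom, pos, pos + size) == unit:
        count += 1
        pos += size
    return count


def microhomology_length(n: NormalizedIndel, ref_genome: ReferenceGenome) -> int:
    """Length of partial homology between a deletion and its flanks.

    Right flank: the longest k < len(seq) such that the first k deleted
    bases equal the k reference bases immediately after the deleted
    segment.  Left flank: the symmetric match of the deletion's last k
    bases against the reference immediately before the start.  Returns
    the larger of the two; a full extra copy is a repeat, not
    microhomology, hence the k < len(seq) cap.
    """
    if n.kind != "deletion" or len(n.seq) < 2:
        raise ValueError("microhomology is defined for >=2 bp deletions only")
    seq = n.seq
    size = len(seq)
    right = 0
    for k in range(1, size):
        if ref_genome.seq(n.chrom, n.start + size, n.start + size + k) == seq[:k]:
            right = k
        else:
            break
    left = 0
    for k in range(1, size):
        if n.start - k < 0:
            break
        if ref_genome.seq(n.chrom, n.start - k, n.start) == seq[size - k :]:
            left = k
        else:
            break
    return max(right, left)


def assign_channel(n: NormalizedIndel, ref_genome: ReferenceGenome) -> ChannelId:
    """Classify a normalized indel into its ID-83 channel.

    1 bp indels go to homopolymer channels with the base expressed as its
    pyrimidine representative.  Longer indels go to repeat channels when
    tandem copies exist (deletions need >= 2 copies, insertions >= 1),
    to microhomology channels for single-copy deletions with flank
    homology, and single-copy deletions without homology fall back to the
    repeat channel with the lowest count bin.  Counts saturate at the top
    display bin.
    """
    size = len(n.seq)
    if size == 1:
        pyr = PYRIMIDINE.get(n.seq)
        if pyr is None:
            raise UnclassifiableIndelError(f"non-ACGT indel base {n.seq!r}")
        ctx = f"homopolymer_{pyr}"
        h = homopolymer_length(n, ref_genome)
        if n.kind == "deletion":
            return ChannelId(DELETION, "1", ctx, str(h) if h <= 5 else "6+")
        return ChannelId(INSERTION, "1", ctx, str(h) if h <= 4 else "5+")
    if not set(n.seq) <= {"A", "C", "G", "T"}:
        raise UnclassifiableIndelError(f"non-ACGT indel sequence {n.seq!r}")
    size_bin = str(size) if size <= 4 else "5+"
    if n.kind == "insertion":
        r = repeat_unit_count(n, ref_genome)
        return ChannelId(INSERTION, size_bin, REPEAT, str(r) if r <= 4 else "5+")
    r = repeat_unit_count(n, ref_genome)
    if r >= 2:
        return ChannelId(DELETION, size_bin, REPEAT, str(r) if r <= 5 else "6+")
    mh = microhomology_length(n, ref_genome)
    if mh >= 1:
        mh = min(mh, size - 1)
        if size_bin == "5+":
            count = str(mh) if mh <= 4 else "5+"
        else:
            count = str(min(mh, size - 1))
        return ChannelId(DELETION, size_bin, MICROHOMOLOGY, count)
    return ChannelId(DELETION, size_bin, REPEAT, "1")


def classify_variant(v: VariantRecord, ref_genome: ReferenceGenome) -> ChannelId:
    """Normalize and classify one VCF indel record in a single call."""
    return assign_channel(normalize_indel(v, ref_genome), ref_genome)


class IndelCatalogEncoder(BaseEstimator, TransformerMixin):
    """Transformer turning filtered variant records into ID-83 catalogs.

    Parameters
    ----------
    reference:
        FASTA path, contig mapping, or :class:`ReferenceGenome`.

    Attributes
    ----------
    channels_ : list of str
        The 83 channel labels, in canonical order (set by :meth:`fit`).
    unclassified_counts_ : dict
        Per-sample counts of complex indels skipped by the last
        :meth:`transform` call.
    """

    def __init__(self, reference=None):
        self.reference = reference

    def fit(self, X=None, y=None):
        if self.reference is None:
            raise DataError("IndelCatalogEncoder requires a reference genome")
        self._genome = (
            self.reference
            if isinstance(self.reference, ReferenceGenome)
            else ReferenceGenome(self.reference)
        )
        self.channels_ = list(ID83_LABELS)
        return self

    def transform(self, X: Mapping[str, Iterable[VariantRecord]]) -> pd.DataFrame:
        """Build one 83-channel count row per sample.

        ``X`` maps sample ids to their (already filtered) variant
        records.  SNVs and other length-preserving variants are ignored;
        complex indels are counted in ``unclassified_counts_``.
        """
        if not hasattr(self, "channels_"):
            self.fit()
        rows = {}
        unclassified = {}
        for sample_id in X:
            counts = np.zeros(83, dtype=np.int64)
            n_bad = 0
            for v in X[sample_id]:
                if len(v.ref) == len(v.alt):
                    continue  # SNV / MNV: not part of the indel catalog
                try:
                    chan = classify_variant(v, self._genome)
                except UnclassifiableIndelError:
                    n_bad += 1
                    continue
                counts[LABEL_TO_INDEX[chan.label]] += 1
            rows[sample_id] = counts
            unclassified[sample_id] = n_bad
        self.unclassified_counts_ = unclassified
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=list(ID83_LABELS)
        ).rename_axis("sample_id")


LABEL_TO_INDEX = {lab: i for i, lab in enumerate(ID83_LABELS)}


def build_catalog(
    records: Mapping[str, Iterable[VariantRecord]],
    ref_genome: ReferenceGenome | str | Path | Mapping[str, str],
) -> pd.DataFrame:
    """Per-sample ID-83 catalogs (samples x 83 counts) from filtered records."""
    enc = IndelCatalogEncoder(reference=ref_genome).fit()
    return enc.transform(records)
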