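"""The 83-channel COSMIC indel (ID-83) classification scheme.

Small insertions and deletions are binned by

* indel size (1, 2, 3, 4, "5+");
* for 1 bp events, the base (expressed on the pyrimidine strand, so A/T
  runs are ``T`` channels and C/G runs are ``C`` channels) and the length
  of the homopolymer run they sit in;
* for >=2 bp events, the number of tandem copies of the indel sequence at
  the locus;
* for >=2 bp deletions at non-repetitive loci, the length of the
  microhomology shared between the deleted sequence and its flanks.

Channel identity is stored with *display* semantics (e.g. a 1 bp deletion
in a homopolymer of length 1..5 or "6+"); the equivalent zero-based
labels used by signature-matrix files ("1:Del:C:0" ... "5:Del:M:5") are
exposed via :attr:`ChannelId.label` and :meth:`ChannelId.from_label`.
The module-level ``ID83_CHANNELS`` tuple fixes the canonical row order
used for every catalog and signature matrix in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import FormatError

DELETION = "Del"
INSERTION = "Ins"

HOMOPOLYMER_C = "homopolymer_C"
HOMOPOLYMER_T = "homopolymer_T"
REPEAT = "repeat"
MICROHOMOLOGY = "microhomology"

#: pyrimidine-strand representative for each base
PYRIMIDINE = {"A": "T", "G": "C", "C": "C", "T": "T"}


@dataclass(frozen=True)
class ChannelId:
    """One of the 83 indel channels, stored with display semantics.

    Parameters
    ----------
    kind:
        ``"Del"`` or ``"Ins"``.
    length_bin:
        Indel size bin: ``"1"``, ``"2"``, ``"3"``, ``"4"`` or ``"5+"``.
    context:
        ``"homopolymer_C"``/``"homopolymer_T"`` (1 bp events), ``"repeat"``
        or ``"microhomology"`` (>=2 bp events).
    count_bin:
        Context count as displayed: homopolymer run length (deletions
        ``"1"``..``"6+"``, insertions ``"0"``..``"5+"``), tandem repeat
        copies (deletions count the deleted copy, ``"1"``..``"6+"``;
        insertions count pre-existing copies, ``"0"``..``"5+"``), or
        microhomology length (``"1"``..``"5+"``, capped at size - 1).
    """

    kind: str
    length_bin: str
    context: str
    count_bin: str

    @property
    def label(self) -> str:
        """Zero-based signature-file label, e.g. ``"1:Del:C:0"``."""
        size = "5" if self.length_bin == "5+" else self.length_bin
        if self.context in (HOMOPOLYMER_C, HOMOPOLYMER_T):
            base = self.context[-1]
            if self.kind == DELETION:
                n = 5 if self.count_bin == "6+" else int(self.count_bin) - 1
            else:
                n = 5 if self.count_bin == "5+" else int(self.count_bin)
            return f"1:{self.kind}:{base}:{n}"
        if self.context == REPEAT:
            if self.kind == DELETION:
                n = 5 if self.count_bin == "6+" else int(self.count_bin) - 1
            else:
                n = 5 if self.count_bin == "5+" else int(self.count_bin)
            return f"{size}:{self.kind}:R:{n}"
        n = 5 if self.count_bin == "5+" else int(self.count_bin)
        return f"{size}:Del:M:{n}"

    @classmethod
    def from_label(cls, label: str) -> "ChannelId":
        """Parse a zero-based label back into a :class:`ChannelId`."""
        try:
            size_s, kind, ctx, n_s = label.strip().split(":")
            n = int(n_s)
        except ValueError as exc:
            raise FormatError(f"malformed ID-83 channel label {label!r}") from exc
        length_bin = "5+" if size_s == "5" else size_s
        if ctx in ("C", "T"):
            if size_s != "1" or kind not in (DELETION, INSERTION):
                raise FormatError(f"invalid homopolymer channel label {label!r}")
            if kind == DELETION:
                count = "6+" if n >= 5 else str(n + 1)
            else:
                count = "5+" if n >= 5 else str(n)
            chan = cls(kind, "1", f"homopolymer_{ctx}", count)
        elif ctx == "R":
            if kind == DELETION:
                count = "6+" if n >= 5 else str(n + 1)
            else:
                count = "5+" if n >= 5 else str(n)
            chan = cls(kind, length_bin, REPEAT, count)
        elif ctx == "M":
            if kind != DELETION:
                raise FormatError(f"microhomology channels are deletions: {label!r}")
            count = "5+" if n >= 5 else str(n)
            chan = cls(DELETION, length_bin, MICROHOMOLOGY, count)
        else:
            raise FormatError(f"unknown context in channel label {label!r}")
        if chan not in CHANNEL_INDEX:
            raise FormatError(f"{label!r} is not one of the 83 indel channels")
        return chan


def _build_channels() -> tuple[ChannelId, ...]:
    chans: list[ChannelId] = []
    for base_ctx in (HOMOPOLYMER_C, HOMOPOLYMER_T):
        for h in ("1", "2", "3", "4", "5", "6+"):
            chans.append(ChannelId(DELETION, "1", base_ctx, h))
    for base_ctx in (HOMOPOLYMER_C, HOMOPOLYMER_T):
        for h in ("0", "1", "2", "3", "4", "5+"):
            chans.append(ChannelId(INSERTION, "1", base_ctx, h))
    for size in ("2", "3", "4", "5+"):
        for r in ("1", "2", "3", "4", "5", "6+"):
            chans.append(ChannelId(DELETION, size, REPEAT, r))
    for size in ("2", "3", "4", "5+"):
        for r in ("0", "1", "2", "3", "4", "5+"):
            chans.append(ChannelId(INSERTION, size, REPEAT, r))
    for size, mhs in (
        ("2", ("1",)),
        ("3", ("1", "2")),
        ("4", ("1", "2", "3")),
        ("5+", ("1", "2", "3", "4", "5+")),
    ):
        for m in mhs:
            chans.append(ChannelId(DELETION, size, MICROHOMOLOGY, m))
    return tuple(chans)


#: canonical channel order shared by catalogs and signature matrices
ID83_CHANNELS: tuple[ChannelId, ...] = _build_channels()
CHANNEL_INDEX: dict[ChannelId, int] = {c: i for i, c in enumerate(ID83_CHANNELS)}
ID83_LABELS: tuple[str, ...] = tuple(c.label for c in ID83_CHANNELS)
LABEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(ID83_LABELS)}

assert len(ID83_CHANNELS) == 83
assert len(set(ID83_LABELS)) == 83
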