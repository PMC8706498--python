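"""Alignment and metadata I/O, validation, and locus concatenation.

FASTA reading is delegated to Biopython; this module adds the shape and
alphabet checks the downstream analysis relies on, and the bookkeeping for
concatenating loci with a 1-based offset map.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    ConcatenationError,
    MetadataError,
)
from .iupac import ALPHABET

PARENTAL_A = "parental_A"
PARENTAL_B = "parental_B"
QUERY = "query"
GROUPS = (PARENTAL_A, PARENTAL_B, QUERY)
PARENTAL_GROUPS = (PARENTAL_A, PARENTAL_B)


def _validate_residues(sample_id: str, residues: str) -> None:
    if not residues:
        raise AlphabetError(f"record {sample_id!r}: empty sequence")
    for i, ch in enumerate(residues, start=1):
        if ch not in ALPHABET:
            raise AlphabetError(
                f"record {sample_id!r}: illegal character {ch!r} at position {i}"
            )


@dataclass(frozen=True)
class AlignedSeq:
    """One aligned sequence of a locus, upper-case IUPAC residues."""

    sample_id: str
    locus: str
    residues: str

    def __post_init__(self) -> None:
        _validate_residues(self.sample_id, self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def at(self, position: int) -> str:
        """Residue at a 1-based position."""
        return self.residues[position - 1]


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: str
    taxon_label: str = ""
    locality: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise MetadataError(
                f"sample {self.sample_id!r}: unknown group {self.group!r}; "
                f"allowed: {', '.join(GROUPS)}"
            )


@dataclass(frozen=True)
class Alignment:
    """Equal-length aligned sequences for one locus; record order preserved."""

    locus: str
    seqs: tuple[AlignedSeq, ...]
    offsets: dict[str, tuple[int, int]] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.seqs:
            raise AlignmentShapeError(f"locus {self.locus!r}: empty alignment")
        ref = len(self.seqs[0])
        for s in self.seqs:
            if len(s) != ref:
                raise AlignmentShapeError(
                    f"locus {self.locus!r}: record {s.sample_id!r} has length "
                    f"{len(s)}, expected {ref}"
                )
        ids = [s.sample_id for s in self.seqs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentShapeError(
                f"locus {self.locus!r}: duplicate sample ids {dup}"
            )

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.seqs)

    def __iter__(self) -> Iterator[AlignedSeq]:
        return iter(self.seqs)

    def __len__(self) -> int:
        return len(self.seqs)

    def get(self, sample_id: str) -> AlignedSeq:
        for s in self.seqs:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def subset(self, sample_ids: Iterable[str]) -> "Alignment":
        wanted = set(sample_ids)
        return Alignment(
            locus=self.locus,
            seqs=tuple(s for s in self.seqs if s.sample_id in wanted),
        )


def _normalize(raw: str) -> str:
    # tolerate lowercase and RNA dialects; anything else is rejected later
    return raw.upper().replace("U", "T")


def read_alignment(path: str | Path, locus: str) -> Alignment:
    """Read a pre-aligned FASTA file into an :class:`Alignment`.

    Residues are case-folded to upper and U is normalized to T. Unequal
    record lengths or symbols outside the IUPAC alphabet raise.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentShapeError(f"{path}: no FASTA records found")
    seqs = tuple(
        AlignedSeq(sample_id=r.id, locus=locus, residues=_normalize(str(r.seq)))
        for r in records
    )
    return Alignment(locus=locus, seqs=seqs)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as plain unwrapped FASTA."""
    with open(path, "w") as fh:
        for s in aln:
            fh.write(f">{s.sample_id}\n{s.residues}\n")


def alignment_to_fasta(aln: Alignment) -> str:
    buf = io.StringIO()
    for s in aln:
        buf.write(f">{s.sample_id}\n{s.residues}\n")
    return buf.getvalue()


_META_COLUMNS = ["sample_id", "group", "taxon_label", "locality"]


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the sample metadata TSV (columns sample_id, group, taxon_label, locality)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    except pd.errors.EmptyDataError:
        raise MetadataError(f"{path}: empty metadata file") from None
    missing = [c for c in ("sample_id", "group") if c not in df.columns]
    if missing:
        raise MetadataError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise MetadataError(f"{path}: metadata table has no rows")
    dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dups:
        raise MetadataError(f"{path}: duplicate sample ids {sorted(set(dups))}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SampleMeta(
                sample_id=row.sample_id,
                group=row.group,
                taxon_label=getattr(row, "taxon_label", ""),
                locality=getattr(row, "locality", ""),
            )
        )
    return out


def write_metadata(meta: Iterable[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [(m.sample_id, m.group, m.taxon_label, m.locality) for m in meta],
        columns=_META_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def metadata_by_id(meta: Iterable[SampleMeta]) -> dict[str, SampleMeta]:
    return {m.sample_id: m for m in meta}


def group_sample_ids(meta: Iterable[SampleMeta], group: str) -> list[str]:
    return [m.sample_id for m in meta if m.group == group]


def check_alignment_metadata(aln: Alignment, meta: Iterable[SampleMeta]) -> None:
    """Every aligned sample must resolve to exactly one metadata row."""
    known = metadata_by_id(meta)
    unknown = [s for s in aln.sample_ids if s not in known]
    if unknown:
        raise MetadataError(
            f"locus {aln.locus!r}: samples without metadata: {unknown}"
        )


def concatenate_loci(alignments: list[Alignment]) -> Alignment:
    """Concatenate loci sharing one sample set, recording 1-based offsets.

    The returned alignment's ``offsets`` maps each input locus to its
    inclusive (start, end) column range in the concatenated frame.
    """
    if not alignments:
        raise ConcatenationError("no alignments to concatenate")
    if len(alignments) == 1:
        only = alignments[0]
        return Alignment(
            locus=only.locus,
            seqs=only.seqs,
            offsets={only.locus: (1, only.length)},
        )
    ref_ids = set(alignments[0].sample_ids)
    for aln in alignments[1:]:
        ids = set(aln.sample_ids)
        if ids != ref_ids:
            missing = sorted(ref_ids ^ ids)
            raise ConcatenationError(
                f"locus {aln.locus!r}: sample sets differ; "
                f"unmatched ids: {missing}"
            )
    offsets: dict[str, tuple[int, int]] = {}
    start = 1
    for aln in alignments:
        offsets[aln.locus] = (start, start + aln.length - 1)
        start += aln.length
    order = alignments[0].sample_ids
    name = "+".join(a.locus for a in alignments)
    seqs = tuple(
        AlignedSeq(
            sample_id=sid,
            locus=name,
            residues="".join(a.get(sid).residues for a in alignments),
        )
        for sid in order
    )
    return Alignment(locus=name, seqs=seqs, offsets=offsets)


def write_offsets(aln: Alignment, path: str | Path) -> None:
    """Emit the per-locus offset map of a concatenated alignment as TSV."""
    df = pd.DataFrame(
        [(locus, s, e) for locus, (s, e) in aln.offsets.items()],
        columns=["locus", "start", "end"],
    )
    df.to_csv(path, sep="\t", index=False)
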