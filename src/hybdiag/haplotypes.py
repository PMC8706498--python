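"""Haplotype collapsing, variable-site tables, and mitochondrial assignment.

Sequences are collapsed by literal residue identity (ambiguity codes and
gaps compared as-is, never expanded). Labels are generated deterministically
from per-group prefixes in order of first appearance; a haplotype shared
between a query and a parental sample receives the parental label.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import AlignmentShapeError, ConfigurationError
from .iupac import hamming_distance
from .seq_io import (
    AlignedSeq,
    Alignment,
    PARENTAL_A,
    PARENTAL_B,
    PARENTAL_GROUPS,
    SampleMeta,
)

AMBIGUOUS = "ambiguous"

#: default label prefixes per metadata group
DEFAULT_PREFIXES = {PARENTAL_A: "A", PARENTAL_B: "B", "query": "Q"}


@dataclass(frozen=True)
class HaplotypeEntry:
    label: str
    sequence: str
    members: tuple[str, ...]
    #: metadata groups represented among the members (empty without metadata)
    groups: frozenset[str] = frozenset()


@dataclass(frozen=True)
class HaplotypeTable:
    locus: str
    entries: tuple[HaplotypeEntry, ...]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.entries)

    def get(self, label: str) -> HaplotypeEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)

    def label_of_sample(self, sample_id: str) -> str:
        for e in self.entries:
            if sample_id in e.members:
                return e.label
        raise KeyError(sample_id)


@dataclass(frozen=True)
class VariableSiteTable:
    locus: str
    positions: tuple[int, ...]
    states: Mapping[str, Mapping[int, str]]  # label -> position -> symbol
    labels: tuple[str, ...] = ()


@dataclass(frozen=True)
class MitoAssignment:
    sample_id: str
    best_haplotype: str
    hamming_to_best: int
    lineage: str  # parental_A | parental_B | ambiguous
    margin: int


def collapse_haplotypes(
    aln: Alignment,
    meta: Sequence[SampleMeta] | None = None,
    group_prefixes: Mapping[str, str] | None = None,
    label_overrides: Mapping[str, str] | None = None,
) -> HaplotypeTable:
    """Group identical residue strings into labelled haplotypes.

    Without metadata every haplotype is labelled ``Hap01``, ``Hap02``, ... in
    order of first appearance. With metadata, each haplotype is labelled with
    the prefix of its owning group (the group of its first *parental* member,
    falling back to its first member) and a per-prefix two-digit counter.
    ``label_overrides`` remaps generated labels afterwards.
    """
    by_seq: dict[str, list[str]] = {}
    for s in aln:
        by_seq.setdefault(s.residues, []).append(s.sample_id)

    groups_of = {}
    if meta is not None:
        groups_of = {m.sample_id: m.group for m in meta}

    entries: list[HaplotypeEntry] = []
    counters: dict[str, int] = {}
    for seq, members in by_seq.items():
        if meta is None:
            prefix = "Hap"
            member_groups: frozenset[str] = frozenset()
        else:
            member_groups = frozenset(groups_of[m] for m in members)
            owner = next(
                (groups_of[m] for m in members if groups_of[m] in PARENTAL_GROUPS),
                groups_of[members[0]],
            )
            prefixes = dict(DEFAULT_PREFIXES)
            if group_prefixes:
                prefixes.update(group_prefixes)
            prefix = prefixes[owner]
        counters[prefix] = counters.get(prefix, 0) + 1
        label = f"{prefix}{counters[prefix]:02d}"
        if label_overrides and label in label_overrides:
            label = label_overrides[label]
        entries.append(
            HaplotypeEntry(
                label=label,
                sequence=seq,
                members=tuple(members),
                groups=member_groups,
            )
        )
    return HaplotypeTable(locus=aln.locus, entries=tuple(entries))


def variable_sites(table: HaplotypeTable) -> VariableSiteTable:
    """Columns at which the haplotype sequences are not all identical."""
    if not table.entries:
        raise ConfigurationError("empty haplotype table")
    seqs = [e.sequence for e in table.entries]
    length = len(seqs[0])
    positions = tuple(
        pos
        for pos in range(1, length + 1)
        if len({s[pos - 1] for s in seqs}) > 1
    )
    states = {
        e.label: {pos: e.sequence[pos - 1] for pos in positions}
        for e in table.entries
    }
    return VariableSiteTable(
        locus=table.locus,
        positions=positions,
        states=states,
        labels=table.labels,
    )


def write_variable_sites(vst: VariableSiteTable, path: str | Path) -> None:
    """TSV export: one row per haplotype, one column per variable position."""
    rows = [
        [label] + [vst.states[label][p] for p in vst.positions]
        for label in vst.labels
    ]
    df = pd.DataFrame(rows, columns=["Taxon/Haplotype"] + [str(p) for p in vst.positions])
    df.to_csv(path, sep="\t", index=False)


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (e.label, len(e.members), ",".join(e.members), e.sequence)
            for e in table.entries
        ],
        columns=["haplotype", "n_members", "members", "sequence"],
    )
    df.to_csv(path, sep="\t", index=False)


def assign_mito_lineage(
    query: AlignedSeq,
    parental_table: HaplotypeTable,
    meta: Sequence[SampleMeta],
) -> MitoAssignment:
    """Assign a query to the nearest parental haplotype and its lineage.

    Distances are Hamming counts under pairwise deletion (sites where either
    symbol is a gap or an ambiguity code are skipped). Ties between the two
    lineages yield ``ambiguous``; the reported margin is the absolute
    difference between the nearest-A and nearest-B distances.
    """
    if not parental_table.entries:
        raise ConfigurationError("empty parental haplotype table")
    ref_len = len(parental_table.entries[0].sequence)
    if len(query) != ref_len:
        raise AlignmentShapeError(
            f"query {query.sample_id!r} length {len(query)} != "
            f"haplotype length {ref_len}"
        )
    groups_of = {m.sample_id: m.group for m in meta}
    dists: list[tuple[str, int, frozenset[str]]] = []
    for e in parental_table.entries:
        lineages = frozenset(
            groups_of[m] for m in e.members if groups_of[m] in PARENTAL_GROUPS
        )
        dists.append((e.label, hamming_distance(query.residues, e.sequence), lineages))

    def nearest(lineage: str) -> int | None:
        ds = [d for _, d, lin in dists if lineage in lin]
        return min(ds) if ds else None

    min_a = nearest(PARENTAL_A)
    min_b = nearest(PARENTAL_B)
    if min_a is None or min_b is None:
        raise ConfigurationError(
            "parental haplotype table must contain both parental lineages"
        )
    best_label, best_d, _ = min(dists, key=lambda t: t[1])  # stable: first wins ties
    margin = abs(min_a - min_b)
    if margin == 0:
        lineage = AMBIGUOUS
    elif min_a < min_b:
        lineage = PARENTAL_A
    else:
        lineage = PARENTAL_B
    return MitoAssignment(
        sample_id=query.sample_id,
        best_haplotype=best_label,
        hamming_to_best=best_d,
        lineage=lineage,
        margin=margin,
    )
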