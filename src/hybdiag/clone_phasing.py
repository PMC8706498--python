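"""Phase cloned allele sequences of a heterozygous sample at diagnostic sites.

Each clone is assigned to a parental allele by majority vote over the
diagnostic sites only; point errors elsewhere in the clone are ignored by
construction. The direct (consensus) sequence can then be checked against
the bases actually observed in the two clone groups.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError
from .iupac import expand
from .seq_io import AlignedSeq
from .diagnostics import DiagnosticSiteSet

ALLELE_A = "allele_A"
ALLELE_B = "allele_B"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class CloneSet:
    sample_id: str
    locus: str
    clones: tuple[AlignedSeq, ...]

    def __len__(self) -> int:
        return len(self.clones)


@dataclass(frozen=True)
class PhasingResult:
    sample_id: str
    locus: str
    groups: Mapping[str, str]  # clone id -> allele_A | allele_B | unassigned
    n_groups_observed: int
    group_consensus: Mapping[str, str]  # allele label -> consensus sequence
    consistent_with_consensus: bool | None = None


def _column_consensus(seqs: Sequence[str]) -> str:
    # most common symbol per column; ties resolved by first appearance
    out = []
    for col in zip(*seqs):
        out.append(Counter(col).most_common(1)[0][0])
    return "".join(out)


def phase_clones(
    clones: CloneSet,
    sites: DiagnosticSiteSet,
    max_mismatch_fraction: float = 0.49,
) -> PhasingResult:
    """Assign each clone to a parental allele by its diagnostic-site states.

    A clone goes to allele_A (resp. B) when it matches state_A (resp. B) at
    a strict majority of the diagnostic sites; ties are left unassigned, as
    are clones whose mismatch fraction against the winning state vector
    exceeds ``max_mismatch_fraction``.
    """
    if len(sites) == 0:
        raise ConfigurationError(
            f"locus {clones.locus!r}: cannot phase without diagnostic sites"
        )
    n_sites = len(sites)
    groups: dict[str, str] = {}
    for clone in clones.clones:
        votes_a = sum(1 for s in sites if clone.at(s.position) == s.state_a)
        votes_b = sum(1 for s in sites if clone.at(s.position) == s.state_b)
        if votes_a > n_sites / 2:
            allele, votes = ALLELE_A, votes_a
        elif votes_b > n_sites / 2:
            allele, votes = ALLELE_B, votes_b
        else:
            groups[clone.sample_id] = UNASSIGNED
            continue
        mismatch_fraction = (n_sites - votes) / n_sites
        groups[clone.sample_id] = (
            allele if mismatch_fraction <= max_mismatch_fraction else UNASSIGNED
        )

    consensus: dict[str, str] = {}
    for allele in (ALLELE_A, ALLELE_B):
        members = [c.residues for c in clones.clones if groups[c.sample_id] == allele]
        if members:
            consensus[allele] = _column_consensus(members)
    return PhasingResult(
        sample_id=clones.sample_id,
        locus=clones.locus,
        groups=groups,
        n_groups_observed=len(consensus),
        group_consensus=consensus,
    )


def check_consensus_consistency(
    phasing: PhasingResult,
    consensus: AlignedSeq,
    sites: DiagnosticSiteSet,
) -> bool:
    """True iff at every diagnostic site the direct-sequencing symbol expands
    to exactly the set of bases observed across the phased clone groups."""
    for site in sites:
        observed = frozenset(
            seq[site.position - 1] for seq in phasing.group_consensus.values()
        )
        if expand(consensus.at(site.position)) != observed:
            return False
    return True


def annotate_consistency(
    phasing: PhasingResult,
    consensus: AlignedSeq,
    sites: DiagnosticSiteSet,
) -> PhasingResult:
    return replace(
        phasing,
        consistent_with_consensus=check_consensus_consistency(phasing, consensus, sites),
    )


def write_phasing_report(
    phasings: Sequence[PhasingResult], path: str | Path
) -> None:
    rows = []
    for p in phasings:
        n_a = sum(1 for g in p.groups.values() if g == ALLELE_A)
        n_b = sum(1 for g in p.groups.values() if g == ALLELE_B)
        n_u = sum(1 for g in p.groups.values() if g == UNASSIGNED)
        rows.append(
            (
                p.sample_id,
                p.locus,
                len(p.groups),
                n_a,
                n_b,
                n_u,
                p.n_groups_observed,
                p.consistent_with_consensus,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "locus",
            "n_clones",
            "n_allele_A",
            "n_allele_B",
            "n_unassigned",
            "n_groups_observed",
            "consistent_with_consensus",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
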