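"""Combine nuclear zygosity profiles and the mitochondrial assignment into
a per-sample hybrid verdict.

A locus is *informative* when it carries at least one diagnostic site.
Loci without fixed differences are reported but never weigh on the call.
The label is deliberately "f1_consistent" rather than "F1": complete
heterozygosity at a handful of diagnostic sites cannot exclude
later-generation hybrids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError
from .haplotypes import MitoAssignment
from .diagnostics import ZygosityProfile
from .seq_io import PARENTAL_A, PARENTAL_B

F1_CONSISTENT = "f1_consistent"
PARENTAL_A_LIKE = "parental_A_like"
PARENTAL_B_LIKE = "parental_B_like"
INCONCLUSIVE = "inconclusive"
NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class LocusSummary:
    n_sites: int
    n_het_ab: int
    n_hom_a: int
    n_hom_b: int
    n_other: int


@dataclass(frozen=True)
class HybridVerdict:
    sample_id: str
    per_locus: Mapping[str, LocusSummary]
    informative_loci: int
    mito: MitoAssignment
    classification: str
    maternal_parent: str


def call_hybrid(
    profiles: Sequence[ZygosityProfile],
    mito: MitoAssignment,
    min_het_fraction: float = 1.0,
) -> HybridVerdict:
    """Classify one sample from its zygosity profiles and mito assignment.

    * ``f1_consistent``: every informative locus is heterozygous for the two
      parental states at >= ``min_het_fraction`` of its diagnostic sites and
      carries no "other" call; the maternal parent is then read off the
      mitochondrial lineage.
    * ``parental_A_like`` / ``parental_B_like``: every informative locus is
      entirely homozygous for that parent's states.
    * anything else: ``inconclusive``.
    """
    if not profiles:
        raise ConfigurationError("no zygosity profiles supplied")
    ids = {p.sample_id for p in profiles}
    if len(ids) != 1:
        raise ConfigurationError(f"profiles span multiple samples: {sorted(ids)}")
    (sample_id,) = ids
    if mito.sample_id != sample_id:
        raise ConfigurationError(
            f"mito assignment is for {mito.sample_id!r}, profiles for {sample_id!r}"
        )
    if not 0 < min_het_fraction <= 1:
        raise ConfigurationError("min_het_fraction must be in (0, 1]")

    per_locus = {
        p.locus: LocusSummary(
            n_sites=p.n_sites,
            n_het_ab=p.n_het_ab,
            n_hom_a=p.n_hom_a,
            n_hom_b=p.n_hom_b,
            n_other=p.n_other,
        )
        for p in profiles
    }
    informative = [s for s in per_locus.values() if s.n_sites > 0]
    if not informative:
        raise ConfigurationError(
            f"sample {sample_id!r}: no informative locus (zero diagnostic sites)"
        )

    if all(
        s.n_het_ab / s.n_sites >= min_het_fraction and s.n_other == 0
        for s in informative
    ):
        classification = F1_CONSISTENT
    elif all(s.n_hom_a == s.n_sites for s in informative):
        classification = PARENTAL_A_LIKE
    elif all(s.n_hom_b == s.n_sites for s in informative):
        classification = PARENTAL_B_LIKE
    else:
        classification = INCONCLUSIVE

    maternal = mito.lineage if classification == F1_CONSISTENT else NOT_APPLICABLE
    return HybridVerdict(
        sample_id=sample_id,
        per_locus=per_locus,
        informative_loci=len(informative),
        mito=mito,
        classification=classification,
        maternal_parent=maternal,
    )


def report(verdicts: Sequence[HybridVerdict]) -> pd.DataFrame:
    """One row per sample; per-locus het counts in deterministic locus order."""
    loci = sorted({locus for v in verdicts for locus in v.per_locus})
    columns = (
        ["sample_id", "classification"]
        + [f"{locus}_het" for locus in loci]
        + [f"{locus}_sites" for locus in loci]
        + ["mito_haplotype", "mito_lineage", "maternal_parent"]
    )
    rows = []
    for v in verdicts:
        row: dict[str, object] = {
            "sample_id": v.sample_id,
            "classification": v.classification,
            "mito_haplotype": v.mito.best_haplotype,
            "mito_lineage": v.mito.lineage,
            "maternal_parent": v.maternal_parent,
        }
        for locus in loci:
            s = v.per_locus.get(locus)
            row[f"{locus}_het"] = s.n_het_ab if s else 0
            row[f"{locus}_sites"] = s.n_sites if s else 0
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


def write_report(verdicts: Sequence[HybridVerdict], path: str | Path) -> None:
    report(verdicts).to_csv(path, sep="\t", index=False)


def swap_parent_labels(classification: str) -> str:
    """A<->B mirror of a classification label (used by equivariance checks)."""
    return {
        PARENTAL_A_LIKE: PARENTAL_B_LIKE,
        PARENTAL_B_LIKE: PARENTAL_A_LIKE,
    }.get(classification, classification)


def swap_lineage(lineage: str) -> str:
    return {PARENTAL_A: PARENTAL_B, PARENTAL_B: PARENTAL_A}.get(lineage, lineage)
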