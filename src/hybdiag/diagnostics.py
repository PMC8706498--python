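"""Fixed interspecific differences, heterozygous-site detection, p-distances.

Conventions used throughout:

* Fixedness is absolute: a diagnostic site must be monomorphic for an
  unambiguous base within each parental group and different between them.
  Any ambiguity code, gap, or second allele inside a group disqualifies the
  column — there is no frequency threshold.
* p-distances use pairwise deletion: only sites where both sequences carry
  an unambiguous base are compared.
* The bootstrap standard error resamples alignment columns with
  replacement; it is reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedDistanceError
from .iupac import BASES, expand, is_ambiguous
from .seq_io import (
    AlignedSeq,
    Alignment,
    PARENTAL_A,
    PARENTAL_B,
    SampleMeta,
)

HET_AB = "het_AB"
HOM_A = "hom_A"
HOM_B = "hom_B"
OTHER = "other"

OVERALL = "overall"
BETWEEN_GROUPS = "between_groups"


@dataclass(frozen=True)
class DiagnosticSite:
    position: int  # 1-based
    state_a: str
    state_b: str


@dataclass(frozen=True)
class DiagnosticSiteSet:
    locus: str
    sites: tuple[DiagnosticSite, ...]

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.sites)


@dataclass(frozen=True)
class HetSite:
    position: int
    symbol: str
    expansion: frozenset[str]


@dataclass(frozen=True)
class ZygosityProfile:
    sample_id: str
    locus: str
    calls: dict[int, str]  # position -> HET_AB | HOM_A | HOM_B | OTHER

    @property
    def n_sites(self) -> int:
        return len(self.calls)

    def count(self, call: str) -> int:
        return sum(1 for c in self.calls.values() if c == call)

    @property
    def n_het_ab(self) -> int:
        return self.count(HET_AB)

    @property
    def n_hom_a(self) -> int:
        return self.count(HOM_A)

    @property
    def n_hom_b(self) -> int:
        return self.count(HOM_B)

    @property
    def n_other(self) -> int:
        return self.count(OTHER)


@dataclass(frozen=True)
class DistanceResult:
    mean_p: float
    se_p: float
    mode: str
    n_pairs: int
    bootstrap_reps: int
    seed: int | None


def find_fixed_differences(
    aln: Alignment, meta: Sequence[SampleMeta]
) -> DiagnosticSiteSet:
    """Columns fixed for different unambiguous bases in the two parental groups.

    Query samples are ignored. Raises if either parental group has no
    sequenced sample in the alignment.
    """
    groups_of = {m.sample_id: m.group for m in meta}
    a_seqs = [s.residues for s in aln if groups_of.get(s.sample_id) == PARENTAL_A]
    b_seqs = [s.residues for s in aln if groups_of.get(s.sample_id) == PARENTAL_B]
    if not a_seqs or not b_seqs:
        raise ConfigurationError(
            f"locus {aln.locus!r}: both parental groups must be non-empty "
            f"(got {len(a_seqs)} parental_A, {len(b_seqs)} parental_B)"
        )
    sites = []
    for pos in range(1, aln.length + 1):
        col_a = {s[pos - 1] for s in a_seqs}
        col_b = {s[pos - 1] for s in b_seqs}
        if len(col_a) != 1 or len(col_b) != 1:
            continue
        (state_a,) = col_a
        (state_b,) = col_b
        if state_a in BASES and state_b in BASES and state_a != state_b:
            sites.append(DiagnosticSite(pos, state_a, state_b))
    return DiagnosticSiteSet(locus=aln.locus, sites=tuple(sites))


def detect_het_sites(seq: AlignedSeq, include_n: bool = False) -> list[HetSite]:
    """Positions carrying a degenerate base symbol (N excluded by default)."""
    out = []
    for pos, sym in enumerate(seq.residues, start=1):
        if is_ambiguous(sym) and (include_n or sym != "N"):
            out.append(HetSite(position=pos, symbol=sym, expansion=expand(sym)))
    return out


def zygosity_profile(seq: AlignedSeq, sites: DiagnosticSiteSet) -> ZygosityProfile:
    """Call each diagnostic site of a sequence as hom_A/hom_B/het_AB/other.

    het_AB requires the observed symbol's IUPAC expansion to equal exactly
    the two parental states; anything else that is not one of the two
    parental bases (N, gap, third allele) is "other".
    """
    calls: dict[int, str] = {}
    for site in sites:
        if site.position > len(seq):
            raise ConfigurationError(
                f"sequence {seq.sample_id!r} shorter than diagnostic "
                f"position {site.position}"
            )
        sym = seq.at(site.position)
        if sym == site.state_a:
            calls[site.position] = HOM_A
        elif sym == site.state_b:
            calls[site.position] = HOM_B
        elif expand(sym) == frozenset({site.state_a, site.state_b}):
            calls[site.position] = HET_AB
        else:
            calls[site.position] = OTHER
    return ZygosityProfile(sample_id=seq.sample_id, locus=sites.locus, calls=calls)


def p_distance(a: AlignedSeq | str, b: AlignedSeq | str) -> float:
    """Uncorrected proportion of differing sites, pairwise deletion."""
    sa = a.residues if isinstance(a, AlignedSeq) else a
    sb = b.residues if isinstance(b, AlignedSeq) else b
    if len(sa) != len(sb):
        raise UndefinedDistanceError("sequences differ in length")
    from .iupac import compare_sequences

    n_diff, n_comp = compare_sequences(sa, sb)
    if n_comp == 0:
        raise UndefinedDistanceError("no comparable sites between sequences")
    return n_diff / n_comp


_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(aln: Alignment) -> np.ndarray:
    """(n_seqs, n_cols) uint8 matrix; 255 marks non-comparable symbols."""
    raw = np.frombuffer(
        "".join(s.residues for s in aln).encode("ascii"), dtype=np.uint8
    )
    return _CODE[raw].reshape(len(aln), aln.length)


def mean_p_distance(
    aln: Alignment,
    mode: str = OVERALL,
    meta: Sequence[SampleMeta] | None = None,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> DistanceResult:
    """Mean pairwise p-distance with a column-bootstrap standard error.

    ``overall`` averages over all unordered pairs of samples;
    ``between_groups`` over all parental_A x parental_B pairs (requires
    metadata). The SE is the standard deviation of the mean recomputed on
    ``bootstrap_reps`` resamplings of alignment columns with replacement.
    """
    mat = _encode(aln)
    n, ncol = mat.shape
    if mode == OVERALL:
        if n < 2:
            raise ConfigurationError("overall mode needs >= 2 sequences")
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    elif mode == BETWEEN_GROUPS:
        if meta is None:
            raise ConfigurationError("between_groups mode requires metadata")
        groups_of = {m.sample_id: m.group for m in meta}
        idx_a = [i for i, s in enumerate(aln) if groups_of.get(s.sample_id) == PARENTAL_A]
        idx_b = [i for i, s in enumerate(aln) if groups_of.get(s.sample_id) == PARENTAL_B]
        if not idx_a or not idx_b:
            raise ConfigurationError("between_groups mode needs both parental groups")
        pairs = [(i, j) for i in idx_a for j in idx_b]
    else:
        raise ConfigurationError(f"unknown distance mode {mode!r}")

    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    comparable = (mat[ii] != 255) & (mat[jj] != 255)
    differing = comparable & (mat[ii] != mat[jj])
    comp_counts = comparable.sum(axis=1)
    if (comp_counts == 0).any():
        raise UndefinedDistanceError("a sample pair has no comparable sites")
    mean_p = float(np.mean(differing.sum(axis=1) / comp_counts))

    se_p = 0.0
    if bootstrap_reps > 0:
        if seed is None:
            raise ConfigurationError("bootstrap requires an explicit seed")
        rng = np.random.default_rng(seed)
        diff64 = differing.astype(np.int64)
        comp64 = comparable.astype(np.int64)
        means = np.empty(bootstrap_reps)
        for r in range(bootstrap_reps):
            w = np.bincount(rng.integers(0, ncol, size=ncol), minlength=ncol)
            d = diff64 @ w
            c = comp64 @ w
            valid = c > 0
            means[r] = np.mean(d[valid] / c[valid])
        se_p = float(np.std(means, ddof=1))

    return DistanceResult(
        mean_p=mean_p,
        se_p=se_p,
        mode=mode,
        n_pairs=len(pairs),
        bootstrap_reps=bootstrap_reps,
        seed=seed,
    )


def write_diagnostic_sites(
    site_sets: Sequence[DiagnosticSiteSet], path: str | Path
) -> None:
    df = pd.DataFrame(
        [(ss.locus, s.position, s.state_a, s.state_b) for ss in site_sets for s in ss],
        columns=["locus", "position", "state_A", "state_B"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_distance_report(
    results: Sequence[DistanceResult], locus: str, path: str | Path
) -> None:
    """Distance report TSV; percentages rounded to one decimal for display."""
    df = pd.DataFrame(
        [
            (
                locus,
                r.mode,
                round(100 * r.mean_p, 1),
                round(100 * r.se_p, 1),
                r.n_pairs,
                r.bootstrap_reps,
                r.seed,
            )
            for r in results
        ],
        columns=["locus", "mode", "mean_p_pct", "se_p_pct", "n_pairs", "bootstrap_reps", "seed"],
    )
    df.to_csv(path, sep="\t", index=False)
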