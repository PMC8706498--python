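"""Synthetic two-lineage datasets with ground truth, and packaged fixtures.

The generator plants a configurable number of fixed substitutions between
two parental lineages per locus, low within-lineage haplotype diversity
(one common haplotype plus rare singleton variants), F1 hybrids whose
nuclear consensus merges the two parental alleles into two-base ambiguity
codes, a maternally inherited mitochondrial sequence, and cloned allele
sequences per nuclear gene with an optional per-site error rate.

All randomness flows from a single top-level seed; each locus gets an
independent substream derived by stable hashing of its name, so adding a
locus never perturbs the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ScoringError
from .iupac import code_for
from .seq_io import (
    AlignedSeq,
    Alignment,
    PARENTAL_A,
    PARENTAL_B,
    QUERY,
    SampleMeta,
    write_alignment,
    write_metadata,
)
from .clone_phasing import ALLELE_A, ALLELE_B, CloneSet, PhasingResult
from .hybrid_caller import (
    F1_CONSISTENT,
    PARENTAL_A_LIKE,
    PARENTAL_B_LIKE,
    HybridVerdict,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class LocusParams:
    name: str
    length: int
    n_fixed_diffs: int
    #: per-lineage count of extra segregating sites, each defining one rare
    #: singleton haplotype; an int applies to both lineages
    within_polymorphism: int | tuple[int, int] = 0
    is_mito: bool = False

    @property
    def poly_a(self) -> int:
        wp = self.within_polymorphism
        return wp[0] if isinstance(wp, (tuple, list)) else wp

    @property
    def poly_b(self) -> int:
        wp = self.within_polymorphism
        return wp[1] if isinstance(wp, (tuple, list)) else wp


def default_loci() -> list[LocusParams]:
    """Four loci mirroring the study system: one 658 bp mitochondrial
    fragment with 4 fixed differences and 3 haplotypes in lineage B, plus
    403/610/445 bp nuclear fragments with 2/0/2 fixed differences."""
    return [
        LocusParams("COI", 658, 4, within_polymorphism=(0, 2), is_mito=True),
        LocusParams("Wg", 403, 2),
        LocusParams("RPS5", 610, 0),
        LocusParams("CaATP", 445, 2),
    ]


@dataclass
class SimParams:
    seed: int = 0
    loci: list[LocusParams] = field(default_factory=default_loci)
    n_parental_a: int = 12
    n_parental_b: int = 15
    n_hybrids: int = 3
    maternal_lineage: str = PARENTAL_B  # parental_A | parental_B | mixed
    n_clones_per_gene: int = 10
    clone_error_rate: float = 0.0

    def validate(self) -> None:
        mito = [l for l in self.loci if l.is_mito]
        if len(mito) != 1:
            raise ParameterError(f"exactly one mito locus required, got {len(mito)}")
        for l in self.loci:
            budget = l.n_fixed_diffs + l.poly_a + l.poly_b
            if budget > l.length:
                raise ParameterError(
                    f"locus {l.name!r}: {budget} variable sites exceed length {l.length}"
                )
            if l.n_fixed_diffs < 0 or l.poly_a < 0 or l.poly_b < 0:
                raise ParameterError(f"locus {l.name!r}: negative site count")
        if self.n_parental_a < 1 or self.n_parental_b < 1:
            raise ParameterError("need at least one sample per parental lineage")
        if self.maternal_lineage not in (PARENTAL_A, PARENTAL_B, "mixed"):
            raise ParameterError(f"bad maternal_lineage {self.maternal_lineage!r}")
        if not 0 <= self.clone_error_rate < 1:
            raise ParameterError("clone_error_rate must be in [0, 1)")

    @property
    def mito_locus(self) -> str:
        return next(l.name for l in self.loci if l.is_mito)


@dataclass
class SimTruth:
    """Ground truth sufficient to score every downstream call exactly."""

    classes: dict[str, str]  # sample -> parental_A | parental_B | hybrid
    maternal: dict[str, str]  # hybrid sample -> parental_A | parental_B
    diagnostic: dict[str, list[tuple[int, str, str]]]  # locus -> (pos, A, B)
    hybrid_alleles: dict[str, dict[str, tuple[str, str]]]  # sample -> locus -> (a, b)
    clone_origins: dict[str, str]  # clone id -> allele_A | allele_B

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(
            classes=d["classes"],
            maternal=d["maternal"],
            diagnostic={
                k: [(int(p), a, b) for p, a, b in v] for k, v in d["diagnostic"].items()
            },
            hybrid_alleles={
                s: {l: (a, b) for l, (a, b) in per.items()}
                for s, per in d["hybrid_alleles"].items()
            },
            clone_origins=d["clone_origins"],
        )


@dataclass
class SimDataset:
    params: SimParams
    alignments: dict[str, Alignment]
    metadata: list[SampleMeta]
    clone_sets: list[CloneSet]
    truth: SimTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for locus, aln in self.alignments.items():
            write_alignment(aln, outdir / f"{locus}.fasta")
        write_metadata(self.metadata, outdir / "metadata.tsv")
        clone_dir = outdir / "clones"
        if self.clone_sets:
            clone_dir.mkdir(exist_ok=True)
        for cs in self.clone_sets:
            with open(clone_dir / f"{cs.sample_id}_{cs.locus}_clones.fasta", "w") as fh:
                for c in cs.clones:
                    fh.write(f">{c.sample_id}\n{c.residues}\n")
        (outdir / "truth.json").write_text(self.truth.to_json())
        (outdir / "params.json").write_text(
            json.dumps(
                {
                    "seed": self.params.seed,
                    "mito_locus": self.params.mito_locus,
                    "loci": [asdict(l) for l in self.params.loci],
                    "n_parental_a": self.params.n_parental_a,
                    "n_parental_b": self.params.n_parental_b,
                    "n_hybrids": self.params.n_hybrids,
                    "maternal_lineage": self.params.maternal_lineage,
                    "n_clones_per_gene": self.params.n_clones_per_gene,
                    "clone_error_rate": self.params.clone_error_rate,
                },
                indent=1,
            )
        )


def _rng(seed: int, *keys: str | int) -> np.random.Generator:
    """Substream generator: stable across runs and platforms."""
    entropy = [seed] + [
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in keys
    ]
    return np.random.default_rng(entropy)


def _mutate(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


@dataclass(frozen=True)
class _LocusModel:
    """Planted haplotypes and diagnostic sites for one locus."""

    diagnostic: tuple[tuple[int, str, str], ...]
    haps_a: tuple[str, ...]  # haps_*[0] is the common haplotype
    haps_b: tuple[str, ...]


def _build_locus(locus: LocusParams, seed: int) -> _LocusModel:
    rng = _rng(seed, locus.name, "model")
    ancestral = _BASES[rng.integers(0, 4, size=locus.length)]
    n_special = locus.n_fixed_diffs + locus.poly_a + locus.poly_b
    special = rng.choice(locus.length, size=n_special, replace=False)
    fixed_pos = np.sort(special[: locus.n_fixed_diffs])
    poly_a_pos = special[locus.n_fixed_diffs : locus.n_fixed_diffs + locus.poly_a]
    poly_b_pos = special[locus.n_fixed_diffs + locus.poly_a :]

    base_a = ancestral.copy()
    base_b = ancestral.copy()
    diagnostic = []
    for pos in fixed_pos:
        state_a = base_a[pos]
        state_b = _mutate(state_a, rng)
        base_b[pos] = state_b
        diagnostic.append((int(pos) + 1, str(state_a), str(state_b)))

    def variants(base: np.ndarray, positions: np.ndarray) -> tuple[str, ...]:
        haps = ["".join(base)]
        for pos in positions:
            var = base.copy()
            var[pos] = _mutate(str(var[pos]), rng)
            haps.append("".join(var))
        return tuple(haps)

    return _LocusModel(
        diagnostic=tuple(diagnostic),
        haps_a=variants(base_a, poly_a_pos),
        haps_b=variants(base_b, poly_b_pos),
    )


def _assign_haplotypes(
    n_samples: int, n_haps: int, rng: np.random.Generator
) -> list[int]:
    """Skewed haplotype frequencies: everyone carries the common haplotype
    except one random singleton carrier per rare variant."""
    assignment = [0] * n_samples
    n_rare = min(n_haps - 1, max(n_samples - 1, 0))
    if n_rare > 0:
        carriers = rng.choice(n_samples, size=n_rare, replace=False)
        for hap_idx, sample_idx in enumerate(carriers, start=1):
            assignment[sample_idx] = hap_idx
    return assignment


def _merge_alleles(a: str, b: str) -> str:
    return "".join(
        x if x == y else code_for({x, y}) for x, y in zip(a, b, strict=True)
    )


def simulate(params: SimParams) -> SimDataset:
    """Generate alignments, metadata, clone sets and ground truth."""
    params.validate()
    seed = params.seed
    ids_a = [f"A{i:02d}" for i in range(1, params.n_parental_a + 1)]
    ids_b = [f"B{i:02d}" for i in range(1, params.n_parental_b + 1)]
    ids_h = [f"H{i:02d}" for i in range(1, params.n_hybrids + 1)]

    metadata = (
        [SampleMeta(s, PARENTAL_A, "lineage_A", "sim") for s in ids_a]
        + [SampleMeta(s, PARENTAL_B, "lineage_B", "sim") for s in ids_b]
        + [SampleMeta(s, QUERY, "putative_hybrid", "sim") for s in ids_h]
    )

    # per-hybrid maternal lineage
    mat_rng = _rng(seed, "maternal")
    maternal: dict[str, str] = {}
    for h in ids_h:
        if params.maternal_lineage == "mixed":
            maternal[h] = PARENTAL_A if mat_rng.random() < 0.5 else PARENTAL_B
        else:
            maternal[h] = params.maternal_lineage

    alignments: dict[str, Alignment] = {}
    diagnostic: dict[str, list[tuple[int, str, str]]] = {}
    hybrid_alleles: dict[str, dict[str, tuple[str, str]]] = {h: {} for h in ids_h}
    clone_sets: list[CloneSet] = []
    clone_origins: dict[str, str] = {}

    for locus in params.loci:
        model = _build_locus(locus, seed)
        diagnostic[locus.name] = list(model.diagnostic)
        rng = _rng(seed, locus.name, "samples")
        hap_a_of = _assign_haplotypes(len(ids_a), len(model.haps_a), rng)
        hap_b_of = _assign_haplotypes(len(ids_b), len(model.haps_b), rng)

        seqs = [
            AlignedSeq(s, locus.name, model.haps_a[hap_a_of[i]])
            for i, s in enumerate(ids_a)
        ] + [
            AlignedSeq(s, locus.name, model.haps_b[hap_b_of[i]])
            for i, s in enumerate(ids_b)
        ]

        hyb_rng = _rng(seed, locus.name, "hybrids")
        for h in ids_h:
            if locus.is_mito:
                # copied from a random specimen of the maternal lineage, so
                # haplotype frequencies carry over
                if maternal[h] == PARENTAL_A:
                    donor = model.haps_a[hap_a_of[hyb_rng.integers(0, len(ids_a))]]
                else:
                    donor = model.haps_b[hap_b_of[hyb_rng.integers(0, len(ids_b))]]
                seqs.append(AlignedSeq(h, locus.name, donor))
            else:
                allele_a = model.haps_a[hyb_rng.integers(0, len(model.haps_a))]
                allele_b = model.haps_b[hyb_rng.integers(0, len(model.haps_b))]
                hybrid_alleles[h][locus.name] = (allele_a, allele_b)
                seqs.append(AlignedSeq(h, locus.name, _merge_alleles(allele_a, allele_b)))

        alignments[locus.name] = Alignment(locus=locus.name, seqs=tuple(seqs))

        # clones only make sense for nuclear genes of heterozygous samples
        if not locus.is_mito and locus.n_fixed_diffs > 0:
            for h in ids_h:
                clone_rng = _rng(seed, locus.name, "clones", zlib.crc32(h.encode()))
                allele_a, allele_b = hybrid_alleles[h][locus.name]
                clones = []
                for j in range(1, params.n_clones_per_gene + 1):
                    origin = ALLELE_A if clone_rng.random() < 0.5 else ALLELE_B
                    template = allele_a if origin == ALLELE_A else allele_b
                    residues = list(template)
                    if params.clone_error_rate > 0:
                        hits = np.nonzero(
                            clone_rng.random(len(residues)) < params.clone_error_rate
                        )[0]
                        for pos in hits:
                            residues[pos] = _mutate(residues[pos], clone_rng)
                    clone_id = f"{h}_{locus.name}_c{j:02d}"
                    clones.append(AlignedSeq(clone_id, locus.name, "".join(residues)))
                    clone_origins[clone_id] = origin
                clone_sets.append(CloneSet(sample_id=h, locus=locus.name, clones=tuple(clones)))

    classes = (
        {s: PARENTAL_A for s in ids_a}
        | {s: PARENTAL_B for s in ids_b}
        | {s: "hybrid" for s in ids_h}
    )
    truth = SimTruth(
        classes=classes,
        maternal=maternal,
        diagnostic=diagnostic,
        hybrid_alleles=hybrid_alleles,
        clone_origins=clone_origins,
    )
    return SimDataset(
        params=params,
        alignments=alignments,
        metadata=metadata,
        clone_sets=clone_sets,
        truth=truth,
    )


_EXPECTED_CLASS = {
    "hybrid": F1_CONSISTENT,
    PARENTAL_A: PARENTAL_A_LIKE,
    PARENTAL_B: PARENTAL_B_LIKE,
}


def score_against_truth(
    verdicts: Sequence[HybridVerdict],
    phasings: Sequence[PhasingResult],
    truth: SimTruth,
    diagnostic_sites: Mapping[str, "object"] | None = None,
) -> pd.DataFrame:
    """Score pipeline outputs against the generator's ground truth.

    Returns a tidy one-row-per-metric table: classification accuracy and
    confusion counts, maternal-lineage accuracy over true hybrids,
    clone-assignment accuracy, and (when ``diagnostic_sites`` is given, a
    mapping locus -> DiagnosticSiteSet) diagnostic-site precision/recall.
    """
    rows: list[tuple[str, float | int]] = []

    n_class_ok = 0
    confusion: dict[tuple[str, str], int] = {}
    for v in verdicts:
        if v.sample_id not in truth.classes:
            raise ScoringError(f"verdict for unknown sample {v.sample_id!r}")
        expected = _EXPECTED_CLASS[truth.classes[v.sample_id]]
        confusion[(expected, v.classification)] = (
            confusion.get((expected, v.classification), 0) + 1
        )
        if v.classification == expected:
            n_class_ok += 1
    if verdicts:
        rows.append(("classification_accuracy", n_class_ok / len(verdicts)))
    for (exp, got), n in sorted(confusion.items()):
        rows.append((f"confusion[{exp}->{got}]", n))

    hybrid_verdicts = [
        v for v in verdicts if truth.classes.get(v.sample_id) == "hybrid"
    ]
    if hybrid_verdicts:
        ok = sum(
            1 for v in hybrid_verdicts if v.maternal_parent == truth.maternal[v.sample_id]
        )
        rows.append(("maternal_accuracy", ok / len(hybrid_verdicts)))

    n_clone = n_clone_ok = 0
    for p in phasings:
        for clone_id, allele in p.groups.items():
            if clone_id not in truth.clone_origins:
                raise ScoringError(f"phasing for unknown clone {clone_id!r}")
            n_clone += 1
            if allele == truth.clone_origins[clone_id]:
                n_clone_ok += 1
    if n_clone:
        rows.append(("clone_assignment_accuracy", n_clone_ok / n_clone))

    if diagnostic_sites is not None:
        tp = fp = fn = 0
        for locus, true_sites in truth.diagnostic.items():
            true_pos = {p for p, _, _ in true_sites}
            found = diagnostic_sites.get(locus)
            found_pos = set(found.positions) if found is not None else set()
            tp += len(true_pos & found_pos)
            fp += len(found_pos - true_pos)
            fn += len(true_pos - found_pos)
        rows.append(("diagnostic_precision", tp / (tp + fp) if tp + fp else 1.0))
        rows.append(("diagnostic_recall", tp / (tp + fn) if tp + fn else 1.0))

    return pd.DataFrame(rows, columns=["metric", "value"])


# ---------------------------------------------------------------------------
# Packaged reference fixtures
# ---------------------------------------------------------------------------
#
# The mitochondrial fixture reconstructs the published 30-specimen, 658 bp
# variable-site matrix exactly: the 9 variable positions carry the printed
# states for the 5 haplotypes; every other column is an arbitrary-but-fixed
# constant base. Specimen ids, groups and localities follow the published
# specimen list; the rare-haplotype carriers within each locality are an
# arbitrary deterministic choice (the source only counts them).

COI_POSITIONS = (40, 82, 103, 271, 310, 361, 400, 406, 529)

COI_HAPLOTYPE_STATES = {
    "Ah01": "GTTAACTTC",
    "Cl01": "ATCTATTTC",
    "Cl02": "ATCTGTTTC",
    "Cl03": "ACCTATCTA",
    "AhCl01": "ATCTATTCC",
}

# sample id -> (group, haplotype, locality)
COI_SPECIMENS: tuple[tuple[str, str, str, str], ...] = (
    ("06FR", PARENTAL_A, "Ah01", "Irkutsk"),
    ("07FR", PARENTAL_A, "Ah01", "Irkutsk"),
    ("08FR", PARENTAL_A, "Ah01", "Irkutsk"),
    ("10FR", PARENTAL_A, "Ah01", "Irkutsk"),
    ("20FR", PARENTAL_A, "Ah01", "Buryatia"),
    ("21FR", PARENTAL_A, "Ah01", "Buryatia"),
    ("22FR", PARENTAL_A, "Ah01", "Buryatia"),
    ("23FR", PARENTAL_A, "Ah01", "Buryatia"),
    ("24FR", PARENTAL_A, "Ah01", "Buryatia"),
    ("25FR", PARENTAL_A, "Ah01", "Omsk"),
    ("26FR", PARENTAL_A, "Ah01", "Omsk"),
    ("27FR", PARENTAL_A, "Ah01", "Omsk"),
    ("01RUB", PARENTAL_B, "Cl01", "Irkutsk"),
    ("02RUB", PARENTAL_B, "Cl01", "Irkutsk"),
    ("03RUB", PARENTAL_B, "Cl01", "Irkutsk"),
    ("04RUB", PARENTAL_B, "Cl01", "Irkutsk"),
    ("05RUB", PARENTAL_B, "Cl02", "Irkutsk"),
    ("15RUB", PARENTAL_B, "Cl01", "Buryatia"),
    ("16RUB", PARENTAL_B, "Cl01", "Buryatia"),
    ("17RUB", PARENTAL_B, "Cl01", "Buryatia"),
    ("18RUB", PARENTAL_B, "Cl01", "Buryatia"),
    ("19RUB", PARENTAL_B, "Cl03", "Buryatia"),
    ("28RUB", PARENTAL_B, "Cl01", "Omsk"),
    ("29RUB", PARENTAL_B, "Cl01", "Omsk"),
    ("30RUB", PARENTAL_B, "Cl01", "Omsk"),
    ("31RUB", PARENTAL_B, "Cl01", "Omsk"),
    ("32RUB", PARENTAL_B, "Cl01", "Omsk"),
    ("CFR01", QUERY, "Cl01", "Irkutsk"),
    ("CFR02", QUERY, "Cl03", "Buryatia"),
    ("CFR03", QUERY, "AhCl01", "Omsk"),
)

COI_TAXON = {
    PARENTAL_A: "Ahlbergia frivaldszkyi",
    PARENTAL_B: "Callophrys rubi",
    QUERY: "A. frivaldszkyi x C. rubi",
}

#: label prefixes reproducing the published haplotype names
COI_PREFIXES = {PARENTAL_A: "Ah", PARENTAL_B: "Cl", QUERY: "AhCl"}

COI_LENGTH = 658

# fixed nuclear diagnostic positions (locus -> (length, ((pos, A, B), ...)))
NUCLEAR_LOCI: dict[str, tuple[int, tuple[tuple[int, str, str], ...]]] = {
    "Wg": (403, ((213, "C", "T"), (271, "G", "A"))),
    "RPS5": (610, ()),
    "CaATP": (445, ((151, "A", "G"), (334, "T", "C"))),
}


def _background(length: int, tag: str) -> np.ndarray:
    rng = np.random.default_rng([zlib.crc32(tag.encode()), 0xF1B])
    return _BASES[rng.integers(0, 4, size=length)]


def coi_haplotype_sequences() -> dict[str, str]:
    """Full-length 658 bp reconstructions of the five reference haplotypes."""
    bg = _background(COI_LENGTH, "coi")
    out = {}
    for label, states in COI_HAPLOTYPE_STATES.items():
        seq = bg.copy()
        for pos, state in zip(COI_POSITIONS, states):
            seq[pos - 1] = state
        out[label] = "".join(seq)
    return out


def table2_coi_fixture() -> tuple[Alignment, list[SampleMeta]]:
    """The packaged 30-specimen mitochondrial reference alignment."""
    haps = coi_haplotype_sequences()
    seqs = tuple(
        AlignedSeq(sample_id=sid, locus="COI", residues=haps[hap])
        for sid, _, hap, _ in COI_SPECIMENS
    )
    meta = [
        SampleMeta(sid, group, COI_TAXON[group], locality)
        for sid, group, _, locality in COI_SPECIMENS
    ]
    return Alignment(locus="COI", seqs=seqs), meta


def _nuclear_fixture_alignment(locus: str) -> tuple[Alignment, list[CloneSet]]:
    length, sites = NUCLEAR_LOCI[locus]
    bg = _background(length, locus)
    seq_a = bg.copy()
    seq_b = bg.copy()
    for pos, state_a, state_b in sites:
        seq_a[pos - 1] = state_a
        seq_b[pos - 1] = state_b
    allele_a, allele_b = "".join(seq_a), "".join(seq_b)
    hybrid = _merge_alleles(allele_a, allele_b)

    seqs = []
    clone_sets: list[CloneSet] = []
    for sid, group, _, _ in COI_SPECIMENS:
        if group == PARENTAL_A:
            res = allele_a
        elif group == PARENTAL_B:
            res = allele_b
        else:
            res = hybrid
        if locus == "RPS5":
            chars = list(res)
            if sid in ("07FR", "16RUB"):  # shared polymorphism, both lineages
                chars[99] = "T" if chars[99] != "T" else "A"
            if sid in ("08FR", "17RUB"):  # low-level heterozygous call
                chars[199] = "R"
            res = "".join(chars)
        seqs.append(AlignedSeq(sample_id=sid, locus=locus, residues=res))
        if group == QUERY and sites:
            clones = tuple(
                AlignedSeq(
                    f"{sid}_{locus}_c{j:02d}",
                    locus,
                    allele_a if j <= 5 else allele_b,
                )
                for j in range(1, 11)
            )
            clone_sets.append(CloneSet(sample_id=sid, locus=locus, clones=clones))
    return Alignment(locus=locus, seqs=tuple(seqs)), clone_sets


def paper_full_fixture() -> tuple[dict[str, Alignment], list[SampleMeta], list[CloneSet]]:
    """Mito reference alignment plus synthetic nuclear stand-ins.

    Nuclear loci carry the published fragment lengths and diagnostic
    positions (403 bp with sites 213/271; 610 bp with none; 445 bp with
    sites 151/334); filler bases are arbitrary-but-fixed. Query samples are
    heterozygous at every diagnostic site and come with 10 clones per gene
    split 5/5 between the two alleles.
    """
    coi_aln, meta = table2_coi_fixture()
    alignments = {"COI": coi_aln}
    clone_sets: list[CloneSet] = []
    for locus in NUCLEAR_LOCI:
        aln, cs = _nuclear_fixture_alignment(locus)
        alignments[locus] = aln
        clone_sets.extend(cs)
    return alignments, meta, clone_sets


FIXTURE_NAMES = ("table2_coi", "paper_full")


def write_fixture(name: str, outdir: str | Path) -> list[Path]:
    """Materialize a packaged fixture; returns the paths written."""
    if name not in FIXTURE_NAMES:
        raise ParameterError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if name == "table2_coi":
        aln, meta = table2_coi_fixture()
        alignments: dict[str, Alignment] = {"COI": aln}
        clone_sets: list[CloneSet] = []
    else:
        alignments, meta, clone_sets = paper_full_fixture()
    for locus, aln in alignments.items():
        p = outdir / f"{locus}.fasta"
        write_alignment(aln, p)
        written.append(p)
    p = outdir / "metadata.tsv"
    write_metadata(meta, p)
    written.append(p)
    if clone_sets:
        clone_dir = outdir / "clones"
        clone_dir.mkdir(exist_ok=True)
        for cs in clone_sets:
            p = clone_dir / f"{cs.sample_id}_{cs.locus}_clones.fasta"
            with open(p, "w") as fh:
                for c in cs.clones:
                    fh.write(f">{c.sample_id}\n{c.residues}\n")
            written.append(p)
    return written
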