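"""Sequence data handling: alignments, sample tables, haplotypes, phased alleles.

The analyses downstream all consume a multiple-sequence alignment tied to a
sample table (sample id, sampling site, basin, coordinates).  This module
reads and validates those inputs, concatenates multi-locus mitochondrial
alignments, collapses redundant haplotypes, and applies the posterior-
probability filter used for computationally phased nuclear alleles.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "AlignmentError",
    "HaplotypeSet",
    "PhasedAllele",
    "read_alignment",
    "write_alignment",
    "read_sample_table",
    "validate_sample_table",
    "concatenate_loci",
    "collapse_haplotypes",
    "filter_phased_alleles",
]

#: Unambiguous bases plus IUPAC ambiguity codes, gap and missing.
VALID_CHARS = frozenset("ACGTRYSWKMBDHVN-")
#: Characters that do not resolve to a single base.
AMBIGUOUS_CHARS = frozenset("RYSWKMBDHVN-")


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, duplicate ids, bad symbols)."""


@dataclass
class Alignment:
    """An aligned set of equal-length nucleotide sequences with unique ids."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            dupes = {i for i in self.ids if self.ids.count(i) > 1}
            raise AlignmentError(f"duplicate sequence ids: {sorted(dupes)}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        bad = set("".join(self.seqs)) - VALID_CHARS
        if bad:
            raise AlignmentError(f"invalid characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def n(self) -> int:
        return len(self.ids)

    def records(self) -> Iterable[tuple[str, str]]:
        return zip(self.ids, self.seqs)

    def sequence(self, sample_id: str) -> str:
        return self.seqs[self.ids.index(sample_id)]

    def subset(self, ids: Sequence[str]) -> "Alignment":
        lookup = dict(zip(self.ids, self.seqs))
        return Alignment(list(ids), [lookup[i] for i in ids])


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_alignment(path: str | Path) -> Alignment:
    """Read a FASTA alignment; uppercases, maps U->T, validates shape and ids."""
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(_normalize(str(rec.seq)))
    if not ids:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(ids, seqs)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in alignment.records()
    ]
    SeqIO.write(records, str(path), "fasta")


SAMPLE_COLUMNS = ["sample_id", "site", "basin", "lat", "lon"]


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a sample table for required columns, unique ids and sane coordinates."""
    missing = [c for c in SAMPLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if table["sample_id"].duplicated().any():
        dupes = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    if (table["lat"].abs() > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    if (table["lon"].abs() > 180).any():
        raise ValueError("longitude outside [-180, 180]")
    return table


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read the CSV sample table (sample_id,site,basin,lat,lon)."""
    table = pd.read_csv(path, dtype={"sample_id": str, "site": str, "basin": str})
    return validate_sample_table(table)


def concatenate_loci(
    alignments: Sequence[Alignment],
    missing_policy: Literal["drop", "fill"] = "drop",
) -> Alignment:
    """Join per-locus alignments into one multi-locus alignment, id by id.

    Loci are joined in the order given (by convention CytB, ND2, ATPase8 for
    the mitochondrial set).  Samples absent from a locus are either dropped
    from the result (default — only complete multi-locus samples are kept) or
    padded with ``N`` across the missing segment.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    for aln in alignments:
        if aln.n == 0:
            raise AlignmentError("cannot concatenate an empty alignment")
    if missing_policy not in ("drop", "fill"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")

    if missing_policy == "drop":
        shared = set(alignments[0].ids)
        for aln in alignments[1:]:
            shared &= set(aln.ids)
        if not shared:
            raise AlignmentError("no sample ids shared across all loci")
        # preserve first-locus order
        ids = [i for i in alignments[0].ids if i in shared]
    else:
        seen: list[str] = []
        for aln in alignments:
            for i in aln.ids:
                if i not in seen:
                    seen.append(i)
        ids = seen

    parts: dict[str, list[str]] = {i: [] for i in ids}
    for aln in alignments:
        lookup = dict(zip(aln.ids, aln.seqs))
        pad = "N" * aln.length
        for i in ids:
            parts[i].append(lookup.get(i, pad))
    return Alignment(ids, ["".join(parts[i]) for i in ids])


@dataclass
class HaplotypeSet:
    """Distinct sequences with the sample ids carrying each of them."""

    labels: list[str]
    seqs: list[str]
    members: list[list[str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.labels)

    def counts(self) -> list[int]:
        return [len(m) for m in self.members]

    def to_alignment(self) -> Alignment:
        return Alignment(list(self.labels), list(self.seqs))

    def expand_ids(self) -> list[str]:
        return [s for m in self.members for s in m]

    def write_map(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["haplotype", "sample_id"])
            for label, member in zip(self.labels, self.members):
                for sample in member:
                    writer.writerow([label, sample])


def collapse_haplotypes(alignment: Alignment) -> HaplotypeSet:
    """Collapse identical sequences into haplotypes.

    Sequences must match exactly to share a haplotype: ambiguity codes are
    treated as distinct states, so a sequence with an ``N`` never merges into
    an otherwise identical unambiguous haplotype (conservative; frequency-
    based tools sometimes merge through ambiguities).
    Haplotypes are labelled H1, H2, ... in order of first appearance.
    """
    index: dict[str, int] = {}
    labels: list[str] = []
    seqs: list[str] = []
    members: list[list[str]] = []
    for sample, seq in alignment.records():
        if seq not in index:
            index[seq] = len(labels)
            labels.append(f"H{len(labels) + 1}")
            seqs.append(seq)
            members.append([])
        members[index[seq]].append(sample)
    return HaplotypeSet(labels, seqs, members)


@dataclass(frozen=True)
class PhasedAllele:
    """A computationally phased allele with its phase posterior probability."""

    sample_id: str
    sequence: str
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"phase probability {self.probability} outside [0, 1]"
            )


def filter_phased_alleles(
    alleles: Sequence[PhasedAllele], threshold: float = 0.60
) -> tuple[list[PhasedAllele], list[PhasedAllele]]:
    """Partition phased alleles into (kept, dropped) at a posterior threshold.

    An allele is kept only when its phase posterior is strictly greater than
    ``threshold`` (default 0.60): an allele resolved at exactly 60% is dropped.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    kept = [a for a in alleles if a.probability > threshold]
    dropped = [a for a in alleles if a.probability <= threshold]
    return kept, dropped


def write_filter_report(
    kept: Sequence[PhasedAllele],
    dropped: Sequence[PhasedAllele],
    path: str | Path,
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "probability", "status"])
        for allele in kept:
            writer.writerow([allele.sample_id, allele.probability, "kept"])
        for allele in dropped:
            writer.writerow([allele.sample_id, allele.probability, "dropped"])
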