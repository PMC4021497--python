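"""Genotype calling from aligned marker sequences.

Nodule isolates are sequenced at one or more marker loci (here the 16S-23S
ribosomal intergenic spacer, *ITS*, and the dinitrogenase alpha-subunit gene,
*NifD*).  Aligned haplotypes are collapsed into genotypes under a strict
identity rule: any single-nucleotide difference separates two genotypes.
Columns containing alignment gaps are removed before comparison, and positions
where either sequence carries an ambiguous base (N) are by default excluded
from both the identity comparison and the pairwise-difference counts.

The module also produces raw nucleotide-difference matrices (counts of
differing sites), the distance currency used downstream by the
population-structure statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_LOCI = ("ITS", "NifD")

#: IUPAC ambiguity codes other than N are normalised to N on input.
_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")


class FastaParseError(ValueError):
    """Malformed FASTA input (empty file, duplicate or unnamed records)."""


class AlignmentError(ValueError):
    """Records violate the alignment contract (unequal lengths, no columns)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence for one isolate at one locus."""

    isolate_id: str
    locus: str
    residues: str

    def __post_init__(self) -> None:
        if not self.isolate_id:
            raise ValueError("isolate_id must be non-empty")
        if not self.residues:
            raise ValueError(f"empty sequence for isolate {self.isolate_id!r}")
        seq = self.residues.upper()
        seq = "".join("N" if c in _IUPAC_AMBIGUOUS else c for c in seq)
        bad = set(seq) - set("ACGTN-")
        if bad:
            raise ValueError(
                f"isolate {self.isolate_id!r}: invalid residues {sorted(bad)}"
            )
        object.__setattr__(self, "residues", seq)


@dataclass
class HaplotypeAlignment:
    """An aligned set of sequences at one locus, one record per isolate."""

    locus: str
    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.isolate_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate isolate ids in {self.locus}: {dupes}")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) > 1:
            off = next(
                r.isolate_id
                for r in self.records
                if len(r.residues) != len(self.records[0].residues)
            )
            raise AlignmentError(
                f"unequal sequence lengths in {self.locus} alignment "
                f"(first offending record: {off!r})"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def isolate_ids(self) -> list[str]:
        return [r.isolate_id for r in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0].residues) if self.records else 0

    def to_matrix(self) -> np.ndarray:
        """Residues as a (records x columns) array of single bytes."""
        return np.array(
            [np.frombuffer(r.residues.encode(), dtype="S1") for r in self.records]
        )

    def has_gaps(self) -> bool:
        return any("-" in r.residues for r in self.records)


@dataclass
class GenotypeAssignment:
    """Partition of a locus's isolates into identical-sequence genotypes.

    Labels are assigned in order of first appearance (G1, G2, ...), so the
    partition is deterministic for a given input order and invariant, up to
    relabelling, under reordering.
    """

    locus: str
    labels: dict[str, str]  # isolate_id -> genotype label
    representatives: dict[str, str]  # genotype label -> representative sequence

    @property
    def n_genotypes(self) -> int:
        return len(self.representatives)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "isolate_id": list(self.labels),
                "locus": self.locus,
                "genotype_label": list(self.labels.values()),
            }
        )


@dataclass
class DistanceMatrix:
    """Symmetric matrix of nucleotide differences (or any distances)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")

    def subset(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="label")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))


def read_alignment(path, locus: str) -> HaplotypeAlignment:
    """Read an aligned FASTA file into a :class:`HaplotypeAlignment`.

    Headers must carry the isolate id as the record id.  All sequences must
    have equal length; a length mismatch raises :class:`AlignmentError`
    naming the offending record.
    """
    if locus not in VALID_LOCI:
        raise ValueError(f"locus must be one of {VALID_LOCI}, got {locus!r}")
    try:
        seqrecords = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise FastaParseError(f"cannot parse {path}: {exc}") from exc
    if not seqrecords:
        raise FastaParseError(f"no FASTA records found in {path}")
    records = []
    for rec in seqrecords:
        if not rec.id:
            raise FastaParseError(f"record without id in {path}")
        if not str(rec.seq):
            raise FastaParseError(f"record {rec.id!r} in {path} has no sequence")
        records.append(SequenceRecord(rec.id, locus, str(rec.seq)))
    return HaplotypeAlignment(locus, records)


def write_alignment(aln: HaplotypeAlignment, path) -> None:
    with open(path, "w") as fh:
        for rec in aln.records:
            fh.write(f">{rec.isolate_id}\n{rec.residues}\n")


def strip_indel_columns(
    aln: HaplotypeAlignment,
) -> tuple[HaplotypeAlignment, int]:
    """Remove every column in which any sequence carries a gap.

    Returns the restricted alignment (column order preserved) and the number
    of columns removed.  Raises :class:`AlignmentError` if no columns remain.
    """
    if not aln.records:
        raise AlignmentError("cannot strip columns of an empty alignment")
    mat = aln.to_matrix()
    keep = ~(mat == b"-").any(axis=0)
    n_removed = int((~keep).sum())
    if not keep.any():
        raise AlignmentError(
            f"{aln.locus}: all {aln.length} columns contain gaps; "
            "no informative sites remain"
        )
    if n_removed == 0:
        return aln, 0
    records = [
        replace(r, residues=mat[i, keep].tobytes().decode())
        for i, r in enumerate(aln.records)
    ]
    return HaplotypeAlignment(aln.locus, records), n_removed


def _sequences_identical(a: str, b: str, ignore_ambiguous: bool) -> bool:
    if not ignore_ambiguous:
        return a == b
    return all(x == y or x == "N" or y == "N" for x, y in zip(a, b))


def call_genotypes(
    aln: HaplotypeAlignment, ignore_ambiguous: bool = True
) -> GenotypeAssignment:
    """Collapse identical sequences into genotypes.

    Any single-nucleotide difference separates two genotypes.  When
    ``ignore_ambiguous`` is set (the default) positions where either sequence
    carries N are excluded from the comparison; because that relation is not
    transitive, each sequence is assigned greedily, in input order, to the
    first existing genotype whose *representative* (first member) it matches.
    """
    if aln.has_gaps():
        warnings.warn(
            f"{aln.locus}: alignment contains gap characters; "
            "strip_indel_columns before genotype calling",
            stacklevel=2,
        )
    labels: dict[str, str] = {}
    reps: dict[str, str] = {}
    for rec in aln.records:
        assigned = None
        for label, rep in reps.items():
            if _sequences_identical(rec.residues, rep, ignore_ambiguous):
                assigned = label
                break
        if assigned is None:
            assigned = f"G{len(reps) + 1}"
            reps[assigned] = rec.residues
        labels[rec.isolate_id] = assigned
    return GenotypeAssignment(aln.locus, labels, reps)


def representative_alignment(assignment: GenotypeAssignment) -> HaplotypeAlignment:
    """Alignment of one representative sequence per genotype label."""
    records = [
        SequenceRecord(label, assignment.locus, seq)
        for label, seq in assignment.representatives.items()
    ]
    return HaplotypeAlignment(assignment.locus, records)


def pairwise_differences(
    aln: HaplotypeAlignment, ignore_ambiguous: bool = True
) -> DistanceMatrix:
    """Count differing sites for every pair of sequences.

    Sites where either sequence carries N are skipped when
    ``ignore_ambiguous`` is set; otherwise N mismatches count.  Entries are
    raw counts of nucleotide differences (symmetric, zero diagonal).
    """
    mat = aln.to_matrix()
    n = len(aln.records)
    out = np.zeros((n, n))
    for i in range(n):
        diff = mat[i][None, :] != mat[i + 1 :]
        if ignore_ambiguous and diff.size:
            valid = (mat[i][None, :] != b"N") & (mat[i + 1 :] != b"N")
            diff = diff & valid
        counts = diff.sum(axis=1) if diff.size else np.zeros(0)
        out[i, i + 1 :] = counts
        out[i + 1 :, i] = counts
    return DistanceMatrix(aln.isolate_ids, out)


def joint_genotype_combinations(
    assignments: dict[str, GenotypeAssignment],
) -> int:
    """Number of distinct multi-locus label combinations.

    Counted over isolates genotyped at *all* supplied loci; isolates missing
    a locus are excluded from the count (they still carry their single-locus
    labels elsewhere).
    """
    if not assignments:
        return 0
    common = set.intersection(*(set(a.labels) for a in assignments.values()))
    combos = {
        tuple(assignments[loc].labels[iso] for loc in sorted(assignments))
        for iso in common
    }
    return len(combos)
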