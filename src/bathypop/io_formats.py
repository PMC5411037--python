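"""Input/output for the standard population-genetic file formats.

Two in-memory containers anchor the pipeline:

* :class:`GenotypeDataset` — diploid multilocus genotypes (microsatellites)
  with locality labels, stored as an integer array of allele codes where 0
  marks a missing half-call.
* :class:`HaplotypeDataset` — an aligned set of equal-length nucleotide
  sequences (mtDNA) with locality labels, plus haplotype collapsing.

The genepop "3-digit" dialect is read and written here (no reader for it
exists in the installed stack); FASTA parsing goes through Biopython.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenotypeDataset",
    "HaplotypeDataset",
    "SampleGrouping",
    "GenepopFormatError",
    "AlignmentError",
    "read_genepop",
    "write_genepop",
    "read_fasta_alignment",
]

MISSING = 0  # allele code for a missing half-call

_VALID_BASES = set(b"ACGTN-")


class GenepopFormatError(ValueError):
    """Raised when a genepop stream violates the dialect."""


class AlignmentError(ValueError):
    """Raised when FASTA records cannot form an alignment."""


@dataclass
class GenotypeDataset:
    """Diploid multilocus genotypes with locality labels.

    Parameters
    ----------
    ids : sequence of str
        Individual identifiers, one per row of ``calls``.
    localities : sequence of str
        Locality label per individual; labels partition the individuals.
    loci : sequence of str
        Locus names, one per column of ``calls``.
    calls : ndarray, shape (n_individuals, n_loci, 2)
        Integer allele codes; 0 encodes a missing half-call. Any 0 half-call
        marks the whole locus call missing for that individual.
    """

    ids: list[str]
    localities: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.localities = list(self.localities)
        self.loci = list(self.loci)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise ValueError("calls must have shape (n_individuals, n_loci, 2)")
        n, L, _ = self.calls.shape
        if n == 0 or L == 0:
            raise ValueError("need at least one individual and one locus")
        if len(self.ids) != n or len(self.localities) != n or len(self.loci) != L:
            raise ValueError("ids/localities/loci lengths do not match calls")
        # conservative missing-data rule: a half-missing call is fully missing
        half = (self.calls == MISSING).any(axis=2)
        self.calls[half] = MISSING

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        """Locality labels in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.localities:
            seen.setdefault(lab)
        return list(seen)

    def indices_of(self, population: str) -> np.ndarray:
        idx = np.array([i for i, p in enumerate(self.localities) if p == population])
        if idx.size == 0:
            raise KeyError(f"unknown population {population!r}")
        return idx

    def subset(self, individuals: Iterable[int]) -> "GenotypeDataset":
        idx = np.asarray(list(individuals), dtype=int)
        return GenotypeDataset(
            [self.ids[i] for i in idx],
            [self.localities[i] for i in idx],
            list(self.loci),
            self.calls[idx].copy(),
        )

    def relabel(self, mapping: Mapping[str, str]) -> "GenotypeDataset":
        """Pool/rename localities, e.g. into regions."""
        return GenotypeDataset(
            list(self.ids),
            [mapping.get(p, p) for p in self.localities],
            list(self.loci),
            self.calls.copy(),
        )

    def allele_counts(self, locus: int, population: str | None = None) -> dict[int, int]:
        """Counts of non-missing gene copies per allele code."""
        rows = self.calls[:, locus, :] if population is None else self.calls[self.indices_of(population), locus, :]
        genes = rows.ravel()
        genes = genes[genes != MISSING]
        vals, counts = np.unique(genes, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.localities == other.localities
            and self.loci == other.loci
            and self.calls.shape == other.calls.shape
            and bool(np.all(np.sort(self.calls, axis=2) == np.sort(other.calls, axis=2)))
        )


@dataclass
class HaplotypeDataset:
    """Aligned nucleotide sequences with per-sequence locality labels."""

    ids: list[str]
    localities: list[str]
    sequences: np.ndarray  # shape (n, L), dtype 'S1', uppercase

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.localities = list(self.localities)
        seqs = np.asarray(self.sequences)
        if seqs.dtype != np.dtype("S1"):
            seqs = np.array([list(s.upper()) if isinstance(s, str) else list(s) for s in self.sequences], dtype="S1")
        seqs = np.char.upper(seqs)
        if seqs.ndim != 2 or seqs.shape[0] == 0:
            raise AlignmentError("need at least one sequence")
        bad = set(np.unique(seqs).tolist()) - {c.to_bytes(1, "big") for c in _VALID_BASES}
        if bad:
            raise AlignmentError(f"invalid alignment characters: {sorted(bad)}")
        self.sequences = seqs
        if len(self.ids) != seqs.shape[0] or len(self.localities) != seqs.shape[0]:
            raise AlignmentError("ids/localities lengths do not match sequences")

    @classmethod
    def from_strings(
        cls,
        seqs: Sequence[str],
        ids: Sequence[str] | None = None,
        localities: Sequence[str] | None = None,
    ) -> "HaplotypeDataset":
        n = len(seqs)
        if n == 0:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"sequences of unequal length: {sorted(lengths)}")
        arr = np.array([list(s.upper()) for s in seqs], dtype="S1")
        ids = list(ids) if ids is not None else [f"seq{i + 1}" for i in range(n)]
        localities = list(localities) if localities is not None else ["?"] * n
        return cls(ids, localities, arr)

    # ------------------------------------------------------------------
    @property
    def n_sequences(self) -> int:
        return self.sequences.shape[0]

    @property
    def length(self) -> int:
        return self.sequences.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.localities:
            seen.setdefault(lab)
        return list(seen)

    def as_strings(self) -> list[str]:
        return [s.tobytes().decode() for s in self.sequences]

    def indices_of(self, population: str) -> np.ndarray:
        idx = np.array([i for i, p in enumerate(self.localities) if p == population])
        if idx.size == 0:
            raise KeyError(f"unknown population {population!r}")
        return idx

    def subset(self, individuals: Iterable[int]) -> "HaplotypeDataset":
        idx = np.asarray(list(individuals), dtype=int)
        return HaplotypeDataset(
            [self.ids[i] for i in idx],
            [self.localities[i] for i in idx],
            self.sequences[idx].copy(),
        )

    def relabel(self, mapping: Mapping[str, str]) -> "HaplotypeDataset":
        return HaplotypeDataset(
            list(self.ids),
            [mapping.get(p, p) for p in self.localities],
            self.sequences.copy(),
        )

    def haplotype_table(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Collapse identical sequences.

        Returns
        -------
        haplotypes : list of str
            Distinct sequences in order of first appearance.
        assignment : ndarray of int
            Haplotype index per sequence.
        counts : ndarray of int
            Occurrence count per haplotype.
        """
        seen: dict[str, int] = {}
        assignment = np.empty(self.n_sequences, dtype=int)
        for i, s in enumerate(self.as_strings()):
            assignment[i] = seen.setdefault(s, len(seen))
        counts = np.bincount(assignment, minlength=len(seen))
        return list(seen), assignment, counts

    def haplotype_counts_by_population(self) -> tuple[list[str], "np.ndarray"]:
        """Haplotype-by-population count matrix (haplotypes x populations)."""
        haps, assignment, _ = self.haplotype_table()
        pops = self.populations
        mat = np.zeros((len(haps), len(pops)), dtype=int)
        pop_index = {p: j for j, p in enumerate(pops)}
        for h, lab in zip(assignment, self.localities):
            mat[h, pop_index[lab]] += 1
        return pops, mat


# A grouping maps locality label -> group label (for AMOVA and pooling).
SampleGrouping = Mapping[str, str]


def validate_grouping(grouping: SampleGrouping, populations: Sequence[str]) -> None:
    missing = [p for p in populations if p not in grouping]
    if missing:
        raise ValueError(f"grouping lacks localities: {missing}")


# ----------------------------------------------------------------------
# genepop 3-digit dialect
# ----------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(source: str | io.TextIOBase) -> GenotypeDataset:
    """Parse a genepop 3-digit stream into a :class:`GenotypeDataset`.

    Accepts both one-locus-per-line and comma-separated locus headers.
    ``000000`` (or any half-call ``000``) encodes missing data. Populations
    are labelled by the id of the *last* individual in each POP block
    (genepop convention), de-duplicated with a numeric suffix if needed.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = source
        if not text.strip():
            raise GenepopFormatError("empty genepop stream")
        if "\n" not in text:
            with open(text, "r") as fh:
                text = fh.read()
    lines = text.splitlines()
    if not lines:
        raise GenepopFormatError("empty genepop stream")

    # title line, then locus names until the first POP
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            loci.extend([c.strip() for c in chunk.split(",") if c.strip()])
        i += 1
    if i == len(lines):
        raise GenepopFormatError("no POP keyword found")
    if not loci:
        raise GenepopFormatError("no locus names before first POP")

    blocks: list[list[tuple[str, list[int], int]]] = []
    current: list[tuple[str, list[int], int]] | None = None
    for lineno, line in enumerate(lines[i:], start=i + 1):
        if _POP_RE.match(line):
            current = []
            blocks.append(current)
            continue
        if not line.strip():
            continue
        if current is None:
            raise GenepopFormatError(f"line {lineno}: genotypes before first POP")
        if "," not in line:
            raise GenepopFormatError(f"line {lineno}: expected 'id , genotypes'")
        ident, _, geno = line.partition(",")
        fields = geno.split()
        if len(fields) != len(loci):
            raise GenepopFormatError(
                f"line {lineno}: {len(fields)} genotype fields for {len(loci)} loci"
            )
        alleles: list[int] = []
        for f in fields:
            if len(f) != 6 or not f.isdigit():
                raise GenepopFormatError(f"line {lineno}: bad diploid code {f!r}")
            alleles.extend((int(f[:3]), int(f[3:])))
        current.append((ident.strip(), alleles, lineno))

    ids: list[str] = []
    localities: list[str] = []
    rows: list[list[int]] = []
    used: set[str] = set()
    for block in blocks:
        if not block:
            raise GenepopFormatError("empty POP block")
        label = block[-1][0]
        if label in used:
            k = 2
            while f"{label}.{k}" in used:
                k += 1
            label = f"{label}.{k}"
        used.add(label)
        for ident, alleles, _ in block:
            ids.append(ident)
            localities.append(label)
            rows.append(alleles)

    calls = np.array(rows, dtype=np.int64).reshape(len(rows), len(loci), 2)
    return GenotypeDataset(ids, localities, loci, calls)


def write_genepop(dataset: GenotypeDataset, title: str = "bathypop export") -> str:
    """Serialize a dataset to the genepop 3-digit dialect.

    The dialect names each population by its last individual id, so that id
    is replaced by the locality label on output; read/write round-trips are
    exact on this canonical form (i.e. for any dataset obtained from
    :func:`read_genepop`).
    """
    if int(dataset.calls.max(initial=0)) > 999:
        raise ValueError("allele code > 999 cannot be encoded in 3 digits")
    out = [title]
    out.extend(dataset.loci)
    for pop in dataset.populations:
        out.append("POP")
        idx = dataset.indices_of(pop)
        for k, i in enumerate(idx):
            # genepop convention: population named by its last individual id;
            # emit that label so a round-trip preserves locality names.
            ident = pop if k == len(idx) - 1 else dataset.ids[i]
            genos = " ".join(f"{a:03d}{b:03d}" for a, b in dataset.calls[i])
            out.append(f"{ident} , {genos}")
    return "\n".join(out) + "\n"


# ----------------------------------------------------------------------
# FASTA
# ----------------------------------------------------------------------


def read_fasta_alignment(
    source: str | io.TextIOBase,
    locality_pattern: str | None = None,
    locality_table: Mapping[str, str] | None = None,
) -> HaplotypeDataset:
    """Read an aligned FASTA into a :class:`HaplotypeDataset`.

    Locality labels are taken from ``locality_table`` (id -> label) when
    given, otherwise from the first group of ``locality_pattern`` matched
    against each record id, otherwise left as ``"?"``.
    """
    if hasattr(source, "read"):
        handle = source
    else:
        text = source
        if "\n" in text or text.lstrip().startswith(">"):
            handle = io.StringIO(text)
        else:
            handle = open(text, "r")
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise AlignmentError("no FASTA records found")
    seqs = [str(r.seq).upper() for r in records]
    ids = [r.id for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(f"records of unequal length: {sorted(lengths)}")
    if locality_table is not None:
        labels = [locality_table.get(i, "?") for i in ids]
    elif locality_pattern is not None:
        rx = re.compile(locality_pattern)
        labels = []
        for i in ids:
            m = rx.search(i)
            labels.append(m.group(1) if m else "?")
    else:
        labels = ["?"] * len(ids)
    return HaplotypeDataset.from_strings(seqs, ids=ids, localities=labels)


def write_fasta(dataset: HaplotypeDataset) -> str:
    return "".join(f">{i}\n{s}\n" for i, s in zip(dataset.ids, dataset.as_strings()))
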