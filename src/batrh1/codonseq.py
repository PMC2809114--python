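"""In-frame codon alignments: reading, validation, translation, summary statistics.

Every downstream stage of the pipeline (partitioned distances, codon-model
fits, ancestral reconstruction, convergence detection) operates on the
:class:`CodonAlignment` defined here.  Sequences are nucleotide strings whose
length is a multiple of three; ambiguity codes and gaps are retained in the
sequence text but any codon containing one is treated as missing data by the
numeric machinery.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}
#: IUPAC ambiguity codes (plus N); tolerated in input, excluded from counting.
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")
GAP_CHARS = frozenset("-.")


class AlignmentError(ValueError):
    """Sequences do not form a valid alignment (unequal lengths, duplicates...)."""


class FrameError(ValueError):
    """Alignment length is not a multiple of three after offset trimming."""


class TranslationError(ValueError):
    """A codon cannot be translated (internal stop)."""


@dataclass(frozen=True, eq=False)  # identity equality: codes are cached singletons
class GeneticCode:
    """A genetic code: total map from the sense codons to amino acids.

    The 64 codons are partitioned into sense codons and stop codons;
    translation is deterministic.
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset

    def __post_init__(self):
        n = len(self.codon_to_aa) + len(self.stop_codons)
        if n != 64 or set(self.codon_to_aa) & self.stop_codons:
            raise ValueError("codons must partition into sense + stop (64 total)")

    @property
    def sense_codons(self) -> tuple:
        """Sense codons in lexicographic order (the model state order)."""
        return tuple(sorted(self.codon_to_aa))

    @functools.cached_property
    def codon_index(self) -> Mapping[str, int]:
        return {c: i for i, c in enumerate(self.sense_codons)}

    def is_sense(self, codon: str) -> bool:
        return codon in self.codon_to_aa

    def translate_codon(self, codon: str) -> str:
        """Translate one codon; '*' for stops, 'X' for anything unrecognised."""
        if codon in self.codon_to_aa:
            return self.codon_to_aa[codon]
        if codon in self.stop_codons:
            return "*"
        return "X"


@functools.lru_cache(maxsize=None)
def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (61 sense codons, 3 stops)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    return GeneticCode(
        table_id=1,
        codon_to_aa=dict(table.forward_table),
        stop_codons=frozenset(table.stop_codons),
    )


@dataclass
class CodonAlignment:
    """An aligned set of in-frame coding sequences.

    Invariants: all sequences equal length, length divisible by three, no
    duplicate taxon labels.  Enforced at construction.
    """

    taxa: list
    sequences: list

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa and sequences differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon labels: {dupes}")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"sequences have unequal lengths: {sorted(lengths)}")
        if self.sequences and len(self.sequences[0]) % 3 != 0:
            raise FrameError(
                f"alignment length {len(self.sequences[0])} is not a multiple of 3"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_codons(self) -> int:
        return self.n_sites // 3

    def codon(self, taxon_index: int, codon_site: int) -> str:
        """Codon at 1-based codon site for the given taxon row."""
        i = 3 * (codon_site - 1)
        return self.sequences[taxon_index][i : i + 3]

    def codons_of(self, taxon_index: int) -> list:
        s = self.sequences[taxon_index]
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def codon_column(self, codon_site: int) -> list:
        return [self.codon(i, codon_site) for i in range(self.n_taxa)]

    def drop_codon_columns(self, codon_sites: Iterable[int]) -> "CodonAlignment":
        """New alignment without the given 1-based codon columns."""
        drop = {int(s) for s in codon_sites}
        bad = [s for s in drop if not 1 <= s <= self.n_codons]
        if bad:
            raise IndexError(f"codon sites out of range 1..{self.n_codons}: {sorted(bad)}")
        keep = [s for s in range(1, self.n_codons + 1) if s not in drop]
        if not keep:
            raise AlignmentError("cannot drop every codon column")
        seqs = [
            "".join(seq[3 * (s - 1) : 3 * s] for s in keep) for seq in self.sequences
        ]
        return CodonAlignment(list(self.taxa), seqs)

    def to_fasta(self, path, wrap: int = 60) -> None:
        with open(path, "w") as fh:
            for t, s in zip(self.taxa, self.sequences):
                fh.write(f">{t}\n")
                for i in range(0, len(s), wrap):
                    fh.write(s[i : i + wrap] + "\n")


@dataclass
class ProteinAlignment:
    taxa: list
    sequences: list

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


@dataclass
class AlignmentStats:
    """Summary of an alignment: variable columns and coding sanity flags."""

    n_sites: int
    n_variable: int
    n_aa_variable: int
    has_internal_stops: bool
    has_gaps: bool

    def to_tsv(self) -> str:
        return (
            "n_sites\tn_variable\tn_aa_variable\n"
            f"{self.n_sites}\t{self.n_variable}\t{self.n_aa_variable}\n"
        )


def read_alignment(path, frame_offset: int = 0) -> CodonAlignment:
    """Read a FASTA codon alignment.

    ``frame_offset`` leading nucleotides are trimmed from every sequence
    before splitting into codons (0, 1 or 2 puts an arbitrary fragment in
    frame; larger values also discard whole leading codons).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    taxa = [r.id for r in records]
    seqs = [str(r.seq)[frame_offset:] for r in records]
    return CodonAlignment(taxa, seqs)


def write_alignment(aln: CodonAlignment, path) -> None:
    aln.to_fasta(path)


def validate_coding(aln: CodonAlignment, code: GeneticCode | None = None) -> AlignmentStats:
    """Compute alignment statistics and coding-sequence sanity flags.

    A nucleotide column is variable when >= 2 distinct unambiguous bases are
    observed in it.  A codon column is amino-acid variable when the
    translations of its unambiguous, gap-free codons differ.  Reports rather
    than raises: stop codons and gaps set flags.
    """
    code = code or standard_code()
    n_variable = 0
    has_gaps = False
    for j in range(aln.n_sites):
        col = {seq[j] for seq in aln.sequences}
        if col & GAP_CHARS:
            has_gaps = True
        observed = {c for c in col if c in NT_INDEX}
        if len(observed) >= 2:
            n_variable += 1
    n_aa_variable = 0
    has_stops = False
    for s in range(1, aln.n_codons + 1):
        aas = set()
        for codon in aln.codon_column(s):
            if codon in code.stop_codons:
                has_stops = True
            elif code.is_sense(codon):
                aas.add(code.codon_to_aa[codon])
        if len(aas) >= 2:
            n_aa_variable += 1
    return AlignmentStats(
        n_sites=aln.n_sites,
        n_variable=n_variable,
        n_aa_variable=n_aa_variable,
        has_internal_stops=has_stops,
        has_gaps=has_gaps,
    )


def translate(aln: CodonAlignment, code: GeneticCode | None = None) -> ProteinAlignment:
    """Translate every sequence; raises naming taxon and codon on a stop."""
    code = code or standard_code()
    prots = []
    for t, taxon in enumerate(aln.taxa):
        aas = []
        for s in range(1, aln.n_codons + 1):
            codon = aln.codon(t, s)
            if codon in code.stop_codons:
                raise TranslationError(
                    f"stop codon {codon} in taxon {taxon!r} at codon site {s}"
                )
            aas.append(code.translate_codon(codon))
        prots.append("".join(aas))
    return ProteinAlignment(list(aln.taxa), prots)


def codon_indices(seq: str, code: GeneticCode | None = None) -> np.ndarray:
    """Sequence -> per-codon index into ``code.sense_codons``; -1 where the
    codon is not a sense codon (gap, ambiguity, or stop)."""
    code = code or standard_code()
    idx = code.codon_index
    out = np.empty(len(seq) // 3, dtype=np.int32)
    for k in range(len(out)):
        out[k] = idx.get(seq[3 * k : 3 * k + 3], -1)
    return out


def alignment_codon_matrix(aln: CodonAlignment, code: GeneticCode | None = None) -> np.ndarray:
    """(n_taxa, n_codons) matrix of sense-codon indices, -1 for missing."""
    code = code or standard_code()
    return np.vstack([codon_indices(s, code) for s in aln.sequences])
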