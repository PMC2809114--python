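"""Li-Wu-Luo (1985) synonymous/nonsynonymous distances and related matrices.

Each position of each sense codon is allocated to a 0-fold, 2-fold or 4-fold
degenerate class (3-fold positions, e.g. Ile third positions, are collapsed
into the 2-fold class, following the original convention; mutations to stop
codons count as nonsynonymous).  Transition/transversion differences between
two sequences are corrected per class with the Kimura two-parameter formula;
one third of the 2-fold sites and all 4-fold sites are synonymous, the rest
nonsynonymous:

    Ks = (L2*A2 + L4*(A4+B4)) / (L2/3 + L4)
    Ka = (L2*B2 + L0*(A0+B0)) / (2*L2/3 + L0)

The module also provides the other distance modes used for tree building:
Poisson-corrected amino-acid distances and plain Kimura two-parameter
nucleotide distances.
"""

from __future__ import annotations

import functools
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .codonseq import (
    NT_INDEX,
    NUCLEOTIDES,
    CodonAlignment,
    GeneticCode,
    alignment_codon_matrix,
    codon_indices,
    standard_code,
    translate,
)

MODES = ("syn", "nonsyn", "aa_poisson", "nt_k2p")
_CLASSES = (0, 2, 4)
_CLASS_POS = {0: 0, 2: 1, 4: 2}  # row order in per-class arrays


class UndefinedDistanceWarning(UserWarning):
    """A pairwise distance is undefined (no sites, or saturated correction)."""


def classify_degeneracy(codon: str, code: GeneticCode | None = None) -> tuple:
    """Fold class (0, 2 or 4) of each of the three positions of a sense codon.

    A position is 4-fold when all three single-nucleotide changes are
    synonymous, 0-fold when none is, 2-fold otherwise (1-of-3 and 2-of-3
    cases included).  Changes that create a stop codon are nonsynonymous.
    """
    code = code or standard_code()
    if not code.is_sense(codon):
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = code.codon_to_aa[codon]
    out = []
    for pos in range(3):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if code.is_sense(mut) and code.codon_to_aa[mut] == aa:
                syn += 1
        out.append(4 if syn == 3 else (0 if syn == 0 else 2))
    return tuple(out)


@functools.lru_cache(maxsize=None)
def _tables(code: GeneticCode):
    """Per-code numpy tables: degeneracy class row and nt indices per codon."""
    sense = code.sense_codons
    deg = np.zeros((len(sense), 3), dtype=np.int8)
    nts = np.zeros((len(sense), 3), dtype=np.int8)
    for i, codon in enumerate(sense):
        deg[i] = classify_degeneracy(codon, code)
        nts[i] = [NT_INDEX[c] for c in codon]
    return deg, nts


def _is_transition(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Boolean mask: differing bases that are a transition (A<->G, C<->T)."""
    s = a + b  # with ACGT -> 0123, transitions are the only differing pairs
    return (a != b) & ((s == 2) | (s == 4))


def _k2p_class(P: float, Q: float):
    """K2P pieces for one site class: A (transition part), B (transversion
    part), with separate saturation flags (A needs both log arguments
    positive, B only the transversion one).

    Returns (A, B, a_defined, b_defined).
    """
    wa = 1.0 - 2.0 * P - Q
    wb = 1.0 - 2.0 * Q
    b_ok = wb > 0.0
    a_ok = wa > 0.0 and b_ok
    B = 0.5 * np.log(1.0 / wb) if b_ok else np.nan
    A = 0.5 * np.log(1.0 / wa) - 0.25 * np.log(1.0 / wb) if a_ok else np.nan
    return A, B, a_ok, b_ok


@dataclass
class PairwiseLWL:
    """LWL85 quantities for one sequence pair.

    ``L``, ``P``, ``Q``, ``A``, ``B``, ``K`` are length-3 arrays over the
    site classes (0-fold, 2-fold, 4-fold).  ``Ks``/``Ka`` are NaN when
    undefined; the flags say so explicitly.
    """

    L: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    A: np.ndarray
    B: np.ndarray
    K: np.ndarray
    class_defined: np.ndarray
    Ks: float
    Ka: float
    ks_defined: bool
    ka_defined: bool
    n_codons_compared: int


def _pairwise_lwl85_idx(idx1, idx2, deg, nts) -> PairwiseLWL:
    valid = (idx1 >= 0) & (idx2 >= 0)
    i1, i2 = idx1[valid], idx2[valid]
    L = np.zeros(3)
    ts = np.zeros(3)
    tv = np.zeros(3)
    for pos in range(3):
        c1 = deg[i1, pos]
        c2 = deg[i2, pos]
        for cls, row in _CLASS_POS.items():
            L[row] += 0.5 * np.count_nonzero(c1 == cls)
            L[row] += 0.5 * np.count_nonzero(c2 == cls)
        n1 = nts[i1, pos]
        n2 = nts[i2, pos]
        diff = n1 != n2
        is_ts = _is_transition(n1, n2)
        for cls, row in _CLASS_POS.items():
            # a difference is attributed half to each sequence's site class
            ts[row] += 0.5 * np.count_nonzero(is_ts & (c1 == cls))
            ts[row] += 0.5 * np.count_nonzero(is_ts & (c2 == cls))
            tv[row] += 0.5 * np.count_nonzero(diff & ~is_ts & (c1 == cls))
            tv[row] += 0.5 * np.count_nonzero(diff & ~is_ts & (c2 == cls))
    P = np.divide(ts, L, out=np.zeros(3), where=L > 0)
    Q = np.divide(tv, L, out=np.zeros(3), where=L > 0)
    A = np.full(3, np.nan)
    B = np.full(3, np.nan)
    a_def = np.zeros(3, dtype=bool)
    b_def = np.zeros(3, dtype=bool)
    for row in range(3):
        if L[row] > 0:
            A[row], B[row], a_def[row], b_def[row] = _k2p_class(P[row], Q[row])
    K = A + B
    defined = a_def & b_def
    L0, L2, L4 = L
    ks_den = L2 / 3.0 + L4
    ka_den = 2.0 * L2 / 3.0 + L0
    ks_ok = ks_den > 0 and (L2 == 0 or a_def[1]) and (L4 == 0 or defined[2])
    ka_ok = ka_den > 0 and (L2 == 0 or b_def[1]) and (L0 == 0 or defined[0])
    Ks = Ka = np.nan
    if ks_ok:
        Ks = ((L2 * A[1] if L2 else 0.0) + (L4 * K[2] if L4 else 0.0)) / ks_den
    if ka_ok:
        Ka = ((L2 * B[1] if L2 else 0.0) + (L0 * K[0] if L0 else 0.0)) / ka_den
    return PairwiseLWL(
        L=L, P=P, Q=Q, A=A, B=B, K=K, class_defined=defined,
        Ks=float(Ks), Ka=float(Ka), ks_defined=bool(ks_ok), ka_defined=bool(ka_ok),
        n_codons_compared=int(valid.sum()),
    )


def pairwise_lwl85(s1, s2, code: GeneticCode | None = None) -> PairwiseLWL:
    """LWL85 synonymous/nonsynonymous distances between two codon sequences.

    Accepts nucleotide strings of equal length (multiple of three); codons
    that are not sense codons in either sequence are excluded pairwise.
    Symmetric in the order of its arguments.
    """
    code = code or standard_code()
    if len(s1) != len(s2):
        raise ValueError("sequences differ in length")
    deg, nts = _tables(code)
    return _pairwise_lwl85_idx(codon_indices(s1, code), codon_indices(s2, code), deg, nts)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances under a named mode.

    Undefined entries are NaN and the offending pairs are listed in
    ``undefined_pairs``.
    """

    taxa: list
    d: np.ndarray
    mode: str
    undefined_pairs: list = field(default_factory=list)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")

    @property
    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.d)))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=self.taxa, columns=self.taxa)


def _nt_k2p(seq1: str, seq2: str) -> float:
    a = np.frombuffer(seq1.encode(), dtype=np.uint8)
    b = np.frombuffer(seq2.encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for nt, i in NT_INDEX.items():
        lut[ord(nt)] = i
    n1, n2 = lut[a], lut[b]
    valid = (n1 >= 0) & (n2 >= 0)
    n = int(valid.sum())
    if n == 0:
        return np.nan
    n1, n2 = n1[valid], n2[valid]
    ts = int(np.count_nonzero(_is_transition(n1, n2)))
    tv = int(np.count_nonzero(n1 != n2)) - ts
    A, B, a_ok, b_ok = _k2p_class(ts / n, tv / n)
    return A + B if (a_ok and b_ok) else np.nan


def distance_matrix(
    aln: CodonAlignment, mode: str, code: GeneticCode | None = None
) -> DistanceMatrix:
    """All pairwise distances under one of the modes in :data:`MODES`.

    syn / nonsyn: LWL85 Ks / Ka.  aa_poisson: -ln(1-p) on the amino-acid
    p-distance.  nt_k2p: Kimura two-parameter on all nucleotide sites.
    Undefined entries are NaN; a named warning lists each such pair.
    """
    code = code or standard_code()
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    n = aln.n_taxa
    d = np.zeros((n, n))
    undefined = []
    if mode in ("syn", "nonsyn"):
        deg, nts = _tables(code)
        mat = alignment_codon_matrix(aln, code)
        for i, j in itertools.combinations(range(n), 2):
            pw = _pairwise_lwl85_idx(mat[i], mat[j], deg, nts)
            v = pw.Ks if mode == "syn" else pw.Ka
            ok = pw.ks_defined if mode == "syn" else pw.ka_defined
            d[i, j] = d[j, i] = v if ok else np.nan
            if not ok:
                undefined.append((aln.taxa[i], aln.taxa[j]))
    elif mode == "aa_poisson":
        prot = translate(aln, code)
        for i, j in itertools.combinations(range(n), 2):
            a, b = prot.sequences[i], prot.sequences[j]
            pairs = [
                (x, y) for x, y in zip(a, b) if x not in "X-" and y not in "X-"
            ]
            if not pairs:
                d[i, j] = d[j, i] = np.nan
                undefined.append((aln.taxa[i], aln.taxa[j]))
                continue
            p = sum(x != y for x, y in pairs) / len(pairs)
            if p >= 1.0:
                d[i, j] = d[j, i] = np.nan
                undefined.append((aln.taxa[i], aln.taxa[j]))
            else:
                d[i, j] = d[j, i] = -np.log(1.0 - p)
    else:  # nt_k2p
        for i, j in itertools.combinations(range(n), 2):
            v = _nt_k2p(aln.sequences[i], aln.sequences[j])
            d[i, j] = d[j, i] = v
            if not np.isfinite(v):
                undefined.append((aln.taxa[i], aln.taxa[j]))
    if undefined:
        warnings.warn(
            f"{len(undefined)} undefined {mode} distance(s): {undefined}",
            UndefinedDistanceWarning,
            stacklevel=2,
        )
    return DistanceMatrix(list(aln.taxa), d, mode, undefined)
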