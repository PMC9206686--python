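"""Protein physicochemical profiling (ProtParam-style indices).

Translation of a coding sequence (standard genetic code) and the classical
Expasy-compatible indices of the resulting protein: average molecular weight,
isoelectric point on the Bjellqvist pKa set, Guruprasad instability index
(DIWV dipeptide weights), Ikai aliphatic index, and Kyte–Doolittle GRAVY.

Sequence handling goes through Biopython; the isoelectric point is located by
bisection on Biopython's Bjellqvist charge function until the net charge is
below 1e-4, so the stopping rule is on charge rather than pH resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .exceptions import EnzkitError, InsufficientDataError

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")
_DNA = set("ACGTN")

#: Kyte-Doolittle hydropathy values (for the brute-force oracle in tests and
#: for GRAVY itself, via Biopython's identical table).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence and its derived physicochemical indices."""

    id: str
    sequence: str
    length: int
    mw: float  # Da, average isotopic
    pi: float  # pH units
    instability_index: float
    aliphatic_index: float
    gravy: float

    def summary(self) -> str:
        return (
            f"Protein {self.id}: {self.length} aa\n"
            f"MW               {self.mw / 1000:.2f} kDa\n"
            f"pI               {self.pi:.2f}\n"
            f"Instability index {self.instability_index:.2f} "
            f"({'stable' if self.instability_index < 40 else 'unstable'})\n"
            f"Aliphatic index  {self.aliphatic_index:.2f}\n"
            f"GRAVY            {self.gravy:.3f}"
        )


def translate_sequence(nucleotides: str, frame: int = 1) -> str:
    """Translate a DNA string codon-by-codon with the standard genetic code.

    Translation starts at ``frame`` (1-based, 1..3) and stops at the first
    stop codon.  Codons containing N translate to X.
    """
    seq = nucleotides.strip().upper().replace("U", "T")
    if not seq or not set(seq) <= _DNA:
        raise EnzkitError("invalid sequence: alphabet must be ACGTN")
    if frame not in (1, 2, 3):
        raise EnzkitError("frame must be 1, 2 or 3")
    seq = seq[frame - 1 :]
    if len(seq) < 3:
        raise EnzkitError("invalid sequence: shorter than one codon")
    seq = seq[: len(seq) - len(seq) % 3]
    protein = str(Seq(seq).translate(table=1, to_stop=True))
    return protein


def isoelectric_point(sequence: str, charge_tol: float = 1e-4) -> float:
    """pI by bisection on the Bjellqvist charge function.

    Bisection narrows [0, 14] until the net charge at the midpoint is below
    ``charge_tol`` in magnitude; the charge is strictly decreasing in pH, so
    the bracket is valid from the start.
    """
    ip = IsoelectricPoint(sequence)
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = ip.charge_at_pH(mid)
        if abs(q) < charge_tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def aliphatic_index(sequence: str) -> float:
    """Ikai aliphatic index: X(Ala) + 2.9·X(Val) + 3.9·(X(Ile) + X(Leu)).

    X are mole percentages of the residues.
    """
    n = len(sequence)
    if n == 0:
        raise EnzkitError("invalid sequence: empty")
    mole = {aa: sequence.count(aa) / n * 100.0 for aa in "AVIL"}
    return mole["A"] + 2.9 * mole["V"] + 3.9 * (mole["I"] + mole["L"])


def protparam_profile(protein: str, seq_id: str = "protein") -> ProteinRecord:
    """Full physicochemical profile of a protein sequence.

    X (unknown) residues are excluded from every index, with a warning, and
    the effective length renormalized; any other non-standard letter is an
    error.
    """
    seq = protein.strip().upper()
    if not seq:
        raise EnzkitError("invalid sequence: empty")
    if not set(seq) <= _AA20 | {"X"}:
        bad = sorted(set(seq) - _AA20 - {"X"})
        raise EnzkitError(f"invalid sequence: non-standard residues {bad}")
    clean = seq.replace("X", "")
    if seq != clean:
        warnings.warn("X residues excluded from physicochemical indices", stacklevel=2)
    if len(clean) < 2:
        raise InsufficientDataError("invalid sequence: need at least 2 unambiguous residues")
    pa = ProteinAnalysis(clean)
    return ProteinRecord(
        id=seq_id,
        sequence=seq,
        length=len(seq),
        mw=float(pa.molecular_weight()),
        pi=float(isoelectric_point(clean)),
        instability_index=float(pa.instability_index()),
        aliphatic_index=float(aliphatic_index(clean)),
        gravy=float(pa.gravy()),
    )
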