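"""Protein-sequence consistency checks.

Covers the sequence-level bookkeeping around the 101-residue cationic
coagulant lectin from *Moringa oleifera* seeds (cMoL): parsing and
validation, residue composition, a simple pH-7 net charge (+1 per Arg/Lys,
-1 per Asp/Glu, His neutral, termini cancelling), Needleman-Wunsch global
percent identity against homologues, and the molarity implied by explicit
solvated-box particle counts (used to sanity-check simulation setups such as
"100 glucose in 27,500 waters = 0.2 M").
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from collections import Counter

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.SeqUtils import molecular_weight as _bio_mw

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: the 101-residue cMoL sequence (single-letter code)
CMOL_SEQUENCE = (
    "QARRPAIQRCCQQLRNIQPRCRCPSLRQAVQLAHQQQGQVGPQQVRQMYRVASNIPAICNLQPMYCPFGQ"
    "GQQQQQCRQQFLTHQRLRACQRFIRRQTQGR"
)

WATER_MW_G_MOL = 18.015

__all__ = [
    "AMINO_ACIDS",
    "CMOL_SEQUENCE",
    "ProteinSeq",
    "parse_sequence",
    "net_charge",
    "global_identity",
    "box_concentration",
    "molecular_weight",
]


@dataclass(frozen=True)
class ProteinSeq:
    """Validated single-letter protein sequence over the 20 canonical residues."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty sequence")
        for i, ch in enumerate(self.residues, start=1):
            if ch not in AMINO_ACIDS:
                raise ValueError(f"illegal residue {ch!r} at position {i}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def composition(self) -> dict:
        return dict(Counter(self.residues))


def parse_sequence(text: str, id: str = "seq") -> ProteinSeq:
    """Parse a raw single-letter string or a FASTA record.

    Whitespace is tolerated and case is folded; an illegal character raises
    a ValueError naming its 1-based position within the cleaned sequence.
    """
    text = text.strip()
    if text.startswith(">"):
        rec = next(SeqIO.parse(io.StringIO(text), "fasta"))
        return ProteinSeq(rec.id, str(rec.seq).upper())
    cleaned = "".join(text.split()).upper()
    return ProteinSeq(id, cleaned)


def read_fasta(path) -> list[ProteinSeq]:
    return [ProteinSeq(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs, path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


def net_charge(seq: ProteinSeq | str, model: str = "simple_pH7") -> int:
    """Integer net charge: +1 per R/K, -1 per D/E; H neutral; termini cancel."""
    if model != "simple_pH7":
        raise ValueError(f"unknown charge model {model!r}")
    residues = seq.residues if isinstance(seq, ProteinSeq) else parse_sequence(seq).residues
    pos = sum(residues.count(a) for a in "RK")
    neg = sum(residues.count(a) for a in "DE")
    return pos - neg


def molecular_weight(seq: ProteinSeq | str) -> float:
    """Average molecular weight of the (monomeric) chain in Da."""
    residues = seq.residues if isinstance(seq, ProteinSeq) else parse_sequence(seq).residues
    return float(_bio_mw(residues, seq_type="protein"))


def _aligner(substitution: str | None, gap_open: float, gap_extend: float,
             match: float, mismatch: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    if substitution is not None:
        aligner.substitution_matrix = substitution_matrices.load(substitution)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_alignment_score(a: str, b: str, substitution: str | None = "BLOSUM62",
                           gap_open: float = 10.0, gap_extend: float = 0.5,
                           match: float = 1.0, mismatch: float = -1.0) -> float:
    """Needleman-Wunsch global alignment score (affine gaps)."""
    return float(_aligner(substitution, gap_open, gap_extend, match, mismatch).score(a, b))


def global_identity(a: ProteinSeq | str, b: ProteinSeq | str,
                    substitution: str = "BLOSUM62",
                    gap_open: float = 10.0, gap_extend: float = 0.5,
                    denominator: str = "query") -> float:
    """Percent identity from a Needleman-Wunsch global alignment, 1 decimal.

    ``denominator`` selects what identical positions are divided by:
    ``query`` (length of ``a``; default), ``alignment`` (aligned columns
    including gaps) or ``shorter`` (the shorter of the two sequences,
    which makes the measure symmetric).
    """
    sa = a.residues if isinstance(a, ProteinSeq) else parse_sequence(a).residues
    sb = b.residues if isinstance(b, ProteinSeq) else parse_sequence(b).residues
    aligner = _aligner(substitution, gap_open, gap_extend, 1.0, -1.0)
    aln = aligner.align(sa, sb)[0]
    identities = 0
    aligned_cols = 0
    blocks_a, blocks_b = aln.aligned
    prev_a_end = prev_b_end = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        aligned_cols += (a0 - prev_a_end) + (b0 - prev_b_end)  # gap columns
        for i, j in zip(range(a0, a1), range(b0, b1)):
            aligned_cols += 1
            if sa[i] == sb[j]:
                identities += 1
        prev_a_end, prev_b_end = a1, b1
    aligned_cols += (len(sa) - prev_a_end) + (len(sb) - prev_b_end)
    if denominator == "query":
        denom = len(sa)
    elif denominator == "alignment":
        denom = aligned_cols
    elif denominator == "shorter":
        denom = min(len(sa), len(sb))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return round(100.0 * identities / denom, 1)


def box_concentration(n_solute: int, n_water: int,
                      water_density_g_ml: float = 0.997) -> float:
    """Molarity implied by particle counts in a solvated box.

    The box volume is approximated by the water volume alone (solute volume
    ignored): M = n_solute * rho * 1000 / (n_water * 18.015).
    """
    if n_solute <= 0 or n_water <= 0:
        raise ValueError("particle counts must be positive")
    return n_solute * water_density_g_ml * 1000.0 / (n_water * WATER_MW_G_MOL)
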