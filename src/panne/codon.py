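"""Codon-level substitution counting (NG86 core).

Implements synonymous/nonsynonymous site counting and pathway-averaged
difference counting for pairs of in-frame codon sequences, with the
Jukes-Cantor multiple-hit correction.  The genetic code is the bacterial
table 11, whose sense-codon translations coincide with the standard code.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

NUCLEOTIDES = "ACGT"

_TABLE11 = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in _TABLE11.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c, aa in _TABLE11.items() if aa != "*"))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

#: 16 dinucleotide prefixes whose codon third position is four-fold degenerate
FOURFOLD_PREFIXES = frozenset(
    p for p in ("".join(t) for t in itertools.product(NUCLEOTIDES, repeat=2))
    if len({_TABLE11[p + n] for n in NUCLEOTIDES}) == 1
    and _TABLE11[p + "A"] != "*"
)

_PURINES = frozenset("AG")


def translate(codon: str) -> str:
    """Amino acid (one letter, '*' for stop) of an unambiguous codon."""
    return _TABLE11[codon]


def is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def count_syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts for one sense codon.

    At each of the three positions the fraction of single-nucleotide
    neighbors that are synonymous is accumulated; mutations creating a stop
    codon are removed from the denominator, so ``s + n == 3`` always holds.

    Raises ``ValueError`` for stop codons or codons with ambiguous bases.
    """
    if codon not in CODON_INDEX:
        raise ValueError(f"not an unambiguous sense codon: {codon!r}")
    aa = _TABLE11[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if _TABLE11[mutant] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def _pathway_diffs(a: str, b: str) -> Optional[tuple[float, float]]:
    """Average (syn, nonsyn) difference counts over all minimal pathways.

    Pathways passing through a stop codon are excluded.  Returns ``None``
    when every ordering is blocked (does not occur for sense-codon pairs
    differing at <=2 positions under table 11, but handled defensively).
    """
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    total_s = total_n = 0.0
    n_paths = 0
    for order in itertools.permutations(positions):
        cur = a
        path_s = path_n = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _TABLE11[nxt] == _TABLE11[cur]:
                path_s += 1
            else:
                path_n += 1
            cur = nxt
        if ok:
            total_s += path_s
            total_n += path_n
            n_paths += 1
    if n_paths == 0:
        return None
    return total_s / n_paths, total_n / n_paths


def _build_tables():
    k = len(SENSE_CODONS)
    s_sites = np.empty(k)
    n_sites = np.empty(k)
    for i, c in enumerate(SENSE_CODONS):
        s_sites[i], n_sites[i] = count_syn_nonsyn_sites(c)
    sd = np.zeros((k, k))
    nd = np.zeros((k, k))
    blocked = np.zeros((k, k), dtype=bool)
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if i > j:
                sd[i, j] = sd[j, i]
                nd[i, j] = nd[j, i]
                blocked[i, j] = blocked[j, i]
                continue
            res = _pathway_diffs(a, b)
            if res is None:
                blocked[i, j] = True
            else:
                sd[i, j], nd[i, j] = res
    return s_sites, n_sites, sd, nd, blocked


S_SITES, N_SITES, SYN_DIFFS, NONSYN_DIFFS, _BLOCKED = _build_tables()


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); raises on saturation."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} at or beyond JC saturation")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


class SaturationError(ValueError):
    """Raised when a difference proportion exceeds the JC-correctable range."""


@dataclass
class PairwiseDivergence:
    """NG86 divergence between two strains' codon sequences."""

    strain_a: str
    strain_b: str
    dn: float
    ds: float
    dnds: Optional[float]
    n_codons_used: int
    saturated: bool = False

    @property
    def dsdn(self) -> Optional[float]:
        if self.dnds is None or self.dnds == 0:
            return None
        return self.ds / self.dn


def codon_indices(seq: str) -> np.ndarray:
    """Map an in-frame nucleotide string to sense-codon indices (-1 = skip).

    Codons containing gaps, ambiguity codes, or stops are marked -1.
    """
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not a multiple of 3")
    n = len(seq) // 3
    out = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        out[i] = CODON_INDEX.get(seq[3 * i: 3 * i + 3], -1)
    return out


def pairwise_dnds(
    seq_a: str,
    seq_b: str,
    strain_a: str = "a",
    strain_b: str = "b",
) -> PairwiseDivergence:
    """NG86 pairwise dN/dS with Jukes-Cantor correction.

    Codon columns containing a gap, ambiguity, or stop in either sequence
    are skipped.  Saturated pairs (p >= 3/4 on either class) are flagged and
    carry ``dnds=None`` so downstream windows exclude them.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    ia = codon_indices(seq_a.upper())
    ib = codon_indices(seq_b.upper())
    usable = (ia >= 0) & (ib >= 0)
    ia, ib = ia[usable], ib[usable]
    if ia.size:
        ok = ~_BLOCKED[ia, ib]
        ia, ib = ia[ok], ib[ok]
    n_used = int(ia.size)
    if n_used == 0:
        return PairwiseDivergence(strain_a, strain_b, 0.0, 0.0, None, 0)
    s_sites = 0.5 * (S_SITES[ia] + S_SITES[ib]).sum()
    n_sites = 0.5 * (N_SITES[ia] + N_SITES[ib]).sum()
    sd = SYN_DIFFS[ia, ib].sum()
    nd = NONSYN_DIFFS[ia, ib].sum()
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    try:
        ds = jukes_cantor(ps)
        dn = jukes_cantor(pn)
    except SaturationError:
        return PairwiseDivergence(
            strain_a, strain_b, math.nan, math.nan, None, n_used, saturated=True
        )
    dnds = dn / ds if ds > 0 else None
    return PairwiseDivergence(strain_a, strain_b, dn, ds, dnds, n_used)


def fourfold_sites(sequences: list[str]) -> list[int]:
    """Alignment column indices (0-based) of strictly four-fold third positions.

    A third-position column qualifies only if, in every row, the codon's
    first two bases form a four-fold degenerate prefix and all three bases
    are unambiguous nucleotides.
    """
    if not sequences:
        return []
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("alignment rows differ in length")
    if length % 3:
        raise ValueError("alignment length not a multiple of 3")
    cols = []
    upper = [s.upper() for s in sequences]
    for c in range(0, length, 3):
        ok = True
        for row in upper:
            codon = row[c:c + 3]
            if codon[:2] not in FOURFOLD_PREFIXES or codon[2] not in NUCLEOTIDES:
                ok = False
                break
        if ok:
            cols.append(c + 2)
    return cols
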